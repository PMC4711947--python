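"""Figure-analogue rendering: trajectories, the intercept construction, kinetics curves.

All quantitative content is computed by the model modules; these panels are
qualitative visual summaries.  The one quantitative element is the
post-puberty intercept construction: a least-squares line through the
post-puberty points of the total (maternal + paternal) trajectory, whose
age-zero intercept recovers the generation-time-effect intercept A* (in
genome-wide units, A* x H) exactly, because those points are collinear by
construction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import damage_repair as dr
from . import replication as rep
from .params import DamageRepairParams, ParameterError, ReplicationParams

__all__ = ["post_puberty_intercept", "plot_figures"]


def post_puberty_intercept(p: ReplicationParams, ages: Sequence[float]):
    """Least-squares age-zero intercept of the post-puberty total trajectory.

    ``ages`` must contain at least three ages ``>= P + t_sg``.  Returns
    ``(intercept, slope)`` in genome-wide units; the intercept equals
    ``a_star(p) * H`` and the slope ``mu4_m * c_m * H``.
    """
    ages_arr = np.asarray(ages, dtype=float)
    post = ages_arr[ages_arr >= p.P + p.t_sg]
    if post.size < 3:
        raise ParameterError("need at least three ages past P + t_sg for the intercept fit")
    totals = np.array([rep.total_mutation_count(p, a) for a in post])
    slope, intercept = np.polyfit(post, totals, 1)
    return float(intercept), float(slope)


def _grid_or_default(grid, default):
    g = np.asarray(default if grid is None else grid, dtype=float)
    if g.size == 0:
        raise ParameterError("empty grid")
    return np.sort(g)


def plot_figures(
    p: ReplicationParams,
    dp: DamageRepairParams,
    outdir,
    *,
    ages: Optional[Sequence[float]] = None,
    T_grid: Optional[Sequence[float]] = None,
    c_grid: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """Render the five standard panels into ``outdir``; return paths and the fitted intercept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ages_arr = _grid_or_default(ages, np.linspace(0, 50, 201))
    if np.any(ages_arr < 0):
        raise ParameterError("ages must be >= 0")
    k = dp.mu + dp.r
    T_arr = _grid_or_default(T_grid, np.geomspace(0.01 / k, 100.0 / k, 100))
    c_arr = _grid_or_default(c_grid, np.geomspace(0.01 * k, 100.0 * k, 100))
    paths: Dict[str, object] = {}

    # Age trajectories by sex and their sum.
    fem = rep.age_trajectory(p, "f", ages_arr)
    mal = rep.age_trajectory(p, "m", ages_arr)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ages_arr, fem, color="tab:red", label="maternal")
    ax.plot(ages_arr, mal, color="tab:blue", label="paternal")
    ax.plot(ages_arr, fem + mal, color="tab:purple", label="total (diploid)")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("expected replication-driven mutations")
    ax.legend()
    fig.savefig(outdir / "age_trajectory.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["age_trajectory"] = outdir / "age_trajectory.png"

    # Male bias vs reproductive age.
    post_ages = ages_arr[ages_arr >= p.P + p.t_sg]
    if post_ages.size:
        alphas = [rep.male_bias(p, a) for a in post_ages]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(post_ages, alphas, color="tab:green")
        ax.set_xlabel("parental age (years)")
        ax.set_ylabel(r"male bias $\alpha$")
        fig.savefig(outdir / "male_bias.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths["male_bias"] = outdir / "male_bias.png"

    # Intercept construction: extrapolate the post-puberty linear fit to age zero.
    fit_ages = np.linspace(p.P + p.t_sg, max(ages_arr.max(), p.P + p.t_sg + 10), 5)
    intercept, slope = post_puberty_intercept(p, fit_ages)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ages_arr, fem + mal, color="tab:purple", label="total per generation")
    xx = np.linspace(0, ages_arr.max() if ages_arr.size else 50, 50)
    ax.plot(xx, intercept + slope * xx, ":", color="tab:purple", label="post-puberty fit")
    ax.axhline(0, color="0.7", lw=0.5)
    ax.annotate(
        f"age-zero intercept = {intercept:.3g}",
        xy=(0, intercept),
        xytext=(0.05, 0.9),
        textcoords="axes fraction",
    )
    ax.set_xlabel("generation time G (years)")
    ax.set_ylabel("mutations per generation")
    ax.legend()
    fig.savefig(outdir / "intercept.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["intercept"] = outdir / "intercept.png"
    paths["fitted_intercept"] = intercept
    paths["fitted_slope"] = slope

    # Per-division mutation rate vs inter-division time, with the two limits.
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grids intentionally reach the equilibrium range
        m_T = dr.per_division_mutation_rate(dp, T_arr)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(T_arr, m_T, color="tab:blue", label="$M(T)$")
    ax.loglog(T_arr, 0.5 * dp.mu * T_arr, "--", color="tab:red", label=r"$\mu T/2$ (slow repair)")
    ax.axhline(dp.mu / (2 * k), ls="--", color="tab:gray", label=r"$\mu/2(\mu+r)$ (equilibrium)")
    if dp.epsilon > 0:
        ext = [dr.extended_per_division_mutation_rate(dp, float(t)) for t in T_arr]
        ax.loglog(T_arr, ext, color="tab:orange", label=f"with repair errors ($\\epsilon$={dp.epsilon:g})")
    ax.set_xlabel("inter-division time T")
    ax.set_ylabel("mutation rate per division")
    ax.legend(fontsize=8)
    fig.savefig(outdir / "per_division_rate.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["per_division_rate"] = outdir / "per_division_rate.png"

    # Per-time mutation rate vs division rate.
    m_c = dr.per_time_mutation_rate(dp, c_arr)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(c_arr, m_c, color="tab:blue")
    ax.axhline(dp.mu / 2, ls="--", color="tab:gray")
    ax.set_xlabel("cell division rate c")
    ax.set_ylabel("mutation rate per unit time m(c)")
    fig.savefig(outdir / "per_time_rate.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["per_time_rate"] = outdir / "per_time_rate.png"

    return paths
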