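"""Arrhenius break temperature (ABT) estimation from cardiac thermal ramps.

Ectotherm heart rate rises roughly exponentially with temperature until the
circulatory system fails, after which it collapses.  On Arrhenius axes --
``ln`` heart rate against inverse absolute temperature ``1000/K`` -- both
regimes are close to linear, and the temperature where the slope changes
(the Arrhenius break temperature) is a standard proxy for the upper thermal
limit of the animal.

The break is located by exhaustive search over admissible split positions:
each candidate split fits an ordinary least-squares line independently on
both sides and the split minimising the summed residual sum of squares wins.
No continuity between the two lines is imposed.  The ABT is reported as the
temperature of the last point assigned to the cool-side segment.  Throughout
this module "left" and "right" refer to temperature order (the cool segment
is left), even though the 1000/K axis runs the other way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ABS_ZERO_C",
    "AbtComparison",
    "ArrheniusSeries",
    "BreakpointFit",
    "CardiacTrace",
    "arrhenius_transform",
    "compare_abt_groups",
    "fit_breakpoint",
    "plot_arrhenius",
]

ABS_ZERO_C = 273.15


@dataclass(frozen=True)
class CardiacTrace:
    """A heart-rate trace along a warming ramp.

    ``temperature_c`` must be strictly increasing; ``rate_bpm`` positive.
    """

    temperature_c: np.ndarray
    rate_bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_c, dtype=float)
        r = np.asarray(self.rate_bpm, dtype=float)
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "rate_bpm", r)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("temperature and rate must be 1-D and equally long")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperature_c)


@dataclass(frozen=True)
class ArrheniusSeries:
    """Arrhenius coordinates of a trace: x = 1000/K, y = ln(rate)."""

    x: np.ndarray
    y: np.ndarray

    def temperature_c(self) -> np.ndarray:
        return 1000.0 / self.x - ABS_ZERO_C


def arrhenius_transform(trace: CardiacTrace) -> ArrheniusSeries:
    """Transform a trace to Arrhenius coordinates.

    Raises ``ValueError`` naming the first offending index if any rate is
    not strictly positive.
    """
    r = trace.rate_bpm
    bad = np.flatnonzero(~(r > 0))
    if bad.size:
        raise ValueError(
            f"non-positive heart rate {r[bad[0]]!r} at index {int(bad[0])}: "
            "ln(rate) undefined"
        )
    x = 1000.0 / (trace.temperature_c + ABS_ZERO_C)
    return ArrheniusSeries(x=x, y=np.log(r))


def _cumulative_rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS of the OLS line through points 0..k, for every prefix k."""
    m = np.arange(1, len(x) + 1, dtype=float)
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cxy, cyy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)
    sxx = cxx - cx * cx / m
    sxy = cxy - cx * cy / m
    syy = cyy - cy * cy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy - np.where(sxx > 0, sxy * sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    return np.maximum(rss, 0.0)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and RSS of a simple OLS fit."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx) if sxx > 0 else 0.0
    intercept = ym - slope * xm
    rss = float(((y - slope * x - intercept) ** 2).sum())
    return slope, intercept, rss


@dataclass
class BreakpointFit:
    """Result of the exhaustive two-segment Arrhenius regression."""

    abt_celsius: float
    break_index: int  # index of the last point on the cool-side segment
    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    rss_left: float
    rss_right: float
    rss_total: float
    rss_profile: np.ndarray  # total RSS per candidate break index
    candidate_indices: np.ndarray
    single_line_rss: float
    degenerate: bool


def fit_breakpoint(
    series: ArrheniusSeries,
    min_segment: int = 3,
    degenerate_tol: float = 1e-9,
) -> BreakpointFit:
    """Locate the Arrhenius break by exhaustive two-segment OLS.

    Every split leaving at least ``min_segment`` points on each side is
    evaluated; ties in total RSS are resolved toward the lower break
    temperature.  When the RSS profile is flat relative to the total
    variance of ``y`` (range < ``degenerate_tol`` x total sum of squares)
    the trace carries no distinguishable break and ``degenerate`` is set;
    the reported ABT is then not meaningful.
    """
    x, y = np.asarray(series.x, float), np.asarray(series.y, float)
    n = len(x)
    if min_segment < 2:
        raise ValueError("min_segment must be at least 2")
    if n < 2 * min_segment:
        raise ValueError(
            f"need at least {2 * min_segment} points for two segments of "
            f"{min_segment}; got {n}"
        )
    left_rss = _cumulative_rss(x, y)
    right_rss = _cumulative_rss(x[::-1], y[::-1])[::-1]
    # break index k = last point of the left segment; right segment starts k+1
    candidates = np.arange(min_segment - 1, n - min_segment)
    profile = left_rss[candidates] + right_rss[candidates + 1]
    # temperatures increase with index; argmin takes the first (= coolest) tie
    best = int(candidates[np.argmin(profile)])

    ls, li, lr = _ols(x[: best + 1], y[: best + 1])
    rs, ri, rr = _ols(x[best + 1 :], y[best + 1 :])
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = bool(tss == 0.0 or float(np.ptp(profile)) < degenerate_tol * tss)
    _, _, single_rss = _ols(x, y)
    return BreakpointFit(
        abt_celsius=float(1000.0 / x[best] - ABS_ZERO_C),
        break_index=best,
        left_slope=ls,
        left_intercept=li,
        right_slope=rs,
        right_intercept=ri,
        rss_left=lr,
        rss_right=rr,
        rss_total=lr + rr,
        rss_profile=profile,
        candidate_indices=candidates,
        single_line_rss=single_rss,
        degenerate=degenerate,
    )


@dataclass
class AbtComparison:
    """One-way ANOVA of ABTs across groups plus pairwise mean differences."""

    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    pairwise_differences: dict[tuple[str, str], float]


def compare_abt_groups(abts_by_group: Mapping[str, Sequence[float]]) -> AbtComparison:
    """Compare ABT distributions between groups.

    Requires at least two groups with at least two values each.  Pairwise
    differences are ``mean(a) - mean(b)`` for every ordered pair in input
    order, reported in degrees Celsius.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in abts_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least two values for ANOVA")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups.values())
    means = {k: float(v.mean()) for k, v in groups.items()}
    names = list(groups)
    pairwise = {
        (a, b): means[a] - means[b] for a in names for b in names if a != b
    }
    return AbtComparison(
        f_statistic=float(f),
        p_value=float(p),
        group_means=means,
        pairwise_differences=pairwise,
    )


def plot_arrhenius(series: ArrheniusSeries, fit: BreakpointFit | None = None, path=None):
    """Plot a trace in Arrhenius coordinates with the fitted segments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(series.x, series.y, ".", ms=3, color="0.4", label="trace")
    if fit is not None and not fit.degenerate:
        k = fit.break_index
        for sl, ic, seg in (
            (fit.left_slope, fit.left_intercept, slice(0, k + 1)),
            (fit.right_slope, fit.right_intercept, slice(k + 1, None)),
        ):
            xs = series.x[seg]
            ax.plot(xs, sl * xs + ic, "-", lw=1.5)
        ax.axvline(series.x[k], ls="--", color="tab:red", lw=1)
        ax.set_title(f"ABT = {fit.abt_celsius:.2f} °C")
    ax.set_xlabel("1000 / K")
    ax.set_ylabel("ln(heart rate, bpm)")
    ax.invert_xaxis()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
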