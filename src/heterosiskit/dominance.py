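"""Dominance-mode classification of hybrid gene expression.

For each gene measured in two parental populations (P1, P2) and their F1
hybrid, the degree of dominance is the ratio of the dominance deviation
``d = F1 - mu`` (departure of the hybrid from the mid-parent value
``mu = (P1 + P2) / 2``) to the additive effect magnitude ``|a|`` taken from
the parental gap.  The ratio locates the gene on the classical
additivity--dominance spectrum:

========  ======================  ==========================================
label     d/|a| interval          meaning
========  ======================  ==========================================
UDO       (-inf, -1.2)            under-dominance (below both parents)
LPD       [-1.2, -0.8)            low-parent dominance
NPD       [-0.8, -0.2)            negative partial dominance
ADD       [-0.2, 0.2]             additive (hybrid near mid-parent)
PPD       (0.2, 0.8]              positive partial dominance
HPD       (0.8, 1.2]              high-parent dominance
ODO       (1.2, +inf)             over-dominance (above both parents)
========  ======================  ==========================================

Genes whose parents are (numerically) equally expressed have no defined
ratio and are reported with the ``PARENT_EQUAL`` sentinel rather than
classified.

Two denominator conventions are provided.  ``full_gap`` divides by the full
parental difference ``|P1 - P2|`` (so a hybrid sitting exactly on the high
parent scores 0.5); ``half_gap`` divides by half the difference, the
classical quantitative-genetics additive effect ``a = |P1 - P2| / 2`` (the
same hybrid scores 1.0, i.e. high-parent dominance).  ``half_gap`` ratios
are exactly twice ``full_gap`` ratios; every output row carries its
convention tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MODE_LABELS",
    "PARENT_EQUAL",
    "ModeSummary",
    "classify_matrix",
    "classify_mode",
    "classify_ratios",
    "compute_d_over_a",
    "summarize_modes",
]

#: Classification labels on the ratio scale, low to high.
MODE_LABELS = ("UDO", "LPD", "NPD", "ADD", "PPD", "HPD", "ODO")

#: Sentinel label for genes with |P1 - P2| below epsilon (no defined ratio).
PARENT_EQUAL = "PARENT_EQUAL"

_CONVENTIONS = ("full_gap", "half_gap")

# Interval edges between consecutive MODE_LABELS.  Closure follows the
# published criteria table: ADD is closed on both sides, the dominance and
# partial-dominance intervals are closed above / open below on the positive
# side and mirrored (closed below, open above... i.e. [lo, hi)) on the
# negative side, so every real ratio receives exactly one label.
_EDGES = (-1.2, -0.8, -0.2, 0.2, 0.8, 1.2)


def compute_d_over_a(
    p1: float,
    p2: float,
    f1: float,
    convention: str = "full_gap",
    epsilon: float = 1e-8,
) -> float | str:
    """Return the dominance ratio d/|a|, or ``PARENT_EQUAL`` when undefined.

    Parameters
    ----------
    p1, p2
        Parental group-mean expression values (any common scale).
    f1
        Hybrid group-mean expression on the same scale.
    convention
        ``"full_gap"`` divides by ``|p1 - p2|``; ``"half_gap"`` by
        ``|p1 - p2| / 2``.
    epsilon
        Parental gaps below this threshold yield the ``PARENT_EQUAL``
        sentinel instead of a division.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {_CONVENTIONS}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    for name, v in (("p1", p1), ("p2", p2), ("f1", f1)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite: {v!r}")
    gap = abs(p1 - p2)
    if gap < epsilon:
        return PARENT_EQUAL
    mu = 0.5 * (p1 + p2)
    denom = gap if convention == "full_gap" else gap / 2.0
    return (f1 - mu) / denom


def classify_mode(ratio: float) -> str:
    """Map a finite d/|a| ratio to its expression-mode label."""
    if isinstance(ratio, str):
        raise TypeError("classify_mode expects a numeric ratio; got a sentinel/label")
    if math.isnan(ratio):
        raise ValueError("cannot classify NaN ratio")
    if ratio < -1.2:
        return "UDO"
    if ratio < -0.8:
        return "LPD"
    if ratio < -0.2:
        return "NPD"
    if ratio <= 0.2:
        return "ADD"
    if ratio <= 0.8:
        return "PPD"
    if ratio <= 1.2:
        return "HPD"
    return "ODO"


def classify_ratios(ratios: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_mode` (NaN entries raise)."""
    r = np.asarray(ratios, dtype=float)
    if np.isnan(r).any():
        raise ValueError("cannot classify NaN ratios")
    # np.searchsorted with side='left' puts x == edge into the lower bin,
    # matching closed-above intervals; the two [lo, hi) negative-side
    # intervals need their lower edge pulled back in.
    idx = np.searchsorted(_EDGES, r, side="left")
    labels = np.asarray(MODE_LABELS)[idx]
    labels[r == -1.2] = "LPD"
    labels[r == -0.8] = "NPD"
    labels[r == -0.2] = "ADD"
    return labels


def classify_matrix(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str,
    normalization: str = "tmm_linear",
    convention: str = "full_gap",
    epsilon: float = 1e-8,
    pseudocount: float = 0.5,
    gate_alpha: float | None = None,
) -> tuple[pd.DataFrame, pd.Index]:
    """Classify every detected gene of one condition into a dominance mode.

    Group means for the three populations (``P1``, ``P2``, ``F1``) are taken
    over the replicates of ``condition`` after TMM scaling; genes with zero
    counts in every sample of the condition are dropped as undetected.

    Parameters
    ----------
    counts
        Genes x samples integer count matrix (gene ids as index).
    samples
        Sample sheet with columns ``sample``, ``population`` (P1/P2/F1),
        ``condition`` and ``replicate``; ``sample`` entries must match the
        count-matrix columns.
    condition
        Condition whose samples are classified (e.g. ``"control"``/``"heat"``).
    normalization
        ``"tmm_linear"`` classifies TMM-scaled counts-per-million group
        means; ``"log2"`` classifies replicate means of
        ``log2(CPM + pseudocount)``.
    convention, epsilon
        Passed through to the ratio computation.
    gate_alpha
        Optional significance gate (off by default): genes whose hybrid
        replicates are not significantly different from the per-replicate
        mid-parent values (Welch test, p >= ``gate_alpha``) are reported as
        ``ADD`` regardless of their point ratio.  This implements the
        reading of "non-additive" as *significantly* different from the
        parental expectation.

    Returns
    -------
    calls, undetected
        ``calls`` has one row per detected gene with columns ``P1``, ``P2``,
        ``F1``, ``mu``, ``ratio`` (NaN for PARENT_EQUAL rows), ``label`` and
        ``convention``; ``undetected`` is the index of dropped genes.
    """
    from .de import tmm_normalize

    if normalization not in ("tmm_linear", "log2"):
        raise ValueError(f"unknown normalization {normalization!r}")
    sub = samples[samples["condition"] == condition]
    missing = [p for p in ("P1", "P2", "F1") if p not in set(sub["population"])]
    if missing:
        raise ValueError(
            f"condition {condition!r} is missing population(s) {missing}; "
            "classification needs both parents and the hybrid"
        )
    cols = list(sub["sample"])
    mat = counts[cols]
    detected = mat.sum(axis=1) > 0
    undetected = mat.index[~detected]
    mat = mat.loc[detected]

    norm = tmm_normalize(mat)
    cpm = norm.cpm
    if normalization == "log2":
        cpm = np.log2(cpm + pseudocount)

    means: dict[str, pd.Series] = {}
    for pop in ("P1", "P2", "F1"):
        pop_cols = list(sub.loc[sub["population"] == pop, "sample"])
        means[pop] = cpm[pop_cols].mean(axis=1)

    p1, p2, f1 = means["P1"], means["P2"], means["F1"]
    gap = (p1 - p2).abs()
    mu = 0.5 * (p1 + p2)
    denom = gap if convention == "full_gap" else gap / 2.0
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")

    equal = gap < epsilon
    ratio = pd.Series(np.nan, index=mat.index)
    ratio[~equal] = (f1[~equal] - mu[~equal]) / denom[~equal]

    label = pd.Series(PARENT_EQUAL, index=mat.index, dtype=object)
    label[~equal] = classify_ratios(ratio[~equal].to_numpy())

    if gate_alpha is not None:
        from scipy import stats as _stats

        f1_reps = cpm[list(sub.loc[sub["population"] == "F1", "sample"])].to_numpy()
        p1_reps = cpm[list(sub.loc[sub["population"] == "P1", "sample"])].to_numpy()
        p2_reps = cpm[list(sub.loc[sub["population"] == "P2", "sample"])].to_numpy()
        k = min(p1_reps.shape[1], p2_reps.shape[1])
        mid_reps = 0.5 * (p1_reps[:, :k] + p2_reps[:, :k])
        with np.errstate(divide="ignore", invalid="ignore"):
            _, gate_p = _stats.ttest_ind(f1_reps, mid_reps, axis=1, equal_var=False)
        gate_p = np.where(np.isnan(gate_p), 1.0, gate_p)
        not_shifted = (gate_p >= gate_alpha) & ~equal.to_numpy()
        label[not_shifted] = "ADD"

    calls = pd.DataFrame(
        {
            "P1": p1,
            "P2": p2,
            "F1": f1,
            "mu": mu,
            "ratio": ratio,
            "label": label,
            "convention": convention,
        }
    )
    calls.index.name = "gene"
    return calls, undetected


def _pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to two decimals, computed exactly."""
    if denom == 0:
        return 0.0
    q = (Decimal(count) * 100) / Decimal(denom)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ModeSummary:
    """Per-class counts and shares for a set of mode calls.

    ``nonadditive_pct`` is the share of non-additive genes among all
    classified genes; ``class_pct`` holds per-label shares over the chosen
    denominator (by default the non-additive genes, which is how class
    proportions are conventionally quoted).
    """

    counts: dict[str, int]
    detected: int
    parent_equal: int
    non_additive: int
    nonadditive_pct: float
    class_pct: dict[str, float]
    denominator: str = "non_additive"

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) + self.parent_equal == self.detected


def summarize_modes(
    calls: pd.DataFrame | Iterable[str] | Mapping[str, int],
    denominator: str = "non_additive",
) -> ModeSummary:
    """Summarise mode calls into counts and rounded percentages.

    ``calls`` may be the DataFrame from :func:`classify_matrix`, a plain
    iterable of labels, or a mapping label -> count.
    """
    if denominator not in ("non_additive", "detected"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if isinstance(calls, pd.DataFrame):
        labels = calls["label"]
        tally = labels.value_counts().to_dict()
    elif isinstance(calls, Mapping):
        tally = {str(k): int(v) for k, v in calls.items()}
    else:
        tally = pd.Series(list(calls), dtype=object).value_counts().to_dict()
    unknown = set(tally) - set(MODE_LABELS) - {PARENT_EQUAL}
    if unknown:
        raise ValueError(f"unknown labels in input: {sorted(unknown)}")
    detected = int(sum(tally.values()))
    if detected == 0:
        raise ValueError("no mode calls to summarise")
    parent_equal = int(tally.get(PARENT_EQUAL, 0))
    counts = {lab: int(tally.get(lab, 0)) for lab in MODE_LABELS}
    non_additive = detected - counts["ADD"] - parent_equal
    if denominator == "non_additive":
        denom = non_additive
        share_labels = [lab for lab in MODE_LABELS if lab != "ADD"]
    else:
        denom = detected
        share_labels = list(MODE_LABELS)
    class_pct = {lab: _pct(counts[lab], denom) for lab in share_labels}
    return ModeSummary(
        counts=counts,
        detected=detected,
        parent_equal=parent_equal,
        non_additive=non_additive,
        nonadditive_pct=_pct(non_additive, detected),
        class_pct=class_pct,
        denominator=denominator,
    )
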