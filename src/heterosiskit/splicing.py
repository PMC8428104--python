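"""Percent-spliced-in (psi) computation and the splice-divergence filter.

An alternative-splicing event is summarised per sample by its inclusion
junction count I and skipping junction count S.  Because the inclusion
isoform spans more junctions than the skipping one, raw counts are
normalised by the effective junction lengths lI and lS before forming the
inclusion fraction

    psi = (I / lI) / (I / lI + S / lS),

undefined when the event has no coverage (I = S = 0).  The between-condition
divergence of an event is ``delta psi`` = mean control psi - mean heat psi.

Event-level testing is a stand-in for likelihood-ratio frameworks built on
junction-count models: the default is a Welch t-test on replicate psi
values, with an exact/sampled label-permutation test as the seed-fixed
alternative.  The significance filter retains events with mean junction
reads across all samples strictly greater than 5, ``|delta psi| >= 0.1``
and BH FDR < 0.05.

Event tables are wide pandas DataFrames, one row per event, with columns
``event_id``, ``gene_id``, ``event_type`` (SE/MXE/A5SS/A3SS/RI), ``li``,
``ls`` and per-sample counts ``I_<cond>_<r>`` / ``S_<cond>_<r>``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "EVENT_TYPES",
    "FilterSummary",
    "compute_psi",
    "event_psi",
    "filter_events",
    "test_events",
]

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")


def compute_psi(inclusion, skipping, li: float = 2.0, ls: float = 1.0):
    """Length-normalised inclusion fraction; NaN where I = S = 0.

    Accepts scalars or arrays; negative counts or lengths below 1 raise.
    """
    i = np.asarray(inclusion, dtype=float)
    s = np.asarray(skipping, dtype=float)
    if (i < 0).any() or (s < 0).any():
        raise ValueError("junction counts must be non-negative")
    if li < 1 or ls < 1:
        raise ValueError("effective lengths must be >= 1")
    ni, ns = i / li, s / ls
    denom = ni + ns
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, ni / np.where(denom > 0, denom, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def _sample_columns(events: pd.DataFrame, conditions=("ctrl", "heat")) -> dict[str, list[tuple[str, str]]]:
    """Map condition -> ordered (I-column, S-column) replicate pairs."""
    out: dict[str, list[tuple[str, str]]] = {}
    for cond in conditions:
        reps = sorted(
            int(c.rsplit("_", 1)[1])
            for c in events.columns
            if c.startswith(f"I_{cond}_")
        )
        if not reps:
            raise ValueError(f"no junction-count columns found for condition {cond!r}")
        pairs = []
        for r in reps:
            ic, sc = f"I_{cond}_{r}", f"S_{cond}_{r}"
            if sc not in events.columns:
                raise ValueError(f"missing skipping column {sc!r}")
            pairs.append((ic, sc))
        out[cond] = pairs
    return out


def event_psi(events: pd.DataFrame, conditions=("ctrl", "heat")) -> dict[str, np.ndarray]:
    """Per-condition replicate psi matrices (events x replicates)."""
    cols = _sample_columns(events, conditions)
    li = events["li"].to_numpy(dtype=float)[:, None]
    ls = events["ls"].to_numpy(dtype=float)[:, None]
    out = {}
    for cond, pairs in cols.items():
        i = events[[ic for ic, _ in pairs]].to_numpy(dtype=float)
        s = events[[sc for _, sc in pairs]].to_numpy(dtype=float)
        ni, ns = i / li, s / ls
        denom = ni + ns
        with np.errstate(invalid="ignore"):
            out[cond] = np.where(denom > 0, ni / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def _permutation_p(values: np.ndarray, n_a: int, rng: np.random.Generator, max_exact: int = 1000) -> float:
    """Two-sided label-permutation p for a difference of group means.

    Enumerates all ``C(n, n_a)`` labelings when that count is at most
    ``max_exact`` (the identity labeling is included, so p >= 1/#labelings);
    otherwise draws 2000 random labelings.
    """
    n = len(values)
    obs = abs(values[:n_a].mean() - values[n_a:].mean())
    total = math.comb(n, n_a)
    idx = np.arange(n)
    if total <= max_exact:
        assignments = list(combinations(range(n), n_a))
    else:
        assignments = [tuple(rng.permutation(n)[:n_a]) for _ in range(2000)]
    hits = 0
    for a in assignments:
        mask = np.zeros(n, dtype=bool)
        mask[list(a)] = True
        stat = abs(values[mask].mean() - values[~mask].mean())
        if stat >= obs - 1e-12:
            hits += 1
    return hits / len(assignments)


def test_events(
    events: pd.DataFrame,
    method: str = "welch",
    conditions=("ctrl", "heat"),
    seed: int | None = 0,
) -> pd.DataFrame:
    """Attach delta-psi, mean junction reads, p and BH FDR to an event table.

    Events with fewer than two defined replicate psi values in either
    condition cannot be tested: they keep NaN p/FDR and are flagged
    ``tested = False`` (the filter later reports them as skipped).
    """
    if method not in ("welch", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    psi = event_psi(events, conditions)
    a, b = psi[conditions[0]], psi[conditions[1]]
    cols = _sample_columns(events, conditions)
    icols = [ic for pairs in cols.values() for ic, _ in pairs]
    scols = [sc for pairs in cols.values() for _, sc in pairs]
    total_reads = events[icols].to_numpy(float) + events[scols].to_numpy(float)
    mean_reads = total_reads.mean(axis=1)

    ok = (np.sum(~np.isnan(a), axis=1) >= 2) & (np.sum(~np.isnan(b), axis=1) >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN rows are reported via 'tested'
        dpsi = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)

    p = np.full(len(events), np.nan)
    rng = np.random.default_rng(seed)
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pw = stats.ttest_ind(a.T, b.T, equal_var=False, nan_policy="omit")
            pw = np.asarray(pw, dtype=float)
            flat = np.nanvar(a, axis=1) == 0
            flat &= np.nanvar(b, axis=1) == 0
        pw = np.where(flat, np.where(dpsi == 0.0, 1.0, 0.0), pw)
        pw = np.where(np.isnan(pw) & ok, 1.0, pw)
        p[ok] = pw[ok]
    else:
        for row in np.flatnonzero(ok):
            va = a[row][~np.isnan(a[row])]
            vb = b[row][~np.isnan(b[row])]
            p[row] = _permutation_p(np.concatenate([va, vb]), len(va), rng)

    fdr = np.full(len(events), np.nan)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])

    out = events.copy()
    out["psi_" + conditions[0]] = mean_a
    out["psi_" + conditions[1]] = mean_b
    out["dpsi"] = dpsi
    out["mean_reads"] = mean_reads
    out["tested"] = ok
    out["p"] = p
    out["fdr"] = fdr
    return out


# the name starts with "test_", but it is an API function, not a pytest test
test_events.__test__ = False  # type: ignore[attr-defined]


@dataclass
class FilterSummary:
    """Tallies reported next to the filtered event table."""

    n_input: int
    n_kept: int
    n_genes: int
    n_untested: int
    by_type: dict[str, int]


def filter_events(
    events: pd.DataFrame,
    min_mean_reads: float = 5.0,
    dpsi_cut: float = 0.1,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, FilterSummary]:
    """Apply the significance filter to a tested event table.

    Keeps events with mean junction reads strictly greater than
    ``min_mean_reads``, ``|delta psi| >= dpsi_cut`` and ``FDR < fdr_cut``.
    Untested events (missing FDR) are excluded and counted in the summary.
    """
    required = {"dpsi", "mean_reads", "fdr"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table lacks columns {sorted(missing)}; run test_events first")
    untested = events["fdr"].isna()
    keep = (
        ~untested
        & (events["mean_reads"] > min_mean_reads)
        & (events["dpsi"].abs() >= dpsi_cut)
        & (events["fdr"] < fdr_cut)
    )
    kept = events[keep]
    by_type = {t: int((kept["event_type"] == t).sum()) for t in EVENT_TYPES if (kept["event_type"] == t).any()}
    summary = FilterSummary(
        n_input=len(events),
        n_kept=len(kept),
        n_genes=int(kept["gene_id"].nunique()),
        n_untested=int(untested.sum()),
        by_type=by_type,
    )
    return kept, summary
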