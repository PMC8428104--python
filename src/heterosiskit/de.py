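"""Count normalisation and a differential-expression stand-in.

Library scaling uses the trimmed mean of M-values (TMM): each sample is
compared with a reference column, log-ratios (M) and log-abundances (A) of
genes expressed in both are doubly trimmed (30 % of M, 5 % of A by default,
the original method's defaults), and the remaining M-values are averaged
with inverse approximate-variance weights.  Scaling factors are rescaled to
geometric mean one and turn raw library sizes into effective sizes, on which
counts-per-million (CPM) are computed.

Differential expression between conditions is called with a Welch two-sample
t-test on ``log2(CPM + 0.5)``.  This is deliberately NOT a reimplementation
of the negative-binomial Wald machinery used by dedicated DE packages: it is
a transparent stand-in that yields gene sets with controlled false-discovery
rate for the downstream overlap analyses, which only consume the sets.  Do
not interpret its per-gene p-values as equivalent to a count-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["NormalizedMatrix", "bh_adjust", "call_degs", "tmm_normalize"]


@dataclass
class NormalizedMatrix:
    """TMM-scaled CPM matrix with the per-sample scaling factors."""

    cpm: pd.DataFrame
    factors: pd.Series
    library_sizes: pd.Series
    effective_sizes: pd.Series
    reference: str


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM scaling factor of one observed column against the reference.

    Weights are the inverse approximate variances of M computed on the
    count-proportion scale, so a uniform rescaling of either library leaves
    the factor exactly unchanged (pure sequencing depth carries no
    composition information).
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep], ref[keep]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = 1.0 / ((1.0 - po) / po + (1.0 - pr) / pr)

    n = len(m)
    lo_m, lo_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    sel = (rank_m > lo_m) & (rank_m <= n - lo_m) & (rank_a > lo_a) & (rank_a <= n - lo_a)
    if not sel.any() or w[sel].sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))


def tmm_normalize(
    counts: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizedMatrix:
    """Compute TMM scaling factors and the CPM matrix.

    The reference is the column whose upper-quartile count proportion is
    closest to the mean upper-quartile -- a depth-invariant stand-in for
    "the most typical library".  Factors are rescaled to geometric mean
    one; an all-zero sample is an error.  ``samples`` is accepted for
    interface symmetry and only used to check that the sheet matches the
    matrix columns.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if samples is not None:
        sheet = set(samples["sample"])
        cols = set(counts.columns)
        if sheet != cols:
            raise ValueError(
                f"sample sheet does not match count columns; "
                f"only in sheet: {sorted(sheet - cols)}, only in matrix: {sorted(cols - sheet)}"
            )
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if not ((mat > 0).all(axis=1)).any():
        raise ValueError("no gene is expressed in every sample; TMM reference undefined")

    uq = np.quantile(mat / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_factor(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))

    eff = lib * factors
    cpm = counts / eff * 1e6
    return NormalizedMatrix(
        cpm=cpm,
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_sizes=pd.Series(lib, index=counts.columns, name="library_size"),
        effective_sizes=pd.Series(eff, index=counts.columns, name="effective_size"),
        reference=str(counts.columns[ref_idx]),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    norm: NormalizedMatrix,
    samples: pd.DataFrame,
    population: str,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
    conditions: tuple[str, str] = ("control", "heat"),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Call DEGs between two conditions within one population.

    The log2 fold-change is ``mean log2(CPM+pc)`` in ``conditions[1]`` minus
    ``conditions[0]`` (heat vs control by default).  A gene is significant
    when its BH-adjusted p is below ``fdr_cut`` and ``|log2FC| > lfc_cut``.

    Returns a DataFrame with columns ``log2fc``, ``p``, ``fdr``,
    ``significant`` and ``direction`` (up/down relative to the baseline
    condition), indexed by gene.
    """
    sub = samples[samples["population"] == population]
    cols: list[list[str]] = []
    for cond in conditions:
        cc = list(sub.loc[sub["condition"] == cond, "sample"])
        if len(cc) < 2:
            raise ValueError(
                f"population {population!r} has {len(cc)} replicate(s) for "
                f"condition {cond!r}; need at least 2"
            )
        cols.append(cc)
    log = np.log2(norm.cpm + pseudocount)
    a = log[cols[0]].to_numpy()  # baseline (control)
    b = log[cols[1]].to_numpy()  # treatment (heat)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    # Zero variance on both sides: the Welch statistic is undefined; an
    # identical pair of groups is maximally null, a separated one maximally
    # significant.
    both_flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(both_flat, np.where(lfc == 0.0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    res = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "significant": (fdr < fdr_cut) & (np.abs(lfc) > lfc_cut),
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        },
        index=norm.cpm.index,
    )
    res.index.name = "gene"
    return res
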