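"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the structure of a hybrid-vs-parents heat-stress
experiment -- two parental populations (P1, P2) and their F1 hybrid, each
sampled under a control and a heat condition with replicate RNA-seq count
triads, cardiac warming ramps, and alternative-splicing event tables -- so
the whole pipeline can be built and validated without any external data.

Triad counts
------------
Per-gene group means are planted on the log2 CPM-like scale.  Each
classifiable gene receives a dominance class, a target d/|a| ratio drawn
from the interior of its class interval, and a parental log2 gap of at
least ``min_parent_gap``; the hybrid mean is placed at
``mid-parent + target * gap`` so the planted ratio is exact by
construction.  Replicate counts are negative binomial with gene-wise mean
and a shared dispersion (the standard bulk RNA-seq noise model).  Because
three replicates at dispersion 0.05 leave ~0.2/gap of noise on the
estimated ratio, parental gaps are drawn with a long right tail
(``min_parent_gap`` + Gamma(5, 1) log2 units, reflecting strongly diverged
parental species) and targets avoid interval boundaries: this keeps the
planted labels recoverable, which is the property the generator exists to
provide.  Extreme-deviation genes are kept on the observable CPM scale by
capping the product ``|target| * gap``.

Cardiac traces
--------------
A warming ramp with ln(heart rate) exactly piecewise-linear against 1000/K,
continuous at the planted break temperature, plus i.i.d. Gaussian noise on
the log scale (the scale on which the break regression operates).

Splice events
-------------
Per-event inclusion levels: replicate psi drawn from a Beta centred on the
condition mean, junction totals Poisson, inclusion counts binomial given
the length-weighted inclusion probability.  A known subset of events gets a
planted between-condition psi shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cardiac import ABS_ZERO_C, CardiacTrace
from .dominance import MODE_LABELS, PARENT_EQUAL
from .splicing import EVENT_TYPES

__all__ = [
    "CardiacSimConfig",
    "ConfigError",
    "SpliceSimConfig",
    "TriadSimConfig",
    "expected_matrix",
    "simulate_cardiac_trace",
    "simulate_splice_events",
    "simulate_triad_counts",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


#: Default class mix.  Every dominance class is represented symmetrically
#: (ODO with UDO, HPD with LPD, PPD with NPD) and a substantial
#: parent-equal fraction provides the invariant "housekeeping" core that
#: between-sample normalisation needs: TMM assumes most genes unchanged
#: between libraries, and a transcriptome where every gene is planted with
#: a large hybrid deviation has no common scale to recover.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    PARENT_EQUAL: 0.35,
    "ADD": 0.13,
    "PPD": 0.08,
    "NPD": 0.08,
    "HPD": 0.05,
    "LPD": 0.05,
    "ODO": 0.13,
    "UDO": 0.13,
}

# Interior sampling windows per class; strict subsets of the classification
# intervals so that planted labels stay identifiable under replicate noise.
# Over/under-dominance targets sit well beyond the 1.2 boundary because
# their effective noise grows with |target| (gap-estimation error is
# multiplied by the ratio).
_TARGET_WINDOWS: dict[str, tuple[float, float]] = {
    "ADD": (-0.10, 0.10),
    "PPD": (0.30, 0.70),
    "NPD": (-0.70, -0.30),
    "HPD": (0.90, 1.10),
    "LPD": (-1.10, -0.90),
    "ODO": (2.00, 2.60),
    "UDO": (-2.60, -2.00),
}

_POPULATIONS = ("P1", "P2", "F1")
_CONDITIONS = ("control", "heat")


@dataclass
class TriadSimConfig:
    """Configuration of the three-population count-triad generator.

    Parameters mirror the emulated study design: three populations, two
    conditions, ``n_replicates`` libraries each (the study used 3).
    ``min_parent_gap`` is the smallest planted parental |log2| difference
    for ratio-classifiable genes; ``gap_shape``/``gap_scale`` parametrise
    the Gamma-distributed extra divergence on top of it.  ``de_fraction``
    of genes receive a heat-response log2 fold-change of ``de_log2fc``
    (random sign, applied to all three populations alike, which leaves the
    dominance ratio untouched).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    library_size_factors: np.ndarray | None = None
    min_parent_gap: float = 1.0
    gap_shape: float = 5.0
    gap_scale: float = 1.0
    gap_cap: float = 6.5
    max_deviation: float = 4.5
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(_POPULATIONS) * len(_CONDITIONS) * self.n_replicates

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("n_genes and n_replicates must be at least 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.min_parent_gap < 0:
            raise ConfigError("min_parent_gap must be non-negative")
        props = dict(self.class_proportions)
        bad = set(props) - set(MODE_LABELS) - {PARENT_EQUAL}
        if bad:
            raise ConfigError(f"unknown class labels in proportions: {sorted(bad)}")
        if any(v < 0 for v in props.values()):
            raise ConfigError("class proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {sum(props.values())}, not 1")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.library_size_factors is not None:
            f = np.asarray(self.library_size_factors, dtype=float)
            if len(f) != self.n_samples:
                raise ConfigError(
                    f"library_size_factors must have length {self.n_samples}, got {len(f)}"
                )
            if (f <= 0).any():
                raise ConfigError("library_size_factors must be positive")


def _sample_sheet(n_replicates: int) -> pd.DataFrame:
    rows = [
        (f"{pop}_{cond}_{r}", pop, cond, r)
        for pop in _POPULATIONS
        for cond in _CONDITIONS
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample", "population", "condition", "replicate"])


def _plant_truth(config: TriadSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    gene_labels = rng.choice(labels, size=config.n_genes, p=probs)

    target = np.full(config.n_genes, np.nan)
    gap = np.zeros(config.n_genes)
    mid = np.zeros(config.n_genes)

    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    extra = rng.gamma(config.gap_shape, config.gap_scale, config.n_genes)
    u = rng.uniform(size=config.n_genes)
    high_is_p1 = rng.uniform(size=config.n_genes) < 0.5

    for i, lab in enumerate(gene_labels):
        if lab == PARENT_EQUAL:
            mid[i] = max(base[i], 3.5)
            continue
        lo, hi = _TARGET_WINDOWS[lab]
        t = lo + u[i] * (hi - lo)
        g = config.min_parent_gap + extra[i]
        g = min(g, config.gap_cap, config.max_deviation / max(abs(t), 0.5))
        # anchor the mid-parent level, then clamp the baseline so every
        # planted group mean stays between the CPM detection floor and the
        # library scale (low means would drown in pseudocount/shot noise)
        min_rel = min(-g / 2.0, t * g)
        max_rel = max(g / 2.0, t * g)
        target[i] = t
        gap[i] = g
        mid[i] = min(max(base[i], 3.5 - min_rel), 16.0 - max_rel)

    p_high = mid + gap / 2.0
    p_low = mid - gap / 2.0
    p1 = np.where(high_is_p1, p_high, p_low)
    p2 = np.where(high_is_p1, p_low, p_high)
    f1 = np.where(np.isnan(target), mid, mid + np.nan_to_num(target) * gap)

    de = rng.uniform(size=config.n_genes) < config.de_fraction
    de_sign = np.where(rng.uniform(size=config.n_genes) < 0.5, -1.0, 1.0)
    de_lfc = np.where(de, de_sign * config.de_log2fc, 0.0)

    truth = pd.DataFrame(
        {
            "label": gene_labels,
            "target": target,
            "p1_log2": p1,
            "p2_log2": p2,
            "f1_log2": f1,
            "gap_log2": gap,
            "de": de,
            "de_lfc": de_lfc,
        },
        index=pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene"),
    )
    return truth


def expected_matrix(truth: pd.DataFrame, config: TriadSimConfig) -> pd.DataFrame:
    """Noise-free expected mean matrix (linear scale, library factors applied)."""
    sheet = _sample_sheet(config.n_replicates)
    factors = (
        np.ones(config.n_samples)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )
    cols = {}
    for j, row in sheet.iterrows():
        log2_mean = truth[f"{row['population'].lower()}_log2"].to_numpy().copy()
        if row["condition"] == "heat":
            log2_mean = log2_mean + truth["de_lfc"].to_numpy()
        cols[row["sample"]] = 2.0 ** log2_mean * factors[j]
    return pd.DataFrame(cols, index=truth.index)


def simulate_triad_counts(
    config: TriadSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a count matrix, sample sheet and ground-truth table.

    Returns ``(counts, samples, truth)``; counts are non-negative integers,
    reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _plant_truth(config, rng)
    means = expected_matrix(truth, config)
    size = 1.0 / config.dispersion
    mu = means.to_numpy()
    counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts, index=truth.index, columns=means.columns)
    return counts_df, _sample_sheet(config.n_replicates), truth


@dataclass
class CardiacSimConfig:
    """Configuration of the piecewise-Arrhenius heart-rate ramp generator.

    Slopes are on Arrhenius axes (ln bpm per 1000/K); the warming segment
    slope is negative (rate rises with temperature), the post-break slope
    positive and steep (collapse).  ``noise_sd`` is the standard deviation
    of Gaussian noise on ln(rate).  The default ramp mirrors a 0.1 degC/min
    protocol sampled once per 0.1 degC from 20 degC.
    """

    true_abt_celsius: float = 32.0
    temp_start: float = 20.0
    temp_end: float = 38.0
    resolution: float = 0.1
    slope_left: float = -8.0
    slope_right: float = 25.0
    baseline_log_rate: float = math.log(30.0)
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.temp_start < self.true_abt_celsius < self.temp_end:
            raise ConfigError(
                "true_abt_celsius must lie strictly between temp_start and temp_end"
            )
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def simulate_cardiac_trace(config: CardiacSimConfig) -> tuple[CardiacTrace, dict]:
    """Generate one heart-rate ramp with a planted Arrhenius break.

    The noiseless signal is exactly two lines in (1000/K, ln rate) space
    meeting at the planted break; returns the trace plus a truth dict.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round((config.temp_end - config.temp_start) / config.resolution)) + 1
    temps = config.temp_start + config.resolution * np.arange(n)
    x = 1000.0 / (temps + ABS_ZERO_C)
    x0 = x[0]
    xb = 1000.0 / (config.true_abt_celsius + ABS_ZERO_C)
    yb = config.baseline_log_rate + config.slope_left * (xb - x0)
    y = np.where(
        x >= xb,  # x >= xb  <=>  T <= ABT
        config.baseline_log_rate + config.slope_left * (x - x0),
        yb + config.slope_right * (x - xb),
    )
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, n)
    trace = CardiacTrace(temperature_c=temps, rate_bpm=np.exp(y))
    truth = {
        "abt_celsius": config.true_abt_celsius,
        "break_x": xb,
        "has_break": config.slope_left != config.slope_right,
    }
    return trace, truth


@dataclass
class SpliceSimConfig:
    """Configuration of the alternative-splicing event-table generator.

    The default event-type mix (91 % skipped exon, 9 % mutually exclusive
    exons) matches the composition reported for significant heat-response
    events in the emulated study.  ``concentration`` is the Beta
    pseudo-sample-size controlling replicate psi variability
    (sd ~= sqrt(m(1-m)/(concentration+1))).
    """

    n_events: int = 1000
    n_replicates: int = 3
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SE": 0.91, "MXE": 0.09}
    )
    psi_low: float = 0.15
    psi_high: float = 0.85
    concentration: float = 100.0
    divergent_fraction: float = 0.1
    true_delta_psi: float = 0.3
    depth_mean: float = 100.0
    li: float = 2.0
    ls: float = 1.0
    shared_gene_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1 or self.n_replicates < 1:
            raise ConfigError("n_events and n_replicates must be at least 1")
        mix = dict(self.type_mix)
        bad = set(mix) - set(EVENT_TYPES)
        if bad:
            raise ConfigError(f"unknown event types: {sorted(bad)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ConfigError("type_mix must be non-negative and sum to 1")
        for name in ("psi_low", "psi_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.psi_low > self.psi_high:
            raise ConfigError("psi_low must not exceed psi_high")
        if abs(self.true_delta_psi) > 1.0:
            raise ConfigError("|true_delta_psi| must be at most 1")
        if self.depth_mean < 0:
            raise ConfigError("depth_mean must be non-negative")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        if self.li < 1 or self.ls < 1:
            raise ConfigError("effective lengths must be >= 1")


def simulate_splice_events(config: SpliceSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a wide event table plus its per-event truth.

    Divergent events have condition-wise expected psi differing by
    ``true_delta_psi`` (shifted toward whichever direction stays inside
    [0.02, 0.98]).  Junction counts are integers; a fixed seed reproduces
    the table bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, reps = config.n_events, config.n_replicates

    types = rng.choice(list(config.type_mix), size=n, p=np.array(list(config.type_mix.values())))
    genes = []
    for i in range(n):
        if i > 0 and rng.uniform() < config.shared_gene_fraction:
            genes.append(genes[-1])
        else:
            genes.append(f"g{i:05d}")

    m_ctrl = rng.uniform(config.psi_low, config.psi_high, n)
    divergent = rng.uniform(size=n) < config.divergent_fraction
    shift_down_ok = (m_ctrl - config.true_delta_psi >= 0.02) & (
        m_ctrl - config.true_delta_psi <= 0.98
    )
    m_heat = m_ctrl.copy()
    m_heat[divergent & shift_down_ok] -= config.true_delta_psi
    m_heat[divergent & ~shift_down_ok] += config.true_delta_psi
    m_heat = np.clip(m_heat, 0.01, 0.99)

    data: dict[str, np.ndarray] = {
        "event_id": np.array([f"ev{i:05d}" for i in range(n)]),
        "gene_id": np.array(genes),
        "event_type": types,
        "li": np.full(n, config.li),
        "ls": np.full(n, config.ls),
    }
    kappa = config.concentration
    for cond, m in (("ctrl", m_ctrl), ("heat", m_heat)):
        for r in range(1, reps + 1):
            psi = rng.beta(m * kappa, (1.0 - m) * kappa)
            depth = rng.poisson(config.depth_mean, n)
            q = psi * config.li / (psi * config.li + (1.0 - psi) * config.ls)
            inc = rng.binomial(depth, q)
            data[f"I_{cond}_{r}"] = inc
            data[f"S_{cond}_{r}"] = depth - inc
    events = pd.DataFrame(data)
    truth = pd.DataFrame(
        {
            "event_id": data["event_id"],
            "gene_id": data["gene_id"],
            "divergent": divergent,
            "psi_ctrl": m_ctrl,
            "psi_heat": m_heat,
            "true_dpsi": m_ctrl - m_heat,
        }
    )
    return events, truth
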