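"""End-to-end pipeline: simulate or load inputs, run every stage, write a manifest.

Stage order mirrors the analysis flow of the emulated study: normalisation
and per-population differential expression, dominance-mode classification
per condition, splice-divergence testing and filtering, then the overlap
integration.  All randomness derives from the single configuration seed, so
a rerun with the same configuration reproduces byte-identical tables; the
manifest records version, seed, parameters and a checksum per output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cardiac import arrhenius_transform, compare_abt_groups, fit_breakpoint
from .de import call_degs, tmm_normalize
from .dominance import classify_matrix, summarize_modes
from .integration import integrate_heterosis
from .io import ValidationError, read_counts, read_events, read_samples, write_table
from .simulate import (
    CardiacSimConfig,
    SpliceSimConfig,
    TriadSimConfig,
    simulate_cardiac_trace,
    simulate_splice_events,
    simulate_triad_counts,
)
from .splicing import filter_events, test_events

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, parameters and the master seed of one pipeline run.

    When ``counts_path``/``events_path`` are unset the synthetic generators
    supply the corresponding inputs (with seeds derived from ``seed``).
    """

    output_dir: str | Path = "heterosiskit_run"
    seed: int = 0
    counts_path: str | Path | None = None
    samples_path: str | Path | None = None
    events_path: str | Path | None = None
    n_cardiac_per_group: int = 6
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    dpsi_cut: float = 0.1
    min_mean_reads: float = 5.0
    mode_convention: str = "full_gap"
    mode_normalization: str = "tmm_linear"
    splice_test: str = "welch"
    triad: TriadSimConfig | None = None
    splice_sim: SpliceSimConfig | None = None
    cardiac_sim: CardiacSimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"{path}: unknown configuration key(s) {sorted(bad)}")
        for key, klass in (
            ("triad", TriadSimConfig),
            ("splice_sim", SpliceSimConfig),
            ("cardiac_sim", CardiacSimConfig),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts_path", "samples_path", "events_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{key} {p!r} does not exist")
        if (self.counts_path is None) != (self.samples_path is None):
            raise ValidationError("counts_path and samples_path must be given together")

    def params(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["output_dir"] = str(out["output_dir"])
        return out

    def analysis_params(self) -> dict[str, Any]:
        """Parameters that determine the results (location-independent)."""
        out = self.params()
        out.pop("output_dir")
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@contextmanager
def _stage(name: str):
    """Re-raise stage failures with the stage name; earlier outputs remain."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = True, sep: str = "\t") -> None:
        written.append(
            write_table(df, out / name, seed=seed, params=config.analysis_params(), index=index, sep=sep)
        )

    # --- inputs -----------------------------------------------------------
    if config.counts_path is None:
        triad_cfg = config.triad or TriadSimConfig()
        triad_cfg = dataclasses.replace(triad_cfg, seed=seed)
        counts, samples, truth = simulate_triad_counts(triad_cfg)
        emit(counts, "counts.tsv")
        emit(samples, "samples.csv", index=False, sep=",")
        emit(truth, "triad_truth.tsv")
    else:
        counts = read_counts(config.counts_path)
        samples = read_samples(config.samples_path, counts)
        truth = None

    if config.events_path is None:
        splice_cfg = config.splice_sim or SpliceSimConfig()
        splice_cfg = dataclasses.replace(splice_cfg, seed=seed + 1)
        events, splice_truth = simulate_splice_events(splice_cfg)
        emit(events, "splice_events.tsv", index=False)
        emit(splice_truth, "splice_truth.tsv", index=False)
    else:
        events = read_events(config.events_path)

    # --- cardiac stage (simulated ramps per population) -------------------
    with _stage("cardiac-abt"):
        cardiac_cfg = config.cardiac_sim or CardiacSimConfig()
        abts: dict[str, list[float]] = {}
        fit_rows = []
        for g, pop in enumerate(("P1", "P2", "F1")):
            abts[pop] = []
            for k in range(config.n_cardiac_per_group):
                cfg = dataclasses.replace(cardiac_cfg, seed=seed + 100 + 10 * g + k)
                trace, _ = simulate_cardiac_trace(cfg)
                fit = fit_breakpoint(arrhenius_transform(trace))
                abts[pop].append(fit.abt_celsius)
                fit_rows.append(
                    (f"{pop}_{k + 1}", pop, fit.abt_celsius, fit.rss_total, fit.degenerate)
                )
        fits = pd.DataFrame(
            fit_rows, columns=["individual", "group", "abt_celsius", "rss", "degenerate"]
        )
        emit(fits, "abt_fits.tsv", index=False)
        cmp_res = compare_abt_groups(abts)
        (out / "abt_comparison.json").write_text(
            json.dumps(
                {
                    "f_statistic": cmp_res.f_statistic,
                    "p_value": cmp_res.p_value,
                    "group_means": cmp_res.group_means,
                    "pairwise_differences": {
                        f"{a}-{b}": d for (a, b), d in cmp_res.pairwise_differences.items()
                    },
                },
                indent=2,
            )
        )
        written.append(out / "abt_comparison.json")

    # --- expression stages ------------------------------------------------
    with _stage("normalisation-and-de"):
        norm = tmm_normalize(counts, samples)
        emit(norm.factors.to_frame(), "tmm_factors.tsv")
        deg_sets = {}
        for pop in ("P1", "P2", "F1"):
            degs = call_degs(norm, samples, pop, fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut)
            emit(degs, f"degs_{pop}.tsv")
            deg_sets[pop] = set(degs.index[degs["significant"]])

    # --- dominance modes --------------------------------------------------
    with _stage("dominance-modes"):
        summaries = {}
        calls_by_condition = {}
        for cond in ("control", "heat"):
            calls, undetected = classify_matrix(
                counts,
                samples,
                cond,
                normalization=config.mode_normalization,
                convention=config.mode_convention,
            )
            calls_by_condition[cond] = calls
            emit(calls, f"modes_{cond}.tsv")
            s = summarize_modes(calls)
            summaries[cond] = {
                "counts": s.counts,
                "detected": s.detected,
                "non_additive": s.non_additive,
                "nonadditive_pct": s.nonadditive_pct,
                "class_pct": s.class_pct,
                "undetected": int(len(undetected)),
            }
        (out / "mode_summary.json").write_text(json.dumps(summaries, indent=2))
        written.append(out / "mode_summary.json")

    # --- splicing ---------------------------------------------------------
    with _stage("splicing"):
        tested = test_events(events, method=config.splice_test, seed=seed + 2)
        kept, splice_summary = filter_events(
            tested,
            min_mean_reads=config.min_mean_reads,
            dpsi_cut=config.dpsi_cut,
            fdr_cut=config.fdr_cut,
        )
        emit(tested, "splice_tested.tsv", index=False)
        emit(kept, "splice_significant.tsv", index=False)
        (out / "splice_summary.json").write_text(
            json.dumps(dataclasses.asdict(splice_summary), indent=2)
        )
        written.append(out / "splice_summary.json")

    # --- integration ------------------------------------------------------
    with _stage("integration"):
        integ = integrate_heterosis(
            deg_sets, calls_by_condition["heat"], set(kept["gene_id"])
        )
        (out / "integration.json").write_text(
            json.dumps(
                {
                    "sizes": integ.sizes,
                    "final_genes": sorted(integ.final),
                    "deg_region_counts": {
                        "&".join(k): v for k, v in integ.deg_venn.region_counts.items()
                    },
                    "summary_region_counts": {
                        "&".join(k): v for k, v in integ.summary_venn.region_counts.items()
                    },
                },
                indent=2,
            )
        )
        written.append(out / "integration.json")

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: str(v) for k, v in config.params().items()},
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
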