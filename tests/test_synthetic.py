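"""Ground-truth generators: determinism, planted-truth containment, noise model."""

import numpy as np
import pandas as pd
import pytest

from heterosiskit import (
    CardiacSimConfig,
    ConfigError,
    SpliceSimConfig,
    TriadSimConfig,
    classify_mode,
    expected_matrix,
    simulate_cardiac_trace,
    simulate_splice_events,
    simulate_triad_counts,
)
from heterosiskit.splicing import event_psi


class TestTriadGenerator:
    def test_fixed_seed_reproduces_identical_outputs(self):
        a = simulate_triad_counts(TriadSimConfig(n_genes=200, seed=7))
        b = simulate_triad_counts(TriadSimConfig(n_genes=200, seed=7))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_counts_are_non_negative_integers(self, small_triad):
        _, counts, _, _ = small_triad
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_planted_ratio_lies_inside_label_interval(self, small_triad):
        """Truth containment: target ratio classifies back to its own label."""
        _, _, _, truth = small_triad
        ratio_rows = truth[truth["label"] != "PARENT_EQUAL"]
        assert len(ratio_rows) > 0
        for lab, t in zip(ratio_rows["label"], ratio_rows["target"]):
            assert classify_mode(t) == lab

    def test_planted_geometry_is_exact(self, small_triad):
        """(F1 - mid-parent) / gap equals the stored target on the log2 scale."""
        cfg, _, _, truth = small_triad
        rows = truth[truth["label"] != "PARENT_EQUAL"]
        mid = (rows["p1_log2"] + rows["p2_log2"]) / 2
        gap = (rows["p1_log2"] - rows["p2_log2"]).abs()
        assert (gap >= cfg.min_parent_gap - 1e-9).all()
        np.testing.assert_allclose((rows["f1_log2"] - mid) / gap, rows["target"], atol=1e-12)
        pe = truth[truth["label"] == "PARENT_EQUAL"]
        np.testing.assert_allclose(pe["p1_log2"], pe["p2_log2"], atol=0)

    def test_group_means_converge_to_configured_means(self):
        """At 200 replicates the mean relative error across genes is < 2 %."""
        cfg = TriadSimConfig(n_genes=200, n_replicates=200, seed=3)
        counts, samples, truth = simulate_triad_counts(cfg)
        expected = expected_matrix(truth, cfg)
        ctrl = list(samples.loc[(samples["population"] == "F1") & (samples["condition"] == "control"), "sample"])
        emp = counts[ctrl].mean(axis=1)
        rel_err = ((emp - expected[ctrl].mean(axis=1)) / expected[ctrl].mean(axis=1)).abs()
        assert rel_err.mean() < 0.02

    def test_class_mix_follows_configured_proportions(self):
        cfg = TriadSimConfig(n_genes=4000, seed=5)
        _, _, truth = simulate_triad_counts(cfg)
        freq = truth["label"].value_counts(normalize=True)
        for lab, p in cfg.class_proportions.items():
            se = np.sqrt(p * (1 - p) / cfg.n_genes)
            assert abs(freq.get(lab, 0.0) - p) < 5 * se + 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dispersion": 0.0},
            {"dispersion": -1.0},
            {"class_proportions": {"ADD": 0.5}},
            {"class_proportions": {"ADD": 0.5, "BAD": 0.5}},
            {"min_parent_gap": -1.0},
            {"n_genes": 0},
            {"library_size_factors": [1.0] * 5},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            simulate_triad_counts(TriadSimConfig(**{"n_genes": 50, **kwargs}))

    def test_library_size_factors_scale_expected_means(self):
        cfg = TriadSimConfig(n_genes=100, seed=1)
        factors = np.ones(cfg.n_samples)
        factors[0] = 2.0
        cfg2 = TriadSimConfig(n_genes=100, seed=1, library_size_factors=factors)
        _, _, truth = simulate_triad_counts(cfg)
        exp1 = expected_matrix(truth, cfg)
        exp2 = expected_matrix(truth, cfg2)
        np.testing.assert_allclose(exp2.iloc[:, 0], 2.0 * exp1.iloc[:, 0])
        np.testing.assert_allclose(exp2.iloc[:, 1], exp1.iloc[:, 1])


class TestCardiacGenerator:
    def test_temperatures_strictly_increasing_and_rates_positive(self):
        trace, _ = simulate_cardiac_trace(CardiacSimConfig(seed=2))
        assert (np.diff(trace.temperature_c) > 0).all()
        assert (trace.rate_bpm > 0).all()

    def test_noiseless_signal_is_exactly_two_lines(self):
        from heterosiskit import arrhenius_transform

        cfg = CardiacSimConfig(noise_sd=0.0)
        trace, truth = simulate_cardiac_trace(cfg)
        s = arrhenius_transform(trace)
        left = s.x >= truth["break_x"]
        for side in (left, ~left):
            if side.sum() >= 3:
                resid = np.polyval(np.polyfit(s.x[side], s.y[side], 1), s.x[side]) - s.y[side]
                assert np.abs(resid).max() < 1e-9

    def test_fixed_seed_reproduces_trace(self):
        t1, _ = simulate_cardiac_trace(CardiacSimConfig(seed=9))
        t2, _ = simulate_cardiac_trace(CardiacSimConfig(seed=9))
        np.testing.assert_array_equal(t1.rate_bpm, t2.rate_bpm)

    def test_break_outside_ramp_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cardiac_trace(CardiacSimConfig(true_abt_celsius=50.0))


class TestSpliceGenerator:
    def test_fixed_seed_reproduces_table(self):
        a, ta = simulate_splice_events(SpliceSimConfig(n_events=100, seed=3))
        b, tb = simulate_splice_events(SpliceSimConfig(n_events=100, seed=3))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_counts_are_integers_and_psi_in_range(self):
        ev, _ = simulate_splice_events(SpliceSimConfig(n_events=100, seed=1))
        count_cols = [c for c in ev.columns if c.startswith(("I_", "S_"))]
        assert np.issubdtype(ev[count_cols].to_numpy().dtype, np.integer)
        psi = event_psi(ev)
        for mat in psi.values():
            finite = mat[~np.isnan(mat)]
            assert ((finite >= 0) & (finite <= 1)).all()

    def test_high_depth_divergent_events_all_pass_dpsi_filter(self):
        """depth -> infinity removes counting noise; planted 0.3 >> 0.1."""
        from heterosiskit import filter_events, test_events

        ev, truth = simulate_splice_events(
            SpliceSimConfig(n_events=50, divergent_fraction=1.0, depth_mean=1e6, seed=8)
        )
        res = test_events(ev)
        assert (res["dpsi"].abs() >= 0.1).all()
        kept, _ = filter_events(res)
        assert set(kept["event_id"]) == set(ev["event_id"])

    def test_type_mix_matches_configuration(self):
        cfg = SpliceSimConfig(n_events=2000, seed=5)
        ev, _ = simulate_splice_events(cfg)
        freq = ev["event_type"].value_counts(normalize=True)
        for t, p in cfg.type_mix.items():
            se = np.sqrt(p * (1 - p) / cfg.n_events)
            assert abs(freq.get(t, 0.0) - p) < 5 * se

    def test_divergent_truth_shift_matches_config(self):
        cfg = SpliceSimConfig(n_events=500, seed=2)
        _, truth = simulate_splice_events(cfg)
        div = truth[truth["divergent"]]
        np.testing.assert_allclose(div["true_dpsi"].abs(), cfg.true_delta_psi)
        null = truth[~truth["divergent"]]
        np.testing.assert_allclose(null["true_dpsi"], 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"psi_low": -0.1},
            {"psi_high": 1.2},
            {"true_delta_psi": 1.5},
            {"type_mix": {"SE": 0.5}},
            {"concentration": 0.0},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            simulate_splice_events(SpliceSimConfig(n_events=10, **kwargs))
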