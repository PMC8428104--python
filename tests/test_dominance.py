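"""Dominance-ratio computation, interval classification and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterosiskit import (
    PARENT_EQUAL,
    classify_matrix,
    classify_mode,
    classify_ratios,
    compute_d_over_a,
    expected_matrix,
    summarize_modes,
)
from heterosiskit.simulate import TriadSimConfig, simulate_triad_counts


class TestComputeRatio:
    @pytest.mark.parametrize(
        "p1,p2,f1,convention,expected",
        [
            (14, 10, 12, "full_gap", 0.0),  # hybrid at mid-parent
            (14, 10, 14, "full_gap", 0.5),  # hybrid at high parent
            (14, 10, 14, "half_gap", 1.0),  # classical additive-effect scaling
            (10, 14, 14, "full_gap", 0.5),  # parent order irrelevant
            (14, 10, 10, "full_gap", -0.5),
            (14, 10, 18, "full_gap", 1.5),  # beyond the high parent
        ],
    )
    def test_ratio_arithmetic(self, p1, p2, f1, convention, expected):
        assert compute_d_over_a(p1, p2, f1, convention) == pytest.approx(expected)

    def test_equal_parents_yield_sentinel_not_division(self):
        assert compute_d_over_a(10, 10, 15, epsilon=1e-8) == PARENT_EQUAL

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            compute_d_over_a(float("nan"), 1.0, 1.0)

    @given(
        p1=st.floats(-1e3, 1e3),
        p2=st.floats(-1e3, 1e3),
        f1=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_half_gap_is_twice_full_gap(self, p1, p2, f1):
        full = compute_d_over_a(p1, p2, f1, "full_gap")
        half = compute_d_over_a(p1, p2, f1, "half_gap")
        if full == PARENT_EQUAL:
            assert half == PARENT_EQUAL
        else:
            assert half == pytest.approx(2.0 * full, rel=1e-12, abs=1e-12)

    @given(
        p1=st.floats(-1e3, 1e3),
        p2=st.floats(-1e3, 1e3),
        f1=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_parent_swap_preserves_ratio_magnitude(self, p1, p2, f1):
        a = compute_d_over_a(p1, p2, f1)
        b = compute_d_over_a(p2, p1, f1)
        if a == PARENT_EQUAL:
            assert b == PARENT_EQUAL
        else:
            assert abs(a) == pytest.approx(abs(b))
            # the additive/non-additive verdict is symmetric too
            assert (abs(a) <= 0.2) == (abs(b) <= 0.2)


class TestClassifyMode:
    @pytest.mark.parametrize(
        "ratio,label",
        [
            (-5.0, "UDO"),
            (-1.2000001, "UDO"),
            (-1.2, "LPD"),  # closed lower edge of low-parent dominance
            (-0.9, "LPD"),
            (-0.8, "NPD"),
            (-0.5, "NPD"),
            (-0.2, "ADD"),  # additive interval closed on both sides
            (0.0, "ADD"),
            (0.2, "ADD"),
            (0.2000001, "PPD"),
            (0.8, "PPD"),
            (0.9, "HPD"),
            (1.2, "HPD"),  # high-parent dominance includes 1.2
            (1.2000001, "ODO"),
            (7.0, "ODO"),
        ],
    )
    def test_interval_boundaries(self, ratio, label):
        assert classify_mode(ratio) == label
        assert classify_ratios(np.array([ratio]))[0] == label

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_mode(float("nan"))

    @given(st.floats(allow_nan=False, allow_infinity=False, width=64))
    @settings(max_examples=500, deadline=None)
    def test_every_ratio_gets_exactly_one_label(self, ratio):
        labels = [
            lab
            for lab, member in (
                ("UDO", ratio < -1.2),
                ("LPD", -1.2 <= ratio < -0.8),
                ("NPD", -0.8 <= ratio < -0.2),
                ("ADD", -0.2 <= ratio <= 0.2),
                ("PPD", 0.2 < ratio <= 0.8),
                ("HPD", 0.8 < ratio <= 1.2),
                ("ODO", ratio > 1.2),
            )
            if member
        ]
        assert len(labels) == 1
        assert classify_mode(ratio) == labels[0]

    def test_vectorised_matches_scalar_on_dense_grid(self, rng):
        ratios = rng.uniform(-3, 3, 5000)
        vec = classify_ratios(ratios)
        assert all(vec[i] == classify_mode(r) for i, r in enumerate(ratios))


class TestSummaries:
    def test_reported_study_percentages_from_counts(self):
        # heat-condition class counts of the emulated study
        heat = {"HPD": 1119, "LPD": 1278, "ODO": 8235, "UDO": 5819,
                "PPD": 2047, "NPD": 2014, "ADD": 21969 - 20512}
        s = summarize_modes(heat)
        assert s.non_additive == 20512
        assert s.nonadditive_pct == 93.37
        assert s.class_pct["ODO"] == 40.15
        assert s.class_pct["UDO"] == 28.37
        assert s.class_pct["HPD"] == 5.46
        assert s.class_pct["NPD"] == 9.82

    def test_control_percentages_from_counts(self):
        control = {"HPD": 1354, "LPD": 1559, "ODO": 7061, "UDO": 5590,
                   "PPD": 2280, "NPD": 2362, "ADD": 21969 - 20206}
        s = summarize_modes(control)
        assert s.nonadditive_pct == 91.98
        assert s.class_pct["HPD"] == 6.70
        assert s.class_pct["UDO"] == 27.67

    def test_all_additive_input(self):
        s = summarize_modes(["ADD"] * 10)
        assert s.non_additive == 0
        assert s.nonadditive_pct == 0.0

    def test_counts_round_trip_label_frequencies(self, rng):
        labels = rng.choice(["ADD", "ODO", "UDO", "PPD", PARENT_EQUAL], 500)
        s = summarize_modes(labels)
        freq = pd.Series(labels).value_counts()
        for lab, c in s.counts.items():
            assert c == int(freq.get(lab, 0))
        assert s.parent_equal == int(freq.get(PARENT_EQUAL, 0))
        assert s.detected == 500

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_modes([])


class TestClassifyMatrix:
    def test_noiseless_means_recover_planted_labels(self, small_triad):
        cfg, _, samples, truth = small_triad
        exact = expected_matrix(truth, cfg)
        calls, undetected = classify_matrix(exact, samples, "control", normalization="log2")
        mask = truth["label"] != PARENT_EQUAL
        got = calls.loc[truth.index[mask], "label"].to_numpy()
        assert (got == truth.loc[mask, "label"].to_numpy()).all()
        assert len(undetected) == 0

    def test_sample_order_invariance(self, small_triad):
        _, counts, samples, _ = small_triad
        calls, _ = classify_matrix(counts, samples, "heat")
        perm = np.random.default_rng(0).permutation(len(samples))
        calls2, _ = classify_matrix(
            counts[counts.columns[::-1]], samples.iloc[perm], "heat"
        )
        pd.testing.assert_frame_equal(calls, calls2)

    def test_missing_population_is_reported(self, small_triad):
        _, counts, samples, _ = small_triad
        sub = samples[samples["population"] != "P2"]
        with pytest.raises(ValueError, match="P2"):
            classify_matrix(counts[list(sub["sample"])], sub, "heat")

    def test_all_zero_genes_dropped_as_undetected(self, small_triad):
        _, counts, samples, _ = small_triad
        counts = counts.copy()
        heat_cols = list(samples.loc[samples["condition"] == "heat", "sample"])
        counts.loc[counts.index[0], heat_cols] = 0
        calls, undetected = classify_matrix(counts, samples, "heat")
        assert counts.index[0] in undetected
        assert counts.index[0] not in calls.index

    def test_recovery_under_replicate_noise(self):
        cfg = TriadSimConfig(n_genes=800, dispersion=0.05, seed=9)
        counts, samples, truth = simulate_triad_counts(cfg)
        calls, _ = classify_matrix(counts, samples, "heat", normalization="log2")
        mask = truth["label"] != PARENT_EQUAL
        got = calls.loc[truth.index[mask], "label"].to_numpy()
        recovery = (got == truth.loc[mask, "label"].to_numpy()).mean()
        assert recovery >= 0.95


class TestSignificanceGate:
    def test_gate_moves_unshifted_genes_to_additive(self, small_triad):
        _, counts, samples, truth = small_triad
        plain, _ = classify_matrix(counts, samples, "heat", normalization="log2")
        gated, _ = classify_matrix(
            counts, samples, "heat", normalization="log2", gate_alpha=0.05
        )
        # the gate can only convert labels to ADD, never away from it
        changed = plain["label"] != gated["label"]
        assert (gated.loc[changed, "label"] == "ADD").all()
        # planted additive genes stay additive at least as often with the gate
        add_truth = truth.index[truth["label"] == "ADD"]
        assert (gated.loc[add_truth, "label"] == "ADD").sum() >= (
            plain.loc[add_truth, "label"] == "ADD"
        ).sum()
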