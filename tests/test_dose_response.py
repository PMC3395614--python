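"""Tests for 3PL fitting, the agonist gate, extra-SS comparison, classification."""

import numpy as np
import pytest

from orfunc.dose_response import (
    DoseResponseDataset,
    DoseResponseError,
    agonist_gate,
    classify_pair,
    extra_ss_compare,
    fit_3pl,
    logistic3,
    normalize_curve_set,
)

LOG_CONC = np.arange(-8.0, -1.0)  # 7 doses, 10 nM .. 10 mM
CONC = 10.0 ** LOG_CONC


def make_dataset(bottom, top, logec50, noise_sd=0.0, n_rep=3, seed=0,
                 receptor="OR", odor="odor", log_conc=LOG_CONC):
    rng = np.random.default_rng(seed)
    clean = logistic3(np.asarray(log_conc), bottom, top, logec50)[:, None]
    resp = np.repeat(clean, n_rep, axis=1)
    if noise_sd:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return DoseResponseDataset(receptor, odor, 10.0 ** np.asarray(log_conc), resp)


def flat_dataset(level=0.0, noise_sd=0.02, seed=1, receptor="vector"):
    rng = np.random.default_rng(seed)
    resp = level + rng.normal(0.0, noise_sd, size=(LOG_CONC.size, 3))
    return DoseResponseDataset(receptor, "odor", CONC, resp)


class TestFit3PL:
    def test_noiseless_recovery(self):
        ds = make_dataset(0.0, 1.0, -6.0)
        fit = fit_3pl(ds)
        assert abs(fit.bottom - 0.0) < 1e-6
        assert abs(fit.top - 1.0) < 1e-6
        assert abs(fit.logec50 + 6.0) < 1e-6
        assert fit.ss < 1e-12
        assert fit.df == ds.n_obs - 3

    def test_flat_data_flagged_degenerate(self):
        fit = fit_3pl(flat_dataset())
        assert fit.degenerate

    def test_ci_contains_point_estimate(self):
        fit = fit_3pl(make_dataset(0.0, 1.0, -5.0, noise_sd=0.05, seed=3))
        assert fit.ci_logec50[0] <= fit.logec50 <= fit.ci_logec50[1]
        assert fit.ci_top[0] <= fit.top <= fit.ci_top[1]

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(DoseResponseError, match="4 distinct"):
            DoseResponseDataset("OR", "odor", [1e-6, 1e-5, 1e-4],
                                np.zeros((3, 3)))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(DoseResponseError, match="positive"):
            DoseResponseDataset("OR", "odor", [0.0, 1e-6, 1e-5, 1e-4],
                                np.zeros((4, 3)))

    def test_response_scaling_equivariance(self):
        ds = make_dataset(0.1, 1.1, -5.5, noise_sd=0.03, seed=7)
        fit = fit_3pl(ds)
        scaled = DoseResponseDataset("OR", "odor", ds.concentrations,
                                     ds.responses * 10.0)
        fit10 = fit_3pl(scaled)
        assert fit10.bottom == pytest.approx(fit.bottom * 10.0, rel=1e-5)
        assert fit10.top == pytest.approx(fit.top * 10.0, rel=1e-5)
        assert fit10.ss == pytest.approx(fit.ss * 100.0, rel=1e-5)
        assert fit10.logec50 == pytest.approx(fit.logec50, abs=1e-6)

    def test_concentration_shift_equivariance(self):
        ds = make_dataset(0.0, 1.0, -5.0, noise_sd=0.03, seed=11)
        fit = fit_3pl(ds)
        shifted = DoseResponseDataset("OR", "odor", ds.concentrations * 10.0,
                                      ds.responses)
        fit_s = fit_3pl(shifted)
        assert fit_s.logec50 == pytest.approx(fit.logec50 + 1.0, abs=1e-6)


class TestAgonistGate:
    def test_flat_data_fails_ci_overlap(self):
        ds = flat_dataset(receptor="OR")
        decision = agonist_gate(fit_3pl(ds), ds, flat_dataset(seed=2))
        assert not decision.agonist
        assert "ci_overlap" in decision.reasons

    def test_strong_sigmoid_vs_flat_control_passes(self):
        ds = make_dataset(0.0, 1.0, -5.0, noise_sd=0.02, seed=5)
        decision = agonist_gate(fit_3pl(ds), ds, flat_dataset(seed=6))
        assert decision.agonist
        assert decision.reasons == ()

    def test_uncertain_ec50_fails_criterion_two(self):
        # a fit whose logEC50 standard error exceeds 1 log unit must fail the
        # second criterion regardless of how the other two come out
        from dataclasses import replace

        ds = make_dataset(0.0, 1.0, -5.0, noise_sd=0.02, seed=5)
        fit = replace(fit_3pl(ds), se_logec50=1.5)
        decision = agonist_gate(fit, ds, flat_dataset(seed=9))
        assert not decision.agonist
        assert "ec50_sd" in decision.reasons

    def test_missing_control_raises(self):
        ds = make_dataset(0.0, 1.0, -5.0)
        with pytest.raises(DoseResponseError):
            agonist_gate(fit_3pl(ds), ds, None)


class TestExtraSS:
    def test_exact_copy_gives_f_zero_p_one(self):
        ds = make_dataset(0.0, 1.0, -5.0, noise_sd=0.04, seed=13)
        res = extra_ss_compare(ds, ds)
        assert res.F == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_denominator_df_for_reference_design(self):
        # 2 curves x 7 concentrations x 3 replicates -> df_den = 42 - 6 = 36
        a = make_dataset(0.0, 1.0, -5.0, noise_sd=0.03, seed=1)
        b = make_dataset(0.0, 1.0, -5.0, noise_sd=0.03, seed=2)
        res = extra_ss_compare(a, b)
        assert res.df_num == 3
        assert res.df_den == 36

    def test_symmetric_in_arguments(self):
        a = make_dataset(0.0, 1.0, -6.0, noise_sd=0.05, seed=21)
        b = make_dataset(0.0, 0.6, -5.0, noise_sd=0.05, seed=22)
        r1 = extra_ss_compare(a, b)
        r2 = extra_ss_compare(b, a)
        assert r1.F == pytest.approx(r2.F, rel=1e-6)
        assert r1.p == pytest.approx(r2.p, rel=1e-6)

    def test_distinct_curves_rejected(self):
        a = make_dataset(0.0, 1.0, -6.0, noise_sd=0.02, seed=31)
        b = make_dataset(0.0, 0.4, -4.0, noise_sd=0.02, seed=32)
        res = extra_ss_compare(a, b)
        assert res.p < 1e-6

    def test_noiseless_identical_data_flagged_exact_fit(self):
        a = make_dataset(0.0, 1.0, -5.0)
        res = extra_ss_compare(a, a)
        assert res.exact_fit
        assert res.p == 1.0


class TestClassifyPair:
    def test_identical_datasets_indistinguishable(self):
        ds = make_dataset(0.0, 1.0, -5.0, noise_sd=0.04, seed=41)
        cls = classify_pair(ds, ds)
        assert cls.label == "indistinguishable"

    def test_concordant_advantage_is_hyperfunctional(self):
        # A: 10x lower EC50 and 2x span
        a = make_dataset(0.0, 2.0, -6.0, noise_sd=0.02, seed=42, receptor="A")
        b = make_dataset(0.0, 1.0, -5.0, noise_sd=0.02, seed=43, receptor="B")
        assert classify_pair(a, b).label == "a_hyperfunctional"
        assert classify_pair(b, a).label == "a_hypofunctional"

    def test_discordant_changes_are_undefined(self):
        # A more potent but less efficacious
        a = make_dataset(0.0, 0.5, -6.5, noise_sd=0.01, seed=44, receptor="A")
        b = make_dataset(0.0, 1.0, -4.5, noise_sd=0.01, seed=45, receptor="B")
        assert classify_pair(a, b).label == "undefined"

    def test_gate_failure_gives_not_comparable(self):
        # B's wells replicate the vector control exactly: it cannot pass the
        # activation-vs-control criterion
        a = make_dataset(0.0, 1.0, -5.0, noise_sd=0.02, seed=46)
        ctrl = flat_dataset(seed=48)
        b = DoseResponseDataset("B", "odor", ctrl.concentrations, ctrl.responses)
        cls = classify_pair(a, b, ctrl, ctrl)
        assert cls.label == "not_comparable"
        assert not cls.gate_b.agonist
        assert "vs_control" in cls.gate_b.reasons


class TestNormalizeCurveSet:
    def test_single_curve_peak_maps_to_one(self):
        ds = make_dataset(0.2, 1.2, -5.0)
        scaled = normalize_curve_set({"A": ds})
        # observed responses approach the fitted asymptote from below
        assert scaled["A"].max() == pytest.approx(1.0, abs=2e-3)

    def test_half_span_member_peaks_at_half(self):
        a = make_dataset(0.0, 1.0, -5.0, receptor="A")
        b = make_dataset(0.0, 0.5, -5.0, receptor="B")
        scaled = normalize_curve_set({"A": a, "B": b})
        assert scaled["B"].max() == pytest.approx(0.5, abs=1e-3)

    def test_reference_mode_hand_computed(self):
        a = make_dataset(0.0, 2.0, -5.0, receptor="A")
        b = make_dataset(0.0, 1.0, -5.0, receptor="B")
        scaled = normalize_curve_set({"A": a, "B": b}, mode="reference",
                                     reference="A")
        # division by the reference top (2.0), no baseline shift
        assert scaled["A"].max() == pytest.approx(1.0, abs=2e-3)
        assert scaled["B"].max() == pytest.approx(0.5, abs=1e-3)
        assert scaled["B"].min() == pytest.approx(b.responses.min() / 2.0)

    def test_zero_span_normalizer_rejected(self):
        from dataclasses import replace

        ds = make_dataset(0.0, 1.0, -5.0)
        flat_fit = replace(fit_3pl(ds), top=0.0, bottom=0.0)
        with pytest.raises(DoseResponseError):
            normalize_curve_set({"A": ds}, fits={"A": flat_fit},
                                mode="reference", reference="A")
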