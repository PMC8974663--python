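"""Metric suite and model calibration against generator-side oracles."""

import numpy as np
import pytest

import fracwk as fw
from fracwk.calibration import (
    NonPhysicalParameterError,
    deviation_metrics,
    metrics_report,
    nrmse,
    params_from_coeffs,
    relative_errors,
)
from fracwk.harmonics import ImpedanceSpectrum
from fracwk.models import TransferCoeffs

from conftest import spectrum_from_model


def spec_of(Z, omega0=2 * np.pi):
    Z = np.asarray(Z, complex)
    return ImpedanceSpectrum(Z=Z, omega0=omega0, N=len(Z) - 1)


class TestGain:
    def test_identity_read(self):
        assert fw.compute_gain(spec_of([1.25 + 0j, 0.3 + 0.1j])) == 1.25

    def test_ratio_of_means(self):
        # DC impedance is mean pressure over mean flow
        G = fw.compute_gain(spec_of([93.33 / 83.33 + 0j, 0.5]))
        assert G == pytest.approx(93.33 / 83.33, rel=1e-12)
        assert G == pytest.approx(1.12, abs=5e-4)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            fw.compute_gain(spec_of([-0.1 + 0j, 0.5]))


class TestNRMSE:
    def test_perfect_fit_is_zero(self):
        z = np.array([1.2, 0.5 - 0.2j, 0.3 + 0.1j])
        assert nrmse(z, z, 1.2) == 0.0

    def test_single_harmonic_hand_value(self):
        # sqrt(1) / (1 * 2) = 0.5
        assert nrmse([2 + 0j], [1 + 0j], 2.0) == pytest.approx(0.5, abs=1e-15)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=21) + 1j * rng.normal(size=21)
        zh = rng.normal(size=21) + 1j * rng.normal(size=21)
        G = 1.7
        acc = 0.0
        for a, b in zip(z, zh):
            acc += (a.real - b.real) ** 2 + (a.imag - b.imag) ** 2
        oracle = np.sqrt(acc) / (21 * G)
        assert nrmse(z, zh, G) == pytest.approx(oracle, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(3, complex), np.ones(4, complex), 1.0)


class TestDeviation:
    def test_zero_when_equal(self):
        z = np.array([1.0, 0.5 + 0.5j])
        D, dev = deviation_metrics(z, z)
        assert np.all(D == 0) and dev == 0

    def test_uniform_inflation_is_twenty_percent(self):
        z = np.array([1.0, 0.4 - 0.3j, 0.2 + 0.1j])
        D, dev = deviation_metrics(z, 1.2 * z)
        np.testing.assert_allclose(D, 20.0, atol=1e-10)
        assert dev == pytest.approx(20.0, abs=1e-10)

    def test_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(1, 0.1, 11) + 1j * rng.normal(0, 0.1, 11)
        zh = rng.normal(1, 0.1, 11) + 1j * rng.normal(0, 0.1, 11)
        D, dev = deviation_metrics(z, zh)
        oracle = [
            (abs(b) - abs(a)) / abs(a) * 100 for a, b in zip(z, zh)
        ]
        np.testing.assert_allclose(D, oracle, atol=1e-12)
        assert dev == pytest.approx(float(np.mean(oracle)), abs=1e-12)


class TestRelativeErrors:
    def test_zero_when_equal(self):
        z = np.array([1.0, 0.5 - 0.5j])
        assert relative_errors(z, z) == (0.0, 0.0)

    def test_moduli_hand_l2_value(self):
        z = np.array([1.0 * np.exp(1j * 0.3), 1.0 * np.exp(1j * 0.3)])
        zh = np.array([1.1 * np.exp(1j * 0.3), 0.9 * np.exp(1j * 0.3)])
        re_mod, re_ph = relative_errors(z, zh)
        assert re_mod == pytest.approx(100 * np.sqrt(0.02) / np.sqrt(2), abs=1e-9)
        assert re_ph == pytest.approx(0.0, abs=1e-9)

    def test_phase_shift_matches_loop_oracle(self):
        true_ph = np.array([-0.2, -0.3])
        est_ph = true_ph + 0.1
        z = np.exp(1j * true_ph)
        zh = np.exp(1j * est_ph)
        _, re_ph = relative_errors(z, zh)
        oracle = (
            np.sqrt(np.sum((true_ph - est_ph) ** 2))
            / np.sqrt(np.sum(true_ph**2))
            * 100
        )
        assert re_ph == pytest.approx(oracle, abs=1e-10)

    def test_all_real_spectrum_gives_nan_phase_sentinel(self):
        z = np.array([1.0 + 0j, 2.0 + 0j])
        zh = np.array([1.0 + 0j, 2.0 + 0.1j])
        re_mod, re_ph = relative_errors(z, zh)
        assert np.isnan(re_ph)
        assert np.isfinite(re_mod)


class TestParamsFromCoeffs:
    def test_fwk2_arithmetic(self):
        c = TransferCoeffs(G=2.0, b1=1.0, alpha=0.5, form="one_pole_fractional")
        p = params_from_coeffs("fwk2", c)
        assert (p.Rp, p.C_alpha, p.alpha) == (2.0, 0.5, 0.5)

    def test_wk3_roundtrip(self):
        from fracwk.models import coeffs_from_params

        truth = fw.WK3Params(Zc=0.05, Rp=1.0, C=1.2)
        back = params_from_coeffs("wk3", coeffs_from_params("wk3", truth))
        assert back.Zc == pytest.approx(truth.Zc, abs=1e-12)
        assert back.Rp == pytest.approx(truth.Rp, abs=1e-12)
        assert back.C == pytest.approx(truth.C, abs=1e-12)

    def test_vwk_realizability_violation(self):
        c = TransferCoeffs(G=1.0, a1=1.5, b1=1.0, form="zero_pole")
        with pytest.raises(NonPhysicalParameterError):
            params_from_coeffs("vwk", c)


class TestFitModel:
    def test_noiseless_fwk2_recovery(self):
        truth = fw.FWK2Params(Rp=1.2, C_alpha=0.9 / 1.2, alpha=0.55)
        Z = spectrum_from_model("fwk2", truth)
        res = fw.fit_model(Z, "fwk2", fw.FitConfig(seed=0))
        assert res.metrics.nrmse < 1e-10
        assert res.params.Rp == pytest.approx(truth.Rp, rel=1e-6)
        assert res.params.C_alpha == pytest.approx(truth.C_alpha, rel=1e-6)
        assert res.params.alpha == pytest.approx(truth.alpha, rel=1e-6)

    def test_wk2_truth_drives_alpha_to_one(self):
        Z = spectrum_from_model("wk2", fw.WK2Params(Rp=1.0, C=1.5))
        res = fw.fit_model(Z, "fwk2", fw.FitConfig(seed=0))
        assert res.params.alpha == pytest.approx(1.0, abs=1e-4)

    def test_wk3_vwk_identical_objective(self):
        Z = spectrum_from_model("wk3", fw.WK3Params(Zc=0.06, Rp=1.1, C=1.4))
        cfg = fw.FitConfig(seed=0)
        r3 = fw.fit_model(Z, "wk3", cfg)
        rv = fw.fit_model(Z, "vwk", cfg)
        assert abs(r3.metrics.nrmse - rv.metrics.nrmse) < 1e-10

    def test_wk2_never_beats_fwk2_on_fractional_truth(self):
        # WK2 is FWK2 with alpha pinned at 1: nesting
        Z = spectrum_from_model("fwk2", fw.FWK2Params(Rp=1.0, C_alpha=1.0, alpha=0.5))
        cfg = fw.FitConfig(seed=0)
        assert (
            fw.fit_model(Z, "wk2", cfg).metrics.nrmse
            >= fw.fit_model(Z, "fwk2", cfg).metrics.nrmse
        )

    def test_gain_fixed_not_optimized(self):
        truth = fw.FWK2Params(Rp=1.3, C_alpha=0.7, alpha=0.4)
        Z = spectrum_from_model("fwk2", truth)
        for tag in fw.MODEL_TAGS:
            res = fw.fit_model(Z, tag, fw.FitConfig(seed=0))
            assert res.coeffs.G == fw.compute_gain(Z)

    def test_objective_equals_reported_nrmse(self):
        Z = spectrum_from_model("fwk2", fw.FWK2Params(1.2, 0.6, 0.5))
        res = fw.fit_model(Z, "wk2", fw.FitConfig(seed=0))
        zhat = res.predicted(Z.omegas)
        assert res.objective == pytest.approx(
            nrmse(Z.Z, zhat, res.coeffs.G), abs=1e-14
        )
        assert res.objective == pytest.approx(res.metrics.nrmse, abs=1e-14)

    def test_fit_result_serializes(self):
        Z = spectrum_from_model("fwk2", fw.FWK2Params(1.2, 0.6, 0.5))
        res = fw.fit_model(Z, "fwk2", fw.FitConfig(seed=0))
        d = res.to_dict()
        assert d["model"] == "fwk2"
        assert "params" in d and d["params"]["alpha"]["value"] > 0
        assert isinstance(res.to_json(), str)

    def test_unknown_model_rejected(self):
        Z = spectrum_from_model("wk2", fw.WK2Params(1.0, 1.0))
        with pytest.raises(ValueError, match="unknown model"):
            fw.fit_model(Z, "wk7")

    def test_metrics_report_bundle(self):
        Z = spectrum_from_model("fwk2", fw.FWK2Params(1.2, 0.6, 0.5))
        rep = metrics_report(Z, Z.Z, G=1.2)
        assert rep.nrmse == 0 and rep.deviation_pct == 0
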