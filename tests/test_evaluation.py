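import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from fenceline.evaluation import (
    bland_altman,
    confusion_and_mcc,
    en13725_check,
    multiclass_mcc,
    shapiro_gate,
)


class TestMcc:
    def test_perfect_prediction(self):
        truth = ["Air", "Biogas", "Organic odour"] * 5
        report = confusion_and_mcc(truth, truth)
        assert report.mcc == pytest.approx(1.0)
        assert report.accuracy == 1.0
        lo, hi = report.accuracy_ci
        assert lo <= report.accuracy <= hi

    def test_constant_prediction_has_zero_mcc(self):
        truth = ["Air", "Biogas", "Organic odour"] * 5
        report = confusion_and_mcc(truth, ["Air"] * 15)
        assert report.mcc == 0.0

    def test_matches_sklearn_on_random_labels(self, rng):
        truth = rng.integers(0, 3, 200).astype(str)
        pred = rng.integers(0, 3, 200).astype(str)
        report = confusion_and_mcc(truth, pred)
        assert report.mcc == pytest.approx(
            matthews_corrcoef(truth, pred), abs=1e-12
        )

    def test_hand_built_matrix_matches_direct_formula(self):
        C = np.array([[8, 2, 1], [1, 9, 2], [0, 0, 7]])
        # independent evaluation of the covariance form
        s, c = C.sum(), np.trace(C)
        t, p = C.sum(axis=1), C.sum(axis=0)
        expected = (c * s - t @ p) / np.sqrt(
            (s**2 - (p**2).sum()) * (s**2 - (t**2).sum())
        )
        assert multiclass_mcc(C) == pytest.approx(expected, rel=1e-12)

    def test_binary_case_equals_classic_matthews(self):
        C = np.array([[40, 5], [8, 47]])
        tp, fn, fp, tn = C[1, 1], C[1, 0], C[0, 1], C[0, 0]
        classic = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert multiclass_mcc(C) == pytest.approx(classic, rel=1e-12)

    def test_empty_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_mcc([], [])
        with pytest.raises(ValueError, match="2 classes"):
            confusion_and_mcc(["Air", "Air"], ["Air", "Biogas"])


class TestShapiroGate:
    def test_normal_sample_passes(self, rng):
        passes = sum(
            shapiro_gate(np.random.default_rng(s).standard_normal(40))[1]
            for s in range(50)
        )
        assert passes >= 45  # ~alpha = 0.05 rejection rate

    def test_bimodal_sample_fails(self, rng):
        d = np.concatenate([rng.normal(-3, 0.1, 25), rng.normal(3, 0.1, 25)])
        p, ok = shapiro_gate(d)
        assert not ok
        assert p < 0.001

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            shapiro_gate(np.full(10, 1.0))


class TestBlandAltman:
    def test_identical_pairs_have_null_agreement_stats(self):
        c = np.array([30.0, 100.0, 400.0, 800.0])
        report = bland_altman(c, c)
        assert report.bias_log == 0.0
        assert report.loa_upper_log == 0.0
        assert report.bias_factor == 1.0
        assert report.loa_upper_factor == 1.0

    def test_multiplicative_factors_are_exact_powers(self, rng):
        c_do = 10 ** rng.uniform(1.3, 3.0, 30)
        c_ioms = c_do * 10 ** rng.normal(0.1, 0.2, 30)
        report = bland_altman(c_ioms, c_do)
        assert report.loa_upper_factor == pytest.approx(
            10**report.loa_upper_log, rel=1e-12
        )
        assert report.loa_lower_factor == pytest.approx(
            10**report.loa_lower_log, rel=1e-12
        )
        assert report.loa_lower_log <= report.bias_log <= report.loa_upper_log
        lo, hi = report.bias_ci_log
        assert lo <= report.bias_log <= hi

    def test_swapping_methods_negates_the_analysis(self, rng):
        c_do = 10 ** rng.uniform(1.3, 3.0, 25)
        c_ioms = c_do * 10 ** rng.normal(0.05, 0.15, 25)
        fwd = bland_altman(c_ioms, c_do)
        rev = bland_altman(c_do, c_ioms)
        assert rev.bias_log == pytest.approx(-fwd.bias_log, rel=1e-10)
        assert rev.loa_lower_log == pytest.approx(-fwd.loa_upper_log, rel=1e-10)

    def test_printed_loa_factors_reproduced(self):
        """The reference factor columns follow from the log limits:
        10^0.63 -> 4.27x, 10^-0.89 -> 0.13x, 10^0.41 -> 2.6x."""
        assert 10**0.63 == pytest.approx(4.27, abs=0.005)
        assert 10**-0.89 == pytest.approx(0.13, abs=0.005)
        assert round(10**0.41, 1) == pytest.approx(2.6)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestEnCriteria:
    def _report_with(self, bias, sd):
        """Construct pairs whose log differences have exactly the given
        mean and standard deviation."""
        n = 24
        base = np.linspace(-1, 1, n)
        d = bias + sd * (base - base.mean()) / base.std(ddof=1)
        c_do = np.full(n, 100.0)
        return bland_altman(c_do * 10**d, c_do)

    def test_precision_factor_rows_reproduced(self):
        """1.96 x dispersion factor for sd giving s_factor 2.41 and 1.71
        reproduces the printed 4.72 (fail) and 3.35 (fail)."""
        for s_factor, printed in ((2.41, 4.72), (1.71, 3.35)):
            report = self._report_with(bias=0.0, sd=np.log10(s_factor))
            verdict = en13725_check(report)
            assert verdict.precision_value == pytest.approx(printed, abs=0.005)
            assert not verdict.precision_pass

    def test_small_bias_passes_accuracy(self):
        report = self._report_with(bias=0.10, sd=0.05)
        verdict = en13725_check(report)
        assert verdict.accuracy_value == pytest.approx(0.10, abs=1e-9)
        assert verdict.accuracy_pass

    def test_large_bias_fails_accuracy(self):
        report = self._report_with(bias=0.30, sd=0.05)
        assert not en13725_check(report).accuracy_pass

    def test_tight_dispersion_passes_precision(self):
        report = self._report_with(bias=0.0, sd=np.log10(1.4))
        verdict = en13725_check(report)
        assert verdict.precision_value == pytest.approx(1.96 * 1.4, rel=1e-9)
        assert verdict.precision_pass
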