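"""Field-performance statistics for odour classification and quantification.

Classification quality is summarized by the confusion matrix, the
multiclass Matthews correlation coefficient (Gorodkin's R_K form) and
the overall accuracy with an exact binomial confidence interval.

Quantification is assessed against dynamic olfactometry with a
Bland-Altman method comparison carried out on ``log10`` concentrations:
the bias is the mean of the paired log differences, the limits of
agreement (LoA) are ``bias +/- 1.96 s`` with ``s`` the standard
deviation of the differences, and each log quantity has a multiplicative
back-transform ``10^x`` that expresses the agreement as a factor.
A Shapiro-Wilk gate checks the normality assumption behind the LoA.

Two olfactometry-style quality criteria close the loop: *accuracy*
requires ``|bias| < 0.217`` in log10 units, and *intermediate precision*
requires ``1.96 * s_factor < 3`` where ``s_factor = 10^s`` is the
dispersion expressed as a factor (so that 95% of repeated measurements
agree within a factor of 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import MODEL_CLASSES

#: log10 bias limit of the accuracy criterion
EN_ACCURACY_LIMIT = 0.217
#: factor limit of the intermediate-precision criterion
EN_PRECISION_LIMIT = 3.0


@dataclass
class ClassificationReport:
    """Confusion matrix plus headline classification scores."""

    classes: list[str]
    confusion: np.ndarray  # rows = truth, cols = prediction
    mcc: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    per_class_recall: dict[str, float]


def multiclass_mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient from a KxK confusion matrix.

    Gorodkin's R_K: ``(c*s - sum_k p_k t_k) /
    sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))`` with c the trace, s the
    total count, t_k the row (truth) sums and p_k the column
    (prediction) sums.  Returns 0 when either marginal is degenerate.
    """
    C = np.asarray(confusion, dtype=float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    denom = math.sqrt(max(s**2 - np.sum(p**2), 0.0)) * math.sqrt(
        max(s**2 - np.sum(t**2), 0.0)
    )
    if denom == 0:
        return 0.0
    return float(np.clip((c * s - np.dot(t, p)) / denom, -1.0, 1.0))


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def confusion_and_mcc(truth, predicted, classes=None) -> ClassificationReport:
    """Confusion matrix, multiclass MCC and accuracy with exact binomial CI."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0 or truth.shape != predicted.shape:
        raise ValueError("truth and prediction must be equal-length and non-empty")
    if classes is None:
        classes = [c for c in MODEL_CLASSES if c in truth] or sorted(
            np.unique(np.concatenate([truth, predicted]))
        )
        extra = sorted(set(np.unique(np.concatenate([truth, predicted]))) - set(classes))
        classes = list(classes) + extra
    if np.unique(truth).size < 2:
        raise ValueError("need at least 2 classes present in the truth labels")
    index = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        C[index[t], index[p]] += 1
    k, n = int(np.trace(C)), int(C.sum())
    recalls = {
        c: (C[i, i] / C[i].sum() if C[i].sum() else float("nan"))
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        classes=list(classes),
        confusion=C,
        mcc=multiclass_mcc(C),
        accuracy=k / n,
        accuracy_ci=_clopper_pearson(k, n),
        per_class_recall=recalls,
    )


def shapiro_gate(d, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality check on the log differences.

    Returns ``(p_value, passed)``; ``passed`` means normality is *not*
    rejected at ``alpha``, which licenses the Bland-Altman limits.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3 or d.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: normality test is degenerate")
    stat, p = stats.shapiro(d)
    return float(p), bool(p > alpha)


@dataclass
class AgreementReport:
    """Bland-Altman agreement between instrument and olfactometry.

    All ``*_log`` quantities are in log10 units; each has a
    multiplicative ``*_factor`` counterpart equal to ``10**value``.
    """

    n: int
    bias_log: float
    sd_log: float
    loa_lower_log: float
    loa_upper_log: float
    bias_ci_log: tuple[float, float]
    loa_lower_ci_log: tuple[float, float]
    loa_upper_ci_log: tuple[float, float]
    shapiro_p: float
    normality_ok: bool

    @property
    def bias_factor(self) -> float:
        return 10.0**self.bias_log

    @property
    def loa_lower_factor(self) -> float:
        return 10.0**self.loa_lower_log

    @property
    def loa_upper_factor(self) -> float:
        return 10.0**self.loa_upper_log

    @property
    def sd_factor(self) -> float:
        return 10.0**self.sd_log

    @property
    def loa_width_log(self) -> float:
        return self.loa_upper_log - self.loa_lower_log

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias_log": self.bias_log,
            "sd_log": self.sd_log,
            "loa_lower_log": self.loa_lower_log,
            "loa_upper_log": self.loa_upper_log,
            "bias_ci_log": list(self.bias_ci_log),
            "loa_lower_ci_log": list(self.loa_lower_ci_log),
            "loa_upper_ci_log": list(self.loa_upper_ci_log),
            "bias_factor": self.bias_factor,
            "loa_lower_factor": self.loa_lower_factor,
            "loa_upper_factor": self.loa_upper_factor,
            "sd_factor": self.sd_factor,
            "shapiro_p": self.shapiro_p,
            "normality_ok": self.normality_ok,
        }


def bland_altman(c_ioms, c_do) -> AgreementReport:
    """Bland-Altman agreement of paired concentrations on the log10 scale.

    ``d_i = log10(c_ioms_i) - log10(c_do_i)``; bias is the mean of d, the
    LoA are ``bias +/- 1.96 sd``.  The bias CI is the t interval with
    standard error ``sd/sqrt(n)``; each LoA CI uses the classical
    ``sd * sqrt(3/n)`` standard error.
    """
    a = np.asarray(c_ioms, dtype=float)
    b = np.asarray(c_do, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired concentrations")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("concentrations must be positive")
    d = np.log10(a) - np.log10(b)
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = stats.t.ppf(0.975, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    if np.ptp(d) == 0:
        p, ok = 1.0, True  # perfectly constant differences: trivially compatible
    else:
        p, ok = shapiro_gate(d)
    return AgreementReport(
        n=n,
        bias_log=bias,
        sd_log=sd,
        loa_lower_log=loa_lo,
        loa_upper_log=loa_hi,
        bias_ci_log=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower_ci_log=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_upper_ci_log=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        shapiro_p=p,
        normality_ok=ok,
    )


@dataclass
class EnVerdicts:
    """Olfactometry quality-criteria verdicts for an agreement report."""

    accuracy_value: float  # |bias| in log10 units
    accuracy_pass: bool
    precision_value: float  # 1.96 * dispersion factor
    precision_pass: bool


def en13725_check(report: AgreementReport) -> EnVerdicts:
    """Apply the accuracy and intermediate-precision criteria.

    Accuracy: ``|bias| < 0.217`` (log10).  Intermediate precision:
    ``1.96 * s_factor < 3`` with ``s_factor = 10^sd_log`` the dispersion
    of the paired measurements expressed as a multiplicative factor.
    """
    acc = abs(report.bias_log)
    prec = 1.96 * report.sd_factor
    return EnVerdicts(
        accuracy_value=acc,
        accuracy_pass=acc < EN_ACCURACY_LIMIT,
        precision_value=prec,
        precision_pass=prec < EN_PRECISION_LIMIT,
    )
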