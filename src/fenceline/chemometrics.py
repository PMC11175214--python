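"""PCA exploration, influence-plot outlier removal, and the two-step
classification / quantification models.

The modelling chain mirrors standard e-nose chemometrics: features are
autoscaled and projected onto a small number of principal components
(default 3, which on typical training campaigns carry ~90% of the
variance); samples with extreme leverage (Hotelling T^2 in score space)
or extreme residual (Q, squared reconstruction error) are removed once
before model fitting; an RBF-kernel SVM on the scores assigns each
window to {Air, Biogas, Organic odour}; and support-vector regression on
log10 odour concentration quantifies non-Air windows — either one global
regressor (mode QA) or one per odour class routed by the classifier
(mode QB, the two-step scheme).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .io import MODEL_CLASSES
from .psychro import BaselineModel

#: concentration reported for windows classified as odourless air, ou_E/m^3
AIR_CONCENTRATION_FLOOR = 20.0


@dataclass
class PcaModel:
    """Autoscaling + principal-component projection of a feature matrix."""

    scaler: StandardScaler
    pca: PCA
    n_pc: int
    feature_names: list[str]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_[: self.n_pc]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Project new samples onto the retained components."""
        if list(X.columns) != self.feature_names:
            X = X[self.feature_names]
        return self.pca.transform(self.scaler.transform(X.to_numpy(dtype=float)))[
            :, : self.n_pc
        ]

    def reconstruct(self, X: pd.DataFrame) -> np.ndarray:
        """Back-project through the retained components (autoscaled units)."""
        z = self.pca.transform(self.scaler.transform(X.to_numpy(dtype=float)))
        z[:, self.n_pc :] = 0.0
        return self.pca.inverse_transform(z)


def fit_pca(X: pd.DataFrame, n_pc: int = 3, variance_target: float | None = None) -> PcaModel:
    """Fit autoscaled PCA on a feature matrix.

    ``n_pc`` fixes the retained components (default 3); alternatively
    ``variance_target`` retains the smallest number of components whose
    cumulative explained variance reaches the target.  Zero-variance
    columns cannot be autoscaled and raise with the offending names.
    """
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 feature columns")
    arr = X.to_numpy(dtype=float)
    zero_var = [c for c, s in zip(X.columns, arr.std(axis=0)) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance feature column(s): {zero_var}")
    scaler = StandardScaler().fit(arr)
    pca = PCA(svd_solver="full").fit(scaler.transform(arr))
    if variance_target is not None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pc = int(np.searchsorted(cum, variance_target) + 1)
    n_pc = min(n_pc, pca.n_components_)
    return PcaModel(scaler=scaler, pca=pca, n_pc=n_pc, feature_names=list(X.columns))


@dataclass
class OutlierReport:
    """Influence-plot statistics: leverage (T^2) vs residual (Q) per sample."""

    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    t2_flag: np.ndarray
    q_flag: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        return self.t2_flag | self.q_flag

    @property
    def flagged_fraction(self) -> float:
        return float(self.flagged.mean())


def flag_outliers(model: PcaModel, X: pd.DataFrame, quantile: float = 0.975) -> OutlierReport:
    """Flag influence-plot outliers of a fitted PCA.

    Leverage uses Hotelling's T^2 over the retained scores with the
    F-based in-model limit; the residual statistic Q (squared
    reconstruction error off the PC plane) uses a moment-matched scaled
    chi-square limit.  Both limits default to the 97.5% quantile.
    """
    n = len(X)
    a = model.n_pc
    if a >= min(n - 1, len(model.feature_names)):
        raise ValueError("n_pc >= rank: residual statistic Q is undefined")
    z = model.transform(X)
    lam = model.pca.explained_variance_[:a]
    t2 = np.sum(z**2 / lam, axis=1)
    t2_limit = a * (n - 1) / (n - a) * stats.f.ppf(quantile, a, n - a)

    scaled = model.scaler.transform(X.to_numpy(dtype=float))
    resid = scaled - model.reconstruct(X)
    q = np.sum(resid**2, axis=1)
    m, v = q.mean(), q.var(ddof=1)
    if v <= 0:
        raise ValueError("degenerate residuals: Q limit undefined")
    g, h = v / (2 * m), 2 * m**2 / v
    q_limit = g * stats.chi2.ppf(quantile, h)

    return OutlierReport(
        t2=t2,
        q=q,
        t2_limit=float(t2_limit),
        q_limit=float(q_limit),
        t2_flag=t2 > t2_limit,
        q_flag=q > q_limit,
    )


def _rbf_gamma_grid(X: np.ndarray) -> list[float]:
    """Median-heuristic kernel width bracketed by two decades each way."""
    n = len(X)
    idx = np.arange(n)
    d2 = np.sum((X[idx[:, None], :] - X[None, idx, :]) ** 2, axis=-1)
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    g0 = 1.0 / med
    return [g0 * 10.0**k for k in (-2, -1, 0, 1, 2)]


_C_GRID = [10.0**k for k in range(-2, 4)]


@dataclass
class ClassifierModel:
    """RBF-SVM odour classifier on principal-component scores."""

    svc: SVC
    classes: list[str]
    cv_mcc: float
    best_params: dict

    def predict(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != self.svc.shape_fit_[1]:
            raise ValueError("score dimensionality does not match the fitted model")
        return self.svc.predict(scores)


def train_classifier(
    scores: np.ndarray, labels, cv: int = 10, seed: int = 0
) -> ClassifierModel:
    """Fit the RBF-SVM classifier with internal stratified k-fold CV.

    Hyperparameters (regularization C, kernel width gamma) are chosen on
    a log-spaced grid maximizing the Matthews correlation coefficient;
    the winning setting is refitted on the full training scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < cv:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} members, "
            f"fewer than cv={cv}; reduce cv or rebalance"
        )
    grid = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": _C_GRID, "gamma": _rbf_gamma_grid(scores)},
        scoring=make_scorer(matthews_corrcoef),
        cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    grid.fit(scores, labels)
    return ClassifierModel(
        svc=grid.best_estimator_,
        classes=[str(c) for c in classes],
        cv_mcc=float(grid.best_score_),
        best_params=dict(grid.best_params_),
    )


def predict_class(model: ClassifierModel, scores: np.ndarray) -> np.ndarray:
    """One predicted model class per window of scores."""
    return model.predict(scores)


@dataclass
class QuantifierModel:
    """SVR odour-concentration quantifier(s) on log10(ou_E/m^3).

    ``mode='QA'`` holds a single global regressor; ``mode='QB'`` one
    regressor per non-Air class, routed by the predicted class.  Windows
    classified as Air bypass regression and report the configured floor.
    Predictions are clamped to the concentration range seen in training:
    the instrument is calibrated only inside it.
    """

    mode: str
    regressors: dict[str, SVR]
    cv_rmse_log: dict[str, float]
    log_range: tuple[float, float]
    air_floor: float = AIR_CONCENTRATION_FLOOR

    def predict_log10(self, scores: np.ndarray, labels=None) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.mode == "QA":
            out = self.regressors["global"].predict(scores)
            return np.clip(out, *self.log_range)
        if labels is None:
            raise ValueError("mode QB requires a class label per window")
        labels = np.asarray(labels)
        out = np.empty(len(scores))
        air = labels == "Air"
        for cls in np.unique(labels):
            sel = labels == cls
            if cls == "Air":
                out[sel] = np.log10(self.air_floor)
                continue
            if cls not in self.regressors:
                raise ValueError(f"no trained regressor for class {cls!r}")
            out[sel] = self.regressors[cls].predict(scores[sel])
        out[~air] = np.clip(out[~air], *self.log_range)
        return out


def train_quantifier(
    scores: np.ndarray,
    concentrations,
    labels,
    mode: str = "QB",
    cv: int = 10,
    seed: int = 0,
) -> QuantifierModel:
    """Fit the SVR quantifier(s) on log10 concentration.

    The global mode (QA) trains on *all* samples — including Air windows,
    whose assigned olfactometry values sit at the method floor — exactly
    because it draws no class distinction; the class-specific mode (QB)
    fits one regressor per odour class and never regresses Air.
    Hyperparameters are chosen by k-fold CV minimizing RMSE in log space.
    """
    if mode not in ("QA", "QB"):
        raise ValueError("mode must be 'QA' or 'QB'")
    scores = np.asarray(scores, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    labels = np.asarray(labels)
    if np.any(conc <= 0):
        raise ValueError("odour concentrations must be positive")
    odour = labels != "Air"

    def _fit(X, y):
        folds = min(cv, len(X))
        grid = GridSearchCV(
            SVR(kernel="rbf", epsilon=0.05),
            {"C": _C_GRID, "gamma": _rbf_gamma_grid(X)},
            scoring="neg_root_mean_squared_error",
            cv=KFold(folds, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        grid.fit(X, y)
        return grid.best_estimator_, float(-grid.best_score_)

    regressors: dict[str, SVR] = {}
    cv_rmse: dict[str, float] = {}
    if mode == "QA":
        regressors["global"], cv_rmse["global"] = _fit(scores, np.log10(conc))
    else:
        Xo, yo, lo = scores[odour], np.log10(conc[odour]), labels[odour]
        for cls in np.unique(lo):
            sel = lo == cls
            if sel.sum() < 10:
                raise ValueError(f"class {cls!r} has {int(sel.sum())} samples; QB needs >= 10")
            regressors[str(cls)], cv_rmse[str(cls)] = _fit(Xo[sel], yo[sel])
    log_range = (float(np.log10(conc.min())), float(np.log10(conc.max())))
    return QuantifierModel(
        mode=mode, regressors=regressors, cv_rmse_log=cv_rmse, log_range=log_range
    )


def predict_concentration(
    model: QuantifierModel, scores: np.ndarray, labels=None
) -> np.ndarray:
    """Predicted odour concentration, ou_E/m^3 (inverse log10 transform)."""
    return 10.0 ** model.predict_log10(scores, labels)


@dataclass
class TrainedIoms:
    """Persisted training bundle: everything needed to process new windows."""

    mode_compensation: str
    baselines: dict[str, BaselineModel] | None
    selected_features: list[str]
    pca: PcaModel
    classifier: ClassifierModel
    quantifiers: dict[str, QuantifierModel]
    seed: int
    training_report: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return MODEL_CLASSES

    def provenance_hash(self) -> str:
        """Deterministic digest of the fitted state (seeds, params, supports)."""
        h = hashlib.sha256()
        h.update(json.dumps(
            {
                "mode": self.mode_compensation,
                "features": self.selected_features,
                "seed": self.seed,
                "svc": self.classifier.best_params,
                "baselines": {
                    k: b.to_dict() for k, b in (self.baselines or {}).items()
                },
            },
            sort_keys=True,
        ).encode())
        h.update(np.ascontiguousarray(self.pca.pca.components_).tobytes())
        h.update(np.ascontiguousarray(self.classifier.svc.dual_coef_).tobytes())
        for mode in sorted(self.quantifiers):
            for cls in sorted(self.quantifiers[mode].regressors):
                h.update(
                    np.ascontiguousarray(
                        self.quantifiers[mode].regressors[cls].dual_coef_
                    ).tobytes()
                )
        return h.hexdigest()

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedIoms":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not hold a TrainedIoms bundle")
        return bundle
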