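"""End-to-end orchestration: training, field testing and monitoring.

``run_training`` executes the full chain on an annotated campaign:
compensation -> feature extraction -> shadow-feature selection -> PCA ->
influence-plot outlier removal -> SVM classifier -> SVR quantifiers,
and packs the fitted state into a :class:`~fenceline.chemometrics.TrainedIoms`
bundle.  ``run_field_test`` evaluates a bundle on held-out annotated
samples (classification report plus Bland-Altman agreement per
quantifier mode), and ``run_monitoring`` turns a continuous stream into
one class + concentration output per 5-min window.

Reference baselines are refit from each campaign's odourless (Air)
windows before prediction ("field re-zeroing"): the static and dynamic
references describe the sensors *as they currently respond*, so
re-zeroing on current clean air absorbs the slow multiplicative drift
of MOX elements between campaigns.  The dynamic model still handles
humidity through its AH input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (
    TrainedIoms,
    fit_pca,
    flag_outliers,
    predict_class,
    predict_concentration,
    train_classifier,
    train_quantifier,
)
from .evaluation import (
    AgreementReport,
    ClassificationReport,
    EnVerdicts,
    bland_altman,
    confusion_and_mcc,
    en13725_check,
)
from .features import build_feature_matrix, extract_features
from .io import SensorStream, TrainingSample, segment_stream, window_for_sample
from .psychro import compensate_window, fit_baselines
from .selection import boruta_select

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the processing chain in one place."""

    compensation: str = "CC"  # CA | CB | CC
    # retained principal components: the operative rule is 90% cumulative
    # explained variance (about 3 components on typical campaigns);
    # setting n_pc overrides the variance target with a fixed count
    n_pc: int | None = None
    variance_target: float = 0.90
    cv: int = 10
    seed: int = 0
    select_features: bool = True
    boruta_iter: int = 30
    outlier_quantile: float = 0.975
    min_fill: float = 0.8
    quantifier_modes: tuple[str, ...] = ("QA", "QB")
    rezero: bool = True
    baseline_degree: int | None = None  # None: automatic degree selection


def _odourless_records(
    stream: SensorStream, samples: list[TrainingSample]
) -> SensorStream:
    """Concatenate the records of all Air windows into one odourless stream."""
    parts = [
        stream.slice(s.start, s.end) for s in samples if s.source_class == "Air"
    ]
    if not parts:
        raise ValueError("no Air windows available to fit reference baselines")
    return SensorStream(
        pd.concat(parts).reset_index(drop=True), cadence_s=stream.cadence_s
    )


def _extract_matrix(
    stream: SensorStream,
    samples: list[TrainingSample],
    baselines,
    config: PipelineConfig,
):
    """Compensated feature matrix + labels + concentrations for annotations."""
    rows, labels, concs, kept = [], [], [], []
    n_skipped = 0
    for s in samples:
        window = window_for_sample(stream, s, min_fill=config.min_fill)
        if window.underfilled:
            n_skipped += 1
            logger.warning("sample %s under-filled; skipped", s.sample_id)
            continue
        comp = compensate_window(window.records, baselines, config.compensation)
        rows.append(extract_features(window, comp))
        labels.append(s.model_class)
        concs.append(s.odour_concentration)
        kept.append(s.sample_id)
    if not rows:
        raise ValueError("no usable annotated windows")
    X = build_feature_matrix(rows, index=kept)
    return X, np.array(labels), np.array(concs), n_skipped


def _normalize_campaigns(campaigns) -> list[tuple[SensorStream, list[TrainingSample]]]:
    if isinstance(campaigns, tuple) and isinstance(campaigns[0], SensorStream):
        return [campaigns]
    return list(campaigns)


def run_training(
    campaigns,
    config: PipelineConfig | None = None,
) -> TrainedIoms:
    """Train the full model bundle on annotated training campaigns.

    ``campaigns`` is one ``(stream, samples)`` pair or a list of them —
    one pair per olfactometric campaign.  Reference baselines are fitted
    per campaign from that campaign's odourless (Air) windows, so slow
    sensor drift between campaigns is absorbed before features are
    pooled; the bundle keeps the *last* campaign's baselines as the
    starting point for monitoring.
    """
    config = config or PipelineConfig()
    pairs = _normalize_campaigns(campaigns)
    parts = []
    baselines = None
    n_train_total = 0
    n_skipped = 0
    for stream, samples in pairs:
        train = [s for s in samples if s.role == "train"]
        if not train:
            continue
        n_train_total += len(train)
        if config.compensation != "CA":
            baselines = fit_baselines(
                _odourless_records(stream, train),
                mode=config.compensation,
                degree=config.baseline_degree,
            )
        parts.append(_extract_matrix(stream, train, baselines, config))
        n_skipped += parts[-1][3]
    if not parts:
        raise ValueError("no samples with role='train'")
    X = pd.concat([p[0] for p in parts])
    labels = np.concatenate([p[1] for p in parts])
    concs = np.concatenate([p[2] for p in parts])

    if config.select_features:
        selection = boruta_select(
            X, labels, max_iter=config.boruta_iter, seed=config.seed
        )
        selected = selection.confirmed
        if len(selected) < 3:
            selected = selection.confirmed + selection.tentative
        if len(selected) < 3:
            selected = list(X.columns)
        selection_summary = {
            "confirmed": len(selection.confirmed),
            "rejected": len(selection.rejected),
            "tentative": len(selection.tentative),
        }
    else:
        selected = list(X.columns)
        selection_summary = None
    Xs = X[selected]

    # influence-plot outlier pass, class-conditional: the TS spans the
    # concentration range by design, so global leverage mostly flags the
    # design extremes; within-class T2/Q statistics target genuine
    # anomalies (contaminated samples, pattern deviations) instead
    def _fit_pca_cfg(frame):
        if config.n_pc is not None:
            return fit_pca(frame, n_pc=config.n_pc)
        return fit_pca(frame, variance_target=config.variance_target)

    flagged = np.zeros(len(Xs), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        try:
            pca_cls = _fit_pca_cfg(Xs.iloc[idx])
            rep_cls = flag_outliers(
                pca_cls, Xs.iloc[idx], quantile=config.outlier_quantile
            )
        except ValueError:
            continue
        flagged[idx] = rep_cls.flagged
    keep = ~flagged
    Xc, labels_c, concs_c = Xs.loc[keep], labels[keep], concs[keep]
    pca = _fit_pca_cfg(Xc)
    scores = pca.transform(Xc)

    cv = min(config.cv, int(np.bincount(pd.factorize(labels_c)[0]).min()))
    classifier = train_classifier(scores, labels_c, cv=cv, seed=config.seed)
    quantifiers = {
        mode: train_quantifier(
            scores, concs_c, labels_c, mode=mode, cv=cv, seed=config.seed
        )
        for mode in config.quantifier_modes
    }

    bundle = TrainedIoms(
        mode_compensation=config.compensation,
        baselines=baselines,
        selected_features=selected,
        pca=pca,
        classifier=classifier,
        quantifiers=quantifiers,
        seed=config.seed,
        training_report={
            "n_train_samples": n_train_total,
            "n_underfilled_skipped": n_skipped,
            "n_outliers_removed": int(flagged.sum()),
            "outlier_fraction": float(flagged.mean()),
            "explained_variance_ratio": [
                float(v) for v in pca.explained_variance_ratio
            ],
            "cv_mcc": classifier.cv_mcc,
            "cv_rmse_log": {m: q.cv_rmse_log for m, q in quantifiers.items()},
            "selection": selection_summary,
        },
    )
    logger.info(
        "training done: CV MCC %.3f, %d/%d outliers removed, %d features",
        classifier.cv_mcc,
        int(flagged.sum()),
        len(X),
        len(selected),
    )
    return bundle


def _bundle_baselines(
    bundle: TrainedIoms,
    stream: SensorStream,
    samples: list[TrainingSample] | None,
    config: PipelineConfig,
):
    """Bundle baselines, optionally re-zeroed on this campaign's Air windows."""
    if bundle.mode_compensation == "CA":
        return None
    if config.rezero and samples is not None:
        try:
            return fit_baselines(
                _odourless_records(stream, samples),
                mode=bundle.mode_compensation,
                degree=config.baseline_degree,
            )
        except ValueError:
            logger.warning("no Air windows for re-zeroing; using training baselines")
    return bundle.baselines


@dataclass
class FieldTestReport:
    """Side-by-side field evaluation of the classifier and both quantifiers."""

    classification: ClassificationReport
    agreement: dict[str, AgreementReport]
    verdicts: dict[str, EnVerdicts]
    n_test: int
    predictions: pd.DataFrame = field(repr=False, default=None)


def run_field_test(
    stream: SensorStream,
    samples: list[TrainingSample],
    bundle: TrainedIoms,
    config: PipelineConfig | None = None,
) -> FieldTestReport:
    """Evaluate a trained bundle on held-out (role='test') samples.

    Classification is scored against the annotated model classes;
    quantification compares each quantifier mode's predictions with the
    olfactometry values of the true-odour (non-Air) samples via
    Bland-Altman on log10 concentrations, plus the olfactometry quality
    criteria.  Quantifier routing (mode QB) uses the *predicted* class,
    as during monitoring.
    """
    config = config or PipelineConfig(compensation=bundle.mode_compensation)
    test = [s for s in samples if s.role == "test"]
    if not test:
        raise ValueError("no samples with role='test'")
    baselines = _bundle_baselines(bundle, stream, test, config)
    cfg = PipelineConfig(
        compensation=bundle.mode_compensation, min_fill=config.min_fill
    )
    X, labels, concs, _ = _extract_matrix(stream, test, baselines, cfg)
    scores = bundle.pca.transform(X[bundle.selected_features])
    predicted = predict_class(bundle.classifier, scores)

    classification = confusion_and_mcc(labels, predicted)

    # agreement pairs need a concentration estimate from both methods: a
    # window the instrument classifies as Air yields no quantification,
    # so only windows with a true olfactometry value *and* a non-Air
    # prediction enter the Bland-Altman comparison (same mask for every
    # quantifier mode, to keep the comparison paired)
    quantified = (labels != "Air") & (predicted != "Air")
    pred_df = pd.DataFrame(
        {
            "sample_id": X.index,
            "true_class": labels,
            "predicted_class": predicted,
            "true_concentration": concs,
            "quantified": quantified,
        }
    )
    agreement, verdicts = {}, {}
    if quantified.sum() >= 3:
        for mode, quantifier in bundle.quantifiers.items():
            pred_conc = predict_concentration(
                quantifier, scores[quantified], predicted[quantified]
            )
            agreement[mode] = bland_altman(pred_conc, concs[quantified])
            verdicts[mode] = en13725_check(agreement[mode])
            col = np.full(len(pred_df), np.nan)
            col[quantified] = pred_conc
            pred_df[f"predicted_conc_{mode}"] = col
    else:
        logger.warning(
            "only %d quantified odour windows: agreement analysis skipped",
            int(quantified.sum()),
        )
    return FieldTestReport(
        classification=classification,
        agreement=agreement,
        verdicts=verdicts,
        n_test=len(test),
        predictions=pred_df,
    )


@dataclass
class MonitoringResult:
    """Per-window outputs plus the summary detection frequencies."""

    windows: pd.DataFrame  # timestamp, predicted class/concentration, flags
    class_frequency: dict[str, float]  # % of valid windows per class
    odour_frequency: float  # % of valid windows classified as non-Air
    n_windows: int
    n_underfilled: int


def run_monitoring(
    stream: SensorStream,
    bundle: TrainedIoms,
    config: PipelineConfig | None = None,
    quantifier_mode: str = "QB",
) -> MonitoringResult:
    """Process a continuous stream into per-5-min class + concentration.

    Under-filled windows yield a flagged no-output row; detection
    frequencies are percentages of the valid (filled) windows.
    """
    config = config or PipelineConfig(compensation=bundle.mode_compensation)
    if quantifier_mode not in bundle.quantifiers:
        raise ValueError(f"bundle holds no quantifier mode {quantifier_mode!r}")
    baselines = bundle.baselines
    windows = segment_stream(stream, width_s=300.0, min_fill=config.min_fill)

    rows, feats, valid_idx = [], [], []
    for k, w in enumerate(windows):
        if w.underfilled or len(w.records) < 3:
            rows.append(
                {"window": k, "start": w.start, "predicted_class": None,
                 "predicted_concentration": np.nan, "underfilled": True}
            )
            continue
        comp = compensate_window(w.records, baselines, bundle.mode_compensation)
        feats.append(extract_features(w, comp))
        valid_idx.append(k)
        rows.append(
            {"window": k, "start": w.start, "predicted_class": None,
             "predicted_concentration": np.nan, "underfilled": False}
        )
    out = pd.DataFrame(rows)

    if valid_idx:
        X = build_feature_matrix(feats)
        scores = bundle.pca.transform(X[bundle.selected_features])
        predicted = predict_class(bundle.classifier, scores)
        conc = predict_concentration(
            bundle.quantifiers[quantifier_mode], scores, predicted
        )
        out.loc[out["window"].isin(valid_idx), "predicted_class"] = predicted
        out.loc[out["window"].isin(valid_idx), "predicted_concentration"] = conc

    valid = out.loc[~out["underfilled"]]
    n_valid = len(valid)
    class_freq = {
        cls: 100.0 * float((valid["predicted_class"] == cls).sum()) / n_valid
        if n_valid
        else 0.0
        for cls in bundle.classifier.classes
    }
    odour_freq = (
        100.0 * float((valid["predicted_class"] != "Air").sum()) / n_valid
        if n_valid
        else 0.0
    )
    return MonitoringResult(
        windows=out,
        class_frequency=class_freq,
        odour_frequency=odour_freq,
        n_windows=len(windows),
        n_underfilled=int(out["underfilled"].sum()),
    )
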