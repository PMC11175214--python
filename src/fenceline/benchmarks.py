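"""Named benchmark experiments on the synthetic sensor bench.

Each function defines one reproducible in-silico study condition and
runs the full pipeline on it.  They exist so that the same experiment
definitions back both the test suite and reproduction scripts:

``compensation_ordering_bench``
    Trains the three pre-treatment variants (raw CA, static CB, dynamic
    CC) on one campaign and field-tests them on a campaign conducted
    four months later, under sinusoidal absolute humidity (5-18 g/m^3)
    and 2% relative MOX noise.  The expected outcome is the ordering
    MCC(CC) >= MCC(CB) >= MCC(CA): only the dynamic reference removes
    the humidity confound, and only the re-zeroed references absorb
    sensor aging.

``quantifier_comparison_bench``
    Compares the global (QA) and class-specific (QB) quantifiers on a
    scenario with strongly class-distinct concentration gains (both in
    the MOX response magnitudes and in the PID response factors), using
    the fixed three-component projection.  The comparison pools
    prediction/olfactometry pairs over independent replicate
    experiments and reports one Bland-Altman agreement per quantifier;
    the expected outcome is a narrower limits-of-agreement interval for
    the two-step QB scheme.

``recovery_bench``
    Generator-truth recovery: exact polynomial recovery of the
    humidity baseline from a noiseless sweep, and classifier /
    quantifier quality on a low-noise campaign.

``calibration_bench``
    Statistical calibration: influence-plot flagging rate on a clean
    Gaussian cloud, and shadow-feature selection behaviour (planted
    informative features confirmed, pure-noise features rejected)
    aggregated over independent seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemometrics import fit_pca, flag_outliers
from .evaluation import bland_altman, en13725_check
from .pipeline import PipelineConfig, run_field_test, run_training
from .psychro import fit_dynamic_baseline
from .selection import boruta_select
from .simulate import SimConfig, simulate_campaign

#: quantifier-comparison scenario: class-distinct concentration gains.
#: MOX response magnitudes differ ~3x between Biogas and the organic
#: sources, and the broadband PID response factor differs ~6x, so equal
#: odour concentrations produce very different signal amplitudes
#: depending on the class — the situation the two-step scheme targets.
DISTINCT_GAINS = {
    "Air": [0.0, 0.0, 0.0, 0.0],
    "Biogas": [0.36, 0.05, 0.24, 0.06],
    "Sheds": [0.05, 0.13, 0.04, 0.11],
    "Biofilter": [0.04, 0.11, 0.03, 0.09],
}
DISTINCT_H2S = {"Air": 0.0, "Biogas": 6e-4, "Sheds": 3e-4, "Biofilter": 2.5e-4}
DISTINCT_NH3 = {"Air": 0.0, "Biogas": 2e-4, "Sheds": 4e-4, "Biofilter": 3.5e-4}
DISTINCT_PID = {"Air": 0.0, "Biogas": 3.0, "Sheds": 0.5, "Biofilter": 0.7}


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def compensation_ordering_bench(
    seed: int, train_per_class: int = 40, test_per_class: int = 20
) -> dict:
    """Field-test MCC of the CA / CB / CC pre-treatments on one seeded study."""
    sim = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    train = simulate_campaign(
        sim, train_per_class, campaign_id="T", role="train",
        seed=_sub_seed(rng), age_months=0.0,
    )
    test = simulate_campaign(
        sim, test_per_class, campaign_id="F", role="test",
        seed=_sub_seed(rng), age_months=4.0,
    )
    out = {}
    for mode in ("CA", "CB", "CC"):
        # classification-only comparison: quantifier training skipped
        config = PipelineConfig(compensation=mode, seed=seed, quantifier_modes=())
        bundle = run_training(train, config)
        report = run_field_test(test[0], test[1], bundle, config)
        out[mode] = {
            "test_mcc": report.classification.mcc,
            "cv_mcc": bundle.training_report["cv_mcc"],
            "n_test": report.n_test,
        }
    return out


def quantifier_comparison_bench(
    seed: int,
    replicates: int = 4,
    train_per_class: int = 60,
    test_per_class: int = 40,
) -> dict:
    """Pooled Bland-Altman comparison of the QA and QB quantifiers."""
    rng = np.random.default_rng(seed + 77)
    pools: dict[str, tuple[list, list]] = {"QA": ([], []), "QB": ([], [])}
    mccs = []
    for _ in range(replicates):
        rep_seed = _sub_seed(rng)
        sim = SimConfig(
            seed=rep_seed,
            gains=dict(DISTINCT_GAINS),
            h2s_content=dict(DISTINCT_H2S),
            nh3_content=dict(DISTINCT_NH3),
            pid_gain=dict(DISTINCT_PID),
            sample_jitter_sd=0.02,
        )
        sub = np.random.default_rng(rep_seed)
        train = simulate_campaign(
            sim, train_per_class, campaign_id="T", role="train",
            seed=_sub_seed(sub), age_months=0.0,
        )
        config = PipelineConfig(compensation="CC", seed=rep_seed, n_pc=3)
        bundle = run_training(train, config)
        test = simulate_campaign(
            sim, test_per_class, campaign_id="F", role="test",
            seed=_sub_seed(sub), age_months=4.0,
        )
        report = run_field_test(test[0], test[1], bundle, config)
        mccs.append(report.classification.mcc)
        df = report.predictions
        mask = df["quantified"]
        for mode in ("QA", "QB"):
            pools[mode][0].extend(df.loc[mask, f"predicted_conc_{mode}"])
            pools[mode][1].extend(df.loc[mask, "true_concentration"])
    out = {"mcc_mean": float(np.mean(mccs))}
    for mode in ("QA", "QB"):
        agreement = bland_altman(pools[mode][0], pools[mode][1])
        verdicts = en13725_check(agreement)
        out[mode] = {
            "agreement": agreement,
            "loa_width_log": agreement.loa_width_log,
            "en_precision_value": verdicts.precision_value,
            "n_pairs": agreement.n,
        }
    return out


def recovery_bench(seed: int, train_per_class: int = 40) -> dict:
    """Generator-truth recovery on noiseless / low-noise conditions."""
    # exact polynomial recovery from a noiseless AH sweep
    sim0 = SimConfig(seed=seed, noise_rel=0.0, sample_jitter_sd=0.0)
    ah = np.linspace(*sim0.ah_range, 400)
    max_rel_err = 0.0
    for sensor in range(4):
        truth = sim0.baseline_coefficients(sensor)
        fitted = fit_dynamic_baseline(
            sim0.baseline_resistance(ah, sensor), ah, degree=2
        )
        rel = np.max(np.abs(np.asarray(fitted.coefficients) - truth) / np.abs(truth))
        max_rel_err = max(max_rel_err, float(rel))

    # classifier and quantifier quality on a low-noise campaign
    sim = SimConfig(seed=seed, noise_rel=0.005, sample_jitter_sd=0.0)
    rng = np.random.default_rng(seed)
    train = simulate_campaign(
        sim, train_per_class, campaign_id="T", role="train",
        seed=_sub_seed(rng), age_months=0.0,
    )
    config = PipelineConfig(compensation="CC", seed=seed)
    bundle = run_training(train, config)
    cv_rmse_qb = max(bundle.training_report["cv_rmse_log"]["QB"].values())
    return {
        "baseline_coeff_max_rel_err": max_rel_err,
        "classifier_cv_mcc": bundle.training_report["cv_mcc"],
        "quantifier_cv_log_rmse": float(cv_rmse_qb),
        "n_train": train_per_class * 3,
    }


def calibration_bench(
    seed: int,
    n_cloud: int = 2000,
    n_features: int = 8,
    boruta_seeds: int = 20,
) -> dict:
    """Outlier-rate calibration and shadow-feature selection behaviour."""
    rng = np.random.default_rng(seed)
    cloud = pd.DataFrame(
        rng.standard_normal((n_cloud, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    pca = fit_pca(cloud, n_pc=3)
    rate = flag_outliers(pca, cloud, quantile=0.975).flagged_fraction

    confirmed_hits = 0
    noise_total = 0
    noise_rejected = 0
    n_noise = 15
    n_rows = 250
    for _ in range(boruta_seeds):
        sub = np.random.default_rng(_sub_seed(rng))
        y = np.repeat([0, 1], n_rows // 2)
        informative = y + 0.05 * sub.standard_normal(n_rows)
        X = pd.DataFrame(
            np.column_stack([informative, sub.standard_normal((n_rows, n_noise))]),
            columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
        )
        result = boruta_select(
            X, y, max_iter=40, seed=_sub_seed(sub), n_estimators=60
        )
        confirmed_hits += int("signal" in result.confirmed)
        noise_total += n_noise
        noise_rejected += sum(
            1 for f in result.rejected if f.startswith("noise")
        )
    return {
        "outlier_flag_rate": float(rate),
        "informative_confirmed_fraction": confirmed_hits / boruta_seeds,
        "noise_rejected_fraction": noise_rejected / noise_total,
        "n_cloud": n_cloud,
        "boruta_seeds": boruta_seeds,
    }
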