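"""Seeded simulator of e-nose sensor streams with ground truth.

The study's field data are confidential, so every pipeline stage is
exercised against this generator instead.  It reproduces the phenomena
the pipeline exists to handle:

* **Humidity-driven MOX baselines** — each MOX sensor's odourless
  resistance is a decreasing polynomial of absolute humidity, evaluated
  on a sinusoidal ambient AH profile (default 5-18 g/m^3) with
  temperature varying in phase so derived RH stays physical.
* **Inter-campaign sensor drift** — each campaign applies an independent
  multiplicative log-normal factor per sensor, emulating the slow
  response drift of MOX elements between seasons.
* **Class-specific response patterns** — an odour of class c at
  concentration C drops sensor i's resistance by the fraction
  ``min(k_ic * log10(C / C0), cap)`` (first-order rise, time constant
  ``tau_s``); electrochemical channels respond in proportion to the
  class's H2S / NH3 content and the PID in proportion to C with a
  class-specific response factor.  Different classes at equal C thus
  produce different array patterns, the premise of the two-step
  classify-then-quantify scheme.
* **Noise** — multiplicative Gaussian noise on MOX resistances,
  additive/proportional noise on the electrochemical and PID channels.

All randomness flows from a single integer seed; identical seeds give
identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    MOX_COLUMNS,
    SENSOR_COLUMNS,
    SensorStream,
    TrainingSample,
)
from .psychro import DEFAULT_CONSTANTS, RW, saturation_vapour_pressure

#: the study's campaign layout: diluted-sample counts per olfactometric
#: campaign and their training/test roles (first four campaigns train,
#: the fifth is the held-out field-test campaign)
STUDY_CAMPAIGN_PLAN = pd.DataFrame(
    {
        "campaign": ["2022-02", "2022-04", "2022-05", "2022-07", "2022-10"],
        "source_samples": [13, 17, 6, 15, 19],
        "diluted_samples": [47, 65, 25, 59, 44],
        "role": ["train", "train", "train", "train", "test"],
    }
)

#: diluted-sample counts and concentration ranges per source class
STUDY_CLASS_TABLE = pd.DataFrame(
    {
        "source_class": ["Air", "Biogas", "Biofilter", "Sheds"],
        "n_diluted": [33, 65, 49, 93],
        "conc_lo": [20.0, 22.0, 32.0, 27.0],
        "conc_hi": [50.0, 990.0, 860.0, 950.0],
    }
).set_index("source_class")

_DEFAULT_GAINS = {
    "Air": [0.0, 0.0, 0.0, 0.0],
    "Biogas": [0.30, 0.05, 0.20, 0.06],
    "Sheds": [0.06, 0.16, 0.05, 0.14],
    "Biofilter": [0.05, 0.13, 0.04, 0.12],
}

# electrochemical content coefficients, ppm per (ou_E/m^3)
_DEFAULT_H2S = {"Air": 0.0, "Biogas": 1.0e-4, "Sheds": 5e-5, "Biofilter": 4e-5}
_DEFAULT_NH3 = {"Air": 0.0, "Biogas": 3e-5, "Sheds": 7e-5, "Biofilter": 6e-5}
# PID response factors, ppb isobutylene-equivalent per (ou_E/m^3);
# class-specific because different odour mixes photo-ionize differently.
# At fenceline concentrations the EC/PID channels sit near their
# detection limits, so these responses are small relative to noise
_DEFAULT_PID = {"Air": 0.0, "Biogas": 0.5, "Sheds": 0.16, "Biofilter": 0.2}


@dataclass
class SimConfig:
    """Configuration of the synthetic sensor-array bench."""

    seed: int = 0
    cadence_s: float = 10.0
    window_s: float = 300.0
    start: str = "2022-02-01T00:00:00+00:00"

    # odourless baseline polynomial per MOX sensor: R0 * (1 - h1*AH + h2*AH^2)
    r0: tuple[float, ...] = (220e3, 150e3, 300e3, 180e3)
    # per-sensor AH sensitivities: deliberately pattern-correlated with a
    # reducing-gas response, so humidity swings mimic odour events on the
    # raw and statically normalized signals (the confound the dynamic
    # reference exists to remove)
    h1: tuple[float, ...] = (0.048, 0.010, 0.036, 0.011)
    h2: tuple[float, ...] = (3.0e-4, 2.0e-4, 4.0e-4, 2.5e-4)

    # ambient generators
    ah_range: tuple[float, float] = (5.0, 18.0)
    # fixed ambient timescale: campaigns of different lengths must see the
    # same within-window AH slope statistics (None: one cycle per stream)
    ambient_period_s: float | None = 21600.0
    temp_mean_c: float = 16.0
    temp_amp_c: float = 9.0

    # odour response
    gains: dict = field(default_factory=lambda: dict(_DEFAULT_GAINS))
    response_law: str = "log"  # 'log' or 'power'
    # sensor response threshold, ou_E/m^3: set below the olfactometry
    # range floor (20) so every odour presentation in the measured range
    # evokes a pattern, as the instruments' field discrimination implies
    c0: float = 5.0
    cap: float = 0.8
    tau_s: float = 40.0
    h2s_content: dict = field(default_factory=lambda: dict(_DEFAULT_H2S))
    nh3_content: dict = field(default_factory=lambda: dict(_DEFAULT_NH3))
    pid_gain: dict = field(default_factory=lambda: dict(_DEFAULT_PID))
    humidity_response_coupling: float = 0.0  # off: compensation targets baseline only
    # per-presentation composition variability: each sample's MOX / H2S /
    # NH3 / PID responses are scaled by independent lognormal factors
    # (same factor across the 4 MOX elements), because two grabs from the
    # same source never have identical chemical make-up
    sample_jitter_sd: float = 0.08

    # noise and drift
    noise_rel: float = 0.02  # MOX multiplicative
    ec_noise: float = 0.05  # ppm additive
    ec_noise_rel: float = 0.2
    pid_noise: float = 5.0  # ppb additive
    pid_air_level: float = 20.0  # ppb odourless background
    # sensor aging: deterministic sensitivity decay per month of campaign
    # age, strongest for the most gas-sensitive MOX elements (as observed
    # for aging MOX layers), plus a small random scatter per campaign
    mox_decay_per_month: tuple[float, ...] = (0.11, 0.025, 0.10, 0.03)
    aux_decay_per_month: tuple[float, ...] = (0.05, 0.05, 0.03)
    drift_noise_sd: float = 0.05
    h1_drift_sd: float = 0.0  # optional drift of AH sensitivity (stress tests)

    def with_noise(self, noise_rel: float) -> "SimConfig":
        return replace(self, noise_rel=noise_rel)

    def baseline_resistance(self, ah, sensor: int, h1_factor: float = 1.0) -> np.ndarray:
        """Ground-truth odourless resistance of one MOX sensor at given AH.

        ``h1_factor`` scales the linear AH sensitivity: aging of the
        sensing layer changes not only the overall scale of a MOX element
        but also how strongly water vapour depresses it.
        """
        ah = np.asarray(ah, dtype=float)
        return self.r0[sensor] * (
            1 - h1_factor * self.h1[sensor] * ah + self.h2[sensor] * ah**2
        )

    def baseline_coefficients(self, sensor: int) -> np.ndarray:
        """Ascending-power polynomial coefficients of the true baseline."""
        r = self.r0[sensor]
        return np.array([r, -r * self.h1[sensor], r * self.h2[sensor]])

    def fractional_drop(self, source_class: str, concentration: float) -> np.ndarray:
        """Per-sensor steady-state fractional resistance drop for an odour."""
        k = np.asarray(self.gains[source_class], dtype=float)
        if self.response_law == "log":
            x = max(np.log10(max(concentration / self.c0, 1.0)), 0.0)
        elif self.response_law == "power":
            x = max(concentration / self.c0 - 1.0, 0.0) ** 0.5
        else:
            raise ValueError(f"unknown response law {self.response_law!r}")
        return np.minimum(k * x, self.cap)


def _ambient_profile(config: SimConfig, t: np.ndarray, duration_s: float, phase: float):
    """Sinusoidal AH with temperature in phase; RH derived psychrometrically."""
    period = config.ambient_period_s or duration_s
    s = np.sin(2 * np.pi * t / period + phase)
    lo, hi = config.ah_range
    ah = (lo + hi) / 2 + (hi - lo) / 2 * s
    temp_c = config.temp_mean_c + config.temp_amp_c * s
    temp_k = temp_c + 273.15
    ps = saturation_vapour_pressure(temp_k, DEFAULT_CONSTANTS)
    rh = ah / 1000.0 * RW * temp_k / ps * 100.0
    return ah, temp_c, np.clip(rh, 1.0, 100.0)


def _event_rise(t: np.ndarray, t_on: float, t_off: float, tau: float) -> np.ndarray:
    """First-order approach to steady state inside [t_on, t_off), 0 outside."""
    rise = np.zeros_like(t)
    inside = (t >= t_on) & (t < t_off)
    rise[inside] = 1.0 - np.exp(-(t[inside] - t_on) / tau)
    return rise


@dataclass
class DriftState:
    """One campaign's sensitivity state relative to nominal.

    ``mox_scale`` multiplies each MOX resistance, ``h1_factor`` its AH
    sensitivity, and ``aux_scale`` the (H2S, NH3, PID) channel
    sensitivities.
    """

    mox_scale: np.ndarray
    h1_factor: np.ndarray
    aux_scale: np.ndarray

    @classmethod
    def identity(cls) -> "DriftState":
        return cls(np.ones(4), np.ones(4), np.ones(3))


def _draw_drift(
    config: SimConfig, rng: np.random.Generator, age_months: float = 0.0
) -> DriftState:
    """Drift state of a campaign conducted ``age_months`` after installation."""
    mox = np.exp(
        -np.asarray(config.mox_decay_per_month) * age_months
        + config.drift_noise_sd * rng.standard_normal(4)
    )
    aux = np.exp(
        -np.asarray(config.aux_decay_per_month) * age_months
        + config.drift_noise_sd * rng.standard_normal(3)
    )
    h1f = np.exp(config.h1_drift_sd * rng.standard_normal(4))
    return DriftState(mox_scale=mox, h1_factor=h1f, aux_scale=aux)


def _render_stream(
    config: SimConfig,
    duration_s: float,
    events: list[tuple[float, float, str, float]],
    rng: np.random.Generator,
    phase: float,
    drift: DriftState,
    t0: pd.Timestamp,
) -> SensorStream:
    """Assemble a stream from ambient profile + events + noise + drift."""
    n = int(round(duration_s / config.cadence_s))
    if n < 2:
        raise ValueError("degenerate duration: fewer than 2 records")
    t = np.arange(n) * config.cadence_s
    ah, temp_c, rh = _ambient_profile(config, t, duration_s, phase)

    mox = np.empty((n, 4))
    for i in range(4):
        mox[:, i] = (
            config.baseline_resistance(ah, i, h1_factor=drift.h1_factor[i])
            * drift.mox_scale[i]
        )
    h2s = np.zeros(n)
    nh3 = np.zeros(n)
    pid = np.full(n, config.pid_air_level, dtype=float)

    for event in events:
        t_on, dur, cls, conc = event[:4]
        jit = event[4] if len(event) > 4 else np.ones(4)
        rise = _event_rise(t, t_on, t_on + dur, config.tau_s)
        active = rise > 0
        if not active.any():
            continue
        drop = np.minimum(config.fractional_drop(cls, conc) * jit[0], config.cap)
        if config.humidity_response_coupling:
            drop = drop[None, :] * (
                1 + config.humidity_response_coupling * (ah[active, None] - 10.0) / 10.0
            )
            mox[active] *= 1 - drop * rise[active, None]
        else:
            mox[active] *= 1 - drop[None, :] * rise[active, None]
        h2s[active] += (
            jit[1] * drift.aux_scale[0] * config.h2s_content[cls] * conc * rise[active]
        )
        nh3[active] += (
            jit[2] * drift.aux_scale[1] * config.nh3_content[cls] * conc * rise[active]
        )
        pid[active] += (
            jit[3] * drift.aux_scale[2] * config.pid_gain[cls] * conc * rise[active]
        )

    mox *= 1 + config.noise_rel * rng.standard_normal(mox.shape)
    mox = np.maximum(mox, 1.0)  # resistances stay positive
    h2s = np.maximum(
        h2s * (1 + config.ec_noise_rel * rng.standard_normal(n))
        + config.ec_noise * np.abs(rng.standard_normal(n)),
        0.0,
    )
    nh3 = np.maximum(
        nh3 * (1 + config.ec_noise_rel * rng.standard_normal(n))
        + config.ec_noise * np.abs(rng.standard_normal(n)),
        0.0,
    )
    pid = np.maximum(pid + config.pid_noise * rng.standard_normal(n), 0.0)

    df = pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(t, unit="s"),
            "mox1_ohm": mox[:, 0],
            "mox2_ohm": mox[:, 1],
            "mox3_ohm": mox[:, 2],
            "mox4_ohm": mox[:, 3],
            "ec_h2s": h2s,
            "ec_nh3": nh3,
            "pid": pid,
            "temp_c": temp_c,
            "rh_pct": rh,
        },
        columns=SENSOR_COLUMNS,
    )
    return SensorStream(df, cadence_s=config.cadence_s)


def simulate_ambient(
    config: SimConfig, duration_s: float, seed: int | None = None
) -> SensorStream:
    """Odourless stream: pure humidity-driven baselines plus noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    phase = rng.uniform(0, 2 * np.pi)
    return _render_stream(
        config,
        duration_s,
        events=[],
        rng=rng,
        phase=phase,
        drift=DriftState.identity(),
        t0=pd.Timestamp(config.start),
    )


def simulate_campaign(
    config: SimConfig,
    samples_per_class: int = 40,
    classes: tuple[str, ...] = ("Air", "Biogas", "Sheds"),
    conc_range: tuple[float, float] | None = None,
    campaign_id: str = "C1",
    role: str = "train",
    seed: int | None = None,
    age_months: float = 0.0,
    drift: DriftState | None = None,
) -> tuple[SensorStream, list[TrainingSample]]:
    """One olfactometric campaign: labelled 5-min presentations with truth.

    Each sample occupies one analysis window; windows are laid out
    back-to-back while ambient AH sweeps one full sinusoidal cycle, so
    every class is presented across the humidity range.  Non-Air
    concentrations are log-uniform over the class's range (defaults from
    the study's per-class table, overridable with ``conc_range``); Air
    windows receive no injected response and carry the nominal odourless
    concentration range.
    """
    if samples_per_class < 1:
        raise ValueError("samples_per_class must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if drift is None:
        drift = _draw_drift(config, rng, age_months)
    n_samples = samples_per_class * len(classes)
    # each presentation occupies a two-window slot: the sample is opened
    # half a window before the annotated analysis window, so the window
    # sees the response plateau (the transient has settled) and ends
    # before the next slot begins
    slot_s = 2 * config.window_s
    duration_s = n_samples * slot_s
    phase = rng.uniform(0, 2 * np.pi)

    schedule = np.repeat(np.array(classes, dtype=object), samples_per_class)
    rng.shuffle(schedule)

    t0 = pd.Timestamp(config.start)
    events = []
    samples = []
    for k, cls in enumerate(schedule):
        slot = k * slot_s
        w_start = slot + config.window_s
        if conc_range is not None and cls != "Air":
            lo, hi = conc_range
        else:
            lo, hi = STUDY_CLASS_TABLE.loc[cls, ["conc_lo", "conc_hi"]]
        if cls == "Air":
            conc = float(rng.uniform(lo, hi))
        else:
            conc = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
            jitter = np.exp(config.sample_jitter_sd * rng.standard_normal(4))
            # the presentation covers the analysis window end-to-end; the
            # next slot's first (buffer) half-window absorbs the shut-off
            events.append(
                (
                    slot + 0.5 * config.window_s,
                    1.5 * config.window_s,
                    cls,
                    conc,
                    jitter,
                )
            )
        samples.append(
            TrainingSample(
                sample_id=f"{campaign_id}-{k:03d}",
                source_class=str(cls),
                odour_concentration=conc,
                start=t0 + pd.Timedelta(seconds=w_start),
                end=t0 + pd.Timedelta(seconds=w_start + config.window_s),
                campaign=campaign_id,
                role=role,
            )
        )
    stream = _render_stream(config, duration_s, events, rng, phase, drift, t0)
    return stream, samples


def simulate_monitoring(
    config: SimConfig,
    duration_s: float,
    event_schedule: list[tuple[float, float, str, float]],
    seed: int | None = None,
    age_months: float = 0.0,
) -> tuple[SensorStream, pd.DataFrame]:
    """Continuous monitoring stream plus per-window truth labels.

    ``event_schedule`` rows are ``(start_s, duration_s, class,
    concentration)``; events must fit inside the stream and events of
    different classes must not overlap.  The truth table assigns a
    window the event class when an event covers at least half of it.
    """
    for t_on, dur, cls, _ in event_schedule:
        if t_on < 0 or t_on + dur > duration_s:
            raise ValueError("event schedule exceeds stream duration")
    ordered = sorted(event_schedule)
    for (a_on, a_dur, a_cls, _), (b_on, _, b_cls, _) in zip(ordered, ordered[1:]):
        if b_on < a_on + a_dur and a_cls != b_cls:
            raise ValueError("overlapping events of different classes are unsupported")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    phase = rng.uniform(0, 2 * np.pi)
    drift = _draw_drift(config, rng, age_months)
    t0 = pd.Timestamp(config.start)
    stream = _render_stream(config, duration_s, event_schedule, rng, phase, drift, t0)

    n_win = int(duration_s // config.window_s)
    rows = []
    for k in range(n_win):
        w_on, w_off = k * config.window_s, (k + 1) * config.window_s
        cls, conc = "Air", np.nan
        for t_on, dur, ecls, econc in event_schedule:
            overlap = max(0.0, min(w_off, t_on + dur) - max(w_on, t_on))
            if overlap >= 0.5 * config.window_s:
                cls, conc = ecls, econc
                break
        rows.append(
            {
                "window": k,
                "start": t0 + pd.Timedelta(seconds=w_on),
                "true_class": cls,
                "true_concentration": conc,
            }
        )
    return stream, pd.DataFrame(rows)


def simulate_study(
    config: SimConfig,
    train_campaigns: int = 4,
    train_per_class_per_campaign: int = 10,
    test_per_class: int = 20,
    classes: tuple[str, ...] = ("Air", "Biogas", "Sheds"),
    seed: int | None = None,
):
    """Full study layout: several training campaigns plus one test campaign.

    Mirrors the field protocol — training data gathered over multiple
    seasonal campaigns (each with its own sensor-drift state and ambient
    phase) and an independent later campaign held out for field
    verification.  Returns ``(train_pairs, (test_stream, test_samples))``
    where each pair is ``(stream, samples)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    train_pairs = []
    for c in range(train_campaigns):
        stream, samples = simulate_campaign(
            config,
            samples_per_class=train_per_class_per_campaign,
            classes=classes,
            campaign_id=f"T{c + 1}",
            role="train",
            seed=int(rng.integers(2**31 - 1)),
            age_months=float(c) * 5.0 / max(train_campaigns, 1),
        )
        train_pairs.append((stream, samples))
    test_pair = simulate_campaign(
        config,
        samples_per_class=test_per_class,
        classes=classes,
        campaign_id="F",
        role="test",
        seed=int(rng.integers(2**31 - 1)),
        age_months=8.0,
    )
    return train_pairs, test_pair
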