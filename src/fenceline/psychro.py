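"""Psychrometrics and humidity compensation of MOX resistances.

MOX gas sensors are cross-sensitive to water vapour: their baseline
resistance in odourless air falls as the absolute humidity (AH) of the
sampled air rises.  Outdoors this produces resistance excursions of the
same order as genuine odour events, so raw signals must be normalized
against a reference baseline before classification.

Three strategies are supported, named after the classification models
they feed:

* ``CA`` — no pre-treatment; raw resistances pass through.
* ``CB`` — static reference: ``y_ref`` is the mean resistance of each
  sensor in odourless ambient air; signals are normalized as
  ``(y - y_ref) / y``.
* ``CC`` — dynamic reference: ``y_ref`` is a per-sensor polynomial in
  absolute humidity, fitted on odourless air, and evaluated at the AH
  measured during each analysis window.

The polynomial is an empirical interpolation of the observed
baseline-vs-AH trend; it makes no claim about the physical chemistry of
water adsorption on the sensor surface.

Absolute humidity (g/m^3) is derived from onboard relative humidity and
temperature via the ideal-gas relation ``AH = (RH/100) * Ps(T) / (Rw*T)``
with the water vapour saturation pressure ``Ps`` from the standard
empirical correlation ``ln Ps = C1 + C2/T + C3*ln(T) + C4*T^C5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MOX_COLUMNS, SensorStream

#: specific gas constant of water vapour, J/(kg K)
RW = 461.5

#: valid temperature band for the vapour-pressure correlation, K
T_BAND = (250.0, 350.0)


@dataclass(frozen=True)
class PsychroConstants:
    """Constants of the water vapour-pressure correlation.

    Defaults are the standard handbook coefficients for water
    (pressure in Pa, temperature in K), overridable via configuration.
    """

    c1: float = 73.649
    c2: float = -7258.2
    c3: float = -7.3037
    c4: float = 4.1653e-6
    c5: float = 2.0
    rw: float = RW


DEFAULT_CONSTANTS = PsychroConstants()


def saturation_vapour_pressure(
    temp_k, constants: PsychroConstants = DEFAULT_CONSTANTS
):
    """Saturation vapour pressure of water, Pa, for T in kelvin.

    Valid over roughly 250-350 K; strictly increasing in T.
    """
    t = np.asarray(temp_k, dtype=float)
    if np.any(t <= T_BAND[0]) or np.any(t >= T_BAND[1]):
        raise ValueError(f"temperature outside correlation band {T_BAND} K")
    ln_ps = (
        constants.c1
        + constants.c2 / t
        + constants.c3 * np.log(t)
        + constants.c4 * t**constants.c5
    )
    out = np.exp(ln_ps)
    return float(out) if np.isscalar(temp_k) else out


def absolute_humidity(
    rh_pct, temp_k, constants: PsychroConstants = DEFAULT_CONSTANTS
):
    """Absolute humidity in g/m^3 from relative humidity (%) and T (K).

    ``AH = (RH/100) * Ps(T) / (Rw * T) * 1000``; exactly linear in RH at
    fixed temperature.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    ps = saturation_vapour_pressure(temp_k, constants)
    t = np.asarray(temp_k, dtype=float)
    out = (rh / 100.0) * ps / (constants.rw * t) * 1000.0
    return float(out) if np.isscalar(rh_pct) and np.isscalar(temp_k) else out


def absolute_humidity_c(rh_pct, temp_c, constants: PsychroConstants = DEFAULT_CONSTANTS):
    """Convenience wrapper taking temperature in degC."""
    return absolute_humidity(rh_pct, np.asarray(temp_c, dtype=float) + 273.15, constants)


@dataclass
class BaselineModel:
    """Per-sensor reference-resistance model.

    ``mode='static'`` holds a single reference resistance (mean in
    odourless air); ``mode='dynamic'`` holds polynomial coefficients in
    AH (lowest order first, degree <= 5) together with the AH range they
    were fitted on.  ``mode='none'`` marks the raw (CA) path and cannot
    be evaluated.
    """

    sensor_id: str
    mode: str  # none | static | dynamic
    static_ref: float | None = None
    coefficients: list[float] | None = None  # a1..a_{d+1}, ascending powers
    ah_range: tuple[float, float] | None = None
    rmse: float | None = None
    extrapolation_margin: float = 0.2  # fraction of fitted AH span

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["ah_range"] is not None:
            d["ah_range"] = list(d["ah_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineModel":
        d = dict(d)
        if d.get("ah_range") is not None:
            d["ah_range"] = tuple(d["ah_range"])
        return cls(**d)


def fit_static_baseline(odourless_resistance, sensor_id: str = "mox") -> BaselineModel:
    """Static reference: mean resistance over all odourless records."""
    y = np.asarray(odourless_resistance, dtype=float)
    if y.size == 0:
        raise ValueError("no odourless data to fit a static baseline")
    return BaselineModel(
        sensor_id=sensor_id,
        mode="static",
        static_ref=float(np.mean(y)),
        rmse=float(np.std(y)),
    )


def _poly_rmse(ah: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    coeffs = np.polynomial.polynomial.polyfit(ah, y, degree)
    resid = y - np.polynomial.polynomial.polyval(ah, coeffs)
    return coeffs, float(np.sqrt(np.mean(resid**2)))


def fit_dynamic_baseline(
    odourless_resistance,
    ah,
    sensor_id: str = "mox",
    degree: int | None = None,
    auto_rel_improvement: float = 0.05,
    max_degree: int = 5,
) -> BaselineModel:
    """Dynamic reference: least-squares polynomial of resistance vs AH.

    With ``degree=None`` the degree is chosen automatically as the lowest
    d in [1, max_degree] whose RMSE improvement over degree d+1 is below
    ``auto_rel_improvement`` (relative), replacing a visual check of the
    fitted curve with a reproducible rule.
    """
    y = np.asarray(odourless_resistance, dtype=float)
    x = np.asarray(ah, dtype=float)
    if y.shape != x.shape:
        raise ValueError("resistance and AH arrays must have equal length")
    n_distinct = np.unique(x).size
    probe = degree if degree is not None else 1
    if n_distinct < probe + 2:
        raise ValueError(
            f"need >= degree+2 distinct AH values (got {n_distinct}) — AH is collinear"
        )
    scale = float(np.mean(np.abs(y))) or 1.0
    if degree is not None:
        if not 1 <= degree <= max_degree:
            raise ValueError(f"degree must be in [1, {max_degree}]")
        coeffs, rmse = _poly_rmse(x, y, degree)
    else:
        fits = {}
        for d in range(1, max_degree + 1):
            if n_distinct < d + 2:
                break
            fits[d] = _poly_rmse(x, y, d)
        degrees = sorted(fits)
        chosen = degrees[-1]
        for d in degrees[:-1]:
            rmse_d = fits[d][1]
            rmse_next = fits[d + 1][1]
            if rmse_d <= 1e-9 * scale:  # already an exact fit
                chosen = d
                break
            if (rmse_d - rmse_next) / rmse_d < auto_rel_improvement:
                chosen = d
                break
        degree = chosen
        coeffs, rmse = fits[degree]
    if not np.all(np.isfinite(coeffs)):
        raise ValueError(f"ill-conditioned baseline fit for sensor {sensor_id}")
    return BaselineModel(
        sensor_id=sensor_id,
        mode="dynamic",
        coefficients=[float(c) for c in coeffs],
        ah_range=(float(x.min()), float(x.max())),
        rmse=rmse,
    )


def reference_resistance(model: BaselineModel, ah=None):
    """Evaluate a baseline model's reference resistance, Ohm.

    Static models ignore ``ah``.  Dynamic models clamp AH values lying
    more than ``extrapolation_margin`` x (fitted span) outside the fitted
    range to the range endpoints, with a warning.
    """
    if model.mode == "none":
        raise ValueError("mode='none' (raw path) has no reference resistance")
    if model.mode == "static":
        if np.isscalar(ah) or ah is None:
            return model.static_ref
        return np.full(np.asarray(ah).shape, model.static_ref)
    if model.mode != "dynamic":
        raise ValueError(f"unknown baseline mode {model.mode!r}")
    if ah is None:
        raise ValueError("dynamic baseline needs an AH value")
    x = np.asarray(ah, dtype=float)
    lo, hi = model.ah_range
    span = max(hi - lo, 1e-12)
    margin = model.extrapolation_margin * span
    if np.any(x < lo - margin) or np.any(x > hi + margin):
        warnings.warn(
            f"sensor {model.sensor_id}: AH outside fitted range "
            f"[{lo:.2f}, {hi:.2f}] g/m^3 by more than the margin; clamping",
            stacklevel=2,
        )
    x = np.clip(x, lo, hi) if (np.any(x < lo - margin) or np.any(x > hi + margin)) else x
    out = np.polynomial.polynomial.polyval(x, model.coefficients)
    return float(out) if np.isscalar(ah) else out


def normalize_signal(y, y_ref, denominator: str = "y"):
    """Normalized resistance ``(y - y_ref) / y`` (dimensionless).

    The raw-signal denominator is the form used throughout; setting
    ``denominator='y_ref'`` switches to the conventional
    ``(y - y_ref)/y_ref`` for sensitivity studies.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0):
        raise ValueError("raw resistance must be positive")
    if denominator == "y":
        out = (y_arr - y_ref) / y_arr
    elif denominator == "y_ref":
        out = (y_arr - np.asarray(y_ref, dtype=float)) / np.asarray(y_ref, dtype=float)
    else:
        raise ValueError("denominator must be 'y' or 'y_ref'")
    return float(out) if np.isscalar(y) else out


def fit_baselines(
    odourless_stream: SensorStream,
    mode: str,
    degree: int | None = None,
    constants: PsychroConstants = DEFAULT_CONSTANTS,
) -> dict[str, BaselineModel]:
    """Fit one baseline model per MOX sensor from an odourless stream.

    ``mode='CB'`` fits static references; ``mode='CC'`` fits dynamic
    polynomials against the record-wise absolute humidity.
    """
    df = odourless_stream.data
    out: dict[str, BaselineModel] = {}
    if mode == "CB":
        for c in MOX_COLUMNS:
            out[c] = fit_static_baseline(df[c].to_numpy(), sensor_id=c)
    elif mode == "CC":
        ah = absolute_humidity_c(df["rh_pct"].to_numpy(), df["temp_c"].to_numpy(), constants)
        for c in MOX_COLUMNS:
            out[c] = fit_dynamic_baseline(df[c].to_numpy(), ah, sensor_id=c, degree=degree)
    else:
        raise ValueError("mode must be 'CB' or 'CC' (CA needs no baselines)")
    return out


def compensate_window(
    records,
    baselines: dict[str, BaselineModel] | None,
    mode: str,
    constants: PsychroConstants = DEFAULT_CONSTANTS,
    denominator: str = "y",
):
    """Compensate one analysis window's records (DataFrame in, DataFrame out).

    For the dynamic (CC) mode the reference is evaluated once per window
    at the window-mean absolute humidity — the AH "measured during the
    analysis time window" — rather than record-wise, so each window sees
    a single reference level.
    """
    if mode == "CA":
        return records.copy()
    if mode not in ("CB", "CC"):
        raise ValueError(f"mode must be one of CA/CB/CC, got {mode!r}")
    if baselines is None:
        raise ValueError(f"mode {mode} requires fitted baselines")
    df = records.copy()
    if mode == "CC":
        ah_mean = float(
            np.mean(
                absolute_humidity_c(
                    df["rh_pct"].to_numpy(), df["temp_c"].to_numpy(), constants
                )
            )
        )
    else:
        ah_mean = None
    for c in MOX_COLUMNS:
        y_ref = reference_resistance(baselines[c], ah_mean)
        df[c] = normalize_signal(df[c].to_numpy(), y_ref, denominator=denominator)
    return df


def compensate_stream(
    stream: SensorStream,
    baselines: dict[str, BaselineModel] | None,
    mode: str,
    constants: PsychroConstants = DEFAULT_CONSTANTS,
    denominator: str = "y",
) -> SensorStream:
    """Apply the selected pre-treatment to the MOX channels of a stream.

    ``CA`` returns the stream unchanged.  ``CB``/``CC`` replace each MOX
    resistance by its normalized value against the static or dynamic
    reference; electrochemical and PID channels pass through unmodified.
    """
    if mode == "CA":
        return SensorStream(stream.data.copy(), cadence_s=stream.cadence_s)
    if mode not in ("CB", "CC"):
        raise ValueError(f"mode must be one of CA/CB/CC, got {mode!r}")
    if baselines is None:
        raise ValueError(f"mode {mode} requires fitted baselines")
    missing = [c for c in MOX_COLUMNS if c not in baselines]
    if missing:
        raise ValueError(f"missing baseline model for sensor(s): {missing}")
    df = stream.data.copy()
    if mode == "CC":
        ah = absolute_humidity_c(df["rh_pct"].to_numpy(), df["temp_c"].to_numpy(), constants)
    else:
        ah = None
    for c in MOX_COLUMNS:
        y_ref = reference_resistance(baselines[c], ah)
        df[c] = normalize_signal(df[c].to_numpy(), y_ref, denominator=denominator)
    return SensorStream(df, cadence_s=stream.cadence_s)
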