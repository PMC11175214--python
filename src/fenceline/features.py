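"""Per-window feature extraction for the sensor array.

Each 5-min analysis window is condensed into a fixed-length vector:
ten shape descriptors per MOX channel (computed on the compensated
signal) and the maximum reading of each electrochemical sensor and of
the PID (raw), 4 x 10 + 2 + 1 = 43 features in total.

MOX feature codes:

=====  =======================================================
code   description
=====  =======================================================
A      minimum of the resistance
B      EMA (alpha=0.05) — area under the curve
C      EMA (alpha=0.05) — minimum
D      EMA (alpha=0.1) — area under the curve
E      EMA (alpha=0.1) — minimum
F      maximum minus minimum of the resistance
G      minimum of the first derivative of the resistance
H      area under the curve
I      mean of the resistance
J      maximum of the resistance
=====  =======================================================

Feature J completes the ten-feature set; it is the counterpart of A and
comes for free from F.  Areas use the trapezoidal rule over actual
timestamps; the derivative is the first difference divided by the actual
timestamp spacing, so irregular cadence is handled without resampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AUX_COLUMNS, MOX_COLUMNS, AnalysisWindow

MOX_FEATURE_CODES = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J"]

#: ordered names of all 43 features
FEATURE_NAMES = [
    f"{sensor}_{code}" for sensor in MOX_COLUMNS for code in MOX_FEATURE_CODES
] + [f"{sensor}_L" for sensor in AUX_COLUMNS]

N_FEATURES = len(FEATURE_NAMES)


def ema(series, alpha: float) -> np.ndarray:
    """Exponential moving average: e1 = x1, e_t = a*x_t + (1-a)*e_{t-1}."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return pd.Series(x).ewm(alpha=alpha, adjust=False).mean().to_numpy()


def _mox_features(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    dy = np.diff(y) / np.diff(t)
    e05 = ema(y, 0.05)
    e10 = ema(y, 0.1)
    return {
        "A": float(y.min()),
        "B": float(np.trapezoid(e05, t)),
        "C": float(e05.min()),
        "D": float(np.trapezoid(e10, t)),
        "E": float(e10.min()),
        "F": float(y.max() - y.min()),
        "G": float(dy.min()),
        "H": float(np.trapezoid(y, t)),
        "I": float(y.mean()),
        "J": float(y.max()),
    }


def extract_features(window: AnalysisWindow, compensated: pd.DataFrame | None = None) -> pd.Series:
    """Extract the 43-feature vector from one analysis window.

    ``compensated`` supplies pre-treated records (same columns as the raw
    ones); when omitted the window's own records are used.  Electrochemical
    and PID maxima are always taken from the raw records: compensation
    targets the MOX resistances only.
    """
    raw = window.records
    if len(raw) < 3:
        raise ValueError("need at least 3 records per window for feature extraction")
    df = compensated if compensated is not None else raw
    t = (raw["timestamp"] - raw["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    out: dict[str, float] = {}
    for sensor in MOX_COLUMNS:
        feats = _mox_features(t, df[sensor].to_numpy(dtype=float))
        for code, val in feats.items():
            out[f"{sensor}_{code}"] = val
    for sensor in AUX_COLUMNS:
        out[f"{sensor}_L"] = float(raw[sensor].max())
    return pd.Series(out, index=FEATURE_NAMES, dtype=float)


def build_feature_matrix(rows: list[pd.Series], index=None) -> pd.DataFrame:
    """Stack per-window feature vectors into a FeatureMatrix (rows = windows)."""
    X = pd.DataFrame(rows, columns=FEATURE_NAMES)
    if index is not None:
        X.index = index
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing cells")
    return X
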