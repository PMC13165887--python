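"""Rest-phase masks and per-impulse drift / dispersion statistics.

The drift analysis rests on a simple observation: during the stationary
("rest") phases immediately before and well after a head impulse, the true
eye velocity should be near zero, so any persistent offset in the recorded
eye velocity measures non-physiological drift (goggle slippage, sensor
baseline error). Each impulse window therefore gets a boolean rest mask
(local time < t_pre or > t_post), and all drift quantities are masked
means while dispersion quantities are masked population SDs.

Per-impulse features collected here form the feature matrix used for the
rank-correlation screening and for the correction objective:

    X = [d_e, d_h, e_gaze_mean, d_gaze, var_e, sd_e, var_h, sd_h,
         var_gaze, sd_gaze, v_max]

where the gaze error is e_gaze(t) = v_e(t) + v_h(t) (zero for a perfect
gain-1 vestibulo-ocular reflex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateMaskError, InputError
from .io_vhit import ImpulseWindow

#: Column order of the numeric feature matrix X.
X_COLUMNS = [
    "d_e",
    "d_h",
    "e_gaze_mean",
    "d_gaze",
    "var_e",
    "sd_e",
    "var_h",
    "sd_h",
    "var_gaze",
    "sd_gaze",
    "v_max",
]

DEFAULT_T_PRE = 0.05
DEFAULT_T_POST = 0.5


@dataclass
class RestMask:
    """Boolean per-sample rest mask of an impulse window.

    A sample at local time t is "rest" iff t < t_pre or t > t_post
    (strict inequalities: boundary samples count as movement).
    """

    mask: np.ndarray
    t_pre: float = DEFAULT_T_PRE
    t_post: float = DEFAULT_T_POST

    @property
    def n_rest(self) -> int:
        return int(np.count_nonzero(self.mask))


def build_rest_mask(
    window: ImpulseWindow,
    t_pre: float = DEFAULT_T_PRE,
    t_post: float = DEFAULT_T_POST,
) -> RestMask:
    """Label the non-movement samples of an impulse window."""
    if not t_pre < t_post:
        raise InputError("t_pre must be < t_post")
    t = window.local_times
    mask = (t < t_pre) | (t > t_post)
    if np.count_nonzero(mask) < 2:
        raise DegenerateMaskError(
            f"rest mask has {np.count_nonzero(mask)} samples; need at least 2"
        )
    return RestMask(mask=mask, t_pre=t_pre, t_post=t_post)


def gaze_error(eye_vel: np.ndarray, head_vel: np.ndarray) -> np.ndarray:
    """Gaze error e_gaze(t) = v_e(t) + v_h(t); zero for an ideal reflex."""
    eye_vel = np.asarray(eye_vel, dtype=float)
    head_vel = np.asarray(head_vel, dtype=float)
    if eye_vel.shape != head_vel.shape:
        raise InputError("eye and head velocity arrays must have equal length")
    return eye_vel + head_vel


def _check_mask(signal: np.ndarray, mask: RestMask | np.ndarray) -> np.ndarray:
    m = mask.mask if isinstance(mask, RestMask) else np.asarray(mask, dtype=bool)
    if m.shape != np.asarray(signal).shape:
        raise InputError("mask and signal lengths differ")
    if np.count_nonzero(m) < 2:
        raise DegenerateMaskError("fewer than 2 masked samples")
    return m


def masked_mean(signal: np.ndarray, mask: RestMask | np.ndarray) -> float:
    """Arithmetic mean of a signal over its rest samples."""
    signal = np.asarray(signal, dtype=float)
    m = _check_mask(signal, mask)
    return float(signal[m].mean())


def masked_sd(signal: np.ndarray, mask: RestMask | np.ndarray) -> tuple[float, float]:
    """Population variance and SD of a signal over its rest samples.

    Normalized by the rest-sample count (not count-1), matching the
    per-impulse estimator used throughout the pipeline.
    """
    signal = np.asarray(signal, dtype=float)
    m = _check_mask(signal, mask)
    var = float(signal[m].var(ddof=0))
    return var, float(np.sqrt(var))


def peak_head_velocity(window: ImpulseWindow) -> float:
    """Peak stimulus intensity v_max = max |v_h| over the window."""
    if len(window) == 0:
        raise InputError("empty window")
    return float(np.max(np.abs(window.head_vel)))


@dataclass
class ImpulseFeatures:
    """Per-impulse scalar features (one row of the feature matrix X)."""

    impulse_id: int
    source_id: str
    protocol: str | None
    d_e: float  # masked mean eye velocity (eye drift), deg/s
    d_h: float  # masked mean head velocity (head drift), deg/s
    e_gaze_mean: float  # full-window mean gaze error, deg/s
    d_gaze: float  # masked mean gaze error (gaze drift), deg/s
    var_e: float
    sd_e: float
    var_h: float
    sd_h: float
    var_gaze: float
    sd_gaze: float
    v_max: float


def compute_features(
    window: ImpulseWindow,
    t_pre: float = DEFAULT_T_PRE,
    t_post: float = DEFAULT_T_POST,
    correction=None,
    dispersion: str = "rest",
) -> ImpulseFeatures:
    """Compute all drift and dispersion features for one impulse.

    When ``correction`` (a :class:`~vhitdrift.correction.CorrectionParams`
    or a length-3 theta sequence) is given, the gaze error uses the
    corrected eye velocity g(v_e, theta) + v_h; otherwise g is the
    identity (theta = [0, 1, 0]).

    ``dispersion`` selects the sample set for the variance/SD features:
    ``"rest"`` (default) uses the rest mask, ``"full"`` the whole window.
    """
    if dispersion not in ("rest", "full"):
        raise InputError("dispersion must be 'rest' or 'full'")
    mask = build_rest_mask(window, t_pre=t_pre, t_post=t_post)
    eye = window.eye_vel
    if correction is not None:
        from .correction import apply_correction

        eye = apply_correction(eye, correction)
    e_gaze = gaze_error(eye, window.head_vel)
    disp_mask = mask.mask if dispersion == "rest" else np.ones(len(window), dtype=bool)
    var_e, sd_e = masked_sd(eye, disp_mask)
    var_h, sd_h = masked_sd(window.head_vel, disp_mask)
    var_g, sd_g = masked_sd(e_gaze, disp_mask)
    return ImpulseFeatures(
        impulse_id=window.impulse_id,
        source_id=window.source_id,
        protocol=window.protocol,
        d_e=masked_mean(eye, mask),
        d_h=masked_mean(window.head_vel, mask),
        e_gaze_mean=float(np.mean(e_gaze)),
        d_gaze=masked_mean(e_gaze, mask),
        var_e=var_e,
        sd_e=sd_e,
        var_h=var_h,
        sd_h=sd_h,
        var_gaze=var_g,
        sd_gaze=sd_g,
        v_max=peak_head_velocity(window),
    )


def feature_table(
    windows: list[ImpulseWindow],
    t_pre: float = DEFAULT_T_PRE,
    t_post: float = DEFAULT_T_POST,
    correction=None,
    dispersion: str = "rest",
) -> pd.DataFrame:
    """Aggregate per-impulse features into a table, one row per impulse.

    Column order: impulse_id, source_id, protocol, then the 11 X columns.
    Row order follows input order. An empty input yields an empty table
    with headers.
    """
    rows = [
        compute_features(
            w, t_pre=t_pre, t_post=t_post, correction=correction, dispersion=dispersion
        )
        for w in windows
    ]
    columns = ["impulse_id", "source_id", "protocol"] + X_COLUMNS
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([vars(r) for r in rows], columns=columns)


def feature_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Restrict a feature table to the 11 numeric X columns."""
    missing = [c for c in X_COLUMNS if c not in features.columns]
    if missing:
        raise InputError(f"feature table missing columns: {missing}")
    return features[X_COLUMNS]
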