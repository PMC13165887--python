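"""Quadratic eye-velocity correction and its gradient-descent calibration.

The correction replaces the recorded eye velocity v_e with

    g(v_e, theta) = theta1 * v_e**2 + theta2 * v_e + theta3

and theta = [theta1, theta2, theta3] is fitted so that the rest-phase
gaze error g(v_e) + v_h is as flat as possible across a calibration set
of impulses. The objective is the RMS over impulses of the masked
gaze-error SD:

    J(theta) = sqrt( (1/N) * sum_i sigma_gaze(i; theta)^2 )

J is minimized by fixed-learning-rate gradient descent from the identity
theta0 = [0, 1, 0], with a finite-difference gradient. Note that J is
invariant to theta3 (a constant shift of the gaze error leaves every SD
unchanged), so the minimizer is a one-parameter family and only the J
value itself — not theta — is a meaningful convergence target.

The default update scales the normalized gradient direction by the
current objective value (a zero-target Polyak step, relaxed by the
learning rate): step sizes then shrink as J approaches its near-zero
minimum, which is what lets a fixed learning rate of 0.7 both make fast
early progress and satisfy a tight ||delta theta|| convergence test.
A ``raw`` gradient mode (plain alpha * grad update) is retained for
experiments; on deg/s-scaled data it diverges for any useful alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drift_metrics import RestMask, build_rest_mask
from .errors import InputError, OptimizationError
from .io_vhit import ImpulseWindow, Recording

IDENTITY_THETA = (0.0, 1.0, 0.0)


@dataclass
class CorrectionParams:
    """Coefficients of the quadratic eye-velocity correction.

    theta1 has units 1/(deg/s), theta2 is dimensionless, theta3 is deg/s.
    The identity correction is exactly [0, 1, 0].
    """

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (3,):
            raise InputError("theta must have exactly 3 components")
        if not np.all(np.isfinite(self.theta)):
            raise InputError("theta must be finite")

    @classmethod
    def identity(cls) -> "CorrectionParams":
        return cls(theta=np.array(IDENTITY_THETA))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"theta": self.theta.tolist()}, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionParams":
        data = json.loads(Path(path).read_text())
        return cls(theta=np.asarray(data["theta"], dtype=float))


@dataclass
class OptimizationConfig:
    """Settings of the fixed-learning-rate gradient descent."""

    learning_rate: float = 0.7
    tol: float = 1e-4          # convergence threshold on ||theta_{n+1} - theta_n||_2
    max_iter: int = 700
    fd_step: float = 1e-6      # relative central-difference step per component
    gradient_mode: str = "normalized"  # "normalized" (objective-scaled) or "raw"
    max_step: float = 10.0     # cap on the step length in normalized mode
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.learning_rate <= 1:
            raise InputError("learning_rate must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1 or self.fd_step <= 0:
            raise InputError("tol, fd_step must be > 0 and max_iter >= 1")
        if self.gradient_mode not in ("normalized", "raw"):
            raise InputError("gradient_mode must be 'normalized' or 'raw'")


@dataclass
class OptimizationTrace:
    """Per-iteration history of a gradient-descent run."""

    theta_history: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    iterations: int = 0

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.theta_history, columns=["theta1", "theta2", "theta3"])
        df.insert(0, "iteration", np.arange(len(df)))
        df["J"] = self.objective_history
        df.to_csv(path, index=False)
        return path


def apply_correction(eye_vel: np.ndarray, params) -> np.ndarray:
    """Apply g(v, theta) = theta1*v^2 + theta2*v + theta3 elementwise."""
    theta = params.theta if isinstance(params, CorrectionParams) else np.asarray(
        params, dtype=float
    )
    if theta.shape != (3,):
        raise InputError("theta must have exactly 3 components")
    v = np.asarray(eye_vel, dtype=float)
    return theta[0] * v * v + theta[1] * v + theta[2]


def _masks_for(windows, masks) -> list[RestMask]:
    if masks is None:
        return [build_rest_mask(w) for w in windows]
    return list(masks)


def objective(
    theta,
    windows: list[ImpulseWindow],
    masks: list[RestMask] | None = None,
) -> float:
    """RMS over impulses of the rest-phase gaze-error SD, in deg/s."""
    if len(windows) == 0:
        raise InputError("need at least one impulse")
    masks = _masks_for(windows, masks)
    theta = theta.theta if isinstance(theta, CorrectionParams) else np.asarray(
        theta, dtype=float
    )
    variances = np.empty(len(windows))
    for i, (w, m) in enumerate(zip(windows, masks)):
        e = apply_correction(w.eye_vel, theta) + w.head_vel
        variances[i] = e[m.mask].var(ddof=0)
    return float(np.sqrt(variances.mean()))


def gradient(
    theta,
    windows: list[ImpulseWindow],
    masks: list[RestMask] | None = None,
    fd_step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference gradient of the pooled objective.

    The probe step for component k is ``fd_step * max(1, |theta_k|)``.
    """
    if fd_step <= 0:
        raise InputError("fd_step must be positive")
    masks = _masks_for(windows, masks)
    theta = np.asarray(
        theta.theta if isinstance(theta, CorrectionParams) else theta, dtype=float
    )
    grad = np.empty(3)
    for k in range(3):
        h = fd_step * max(1.0, abs(theta[k]))
        plus, minus = theta.copy(), theta.copy()
        plus[k] += h
        minus[k] -= h
        jp = objective(plus, windows, masks)
        jm = objective(minus, windows, masks)
        if not (np.isfinite(jp) and np.isfinite(jm)):
            raise OptimizationError("non-finite objective at finite-difference probe")
        grad[k] = (jp - jm) / (2 * h)
    return grad


def optimize(
    windows: list[ImpulseWindow],
    config: OptimizationConfig | None = None,
    theta0=IDENTITY_THETA,
    masks: list[RestMask] | None = None,
) -> tuple[CorrectionParams, OptimizationTrace]:
    """Fit the correction by gradient descent from theta0 = [0, 1, 0].

    Iterates ``theta <- theta - step`` until ``||step||_2 < tol`` or
    ``max_iter`` updates, whichever comes first, where the step is the
    learning rate times the objective-scaled gradient direction
    (``gradient_mode="normalized"``, the default) or the raw gradient.
    Returns the best-objective iterate (fixed-step descent can overshoot,
    so the last iterate is not necessarily the best) plus the full trace.
    """
    config = config or OptimizationConfig()
    if len(windows) == 0:
        raise InputError("need at least one impulse")
    masks = _masks_for(windows, masks)
    theta = np.asarray(theta0, dtype=float).copy()

    theta_hist: list[np.ndarray] = []
    j_hist: list[float] = []
    best_j = np.inf
    best_theta = theta.copy()
    converged = False
    iterations = 0

    def record(th: np.ndarray, j: float) -> None:
        nonlocal best_j, best_theta
        theta_hist.append(th.copy())
        j_hist.append(j)
        if j < best_j:
            best_j = j
            best_theta = th.copy()

    def make_trace() -> OptimizationTrace:
        return OptimizationTrace(
            theta_history=np.array(theta_hist).reshape(-1, 3),
            objective_history=np.array(j_hist),
            converged=converged,
            iterations=iterations,
        )

    for _ in range(config.max_iter):
        j = objective(theta, windows, masks)
        if not np.isfinite(j):
            raise OptimizationError("objective diverged (non-finite J)", make_trace())
        record(theta, j)
        try:
            g = gradient(theta, windows, masks, fd_step=config.fd_step)
        except OptimizationError as exc:
            raise OptimizationError(str(exc), make_trace()) from None
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            converged = True
            break
        if config.gradient_mode == "normalized":
            length = config.learning_rate * min(j / gnorm, config.max_step)
            step = length * g / gnorm
        else:
            step = config.learning_rate * g
        theta = theta - step
        iterations += 1
        if float(np.linalg.norm(step)) < config.tol:
            converged = True
            break

    j = objective(theta, windows, masks)
    if np.isfinite(j):
        record(theta, j)
    return CorrectionParams(theta=best_theta), make_trace()


def correct_dataset(recordings, params: CorrectionParams):
    """Apply a fitted correction to the eye velocity of each recording.

    Accepts a list of :class:`Recording` or :class:`ImpulseWindow`; times
    and head velocity are passed through untouched.
    """
    out = []
    for rec in recordings:
        if not isinstance(rec, (Recording, ImpulseWindow)):
            raise InputError(f"cannot correct object of type {type(rec).__name__}")
        corrected = apply_correction(rec.eye_vel, params)
        if isinstance(rec, Recording):
            out.append(
                Recording(
                    times=rec.times.copy(),
                    head_vel=rec.head_vel.copy(),
                    eye_vel=corrected,
                    sample_rate=rec.sample_rate,
                    label=rec.label,
                    source_id=rec.source_id,
                )
            )
        elif isinstance(rec, ImpulseWindow):
            out.append(
                ImpulseWindow(
                    local_times=rec.local_times.copy(),
                    head_vel=rec.head_vel.copy(),
                    eye_vel=corrected,
                    protocol=rec.protocol,
                    impulse_id=rec.impulse_id,
                    source_id=rec.source_id,
                )
            )
        else:
            raise InputError(f"cannot correct object of type {type(rec).__name__}")
    return out
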