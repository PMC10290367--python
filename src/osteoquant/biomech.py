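"""Torque-rotation analysis for physical (or simulated) torsion tests.

Torsional stiffness (Nm/deg) is the OLS slope of torque on rotation over a
torque window on the loading ramp — by default 6-10 Nm, which skips the
low-torque toe region where the specimen settles in the fixture. Rigidity
(Nm^2/deg) is stiffness times the gauge length, and an operated limb is
conventionally reported as a percentage of the same animal's contralateral
non-operated limb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TorqueRotationTrace",
    "RigidityResult",
    "WindowUnreachableError",
    "stiffness_from_trace",
    "rigidity_from_stiffness",
    "normalize_rigidity",
]


class WindowUnreachableError(RuntimeError):
    """The trace never enters the regression torque window."""

    def __init__(self, window_low: float, max_torque: float):
        self.window_low = window_low
        self.max_torque = max_torque
        super().__init__(
            f"trace peaks at {max_torque:.3f} Nm, below the regression window "
            f"start of {window_low:.3f} Nm (test stopped at the rotation cap?)"
        )


@dataclass
class TorqueRotationTrace:
    """Sampled torsion loading curve: rotation (deg) vs torque (Nm)."""

    rotation: np.ndarray  # deg, monotone non-decreasing on the loading ramp
    torque: np.ndarray  # Nm
    sampling_rate: float = 20.0  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.rotation.shape != self.torque.shape or self.rotation.ndim != 1:
            raise ValueError("rotation and torque must be equal-length 1-D arrays")
        if self.rotation.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.rotation) < -1e-12):
            raise ValueError("rotation must be monotone non-decreasing")

    def loading_ramp(self) -> "TorqueRotationTrace":
        """Samples up to and including the torque maximum (unloading dropped)."""
        i_max = int(np.argmax(self.torque))
        return TorqueRotationTrace(
            self.rotation[: i_max + 1],
            self.torque[: i_max + 1],
            self.sampling_rate,
            dict(self.meta),
        )

    @classmethod
    def from_csv(cls, path, sampling_rate: float = 20.0) -> "TorqueRotationTrace":
        arr = np.genfromtxt(path, delimiter=",", names=True)
        return cls(arr["rotation_deg"], arr["torque_Nm"], sampling_rate)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.rotation, self.torque]),
            delimiter=",",
            header="rotation_deg,torque_Nm",
            comments="",
        )


@dataclass(frozen=True)
class RigidityResult:
    stiffness: float  # Nm/deg
    rigidity: float  # Nm^2/deg
    normalized: float | None  # % of contralateral
    window_used: tuple[float, float]  # Nm
    n_points_in_window: int


def stiffness_from_trace(
    trace: TorqueRotationTrace, window: tuple[float, float] = (6.0, 10.0)
) -> float:
    """OLS slope (Nm/deg) of torque vs rotation inside the torque window.

    Only the loading ramp is used; samples after the torque maximum are
    discarded. Raises :class:`WindowUnreachableError` when the trace never
    reaches the lower window bound (a test stopped at the rotation cap),
    carrying the trace's maximum torque so the caller can decide on a
    documented fallback window.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must be (low, high) with low < high")
    ramp = trace.loading_ramp()
    if ramp.torque.max() < lo:
        raise WindowUnreachableError(lo, float(ramp.torque.max()))
    sel = (ramp.torque >= lo) & (ramp.torque <= hi)
    if np.count_nonzero(sel) < 3:
        # a ramp that barely clips the window before the rotation cap is the
        # same failure mode as never reaching it: no usable regression
        raise WindowUnreachableError(lo, float(ramp.torque.max()))
    slope = np.polyfit(ramp.rotation[sel], ramp.torque[sel], 1)[0]
    return float(slope)


def analyze_trace(
    trace: TorqueRotationTrace,
    gauge_length_mm: float,
    contralateral_rigidity: float | None = None,
    window: tuple[float, float] = (6.0, 10.0),
) -> RigidityResult:
    """Stiffness, rigidity, and (optionally) contralateral-normalized rigidity."""
    k = stiffness_from_trace(trace, window)
    ramp = trace.loading_ramp()
    n_in = int(np.count_nonzero((ramp.torque >= window[0]) & (ramp.torque <= window[1])))
    rig = rigidity_from_stiffness(k, gauge_length_mm)
    norm = None
    if contralateral_rigidity is not None:
        norm = normalize_rigidity(rig, contralateral_rigidity)
    return RigidityResult(k, rig, norm, tuple(window), n_in)


def rigidity_from_stiffness(stiffness: float, gauge_length_mm: float) -> float:
    """Rigidity (Nm^2/deg) = stiffness (Nm/deg) x gauge length (m)."""
    if gauge_length_mm <= 0:
        raise ValueError("gauge length must be positive")
    return stiffness * gauge_length_mm / 1000.0


def normalize_rigidity(operated: float, contralateral: float) -> float:
    """Operated-limb rigidity as a percentage of the contralateral limb."""
    if contralateral <= 0:
        raise ValueError("contralateral rigidity must be positive")
    return 100.0 * operated / contralateral
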