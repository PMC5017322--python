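"""Core domain types for trunk-accelerometer gait analysis.

An :class:`AccelerationTrace` holds the tri-axial lower-back acceleration
(anterior-posterior, medial-lateral, vertical, units g) on a uniform time
base.  :class:`GateEvents` carries the start-line / end-line crossing times
that delimit the analysis window — measured by photo gates or entered
manually from a stopwatch.  A :class:`WalkSession` bundles both with the
walk distance.  Results flow through :class:`StepCountResult` (fractional
step count) and :class:`GaitProfile` (the full per-walk parameter set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GateOrderError, SamplingError, WindowError

#: tolerated deviation of each time step from 1/sample_rate, seconds.
#: Permits benign timestamp jitter while catching dropped samples.
UNIFORMITY_TOL_S = 1e-4

GATE_SOURCES = ("gate", "manual")


@dataclass
class AccelerationTrace:
    """Uniformly sampled tri-axial trunk acceleration.

    Parameters
    ----------
    sample_rate : float
        Samples per second (nominally 100 Hz).
    time : array-like
        Sample times in seconds, strictly increasing and uniform at
        ``1/sample_rate`` within :data:`UNIFORMITY_TOL_S`.
    ap, ml, v : array-like
        Anterior-posterior, medial-lateral and vertical acceleration in g.
    """

    sample_rate: float
    time: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise DomainError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.time = np.asarray(self.time, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = self.time.size
        if n < 2:
            raise DomainError(f"trace needs at least 2 samples, got {n}")
        for name in ("ap", "ml", "v"):
            m = getattr(self, name).size
            if m != n:
                raise DomainError(
                    f"series length mismatch: time has {n} samples, {name} has {m}"
                )
        dt = np.diff(self.time)
        bad = np.nonzero(np.abs(dt - 1.0 / self.sample_rate) > UNIFORMITY_TOL_S)[0]
        if bad.size:
            i = int(bad[0])
            raise SamplingError(
                f"non-uniform time base at index {i}: dt={dt[i]:.6f} s, "
                f"expected {1.0 / self.sample_rate:.6f} s",
                index=i,
            )

    def __len__(self) -> int:
        return self.time.size

    @property
    def t0(self) -> float:
        return float(self.time[0])

    @property
    def t1(self) -> float:
        return float(self.time[-1])

    def axis(self, name: str) -> np.ndarray:
        """Return one acceleration channel by axis name ('ap', 'ml' or 'v')."""
        if name not in ("ap", "ml", "v"):
            raise DomainError(f"unknown axis {name!r}")
        return getattr(self, name)

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask of samples in the closed interval [t_start, t_end].

        Raises :class:`WindowError` if the interval is not covered by the
        trace.  A small tolerance (half the uniformity tolerance) keeps
        samples that nominally coincide with a gate timestamp in-window.
        """
        eps = UNIFORMITY_TOL_S / 2
        if t_start < self.t0 - eps or t_end > self.t1 + eps:
            raise WindowError(
                f"window [{t_start:.3f}, {t_end:.3f}] s outside trace span "
                f"[{self.t0:.3f}, {self.t1:.3f}] s"
            )
        if t_end <= t_start:
            raise WindowError(f"empty window [{t_start}, {t_end}]")
        return (self.time >= t_start - eps) & (self.time <= t_end + eps)

    def shifted(self, dt: float) -> "AccelerationTrace":
        """Copy of the trace with all timestamps shifted by ``dt`` seconds."""
        return AccelerationTrace(self.sample_rate, self.time + dt, self.ap, self.ml, self.v)


@dataclass
class GateEvents:
    """Start-line and end-line crossing timestamps, trace clock, seconds.

    ``source`` records whether the times came from the photo gates
    (``"gate"``) or were entered manually from a stopwatch (``"manual"``);
    downstream computation is agnostic to the source.
    """

    t_start: float
    t_end: float
    source: str = "gate"

    def __post_init__(self):
        if self.source not in GATE_SOURCES:
            raise GateOrderError(
                f"gate source must be one of {GATE_SOURCES}, got {self.source!r}"
            )
        if not (self.t_end > self.t_start):
            raise GateOrderError(
                f"end-line time ({self.t_end}) must exceed start-line time ({self.t_start})"
            )

    @property
    def walking_time_s(self) -> float:
        return self.t_end - self.t_start

    def shifted(self, dt: float) -> "GateEvents":
        return GateEvents(self.t_start + dt, self.t_end + dt, self.source)


@dataclass
class WalkSession:
    """One recorded walk: trace + gates + walk distance (default 5 m)."""

    trace: AccelerationTrace
    gates: GateEvents
    distance_m: float = 5.0
    subject_id: str = "S0"
    occasion: int = 1

    def __post_init__(self):
        if self.distance_m <= 0:
            raise DomainError(f"distance_m must be > 0, got {self.distance_m}")
        if self.occasion < 1:
            raise DomainError(f"occasion must be >= 1, got {self.occasion}")
        # gates must lie within the trace span
        self.trace.window_mask(self.gates.t_start, self.gates.t_end)

    def shifted(self, dt: float) -> "WalkSession":
        return WalkSession(
            self.trace.shifted(dt), self.gates.shifted(dt),
            self.distance_m, self.subject_id, self.occasion,
        )


@dataclass
class StepCountResult:
    """Fractional step count over the analysis window.

    The total is the number of whole steps completed between successive
    detected foot contacts (``integer_step_count``) plus the partial first
    and last steps cut by the gate lines, each expressed as that partial
    interval divided by the mean step interval::

        total = integer + initial_fraction + last_fraction

    ``integer_step_count`` therefore equals ``len(peak_times) - 1``: each
    contact after the first completes one whole step, while the first
    contact terminates the partial initial step.
    """

    integer_step_count: int
    initial_step_fraction: float
    last_step_fraction: float
    total_step_count: float
    peak_times: np.ndarray
    mean_step_interval_s: float
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        expected = (
            self.integer_step_count
            + self.initial_step_fraction
            + self.last_step_fraction
        )
        if not math.isclose(self.total_step_count, expected, rel_tol=0, abs_tol=1e-12):
            raise DomainError(
                f"total_step_count {self.total_step_count} != integer + fractions {expected}"
            )
        if self.peak_times.size >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise DomainError("peak_times must be strictly increasing")
        if self.integer_step_count >= 2 and not self.mean_step_interval_s > 0:
            raise DomainError("mean_step_interval_s must be > 0")


#: JSON field names of a serialized profile, in report order.
PROFILE_FIELDS = (
    "velocity_mps", "cadence_spm", "step_length_cm", "walking_time_s",
    "total_steps",
    "rms_ap_g", "rms_ml_g", "rms_v_g", "rmsr_ml",
    "step_regularity_ap", "step_regularity_ml", "step_regularity_v",
    "stride_regularity_ap", "stride_regularity_ml", "stride_regularity_v",
    "symmetry_ap_pct", "symmetry_ml_pct", "symmetry_v_pct",
)


@dataclass
class GaitProfile:
    """Full per-walk parameter set.

    Regularity values are normalized unbiased autocorrelation coefficients
    at roughly one step / one stride of lag (near 1 = highly regular);
    symmetry is 100 × stride regularity / step regularity (near 100% =
    symmetric).  Missing values (quality failures) are NaN with an entry in
    ``warnings``.
    """

    velocity_mps: float
    cadence_spm: float
    step_length_cm: float
    walking_time_s: float
    rms_ap_g: float
    rms_ml_g: float
    rms_v_g: float
    rmsr_ml: float
    step_regularity_ap: float
    step_regularity_ml: float
    step_regularity_v: float
    stride_regularity_ap: float
    stride_regularity_ml: float
    stride_regularity_v: float
    symmetry_ap_pct: float
    symmetry_ml_pct: float
    symmetry_v_pct: float
    steps: StepCountResult | None = None
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        """Flat dict with the serialized field names (see PROFILE_FIELDS)."""
        d = {}
        for key in PROFILE_FIELDS:
            if key == "total_steps":
                d[key] = float(self.steps.total_step_count) if self.steps else float("nan")
            else:
                d[key] = float(getattr(self, key))
        return d

    @property
    def is_complete(self) -> bool:
        return not any(math.isnan(v) for v in self.as_dict().values())
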