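"""Per-walk gait parameters.

Spatiotemporal: speed = distance / walking time; cadence = 60 × total
steps / walking time; step length = distance / total steps.

Trunk control, all computed on the windowed, zero-meaned signals:

* per-axis RMS (g) — average acceleration magnitude along each axis;
* RMSR — axis RMS divided by the RMS of the acceleration-vector magnitude
  (ML RMSR indexes body sway / walking balance); the three axis RMSRs
  satisfy Σ RMSR² = 1 by construction;
* step / stride regularity — the normalized *unbiased* autocorrelation
  coefficient at roughly one step / one stride of lag (the biased estimate
  would shrink toward zero with lag; the unbiased form divides each lag's
  sum by the number of overlapping samples);
* symmetry — 100 × stride regularity / step regularity.

The ML channel alternates sign between left and right steps, so its
step-lag autocorrelation extremum is typically *negative*; by default the
magnitude of that extremum is reported (``ml_abs``), matching the
convention of reporting ML step regularity as a positive number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import DomainError, WindowError
from .model import AccelerationTrace, GaitProfile, GateEvents, StepCountResult, WalkSession
from .steps import count_steps

AXES = ("ap", "ml", "v")


def spatiotemporal(
    steps: StepCountResult, gates: GateEvents, distance_m: float
) -> tuple[float, float, float]:
    """(velocity m/s, cadence steps/min, step length cm) for one walk."""
    walking_time = gates.walking_time_s
    if walking_time <= 0:
        raise DomainError(f"walking time must be > 0, got {walking_time}")
    total = steps.total_step_count
    if total <= 0:
        raise DomainError(f"total step count must be > 0, got {total}")
    if distance_m <= 0:
        raise DomainError(f"distance must be > 0, got {distance_m}")
    velocity = distance_m / walking_time
    cadence = 60.0 * total / walking_time
    step_length_cm = 100.0 * distance_m / total
    return velocity, cadence, step_length_cm


def _windowed(trace: AccelerationTrace, gates: GateEvents, axis: str, demean: bool) -> np.ndarray:
    x = trace.axis(axis)[trace.window_mask(gates.t_start, gates.t_end)]
    if x.size == 0:
        raise WindowError("empty analysis window")
    return x - x.mean() if demean else x


def axis_rms(
    trace: AccelerationTrace, gates: GateEvents, demean: bool = True
) -> tuple[float, float, float]:
    """RMS of each windowed (zero-meaned) axis signal, in g."""
    return tuple(
        float(np.sqrt(np.mean(_windowed(trace, gates, ax, demean) ** 2))) for ax in AXES
    )


def rmsr(
    trace: AccelerationTrace, gates: GateEvents, axis: str = "ml", demean: bool = True
) -> float:
    """Axis RMS over the RMS of the acceleration-vector magnitude.

    The denominator equals sqrt(rms_ap² + rms_ml² + rms_v²), so the three
    axis ratios satisfy Σ RMSR² = 1 exactly.
    """
    rms = dict(zip(AXES, axis_rms(trace, gates, demean)))
    mag = math.sqrt(sum(r**2 for r in rms.values()))
    if mag == 0.0:
        raise DomainError("all-zero window: RMS magnitude is zero")
    return rms[axis] / mag


@dataclass
class AutocorrResult:
    """Normalized unbiased autocorrelation of a windowed signal."""

    lags_s: np.ndarray
    coefficients: np.ndarray
    step_lag_s: float = float("nan")
    stride_lag_s: float = float("nan")
    clipped: bool = False


def unbiased_autocorrelation(
    x: np.ndarray, max_lag_s: float, sample_rate: float
) -> AutocorrResult:
    """Unbiased autocorrelation estimate, normalized to 1 at lag zero.

    coefficient(k) = [1/(N−k) Σ_i x_i x_{i+k}] / [1/N Σ_i x_i²]

    The unbiased numerator can marginally exceed the lag-0 value for
    near-periodic finite windows; coefficients beyond 1 + 1e-9 in magnitude
    are clipped to ±1 and flagged.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    max_lag = int(round(max_lag_s * sample_rate))
    if max_lag < 1:
        raise WindowError(f"max lag {max_lag_s} s is under one sample")
    if n < 2 * max_lag:
        raise WindowError(
            f"window of {n} samples is too short for a {max_lag}-sample lag "
            f"(needs at least {2 * max_lag})"
        )
    raw = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    denom = raw[0] / n
    if denom == 0.0:
        raise DomainError("zero-variance signal: autocorrelation undefined")
    counts = n - np.arange(max_lag + 1)
    coeff = (raw / counts) / denom
    clipped = bool(np.any(np.abs(coeff) > 1.0 + 1e-9))
    coeff = np.clip(coeff, -1.0, 1.0)
    lags = np.arange(max_lag + 1) / sample_rate
    return AutocorrResult(lags_s=lags, coefficients=coeff, clipped=clipped)


def _dominant_extremum(
    ac: AutocorrResult, lo_s: float, hi_s: float, use_abs: bool
) -> tuple[float, float]:
    """Largest local extremum of the autocorrelation in the lag band.

    ``use_abs=False``: largest local maximum of the coefficients.
    ``use_abs=True``: local extremum with the largest magnitude (for the
    sign-alternating ML channel); the magnitude is returned.
    Ties break toward the shorter lag.  Returns (value, lag_s); NaNs when
    the band holds no local extremum.
    """
    c = ac.coefficients
    y = np.abs(c) if use_abs else c
    interior = np.arange(1, c.size - 1)
    is_ext = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
    cand = interior[is_ext]
    in_band = cand[(ac.lags_s[cand] >= lo_s) & (ac.lags_s[cand] <= hi_s)]
    if in_band.size == 0:
        return float("nan"), float("nan")
    best = in_band[np.argmax(y[in_band])]  # argmax takes the first (shortest lag) on ties
    return float(y[best]), float(ac.lags_s[best])


def regularity(
    trace: AccelerationTrace,
    gates: GateEvents,
    axis: str,
    est_step_interval_s: float,
    config: AnalysisConfig | None = None,
) -> tuple[float, float, list]:
    """(step_regularity, stride_regularity, warnings) for one axis.

    Step regularity is the dominant autocorrelation extremum with lag in
    [0.5, 1.5] × the estimated step interval; stride regularity the one in
    [1.5, 2.5] ×.  A band with no local extremum yields NaN plus a warning
    rather than a fabricated value.
    """
    config = config or AnalysisConfig()
    if est_step_interval_s <= 0:
        raise DomainError(f"step interval must be > 0, got {est_step_interval_s}")
    x = _windowed(trace, gates, axis, config.demean)
    max_lag_s = 2.5 * est_step_interval_s + 2.0 / trace.sample_rate
    ac = unbiased_autocorrelation(x, max_lag_s, trace.sample_rate)

    warnings: list = []
    if ac.clipped:
        warnings.append(f"{axis}: autocorrelation coefficients beyond 1 were clipped")
    use_abs_step = config.ml_abs and axis == "ml"
    step_reg, step_lag = _dominant_extremum(
        ac, 0.5 * est_step_interval_s, 1.5 * est_step_interval_s, use_abs_step
    )
    stride_reg, stride_lag = _dominant_extremum(
        ac, 1.5 * est_step_interval_s, 2.5 * est_step_interval_s, False
    )
    if math.isnan(step_reg):
        warnings.append(f"{axis}: no autocorrelation extremum in the step-lag band")
    if math.isnan(stride_reg):
        warnings.append(f"{axis}: no autocorrelation extremum in the stride-lag band")
    return step_reg, stride_reg, warnings


def symmetry(
    step_regularity: float, stride_regularity: float, cap_pct: float = 999.0
) -> tuple[float, list]:
    """Gait symmetry: 100 × stride regularity / step regularity, percent.

    May exceed 100% when stride regularity is the larger; capped at
    ``cap_pct`` (with a warning) to avoid blow-ups near zero step
    regularity.  NaN inputs propagate as NaN.
    """
    if math.isnan(step_regularity) or math.isnan(stride_regularity):
        return float("nan"), []
    if step_regularity == 0.0:
        raise DomainError("zero step regularity: symmetry undefined")
    value = 100.0 * stride_regularity / step_regularity
    if abs(value) > cap_pct:
        return math.copysign(cap_pct, value), [
            f"symmetry {value:.0f}% capped at {cap_pct:.0f}%"
        ]
    return value, []


def analyze_walk(session: WalkSession, config: AnalysisConfig | None = None) -> GaitProfile:
    """Run the full pipeline on one walk session.

    Composes step counting, spatiotemporal parameters, per-axis RMS, ML
    RMSR, and per-axis regularity/symmetry into a :class:`GaitProfile`.
    Quality problems surface as NaN fields plus ``profile.warnings``.
    """
    config = config or AnalysisConfig()
    trace, gates = session.trace, session.gates

    steps = count_steps(trace, gates, config.detection)
    velocity, cadence, step_length_cm = spatiotemporal(steps, gates, session.distance_m)
    rms = dict(zip(AXES, axis_rms(trace, gates, config.demean)))
    rmsr_ml = rmsr(trace, gates, "ml", config.demean)

    warnings = list(steps.warnings)
    reg: dict[str, tuple[float, float]] = {}
    sym: dict[str, float] = {}
    for ax in AXES:
        step_reg, stride_reg, reg_warn = regularity(
            trace, gates, ax, steps.mean_step_interval_s, config
        )
        warnings += reg_warn
        reg[ax] = (step_reg, stride_reg)
        sym_val, sym_warn = symmetry(step_reg, stride_reg, config.symmetry_cap_pct)
        warnings += [f"{ax}: {w}" for w in sym_warn]
        sym[ax] = sym_val

    return GaitProfile(
        velocity_mps=velocity,
        cadence_spm=cadence,
        step_length_cm=step_length_cm,
        walking_time_s=gates.walking_time_s,
        rms_ap_g=rms["ap"], rms_ml_g=rms["ml"], rms_v_g=rms["v"],
        rmsr_ml=rmsr_ml,
        step_regularity_ap=reg["ap"][0], step_regularity_ml=reg["ml"][0],
        step_regularity_v=reg["v"][0],
        stride_regularity_ap=reg["ap"][1], stride_regularity_ml=reg["ml"][1],
        stride_regularity_v=reg["v"][1],
        symmetry_ap_pct=sym["ap"], symmetry_ml_pct=sym["ml"], symmetry_v_pct=sym["v"],
        steps=steps,
        warnings=warnings,
    )
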