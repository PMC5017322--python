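"""Ground-truthed synthetic trunk-acceleration walking signals.

The generator emulates what a lower-back (L3–L4) accelerometer records
during steady walking through a gated walkway:

* AP channel: a pulse train built from 2–3 harmonics of the step frequency,
  with one dominant peak per step exactly at each initial foot contact.
* V channel: periodic at the step frequency, phase-shifted relative to AP.
* ML channel: periodic at the *stride* frequency — trunk sway changes sign
  between left and right steps — built from odd harmonics only so the sign
  alternation is exact.
* Left/right asymmetry: the amplitude of every second step is scaled by
  (1 − asymmetry) via a stride-periodic envelope; an optional timing offset
  shifts alternate contacts by a fraction of the step interval.
* Gate events are placed so the analysis window contains a non-integer
  number of steps: the start line precedes the first in-window contact by
  ``start_phase`` step intervals, and the window length equals the true
  fractional step count times the step interval.  The Eq.-style step-count
  fractions are therefore analytically known.
* Additive zero-mean Gaussian noise on every channel.

Because every channel is a closed-form harmonic sum, the noise-free RMS of
each axis is known exactly (:meth:`GaitSimParams.expected_rms`), and the
ground truth satisfies ``distance = step_length × total_steps`` and
``cadence × walking_time / 60 = total_steps`` to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .model import AccelerationTrace, GateEvents, WalkSession

# Relative harmonic amplitudes per axis. AP uses three harmonics of the
# step frequency (sharp, single peak per step); V two; ML two odd
# harmonics of the stride frequency (antisymmetric under a one-step shift).
_AP_HARMONICS = (1.0, 0.5, 0.25)
_V_HARMONICS = (1.0, 0.3)
_ML_HARMONICS = (1.0, 0.2)
_V_PHASE = 0.3 * math.pi  # V peak offset from the AP contact peak


@dataclass
class GaitSimParams:
    """Simulation parameters.

    Defaults target the regime of a healthy adult walking a gated 5-m
    corridor at self-selected speed: cadence ≈ 141 steps/min, step length
    ≈ 0.57 m (hence speed ≈ 1.33 m/s), axis amplitudes chosen so the
    noise-free per-axis RMS lands near 0.14 / 0.13 / 0.19 g (AP/ML/V).
    """

    cadence_spm: float = 140.87       # steps per minute
    step_length_m: float = 0.5683     # metres per step
    distance_m: float = 5.0           # gated analysis distance
    lead_in_m: float = 1.5            # walkway before the start line (and after the end line)
    asymmetry: float = 0.0            # fractional L/R amplitude difference, [0, 1)
    timing_asymmetry: float = 0.0     # shift of alternate contacts, fraction of a step
    ml_sway_g: float = 0.18           # ML fundamental amplitude, g
    ap_amp_g: float = 0.17            # AP fundamental amplitude, g
    v_amp_g: float = 0.26             # V fundamental amplitude, g
    noise_sd_g: float = 0.01          # additive Gaussian noise SD, g
    start_phase: float = 0.4          # fraction of a step by which the start line precedes the first in-window contact
    sample_rate: float = 100.0        # Hz
    seed: int = 0

    def __post_init__(self):
        if self.cadence_spm <= 0:
            raise DomainError(f"cadence_spm must be > 0, got {self.cadence_spm}")
        if self.step_length_m <= 0:
            raise DomainError(f"step_length_m must be > 0, got {self.step_length_m}")
        if self.distance_m <= 0:
            raise DomainError(f"distance_m must be > 0, got {self.distance_m}")
        if min(self.ml_sway_g, self.ap_amp_g, self.v_amp_g) < 0:
            raise DomainError("axis amplitudes must be >= 0")
        if self.noise_sd_g < 0:
            raise DomainError("noise_sd_g must be >= 0")
        if not 0.0 <= self.asymmetry < 1.0:
            raise DomainError(f"asymmetry must be in [0, 1), got {self.asymmetry}")
        if not 0.0 <= self.start_phase < 1.0:
            raise DomainError(f"start_phase must be in [0, 1), got {self.start_phase}")
        if abs(self.timing_asymmetry) >= 0.5:
            raise DomainError("timing_asymmetry must be in (-0.5, 0.5)")

    @property
    def step_interval_s(self) -> float:
        return 60.0 / self.cadence_spm

    @property
    def true_total_steps(self) -> float:
        return self.distance_m / self.step_length_m

    def expected_rms(self) -> dict:
        """Closed-form per-axis RMS of the generated signal, in g.

        Exact for the noise-free, amplitude-symmetric case; the asymmetry
        envelope contributes its mean-square factor and noise adds in
        quadrature (both small corrections, edge effects ignored).
        """
        env_msq = (1.0 + (1.0 - self.asymmetry) ** 2) / 2.0
        out = {}
        for axis, amp, harmonics, enveloped in (
            ("ap", self.ap_amp_g, _AP_HARMONICS, True),
            ("ml", self.ml_sway_g, _ML_HARMONICS, False),
            ("v", self.v_amp_g, _V_HARMONICS, True),
        ):
            msq = amp**2 * sum(h**2 for h in harmonics) / 2.0
            if enveloped:
                msq *= env_msq
            out[axis] = math.sqrt(msq + self.noise_sd_g**2)
        return out


@dataclass
class GaitGroundTruth:
    """True values the pipeline should recover from a simulated walk."""

    true_total_steps: float
    true_step_times: np.ndarray   # in-window initial contacts, seconds
    true_walking_time_s: float
    true_cadence_spm: float
    true_step_length_cm: float

    def __post_init__(self):
        self.true_step_times = np.asarray(self.true_step_times, dtype=float)


def _contact_times(params: GaitSimParams, t_first: float, t_lo: float, t_hi: float):
    """Contact times (nominal + optional alternate-step timing shift) covering
    the whole span [t_lo, t_hi] with one spare contact on each side."""
    T = params.step_interval_s
    k_lo = math.floor((t_lo - t_first) / T) - 1
    k_hi = math.ceil((t_hi - t_first) / T) + 1
    k = np.arange(k_lo, k_hi + 1)
    times = t_first + k * T
    if params.timing_asymmetry:
        times = times + (k % 2) * params.timing_asymmetry * T
    return times, k


def simulate_walk(params: GaitSimParams) -> tuple[WalkSession, GaitGroundTruth]:
    """Simulate one gated walk; returns the session and its ground truth."""
    T = params.step_interval_s
    total = params.true_total_steps
    if total < 1.0:
        raise DomainError(
            f"analysis window holds {total:.3f} steps; needs at least one full step"
        )
    true_time = total * T

    n_lead = max(1, math.ceil(params.lead_in_m / params.step_length_m))
    t_first = 1.0 + n_lead * T          # first in-window contact; 1 s lead margin
    t_start = t_first - params.start_phase * T
    t_end = t_start + true_time

    duration = t_end + n_lead * T + 1.0
    n = int(round(duration * params.sample_rate)) + 1
    t = np.arange(n) / params.sample_rate

    contacts, k = _contact_times(params, t_first, t[0], t[-1])
    # Phase in step cycles: integer exactly at each contact (phi = k there).
    # Piecewise-linear interpolation keeps the construction exact even with
    # a nonzero alternate-step timing offset.
    phi = np.interp(t, contacts, k.astype(float))

    env = 1.0 - params.asymmetry / 2.0 + (params.asymmetry / 2.0) * np.cos(np.pi * phi)
    ap = env * params.ap_amp_g * sum(
        a * np.cos(2 * np.pi * (h + 1) * phi) for h, a in enumerate(_AP_HARMONICS)
    )
    v = env * params.v_amp_g * sum(
        a * np.cos(2 * np.pi * (h + 1) * phi - (h + 1) * _V_PHASE)
        for h, a in enumerate(_V_HARMONICS)
    )
    ml = params.ml_sway_g * sum(
        a * np.sin((2 * h + 1) * np.pi * phi) for h, a in enumerate(_ML_HARMONICS)
    )

    if params.noise_sd_g > 0:
        rng = np.random.default_rng(params.seed)
        ap = ap + rng.normal(0.0, params.noise_sd_g, n)
        ml = ml + rng.normal(0.0, params.noise_sd_g, n)
        v = v + rng.normal(0.0, params.noise_sd_g, n)

    trace = AccelerationTrace(params.sample_rate, t, ap, ml, v)
    gates = GateEvents(t_start=t_start, t_end=t_end, source="gate")
    session = WalkSession(trace=trace, gates=gates, distance_m=params.distance_m)

    in_win = contacts[(contacts >= t_start) & (contacts <= t_end)]
    truth = GaitGroundTruth(
        true_total_steps=total,
        true_step_times=in_win,
        true_walking_time_s=true_time,
        true_cadence_spm=60.0 * total / true_time,
        true_step_length_cm=100.0 * params.step_length_m,
    )
    return session, truth


#: between-subject SDs of the latent gait parameters in a simulated cohort;
#: spatiotemporal spreads mirror a healthy adult sample, amplitude spreads
#: are modest fractions of the defaults.
DEFAULT_BETWEEN_SD = {
    "cadence_spm": 11.85,
    "step_length_m": 0.0595,
    "ap_amp_g": 0.02,
    "ml_sway_g": 0.03,
    "v_amp_g": 0.03,
}

#: default week-to-week (occasion 2) perturbation SDs of the same parameters.
#: ``start_phase`` perturbs where the gate line cuts the step cycle on the
#: retest (wrapped into [0, 1)); a large SD makes the retest phase
#: effectively independent.
DEFAULT_OCCASION_SD = {
    "cadence_spm": 5.0,
    "step_length_m": 0.02,
    "ap_amp_g": 0.008,
    "ml_sway_g": 0.008,
    "v_amp_g": 0.008,
    "start_phase": 0.25,
}

# physiological clamps applied to drawn latent parameters
_PARAM_BOUNDS = {
    "cadence_spm": (70.0, 180.0),
    "step_length_m": (0.30, 0.90),
    "ap_amp_g": (0.02, 0.60),
    "ml_sway_g": (0.02, 0.60),
    "v_amp_g": (0.02, 0.60),
}


@dataclass
class CohortSubject:
    """One simulated subject: a pair of walk sessions one occasion apart."""

    subject_id: str
    session1: WalkSession
    truth1: GaitGroundTruth
    session2: WalkSession
    truth2: GaitGroundTruth
    latent: dict = field(default_factory=dict)


def simulate_cohort(
    n_subjects: int,
    occasion_effects: dict | None = None,
    seed: int = 0,
    base: GaitSimParams | None = None,
    between_sd: dict | None = None,
) -> list[CohortSubject]:
    """Simulate a two-occasion test-retest cohort.

    Each subject's latent gait parameters are drawn around ``base`` with
    between-subject SDs ``between_sd``; occasion 2 re-simulates the same
    subject with independent noise, an independent start phase, and latent
    parameters perturbed by ``occasion_effects`` SDs (all zeros → occasion 2
    differs only by noise/phase; with noise 0 the paired walks are
    identical).
    """
    if n_subjects < 2:
        raise DomainError(f"n_subjects must be >= 2, got {n_subjects}")
    base = base if base is not None else GaitSimParams()
    between_sd = DEFAULT_BETWEEN_SD if between_sd is None else between_sd
    occ_sd = DEFAULT_OCCASION_SD if occasion_effects is None else occasion_effects

    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        latent = {}
        for name, sd in between_sd.items():
            lo, hi = _PARAM_BOUNDS[name]
            latent[name] = float(np.clip(getattr(base, name) + rng.normal(0.0, sd), lo, hi))
        latent["start_phase"] = float(rng.uniform(0.0, 1.0))

        sessions = []
        for occ in (1, 2):
            p = dict(latent)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            if occ == 2:
                for name, sd in occ_sd.items():
                    if sd <= 0:
                        continue
                    if name == "start_phase":
                        p[name] = float((p[name] + rng.normal(0.0, sd)) % 1.0)
                    else:
                        lo, hi = _PARAM_BOUNDS[name]
                        p[name] = float(np.clip(p[name] + rng.normal(0.0, sd), lo, hi))
            params = replace(base, **p, seed=noise_seed)
            session, truth = simulate_walk(params)
            session.subject_id = f"S{i + 1:03d}"
            session.occasion = occ
            sessions.append((session, truth))

        subjects.append(
            CohortSubject(
                subject_id=f"S{i + 1:03d}",
                session1=sessions[0][0], truth1=sessions[0][1],
                session2=sessions[1][0], truth2=sessions[1][1],
                latent=latent,
            )
        )
    return subjects
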