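"""Two-occasion test-retest reliability statistics.

For each gait parameter measured on the same subjects on two occasions:

* ICC(3,1) — single-measures intra-class correlation from the two-way
  mixed-effects mean squares, (BMS − EMS) / (BMS + (k−1) EMS) with k = 2
  raters (occasions), plus an F-based 95% CI.  An absolute-agreement
  variant (sensitive to a systematic occasion shift) is available as
  ``variant="agreement"``.
* SEM — standard error of measurement, SD_all × √(1 − ICC), where SD_all
  is the SD of the 2n pooled scores.
* SDD — smallest detectable difference, 1.96 × √2 × SEM, also expressed
  as a percentage of the grand mean.
* Paired t-test for a systematic occasion difference; one-sample
  Kolmogorov-Smirnov normality check (against a normal with the sample's
  own mean/SD — a Lilliefors-style screen whose p-values are conservative).
* Bland-Altman bias and 95% limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

#: SDD / SEM conversion factor, 1.96·√2.
SDD_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PairedMeasurements:
    """One parameter measured on the same subjects on two occasions.

    Subject rows where either occasion is missing (NaN) are dropped and
    counted in ``n_dropped``.
    """

    parameter_name: str
    occasion1: np.ndarray
    occasion2: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        o1 = np.asarray(self.occasion1, dtype=float)
        o2 = np.asarray(self.occasion2, dtype=float)
        if o1.size != o2.size:
            raise DomainError(
                f"{self.parameter_name}: occasion lengths differ ({o1.size} vs {o2.size})"
            )
        keep = ~(np.isnan(o1) | np.isnan(o2))
        self.n_dropped += int((~keep).sum())
        self.occasion1 = o1[keep]
        self.occasion2 = o2[keep]
        if self.occasion1.size < 3:
            raise DomainError(
                f"{self.parameter_name}: need >= 3 complete pairs, got {self.occasion1.size}"
            )

    @property
    def n(self) -> int:
        return self.occasion1.size

    @property
    def scores(self) -> np.ndarray:
        """The 2n pooled scores."""
        return np.concatenate([self.occasion1, self.occasion2])


def _mean_squares(pairs: PairedMeasurements) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares: (BMS, JMS, EMS, n, k)."""
    data = np.column_stack([pairs.occasion1, pairs.occasion2])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    occ_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_occ = n * np.sum((occ_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_occ
    bms = ss_subj / (n - 1)
    jms = ss_occ / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return float(bms), float(jms), float(ems), n, k


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str
    warnings: list = field(default_factory=list)


def icc_3_1(
    pairs: PairedMeasurements, variant: str = "consistency", alpha: float = 0.05
) -> ICCResult:
    """Single-measures ICC from the two-way mixed model, with 95% CI.

    ``consistency``: (BMS − EMS)/(BMS + (k−1)EMS); invariant under a pure
    additive occasion shift.  ``agreement``: adds the occasion variance to
    the denominator, penalizing systematic shifts.  With zero
    between-subject variance the coefficient is undefined and NaN is
    returned with a diagnostic.
    """
    if variant not in ("consistency", "agreement"):
        raise DomainError(f"unknown ICC variant {variant!r}")
    bms, jms, ems, n, k = _mean_squares(pairs)
    # cancellation in the sums-of-squares subtraction can leave a tiny
    # negative or spurious residual; snap it to zero
    if abs(ems) < 1e-12 * max(bms, 1e-300):
        ems = 0.0
    if abs(jms) < 1e-12 * max(bms, 1e-300):
        jms = 0.0
    if bms <= 0 or (bms == 0 and ems == 0):
        return ICCResult(
            float("nan"), float("nan"), float("nan"), variant,
            ["zero between-subject variance: ICC undefined"],
        )

    if variant == "consistency":
        if bms == ems == 0:
            return ICCResult(float("nan"), float("nan"), float("nan"), variant,
                             ["degenerate data: all mean squares zero"])
        icc = (bms - ems) / (bms + (k - 1) * ems)
        if ems == 0:
            return ICCResult(1.0, 1.0, 1.0, variant, [])
        f_obs = bms / ems
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
        return ICCResult(float(icc), float(ci_low), float(ci_high), variant, [])

    # absolute agreement (McGraw & Wong A-1 form for the two-way model)
    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    if denom == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"), variant,
                         ["degenerate data: zero denominator"])
    icc = (bms - ems) / denom
    if ems == 0 and jms == 0:
        return ICCResult(1.0, 1.0, 1.0, variant, [])
    a = k * icc / (n * (1 - icc)) if icc < 1 else float("inf")
    if not math.isfinite(a):
        return ICCResult(float(icc), float(icc), float(icc), variant,
                         ["zero residual variance: CI collapsed"])
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a * jms + b * ems) ** 2 / (
        (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (bms - f1 * ems) / (
        f1 * (k * jms + (k * n - k - n) * ems) + n * bms
    )
    ci_high = n * (f2 * bms - ems) / (
        k * jms + (k * n - k - n) * ems + n * f2 * bms
    )
    return ICCResult(float(icc), float(ci_low), float(ci_high), variant, [])


def sdd_from_sem(sem: float) -> float:
    """Smallest detectable difference from the SEM: 1.96 × √2 × SEM."""
    if sem < 0:
        raise DomainError(f"SEM must be >= 0, got {sem}")
    return SDD_FACTOR * sem


def sdd_percent(sdd: float, mean_of_measurements: float) -> float:
    """SDD as a percentage of the mean of the measurements."""
    if mean_of_measurements == 0:
        raise DomainError("zero mean of measurements: SDD% undefined")
    return 100.0 * sdd / mean_of_measurements


def sem_sdd(pairs: PairedMeasurements, icc: float) -> tuple[float, float, float, float]:
    """(sd_all, sem, sdd, sdd_pct) from the pooled scores and the ICC.

    sd_all is the SD (ddof=1) of the 2n pooled scores; SEM = sd_all ×
    √(1 − ICC); SDD = 1.96·√2·SEM; SDD% uses the grand mean of the pooled
    scores (for equal n this equals the mean of the two occasion means).
    """
    if not 0.0 <= icc <= 1.0:
        raise DomainError(f"ICC must be in [0, 1] for the SEM chain, got {icc}")
    scores = pairs.scores
    sd_all = float(np.std(scores, ddof=1))
    sem = sd_all * math.sqrt(1.0 - icc)
    sdd = sdd_from_sem(sem)
    grand = float(scores.mean())
    sdd_pct = sdd_percent(sdd, grand) if grand != 0 else float("nan")
    return sd_all, sem, sdd, sdd_pct


@dataclass
class PairedTResult:
    t: float
    p_value: float
    degenerate: bool = False


def paired_t(pairs: PairedMeasurements) -> PairedTResult:
    """Two-sided paired t-test for a systematic occasion difference."""
    d = pairs.occasion1 - pairs.occasion2
    n = d.size
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        # all differences equal; zero mean difference is a perfect null fit
        return PairedTResult(
            t=0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean()),
            p_value=1.0 if d.mean() == 0 else 0.0,
            degenerate=True,
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, p_value=p)


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def normality_check(values) -> NormalityResult:
    """One-sample KS test against a normal with the sample's mean and SD.

    Estimating the parameters from the same sample makes the p-values
    conservative (the Lilliefors caveat); treat this as a screen, not an
    exact test.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DomainError(f"need >= 3 values for a normality check, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return NormalityResult(float("nan"), float("nan"), degenerate=True)
    stat, p = stats.kstest(x, "norm", args=(float(x.mean()), sd))
    return NormalityResult(float(stat), float(p))


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bias and 95% limits of agreement (bias ± 1.96 × SD of differences)."""
    d = pairs.occasion1 - pairs.occasion2
    m = (pairs.occasion1 + pairs.occasion2) / 2.0
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        means=m, differences=d,
    )


def plot_bland_altman(result: BlandAltmanResult, path, title: str = "") -> None:
    """Render a Bland-Altman agreement plot to ``path`` (PNG/PDF/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.7)
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of the two occasions")
    ax.set_ylabel("occasion 1 − occasion 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ReliabilityReport:
    """One row of the per-parameter test-retest report."""

    parameter_name: str
    n: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t_p_value: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    sd_all: float
    sem: float
    sdd: float
    sdd_pct: float
    bland_altman_bias: float
    loa_low: float
    loa_high: float
    normality_p: float = float("nan")
    warnings: list = field(default_factory=list)
    error: str | None = None


def reliability_for_parameter(
    pairs: PairedMeasurements, icc_variant: str = "consistency"
) -> ReliabilityReport:
    """Full reliability panel for one parameter."""
    icc_res = icc_3_1(pairs, variant=icc_variant)
    warnings = list(icc_res.warnings)
    if math.isnan(icc_res.icc) or not 0.0 <= icc_res.icc <= 1.0:
        # a negative or undefined ICC leaves the SEM chain undefined
        sd_all = float(np.std(pairs.scores, ddof=1))
        sem = sdd = sdd_pct = float("nan")
        if not math.isnan(icc_res.icc):
            warnings.append(
                f"ICC {icc_res.icc:.3f} outside [0, 1]: SEM/SDD not computed"
            )
    else:
        sd_all, sem, sdd, sdd_pct = sem_sdd(pairs, icc_res.icc)
    t_res = paired_t(pairs)
    if t_res.degenerate:
        warnings.append("zero variance of paired differences: t-test degenerate")
    ba = bland_altman(pairs)
    norm = normality_check(pairs.scores)
    if norm.degenerate:
        warnings.append("constant scores: normality check degenerate")
    return ReliabilityReport(
        parameter_name=pairs.parameter_name,
        n=pairs.n,
        mean1=float(pairs.occasion1.mean()), sd1=float(np.std(pairs.occasion1, ddof=1)),
        mean2=float(pairs.occasion2.mean()), sd2=float(np.std(pairs.occasion2, ddof=1)),
        t_p_value=t_res.p_value,
        icc=icc_res.icc, icc_ci_low=icc_res.ci_low, icc_ci_high=icc_res.ci_high,
        sd_all=sd_all, sem=sem, sdd=sdd, sdd_pct=sdd_pct,
        bland_altman_bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
        normality_p=norm.p_value,
        warnings=warnings,
    )


def reliability_report(
    pairs_list: list[PairedMeasurements], icc_variant: str = "consistency"
) -> list[ReliabilityReport]:
    """One report row per parameter; a failing parameter is reported with
    its error message instead of aborting the remaining parameters."""
    rows = []
    for pairs in pairs_list:
        try:
            rows.append(reliability_for_parameter(pairs, icc_variant))
        except DomainError as exc:
            rows.append(
                ReliabilityReport(
                    parameter_name=pairs.parameter_name, n=getattr(pairs, "n", 0),
                    mean1=float("nan"), sd1=float("nan"),
                    mean2=float("nan"), sd2=float("nan"),
                    t_p_value=float("nan"),
                    icc=float("nan"), icc_ci_low=float("nan"), icc_ci_high=float("nan"),
                    sd_all=float("nan"), sem=float("nan"),
                    sdd=float("nan"), sdd_pct=float("nan"),
                    bland_altman_bias=float("nan"),
                    loa_low=float("nan"), loa_high=float("nan"),
                    error=str(exc),
                )
            )
    return rows


def report_frame(rows: list[ReliabilityReport]) -> pd.DataFrame:
    """Reports as a table: one parameter per row, occasion means, ICC with
    CI, SEM, SDD and SDD% as columns."""
    records = []
    for r in rows:
        records.append(
            {
                "parameter": r.parameter_name, "n": r.n,
                "mean1": r.mean1, "sd1": r.sd1, "mean2": r.mean2, "sd2": r.sd2,
                "t_p_value": r.t_p_value,
                "icc": r.icc, "icc_ci_low": r.icc_ci_low, "icc_ci_high": r.icc_ci_high,
                "sem": r.sem, "sdd": r.sdd, "sdd_pct": r.sdd_pct,
                "ba_bias": r.bland_altman_bias, "loa_low": r.loa_low, "loa_high": r.loa_high,
                "normality_p": r.normality_p,
                "error": r.error or "",
            }
        )
    return pd.DataFrame.from_records(records)


def pairs_from_profiles(
    profiles1: list[dict], profiles2: list[dict], parameters: list[str] | None = None
) -> list[PairedMeasurements]:
    """Build per-parameter paired measurements from two equal-length lists
    of per-subject profile dicts (as produced by GaitProfile.as_dict)."""
    if len(profiles1) != len(profiles2):
        raise DomainError("profile lists must pair up one-to-one")
    if parameters is None:
        parameters = sorted(set(profiles1[0]) & set(profiles2[0]))
    out = []
    for name in parameters:
        o1 = [p.get(name, float("nan")) for p in profiles1]
        o2 = [p.get(name, float("nan")) for p in profiles2]
        out.append(PairedMeasurements(name, np.asarray(o1), np.asarray(o2)))
    return out
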