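"""Dual-instrument agreement battery for spatiotemporal gait parameters.

For each parameter, paired per-subject values from the pressure-sensitive
walkway (PSW) and markerless motion capture (MLMC) are compared with:

* the mean difference (signed PSW - MLMC: negative means the walkway reads
  lower) and the percent error of the absolute difference relative to the
  walkway mean;
* Bland-Altman 95 % limits of agreement, d_bar +/- 1.96 x SD of the paired
  differences, with a 95 % CI of the mean difference;
* intraclass correlation coefficients from the two-way ANOVA decomposition:
  ICC(2,1) (absolute agreement, two-way random effects, sensitive to
  systematic offsets) and ICC(3,1) (consistency, two-way mixed effects,
  offset-invariant), each with F-distribution 95 % confidence intervals and
  the conventional qualitative rating (< 0.5 poor, 0.5-0.75 moderate,
  0.75-0.9 good, > 0.9 excellent).

The module exposes both plain functions and a small model/results pair:
``InstrumentAgreement(...).fit()`` returns an :class:`AgreementResults`
whose ``summary()`` prints the full per-parameter table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatiotemporal import PARAMETERS, SubjectSummary

__all__ = [
    "PairedSample",
    "BlandAltmanResult",
    "ICCResult",
    "AgreementRow",
    "InstrumentAgreement",
    "AgreementResults",
    "mean_difference",
    "bland_altman",
    "icc",
    "rate_icc",
    "compare_instruments",
]


@dataclass(frozen=True)
class PairedSample:
    """Per-subject paired (PSW, MLMC) values of one parameter."""

    parameter: str
    units: str
    psw: np.ndarray
    mlmc: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "psw", np.asarray(self.psw, dtype=float))
        object.__setattr__(self, "mlmc", np.asarray(self.mlmc, dtype=float))
        if self.psw.shape != self.mlmc.shape or self.psw.ndim != 1:
            raise ValueError("psw and mlmc must be equal-length 1-D arrays")
        if self.n < 2:
            raise ValueError("paired comparison needs n >= 2 subjects")
        if np.isnan(self.psw).any() or np.isnan(self.mlmc).any():
            raise ValueError("missing halves are not allowed in a PairedSample")

    @property
    def n(self) -> int:
        return int(self.psw.size)

    @property
    def diffs(self) -> np.ndarray:
        return self.psw - self.mlmc


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_lower: float
    ci_mean_upper: float


@dataclass(frozen=True)
class ICCResult:
    form: str            # "2,1" or "3,1"
    estimate: float
    ci_lower: float
    ci_upper: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementRow:
    parameter: str
    units: str
    n: int
    psw_mean: float
    psw_sd: float
    mlmc_mean: float
    mlmc_sd: float
    mean_diff: float
    sd_diff: float
    pct_error: float
    bland_altman: BlandAltmanResult
    icc21: ICCResult
    icc31: ICCResult
    rating21: str
    rating31: str


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mean_difference(sample: PairedSample) -> tuple[float, float, float]:
    """Mean difference (PSW - MLMC), its sample SD, and percent error.

    Percent error is ``100 * mean(|d_i|) / mean(psw)``; a negative mean
    difference indicates the walkway reads lower than motion capture.
    """
    d = sample.diffs
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    psw_mean = float(sample.psw.mean())
    if psw_mean == 0.0:
        warnings.warn(f"{sample.parameter}: PSW mean is zero, percent error "
                      "undefined", stacklevel=2)
        pct = float("nan")
    else:
        pct = float(100.0 * np.abs(d).mean() / psw_mean)
    return mean_diff, sd_diff, pct


def bland_altman(sample: PairedSample, level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman limits of agreement, d_bar +/- 1.96 SD.

    The classic fixed 1.96 normal multiplier is used at the default 95 %
    level (no small-sample t-correction); other levels use the normal
    quantile.
    """
    d = sample.diffs
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    se = sd_diff / math.sqrt(sample.n)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, sample.n - 1))
    return BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_lower=mean_diff - z * sd_diff, loa_upper=mean_diff + z * sd_diff,
        ci_mean_lower=mean_diff - tcrit * se, ci_mean_upper=mean_diff + tcrit * se,
    )


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=raters)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(max(mse, 0.0))


def icc(sample: PairedSample, form: str = "2,1", level: float = 0.95
        ) -> ICCResult:
    """Single-measure intraclass correlation from the two-way ANOVA.

    ``form="2,1"``: two-way random effects, absolute agreement;
    ``form="3,1"``: two-way mixed effects, consistency. Confidence
    intervals use the standard F-distribution formulas.
    """
    if form not in ("2,1", "3,1"):
        raise ValueError("form must be '2,1' or '3,1'")
    data = np.column_stack([sample.psw, sample.mlmc])
    n, k = data.shape
    if n < 3:
        warnings.warn("ICC with fewer than 3 subjects is unstable", stacklevel=2)
    msr, msc, mse = _anova_mean_squares(data)
    alpha = 1.0 - level
    degenerate = False
    denom31 = msr + (k - 1) * mse
    denom21 = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom31 <= 0 or denom21 <= 0:
        degenerate = True

    if form == "3,1":
        est = (msr - mse) / denom31 if denom31 > 0 else float("nan")
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if mse > 0 and df2 > 0:
            f_obs = msr / mse
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            degenerate = True
            lo, hi = float("nan"), float("nan")
    else:
        est = (msr - mse) / denom21 if denom21 > 0 else float("nan")
        # Satterthwaite degrees of freedom for the ICC(2,1) interval
        if mse > 0 and not math.isnan(est):
            a = k * est / (n * (1 - est)) if est < 1 else float("inf")
            b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else float("inf")
            if math.isinf(a) or math.isinf(b):
                degenerate = True
                lo, hi = float("nan"), float("nan")
            else:
                num = (a * msc + b * mse) ** 2
                den = ((a * msc) ** 2 / (k - 1)
                       + (b * mse) ** 2 / ((n - 1) * (k - 1)))
                v = num / den if den > 0 else float("nan")
                if math.isnan(v) or v == math.inf:
                    # estimate within float epsilon of 1: interval collapses
                    lo, hi = est, est
                else:
                    fl = float(stats.f.ppf(1 - alpha / 2, n - 1, v)) \
                        if v > 0 else float("nan")
                    fu = float(stats.f.ppf(1 - alpha / 2, v, n - 1)) \
                        if v > 0 else float("nan")
                    if math.isfinite(fl) and math.isfinite(fu):
                        denom_lo = (fl * (k * msc + (k * n - k - n) * mse)
                                    + n * msr)
                        denom_hi = (k * msc + (k * n - k - n) * mse
                                    + n * fu * msr)
                        lo = (n * (msr - fl * mse) / denom_lo
                              if denom_lo != 0 else float("nan"))
                        hi = (n * (fu * msr - mse) / denom_hi
                              if denom_hi != 0 else float("nan"))
                    else:
                        # Satterthwaite df undefined (negative estimate)
                        degenerate = True
                        lo, hi = float("nan"), float("nan")
        else:
            degenerate = True
            lo, hi = float("nan"), float("nan")

    if not math.isnan(est):
        if not math.isnan(lo):
            lo = min(lo, est)
        if not math.isnan(hi):
            hi = max(hi, est)
    return ICCResult(form=form, estimate=float(est), ci_lower=float(lo),
                     ci_upper=float(hi), msr=msr, msc=msc, mse=mse,
                     n=n, k=k, degenerate=degenerate)


def rate_icc(estimate: float) -> str:
    """Qualitative ICC rating with half-open category boundaries."""
    if math.isnan(estimate):
        return "undefined"
    if estimate > 1.0:
        raise ValueError("ICC estimate cannot exceed 1")
    if estimate < 0.5:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Model / results surface
# ---------------------------------------------------------------------------

class InstrumentAgreement:
    """Agreement model over matched per-subject summaries.

    Parameters
    ----------
    psw_summaries, mlmc_summaries : list of SubjectSummary
        Per-subject task summaries from the two instruments; subjects are
        matched by id and must coincide.
    mode : {"subject_means", "pooled"}
        Pairing unit. The default pairs per-subject parameter means
        (one pair per subject, as in a per-parameter comparison table);
        "pooled" requires pre-paired pooled values supplied via ``pairs``.
    """

    def __init__(self, psw_summaries: list[SubjectSummary],
                 mlmc_summaries: list[SubjectSummary],
                 mode: str = "subject_means"):
        if mode not in ("subject_means", "pooled"):
            raise ValueError("mode must be 'subject_means' or 'pooled'")
        psw_ids = [s.subject for s in psw_summaries]
        mlmc_ids = [s.subject for s in mlmc_summaries]
        if len(set(psw_ids)) != len(psw_ids) or len(set(mlmc_ids)) != len(mlmc_ids):
            raise ValueError("duplicate subject ids in summaries")
        if set(psw_ids) != set(mlmc_ids):
            missing = set(psw_ids) ^ set(mlmc_ids)
            raise ValueError(f"unmatched subject sets; odd subjects: {sorted(missing)}")
        if len(psw_ids) < 2:
            raise ValueError("agreement analysis needs at least 2 matched subjects")
        order = sorted(psw_ids)
        self.subjects = order
        self._psw = {s.subject: s for s in psw_summaries}
        self._mlmc = {s.subject: s for s in mlmc_summaries}
        self.mode = mode

    def paired_sample(self, parameter: str) -> PairedSample:
        return PairedSample(
            parameter=parameter, units=PARAMETERS[parameter],
            psw=np.array([self._psw[s].mean[parameter] for s in self.subjects]),
            mlmc=np.array([self._mlmc[s].mean[parameter] for s in self.subjects]),
        )

    def fit(self, level: float = 0.95) -> "AgreementResults":
        rows = []
        for param in PARAMETERS:
            sample = self.paired_sample(param)
            md, sd, pct = mean_difference(sample)
            ba = bland_altman(sample, level=level)
            i21 = icc(sample, "2,1", level=level)
            i31 = icc(sample, "3,1", level=level)
            rows.append(AgreementRow(
                parameter=param, units=PARAMETERS[param], n=sample.n,
                psw_mean=float(sample.psw.mean()),
                psw_sd=float(sample.psw.std(ddof=1)),
                mlmc_mean=float(sample.mlmc.mean()),
                mlmc_sd=float(sample.mlmc.std(ddof=1)),
                mean_diff=md, sd_diff=sd, pct_error=pct, bland_altman=ba,
                icc21=i21, icc31=i31,
                rating21=rate_icc(i21.estimate), rating31=rate_icc(i31.estimate),
            ))
        return AgreementResults(rows)


@dataclass
class AgreementResults:
    """Per-parameter agreement battery results."""

    rows: list[AgreementRow]

    def row(self, parameter: str) -> AgreementRow:
        for r in self.rows:
            if r.parameter == parameter:
                return r
        raise KeyError(parameter)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "parameter": r.parameter, "units": r.units, "n": r.n,
                "psw_mean": r.psw_mean, "psw_sd": r.psw_sd,
                "mlmc_mean": r.mlmc_mean, "mlmc_sd": r.mlmc_sd,
                "mean_diff": r.mean_diff, "sd_diff": r.sd_diff,
                "pct_error": r.pct_error,
                "loa_lower": r.bland_altman.loa_lower,
                "loa_upper": r.bland_altman.loa_upper,
                "icc21": r.icc21.estimate, "icc21_lo": r.icc21.ci_lower,
                "icc21_hi": r.icc21.ci_upper,
                "icc31": r.icc31.estimate, "icc31_lo": r.icc31.ci_lower,
                "icc31_hi": r.icc31.ci_upper,
                "rating21": r.rating21, "rating31": r.rating31,
            })
        return pd.DataFrame(recs)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Instrument agreement: PSW vs MLMC "
            f"(n = {df['n'].iloc[0]} subjects; diff = PSW - MLMC)",
            "",
        ]
        with pd.option_context("display.width", 200, "display.max_columns", 30,
                               "display.float_format", lambda x: f"{x:0.4g}"):
            lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_bland_altman(self, parameter: str, ax=None):
        """Bland-Altman scatter for one parameter (requires matplotlib)."""
        import matplotlib.pyplot as plt

        r = self.row(parameter)
        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(r.mean_diff, color="k", lw=1, label="mean diff")
        ax.axhline(r.bland_altman.loa_lower, color="gray", ls="--", lw=1)
        ax.axhline(r.bland_altman.loa_upper, color="gray", ls="--", lw=1,
                   label="95% LOA")
        ax.set_xlabel(f"pair mean ({r.units})")
        ax.set_ylabel(f"PSW - MLMC ({r.units})")
        ax.set_title(parameter)
        ax.legend(loc="best", fontsize=8)
        return ax


def compare_instruments(psw_summaries: list[SubjectSummary],
                        mlmc_summaries: list[SubjectSummary],
                        mode: str = "subject_means") -> AgreementResults:
    """Build and fit the full 12-parameter agreement table."""
    return InstrumentAgreement(psw_summaries, mlmc_summaries, mode=mode).fit()
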