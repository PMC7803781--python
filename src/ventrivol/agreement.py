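"""Method-comparison statistics for paired volume series.

Quantifies agreement between a reference (manual, VOCAL-style) and an
automatic volumetry method over paired measurements of the same
ventricles:

* ICC -- intraclass correlation, two-way random effects, absolute
  agreement, average measures (ICC(A,k) with k = 2 methods), with the
  F-distribution confidence bounds of McGraw & Wong.
* Passing-Bablok regression -- rank-based fit y = A + B x whose slope is
  the shifted median of all pairwise slopes; its CIs test for constant
  (A != 0) and proportional (B != 1) bias without assuming error-free x.
* Lin's concordance correlation coefficient (CCC) -- agreement with the
  identity line, from biased (1/n) moment estimators.
* Bland-Altman -- bias = mean(y - x), limits of agreement
  bias +/- 1.96 SD, each limit with a 95% CI from SE = SD * sqrt(3/n),
  and tallies of differences outside the limits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class PairedSeries:
    """Paired (reference x, test y) measurements with optional keys."""

    x: np.ndarray
    y: np.ndarray
    keys: Optional[list[tuple]] = None  # (patient, acquisition_index, side)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in series")

    @property
    def n(self) -> int:
        return len(self.x)

    @classmethod
    def from_measurements(cls, manual, auto) -> "PairedSeries":
        """Pair VentricleMeasurement lists on (patient, day, side)."""
        key = lambda m: (m.patient_id, m.acquisition_index, m.side)
        man = {key(m): m.volume_cm3 for m in manual}
        aut = {key(m): m.volume_cm3 for m in auto}
        common = sorted(set(man) & set(aut))
        if len(common) < 3:
            raise ValueError("fewer than 3 common (patient, day, side) keys")
        return cls(
            x=np.array([man[k] for k in common]),
            y=np.array([aut[k] for k in common]),
            keys=list(common),
        )


@dataclass
class Estimate:
    value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: Estimate
    loa_upper: Estimate
    n: int
    n_above: int
    n_below: int
    pct_within: float


@dataclass
class AgreementReport:
    icc: Estimate
    pb_intercept: Estimate
    pb_slope: Estimate
    ccc: float
    bland_altman: BlandAltmanResult
    n: int
    subgroups: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    def summary(self) -> str:
        """Plain-text agreement table."""
        rows = [
            ("n pairs", f"{self.n}"),
            ("ICC (A,2) [95% CI]",
             f"{self.icc.value:.3f} [{self.icc.ci_low:.3f}, {self.icc.ci_high:.3f}]"),
            ("PB intercept A [95% CI]",
             f"{self.pb_intercept.value:.3f} "
             f"[{self.pb_intercept.ci_low:.3f}, {self.pb_intercept.ci_high:.3f}]"),
            ("PB slope B [95% CI]",
             f"{self.pb_slope.value:.3f} "
             f"[{self.pb_slope.ci_low:.3f}, {self.pb_slope.ci_high:.3f}]"),
            ("Lin's CCC", f"{self.ccc:.4f}"),
            ("BA bias (SD)",
             f"{self.bland_altman.bias:.3f} ({self.bland_altman.sd:.3f})"),
            ("BA LoA",
             f"[{self.bland_altman.loa_lower.value:.3f}, "
             f"{self.bland_altman.loa_upper.value:.3f}]"),
            ("BA % within LoA", f"{self.bland_altman.pct_within:.1f}%"),
        ]
        for name, sub in self.subgroups.items():
            rows.append((f"ICC {name} (n={sub['n']})",
                         f"{sub['icc']:.3f} [{sub['ci_low']:.3f}, {sub['ci_high']:.3f}]"))
        width = max(len(r[0]) for r in rows)
        lines = ["Agreement report", "=" * 40]
        lines += [f"{name:<{width}}  {val}" for name, val in rows]
        return "\n".join(lines)


def _anova_mean_squares(x: np.ndarray, y: np.ndarray):
    """Two-way ANOVA mean squares for an n x 2 ratings table."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_agreement(series: PairedSeries, average_measures: bool = True) -> Estimate:
    """ICC for absolute agreement under a two-way random-effects model.

    Default is the average-measures form ICC(A,k) with k = 2 methods:
    (MSR - MSE) / (MSR + (MSC - MSE)/n).  ``average_measures=False``
    returns the single-measures form ICC(A,1).  The 95% CI follows
    McGraw & Wong: F bounds on ICC(A,1), carried to ICC(A,k) by the
    Spearman-Brown step-up.
    """
    if series.n < 4:
        raise ValueError("ICC requires at least 4 pairs")
    msr, msc, mse, n, k = _anova_mean_squares(series.x, series.y)
    if msr <= mse:
        warnings.warn("zero (or negative) between-subject variance: ICC degenerate")
    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icck = (msr - mse) / (msr + (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1)
    a = k * icc1 / (n * (1.0 - icc1)) if icc1 < 1.0 else np.inf
    b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1)) if icc1 < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(0.975, n - 1, v)
        f_u = stats.f.ppf(0.975, v, n - 1)
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:  # perfect agreement: CI collapses
        lo1 = hi1 = icc1
    step_up = lambda r: r * k / (1.0 + (k - 1) * r)
    if average_measures:
        return Estimate(float(icck), float(step_up(lo1)), float(step_up(hi1)))
    return Estimate(float(icc1), float(lo1), float(hi1))


def passing_bablok(series: PairedSeries, tau_threshold: float = 0.3):
    """Passing-Bablok regression with rank-based 95% CIs.

    The slope B is the shifted median of all pairwise slopes
    S_ij = (y_j - y_i) / (x_j - x_i), i < j, excluding undefined slopes
    (x_i = x_j) and slopes exactly -1, with offset K = #{S_ij < -1}; the
    intercept A = median(y_i - B x_i).  CIs use the normal approximation
    to the rank of the slope median; the intercept CI comes from the
    slope CI endpoints.  Returns (A, B, flags); flags notes weak
    correlation (Kendall tau below ``tau_threshold``).
    """
    x, y, n = series.x, series.y, series.n
    if np.all(x == x[0]):
        raise ValueError("all x identical: slope undefined")
    flags = []
    tau = stats.kendalltau(x, y).statistic
    if not np.isnan(tau) and tau < tau_threshold:
        flags.append(f"weak correlation: Kendall tau = {tau:.3f} < {tau_threshold}")

    slopes = []
    n_neg1 = 0
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        valid = dx != 0
        s = dy[valid] / dx[valid]
        n_neg1 += int((s == -1.0).sum())
        slopes.append(s[s != -1.0])
    s = np.sort(np.concatenate(slopes))
    big_n = len(s)
    if big_n == 0:
        raise ValueError("no valid pairwise slopes")
    kk = int((s < -1.0).sum())  # offset K

    def shifted_median(arr, offset):
        m = len(arr)
        if m % 2 == 1:
            return arr[(m + 1) // 2 + offset - 1]
        return 0.5 * (arr[m // 2 + offset - 1] + arr[m // 2 + offset])

    b = float(shifted_median(s, kk))
    a = float(np.median(y - b * x))

    w = 1.959964 * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = np.clip(m1 + kk, 1, big_n) - 1
    hi_idx = np.clip(m2 + kk, 1, big_n) - 1
    b_lo, b_hi = float(s[lo_idx]), float(s[hi_idx])
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return (
        Estimate(a, min(a_lo, a_hi), max(a_lo, a_hi)),
        Estimate(b, b_lo, b_hi),
        flags,
    )


def lin_ccc(series: PairedSeries) -> float:
    """Lin's concordance correlation with biased (1/n) moment estimators."""
    x, y = series.x, series.y
    sx2 = x.var()  # 1/n
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        warnings.warn("zero variance in both arms: CCC degenerate")
        return 1.0
    return float(2.0 * sxy / denom)


def loa_from_moments(bias: float, sd: float, n: int):
    """Limits of agreement and their CIs from printed moments.

    LoA = bias -/+ 1.96 SD; each limit's standard error is SD*sqrt(3/n)
    and its 95% CI is the limit +/- 1.96 SE.  The multiplier 1.96 is used
    exactly (not a t quantile).
    """
    z = 1.96
    lo = bias - z * sd
    hi = bias + z * sd
    se = sd * math.sqrt(3.0 / n)
    return (
        Estimate(lo, lo - z * se, lo + z * se),
        Estimate(hi, hi - z * se, hi + z * se),
    )


def bland_altman(series: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman analysis of differences d = y - x."""
    d = series.y - series.x
    n = series.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lower, loa_upper = loa_from_moments(bias, sd, n)
    n_above = int((d > loa_upper.value).sum())
    n_below = int((d < loa_lower.value).sum())
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        n=n,
        n_above=n_above,
        n_below=n_below,
        pct_within=100.0 * (n - n_above - n_below) / n,
    )


def agreement_report(
    series: PairedSeries, sides: Optional[Sequence[str]] = None
) -> AgreementReport:
    """Run all four estimators and assemble a structured report.

    ``sides`` (or the side element of ``series.keys``) enables per-side
    subgroup ICCs; subgroups with fewer than 5 pairs are omitted with a
    note in ``flags``.
    """
    if series.n < 5:
        raise ValueError("agreement report requires at least 5 pairs")
    icc = icc_agreement(series)
    a, b, flags = passing_bablok(series)
    ccc = lin_ccc(series)
    ba = bland_altman(series)
    report = AgreementReport(
        icc=icc, pb_intercept=a, pb_slope=b, ccc=ccc, bland_altman=ba,
        n=series.n, flags=list(flags),
    )
    side_labels = sides
    if side_labels is None and series.keys is not None:
        side_labels = [k[2] for k in series.keys]
    if side_labels is not None:
        for side in sorted(set(side_labels)):
            sel = np.array([s == side for s in side_labels])
            if sel.sum() < 5:
                report.flags.append(f"subgroup {side!r} omitted: n = {int(sel.sum())} < 5")
                continue
            sub = PairedSeries(series.x[sel], series.y[sel])
            est = icc_agreement(sub)
            report.subgroups[side] = {
                "n": int(sel.sum()), "icc": est.value,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            }
    return report


def plot_agreement(series: PairedSeries, report: AgreementReport, out_dir: str):
    """Passing-Bablok scatter and Bland-Altman difference plots (PNG)."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(series.x, series.y, s=12, alpha=0.7)
    xs = np.linspace(series.x.min(), series.x.max(), 50)
    ax.plot(xs, report.pb_intercept.value + report.pb_slope.value * xs, "r-",
            label=f"y = {report.pb_intercept.value:.3f} + {report.pb_slope.value:.3f} x")
    ax.plot(xs, xs, "k:", label="identity")
    ax.set_xlabel("reference volume (cm$^3$)")
    ax.set_ylabel("automatic volume (cm$^3$)")
    ax.legend()
    fig.savefig(os.path.join(out_dir, "passing_bablok.png"), dpi=120)
    plt.close(fig)

    ba = report.bland_altman
    d = series.y - series.x
    mean = (series.x + series.y) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, d, s=12, alpha=0.7)
    for v, style in ((ba.bias, "r-"), (ba.loa_lower.value, "r--"),
                     (ba.loa_upper.value, "r--")):
        ax.axhline(v, ls=style[1:], color="r")
    ax.set_xlabel("mean of methods (cm$^3$)")
    ax.set_ylabel("difference Y - X (cm$^3$)")
    fig.savefig(os.path.join(out_dir, "bland_altman.png"), dpi=120)
    plt.close(fig)
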