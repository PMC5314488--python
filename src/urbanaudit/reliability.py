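"""Internal consistency and interrater reliability of audit responses.

Two questions about the instrument are answered here.  Do the items measure
one construct?  Cronbach's alpha

    alpha = k/(k-1) * (1 - sum_j var(item_j) / var(row totals))

with a unit-resampling percentile bootstrap CI (default 2000 iterations),
alpha-if-item-dropped, and item-total correlations.  Do two observers agree
in absolute terms?  The two-way, absolute-agreement, average-measures
intraclass correlation ICC(A,k), from the two-way ANOVA decomposition of the
subjects x raters table:

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

with the F-based confidence interval and the F test of ICC = 0 (raters as a
fixed panel — the "two-way mixed" reading — which shares this estimator with
the random-raters case).  Likert ordinals are treated as interval-scaled
reals throughout, and not-applicable entries are handled by per-item
pairwise deletion of units, so each item reports its own n.

All sample variances use denominator n-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ObservationMatrix

__all__ = [
    "AlphaResult",
    "IccResult",
    "cronbach_alpha",
    "item_total_correlation",
    "icc_absolute_average",
    "reliability_report",
    "format_reliability_table",
]


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    ci: tuple[float, float]
    level: float
    alpha_if_dropped: pd.Series
    n_units: int
    n_boot: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci: tuple[float, float]
    p_value: float
    level: float
    n_subjects: int
    n_raters: int

    @property
    def significant(self) -> bool:
        """Table-convention flag: False mirrors the 'not significant at p<0.05' mark."""
        return self.p_value < 0.05


def _alpha_point(x: np.ndarray) -> float:
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero variance of row totals; alpha undefined")
    return (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)


def cronbach_alpha(
    matrix: pd.DataFrame | np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> AlphaResult:
    """Cronbach's alpha with percentile-bootstrap CI and alpha-if-dropped.

    Rows with any missing value are dropped (complete-case); the count of
    units actually used is reported.  The bootstrap resamples units.
    """
    df = pd.DataFrame(matrix)
    df = df.dropna(axis=0)
    x = df.to_numpy(float)
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 complete units")
    alpha = _alpha_point(x)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, n, n)]
        try:
            boots[b] = _alpha_point(xb)
        except ValueError:  # resample with zero total variance
            boots[b] = np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])

    dropped = {}
    for j, col in enumerate(df.columns):
        # with only 2 items, dropping one leaves no scale to assess
        dropped[col] = (
            _alpha_point(np.delete(x, j, axis=1)) if k >= 3 else np.nan
        )
    return AlphaResult(
        alpha=float(alpha),
        ci=(float(lo), float(hi)),
        level=level,
        alpha_if_dropped=pd.Series(dropped, name="alpha_if_dropped"),
        n_units=n,
        n_boot=n_boot,
    )


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlation of each variable on the others."""
    inv = np.linalg.pinv(corr)
    return 1.0 - 1.0 / np.diag(inv)


def item_total_correlation(
    matrix: pd.DataFrame | np.ndarray,
    variant: str = "item_rest",
) -> pd.Series:
    """Per-item correlation with the rest of the scale.

    ``item_rest``: Pearson correlation of the item with the row total minus
    the item.  ``overlap_reliability_corrected``: the item-rest correlation
    divided by sqrt(alpha-without-item * SMC of the item on the remaining
    items) — a correction for item overlap and scale (un)reliability; both
    variants should be read together since corrections of this family vary
    between packages.  Zero-variance items are reported as NaN with a warning.
    """
    df = pd.DataFrame(matrix).dropna(axis=0)
    x = df.to_numpy(float)
    n, k = x.shape
    if k < 3 and variant != "item_rest":
        raise ValueError("corrected variant needs at least 3 items")
    out = {}
    for j, col in enumerate(df.columns):
        item = x[:, j]
        rest = np.delete(x, j, axis=1)
        rest_total = rest.sum(axis=1)
        if item.var(ddof=1) <= 0 or rest_total.var(ddof=1) <= 0:
            warnings.warn(
                f"item {col!r} (or the rest-score) has zero variance; "
                "item-total correlation undefined",
                UserWarning,
                stacklevel=2,
            )
            out[col] = np.nan
            continue
        r = float(np.corrcoef(item, rest_total)[0, 1])
        if variant == "item_rest":
            out[col] = r
        elif variant == "overlap_reliability_corrected":
            alpha_wo = _alpha_point(rest)
            smc_j = float(_smc(np.corrcoef(x, rowvar=False))[j])
            denom = alpha_wo * smc_j
            out[col] = r / np.sqrt(denom) if denom > 0 else np.nan
        else:
            raise ValueError(f"unknown variant {variant!r}")
    return pd.Series(out, name=f"itc_{variant}")


def icc_absolute_average(
    matrix: pd.DataFrame | np.ndarray, level: float = 0.95
) -> IccResult:
    """ICC(A,k): two-way, absolute-agreement, average-measures.

    ``matrix`` is subjects x raters, complete cases only (drop incomplete
    rows before calling, or let this function do it).  CI follows the
    McGraw & Wong F-based construction for average measures with absolute
    agreement; p is from the F test of ICC = 0 (F = MSR/MSE on (n-1),
    (n-1)(k-1) df).
    """
    df = pd.DataFrame(matrix).dropna(axis=0)
    x = df.to_numpy(float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 3:
        raise ValueError("need at least 3 subjects with complete ratings")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero between-subject variance; ICC undefined")

    icc = (msr - mse) / (msr + (msc - mse) / n)

    # F test of ICC = 0
    if mse > 0:
        f0 = msr / mse
        p = float(stats.f.sf(f0, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    # McGraw & Wong CI for ICC(A,1), Spearman-Brown stepped up to k raters
    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha2 = (1 - level) / 2
    a = k * icc_a1 / (n * (1 - icc_a1)) if icc_a1 < 1 else np.inf
    b = 1 + k * icc_a1 * (n - 1) / (n * (1 - icc_a1)) if icc_a1 < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_lo = stats.f.ppf(1 - alpha2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha2, v, n - 1)
        lo1 = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        step = lambda r1: k * r1 / (1 + (k - 1) * r1)  # noqa: E731
        lo, hi = step(lo1), step(hi1)
    else:  # degenerate: raters in perfect agreement
        lo, hi = icc, icc
    lo = min(lo, icc)
    hi = max(hi, icc)
    return IccResult(
        icc=float(icc),
        ci=(float(lo), float(hi)),
        p_value=p,
        level=level,
        n_subjects=n,
        n_raters=k,
    )


def reliability_report(
    matrices: list[ObservationMatrix],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Full instrument report from >= 2 per-auditor observation matrices.

    Internal consistency (alpha, alpha-if-dropped, both ITC variants) is
    computed on the auditor-averaged responses; interrater reliability is a
    per-item ICC(A,k) across locations with per-item pairwise deletion,
    which is why n varies between items.
    """
    from .scoring import combine_auditors

    combined = combine_auditors(matrices, policy="mean")
    alpha = cronbach_alpha(combined.data, n_boot=n_boot, level=level, seed=seed)
    itc_rest = item_total_correlation(combined.data, "item_rest")
    itc_corr = item_total_correlation(combined.data, "overlap_reliability_corrected")

    icc_rows = {}
    base_index = matrices[0].data.index
    for item in matrices[0].item_ids:
        sub = pd.DataFrame(
            {i: m.data.loc[base_index, item] for i, m in enumerate(matrices)}
        )
        sub = sub.dropna(axis=0)  # pairwise deletion per item
        res = icc_absolute_average(sub, level=level)
        icc_rows[item] = {
            "n": res.n_subjects,
            "icc": res.icc,
            "ci_lo": res.ci[0],
            "ci_hi": res.ci[1],
            "p": res.p_value,
            "significant": res.significant,
        }
    return {
        "alpha": alpha,
        "item_total": pd.DataFrame({"item_rest": itc_rest, "corrected": itc_corr}),
        "icc": pd.DataFrame(icc_rows).T,
    }


def format_reliability_table(report: dict) -> str:
    """Human-readable text table: alpha block, then per-item ITC / n / ICC."""
    a: AlphaResult = report["alpha"]
    lines = [
        f"Cronbach's alpha = {a.alpha:.2f} "
        f"({a.level:.0%} CI [{a.ci[0]:.2f}, {a.ci[1]:.2f}], "
        f"n = {a.n_units}, {a.n_boot} bootstrap iterations)",
        "",
        f"{'item':<24}{'alpha-drop':>11}{'ITC':>7}{'n':>6}{'ICC':>7}"
        f"{'95% CI':>16}  sig",
    ]
    icc = report["icc"]
    itc = report["item_total"]
    for item in icc.index:
        row = icc.loc[item]
        flag = "" if row["significant"] else "#"
        lines.append(
            f"{item:<24}{a.alpha_if_dropped[item]:>11.2f}"
            f"{itc.loc[item, 'corrected']:>7.2f}{int(row['n']):>6}"
            f"{row['icc']:>7.2f}"
            f"{'[' + format(row['ci_lo'], '.2f') + ',' + format(row['ci_hi'], '.2f') + ']':>16}"
            f"  {flag}"
        )
    lines.append("")
    lines.append("# not significant at p < 0.05")
    return "\n".join(lines)
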