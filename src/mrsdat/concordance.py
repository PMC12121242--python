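"""Relative-validity statistics for paired dietary measurements.

Agreement between a test method (FFQ-derived scores) and a reference method
(averaged 24-h recalls) on the same participants is summarised with:

* Lin's concordance correlation coefficient (CCC) — precision x accuracy
  relative to the 45-degree line, with a Fisher-z asymptotic confidence
  interval;
* Bland-Altman mean difference and 95% limits of agreement, plus a
  proportional-bias test (OLS slope of differences on pairwise means);
* weighted Cohen's kappa on tertiles of each method's scores, with
  same/adjacent/gross cross-classification percentages;
* paired t or Wilcoxon signed-rank tests with Bonferroni adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateInputError

CCC_MIN_PAIRS = 10  # below this the CCC is reported with a robustness warning


@dataclass(frozen=True)
class PairedSample:
    """Paired method values for one analysis stratum."""

    participant_ids: tuple[str, ...]
    x: np.ndarray  # test method (FFQ)
    y: np.ndarray  # reference method (recall average)
    stratum: str = "all"
    pairs_only: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ConfigError("x and y must be 1-d arrays of equal length")
        if len(self.participant_ids) != len(x):
            raise ConfigError("participant_ids must match the value vectors")
        if len(x) < 2:
            raise DegenerateInputError("paired sample needs n >= 2")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ConfigError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.x)

    def subset(self, keep: Sequence[bool], stratum: str | None = None) -> "PairedSample":
        keep = np.asarray(keep, dtype=bool)
        return PairedSample(
            participant_ids=tuple(np.asarray(self.participant_ids)[keep]),
            x=self.x[keep],
            y=self.y[keep],
            stratum=self.stratum if stratum is None else stratum,
            pairs_only=self.pairs_only,
        )


@dataclass(frozen=True)
class PairedTestResult:
    comparison_id: str
    statistic_kind: str  # "t" | "wilcoxon_z"
    statistic: float  # mean difference (t) or Z (wilcoxon), as reported
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    n: int


@dataclass
class ConcordanceReport:
    stratum: str
    pairs_only: bool
    n: int
    rc: float
    rc_ci: tuple[float, float]
    bias: float
    loa: tuple[float, float]
    ba_slope: float
    ba_slope_p: float
    kappa_w: float
    kappa_weights: str
    tertile_table: np.ndarray  # 3x3 counts, rows = x tertile, cols = y tertile
    pct_same_tertile: float
    pct_adjacent: float
    n_gross: int

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "pairs_only": self.pairs_only,
            "n": self.n,
            "rc": self.rc,
            "rc_ci": list(self.rc_ci),
            "bias": self.bias,
            "loa": list(self.loa),
            "ba_slope": self.ba_slope,
            "ba_slope_p": self.ba_slope_p,
            "kappa_w": self.kappa_w,
            "kappa_weights": self.kappa_weights,
            "tertile_table": self.tertile_table.tolist(),
            "pct_same_tertile": self.pct_same_tertile,
            "pct_adjacent": self.pct_adjacent,
            "n_gross": self.n_gross,
        }


# ---------------------------------------------------------------------------
# Lin's CCC


def lins_ccc(
    x: np.ndarray | PairedSample,
    y: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with an asymptotic CI.

    rc = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2) using
    population (1/n) moments. The confidence interval applies the Fisher z
    transform with Lin's asymptotic variance and back-transforms.
    """
    if isinstance(x, PairedSample):
        sample = x
        x, y = sample.x, sample.y
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise DegenerateInputError("lins_ccc needs two equal-length vectors, n >= 2")
    if n < CCC_MIN_PAIRS:
        warnings.warn(
            f"Lin's CCC computed on n={n} < {CCC_MIN_PAIRS} pairs; "
            "the estimate may not be robust",
            stacklevel=2,
        )
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    if sx2 <= 0 or sy2 <= 0:
        raise DegenerateInputError("lins_ccc undefined when either vector is constant")
    rc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    ci = _ccc_fisher_ci(rc, x, y, mx, my, sx2, sy2, sxy, ci_level)
    return rc, ci


def _ccc_fisher_ci(rc, x, y, mx, my, sx2, sy2, sxy, ci_level):
    n = len(x)
    r = sxy / math.sqrt(sx2 * sy2)  # Pearson
    if n <= 2 or abs(rc) >= 1.0 or r == 0.0:
        return (rc, rc)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location shift relative to scale
    one_m_rc2 = 1.0 - rc**2
    var_z = (
        (1.0 - r**2) * rc**2 / (one_m_rc2 * r**2)
        + 2.0 * rc**3 * (1.0 - rc) * u**2 / (r * one_m_rc2**2)
        - rc**4 * u**4 / (2.0 * r**2 * one_m_rc2**2)
    ) / (n - 2)
    if var_z <= 0:
        return (rc, rc)
    z = math.atanh(rc)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zcrit * math.sqrt(var_z)
    return (math.tanh(z - half), math.tanh(z + half))


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(
    x: np.ndarray | PairedSample, y: np.ndarray | None = None
) -> tuple[float, tuple[float, float], float, float]:
    """Mean difference, 95% limits of agreement, and proportional-bias slope.

    Differences are x - y; limits are bias +/- 1.96 x sample SD of the
    differences; the slope (with its two-sided p) comes from OLS of the
    differences on the pairwise means, the standard proportional-bias check.
    """
    if isinstance(x, PairedSample):
        x, y = x.x, x.y
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    means = (x + y) / 2.0
    if len(x) < 3:
        raise DegenerateInputError("proportional-bias slope needs n >= 3")
    if np.ptp(means) == 0:
        raise DegenerateInputError("pairwise means are constant; slope undefined")
    if np.ptp(d) == 0:
        # constant differences: exact zero slope, no evidence of proportional bias
        return bias, loa, 0.0, 1.0
    fit = stats.linregress(means, d)
    return bias, loa, float(fit.slope), float(fit.pvalue)


# ---------------------------------------------------------------------------
# tertiles and kappa


def assign_tertiles(values: np.ndarray) -> np.ndarray:
    """Labels in {1, 2, 3} cut at the empirical 1/3 and 2/3 quantiles
    (linear interpolation); values at or below a cut take the lower tertile.
    With all values tied every label is 1 and a degenerate-cut warning is
    issued."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DegenerateInputError("tertiles need n >= 3")
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2 and np.ptp(values) == 0:
        warnings.warn("all values tied; tertile cuts are degenerate", stacklevel=2)
    labels = np.where(values <= q1, 1, np.where(values <= q2, 2, 3))
    return labels.astype(int)


def tertile_crosstab(t_x: np.ndarray, t_y: np.ndarray) -> np.ndarray:
    t_x = np.asarray(t_x, dtype=int)
    t_y = np.asarray(t_y, dtype=int)
    if t_x.shape != t_y.shape:
        raise ConfigError("tertile label vectors differ in length")
    if not (np.isin(t_x, (1, 2, 3)).all() and np.isin(t_y, (1, 2, 3)).all()):
        raise ConfigError("tertile labels must be in {1, 2, 3}")
    table = np.zeros((3, 3), dtype=int)
    for a, b in zip(t_x, t_y):
        table[a - 1, b - 1] += 1
    return table


def weighted_kappa(
    t_x: np.ndarray, t_y: np.ndarray, weights: str = "linear"
) -> float:
    """Weighted Cohen's kappa on ordinal labels in {1, 2, 3}.

    Agreement weights default to linear, w_ij = 1 - |i - j| / (k - 1)
    (quadratic optional); chance agreement comes from the marginal products.
    """
    table = tertile_crosstab(t_x, t_y).astype(float)
    n = table.sum()
    k = table.shape[0]
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    if weights == "linear":
        w = 1.0 - dist
    elif weights == "quadratic":
        w = 1.0 - dist**2
    else:
        raise ConfigError(f"weights must be 'linear' or 'quadratic', got {weights!r}")
    po = float((w * table).sum() / n)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    pe = float((w * expected).sum() / n)
    if pe >= 1.0:
        raise DegenerateInputError("chance agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def agreement_summary(t_x: np.ndarray, t_y: np.ndarray) -> tuple[float, float, int]:
    """(% same tertile, % adjacent tertile, count grossly misclassified).

    Gross misclassification is assignment to opposite extreme tertiles.
    """
    t_x = np.asarray(t_x, dtype=int)
    t_y = np.asarray(t_y, dtype=int)
    diff = np.abs(t_x - t_y)
    n = len(diff)
    pct_same = 100.0 * float((diff == 0).sum()) / n
    pct_adjacent = 100.0 * float((diff == 1).sum()) / n
    n_gross = int((diff == 2).sum())
    return pct_same, pct_adjacent, n_gross


# ---------------------------------------------------------------------------
# paired tests


def paired_compare(
    x: np.ndarray,
    y: np.ndarray,
    test: str = "t",
    m: int = 1,
    comparison_id: str = "",
) -> PairedTestResult:
    """Paired t-test or Wilcoxon signed-rank test with Bonferroni adjustment.

    The reported statistic follows the usual presentation: the mean
    difference for the t-test, the normal-approximation Z (zero differences
    dropped, midranks and a tie correction) for Wilcoxon. The adjusted
    p-value is min(1, m x p_raw) for a declared family of m comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-d arrays of equal length")
    if m < 1:
        raise ConfigError(f"family size m must be >= 1, got {m}")
    d = x - y
    if test == "t":
        if len(d) < 2:
            raise DegenerateInputError("paired t-test needs n >= 2")
        mean_d = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            p_raw = 1.0 if mean_d == 0.0 else 0.0
        else:
            p_raw = float(stats.ttest_rel(x, y).pvalue)
        statistic, kind = mean_d, "t"
    elif test == "wilcoxon":
        z, p_raw = _wilcoxon_z(d)
        statistic, kind = z, "wilcoxon_z"
    else:
        raise ConfigError(f"test must be 't' or 'wilcoxon', got {test!r}")
    return PairedTestResult(
        comparison_id=comparison_id,
        statistic_kind=kind,
        statistic=statistic,
        p_raw=p_raw,
        p_adjusted=bonferroni(p_raw, m),
        m_comparisons=m,
        n=len(d),
    )


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def _wilcoxon_z(d: np.ndarray) -> tuple[float, float]:
    """Signed-rank Z: zero differences dropped, midranks, tie-corrected
    variance, two-sided normal p."""
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((counts**3 - counts).sum()) / 48.0)
    if var <= 0:
        raise DegenerateInputError("signed-rank variance is zero")
    z = (w_plus - mu) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(1.0, p)


# ---------------------------------------------------------------------------
# full report and sensitivity analysis


def concordance_report(
    sample: PairedSample,
    ci_level: float = 0.95,
    kappa_weights: str = "linear",
) -> ConcordanceReport:
    """All agreement statistics for one stratum in a single report."""
    rc, ci = lins_ccc(sample, ci_level=ci_level)
    bias, loa, slope, slope_p = bland_altman(sample)
    t_x = assign_tertiles(sample.x)
    t_y = assign_tertiles(sample.y)
    kappa = weighted_kappa(t_x, t_y, weights=kappa_weights)
    pct_same, pct_adj, n_gross = agreement_summary(t_x, t_y)
    return ConcordanceReport(
        stratum=sample.stratum,
        pairs_only=sample.pairs_only,
        n=sample.n,
        rc=rc,
        rc_ci=ci,
        bias=bias,
        loa=loa,
        ba_slope=slope,
        ba_slope_p=slope_p,
        kappa_w=kappa,
        kappa_weights=kappa_weights,
        tertile_table=tertile_crosstab(t_x, t_y),
        pct_same_tertile=pct_same,
        pct_adjacent=pct_adj,
        n_gross=n_gross,
    )


def sensitivity_with_outlier(
    sample: PairedSample,
    flagged_ids: Sequence[str],
    ci_level: float = 0.95,
    kappa_weights: str = "linear",
) -> tuple[ConcordanceReport, ConcordanceReport, dict[str, float]]:
    """Primary analysis with and without flagged participants.

    Returns (report_including, report_excluding, deltas) where the deltas are
    including-minus-excluding for rc, bias and kappa. With no flagged
    participants the two reports are identical.
    """
    flagged = set(flagged_ids)
    keep = [pid not in flagged for pid in sample.participant_ids]
    with_all = concordance_report(sample, ci_level=ci_level, kappa_weights=kappa_weights)
    without = concordance_report(
        sample.subset(keep), ci_level=ci_level, kappa_weights=kappa_weights
    )
    deltas = {
        "rc": with_all.rc - without.rc,
        "bias": with_all.bias - without.bias,
        "kappa_w": with_all.kappa_w - without.kappa_w,
    }
    return with_all, without, deltas
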