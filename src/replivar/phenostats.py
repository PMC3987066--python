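"""Trait-population and qRT-PCR variability statistics.

Growth-assay populations (root length, hypocotyl length, cotyledon and leaf
area, rosette diameter) are summarised by mean, unbiased variance and the
coefficient of variation CV = sd/mean, and compared between lines by

* Levene's test of variance homogeneity (mean- or median-centred),
* the Mann-Whitney U test for location (exact for small tie-free samples,
  tie- and continuity-corrected normal approximation otherwise),
* the Shapiro-Wilk normality test (Royston approximation via scipy), and
* an adjusted rank transform (ART) test for crossed two-factor designs:
  main effects are tested by two-way ANOVA on the ranks of the raw data;
  the interaction is tested after subtracting both estimated main effects,
  ranking the adjusted values, and running the ANOVA on those ranks.

qRT-PCR expression values are normalised per individual to a reference gene
and min-scaled so each gene's lowest value within a line is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class DegenerateVarianceError(ValueError):
    """The statistic is undefined because all dispersion is zero."""


@dataclass(frozen=True)
class TraitSample:
    """One line/condition's vector of individual trait measurements."""

    line: str
    values: np.ndarray
    trait: str = "trait"
    units: str = ""
    factors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("values must be a non-empty 1-D vector")
        if not np.isfinite(arr).all():
            raise ValueError("trait values must be finite")
        if arr.min() <= 0:
            raise ValueError("trait measurements must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TraitSummary:
    n: int
    mean: float
    variance: float
    sd: float
    cv: float
    median: float


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom, and p-value of one hypothesis test."""

    statistic: float
    df: tuple
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _values(x) -> np.ndarray:
    if isinstance(x, TraitSample):
        return x.values
    return np.asarray(x, dtype=float)


def summarize_trait(sample: TraitSample | Sequence[float]) -> TraitSummary:
    """n, mean, unbiased variance (n-1 denominator), sd, CV = sd/mean, median."""
    v = _values(sample)
    if v.size < 2:
        raise InsufficientDataError("need n >= 2 for variance-based summaries")
    mean = float(v.mean())
    var = float(v.var(ddof=1))
    if mean <= 0:
        raise ValueError("CV undefined: mean <= 0")
    sd = float(np.sqrt(var))
    return TraitSummary(
        n=int(v.size), mean=mean, variance=var, sd=sd,
        cv=sd / mean, median=float(np.median(v)),
    )


def percent_reduction(reference_mean: float, test_mean: float) -> float:
    """100 * (1 - test/reference); full precision, round only for reporting."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (1.0 - test_mean / reference_mean)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def significance_stars(p: float) -> str:
    """'*', '**', '***' at the 0.05, 0.01, 0.001 levels; '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def levene_test(
    groups: Sequence[TraitSample | Sequence[float]], center: str = "mean"
) -> TestResult:
    """Levene's test of variance homogeneity across two or more groups.

    With Z_ij = |Y_ij - center_i| (group mean by default; group median gives
    the Brown-Forsythe variant),

        W = (N - k)/(k - 1) * sum_i n_i (Zbar_i - Zbar)^2
                              / sum_ij (Z_ij - Zbar_i)^2

    referred to the F distribution with (k - 1, N - k) degrees of freedom.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    zs = []
    for g in groups:
        v = _values(g)
        if v.size < 2:
            raise InsufficientDataError("each group needs n >= 2")
        c = v.mean() if center == "mean" else np.median(v)
        zs.append(np.abs(v - c))
    k = len(zs)
    if k < 2:
        raise InsufficientDataError("need at least 2 groups")
    n_i = np.array([z.size for z in zs], dtype=float)
    n_total = float(n_i.sum())
    zbar_i = np.array([z.mean() for z in zs])
    zbar = float(np.concatenate(zs).mean())
    num = float(np.sum(n_i * (zbar_i - zbar) ** 2))
    den = float(sum(np.sum((z - zb) ** 2) for z, zb in zip(zs, zbar_i)))
    if den == 0:
        if num == 0:
            raise DegenerateVarianceError(
                "all absolute deviations are zero; Levene's W is undefined"
            )
        w = float("inf")
    else:
        w = ((n_total - k) / (k - 1)) * num / den
    df = (k - 1, int(n_total - k))
    p = float(stats.f.sf(w, df[0], df[1]))
    return TestResult(statistic=w, df=df, p_value=p,
                      method=f"levene-{center}")


def shapiro_wilk(values: TraitSample | Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation), 3 <= n <= 5000."""
    v = _values(values)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise DegenerateVarianceError("constant sample: W undefined")
    res = stats.shapiro(v)
    return TestResult(statistic=float(res.statistic), df=(int(v.size),),
                      p_value=float(res.pvalue), method="shapiro-wilk")


def mann_whitney_u(
    a: TraitSample | Sequence[float], b: TraitSample | Sequence[float]
) -> TestResult:
    """Two-sided Mann-Whitney U test; U = min(U_a, U_b) from mid-ranked sums.

    p is exact (full enumeration) when n_a + n_b <= 12 and the pooled data is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections is used.  Identical pooled constants give p = 1 by symmetry.
    """
    va, vb = _values(a), _values(b)
    if va.size == 0 or vb.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n1, n2 = int(va.size), int(vb.size)
    pooled = np.concatenate([va, vb])
    if np.ptp(pooled) == 0:
        return TestResult(statistic=n1 * n2 / 2.0, df=(n1, n2), p_value=1.0,
                          method="mann-whitney-u-degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method,
                             use_continuity=True)
    u = float(min(res.statistic, n1 * n2 - res.statistic))
    return TestResult(statistic=u, df=(n1, n2),
                      p_value=float(min(res.pvalue, 1.0)),
                      method=f"mann-whitney-u-{method}")


# --- two-way ANOVA machinery for the adjusted rank transform -----------------

@dataclass(frozen=True)
class _TwoWaySS:
    ss_a: float
    ss_b: float
    ss_int: float
    mse: float
    df_a: int
    df_b: int
    df_int: int
    df_resid: int


def _rss_by_groups(y: np.ndarray, codes: np.ndarray, k: int) -> float:
    # within-group residual SS of the one-factor cell-means fit
    sums = np.bincount(codes, weights=y, minlength=k)
    counts = np.bincount(codes, minlength=k).astype(float)
    return float(np.sum(y * y) - np.sum(sums**2 / counts))


def _two_way_ss(y: np.ndarray, a: np.ndarray, b: np.ndarray,
                na: int, nb: int) -> _TwoWaySS:
    """Type-II sums of squares for the crossed two-factor layout.

    Full model is the cell-means fit; the additive model is fitted by least
    squares on dummy codes.  SS(A) = RSS(B) - RSS(A+B), SS(B) symmetric,
    SS(AB) = RSS(A+B) - RSS(full).  For balanced data this coincides with the
    classical decomposition.
    """
    n = y.size
    cell = a * nb + b
    rss_full = _rss_by_groups(y, cell, na * nb)
    rss_a = _rss_by_groups(y, a, na)
    rss_b = _rss_by_groups(y, b, nb)
    x = np.ones((n, 1 + (na - 1) + (nb - 1)))
    for i in range(1, na):
        x[:, i] = (a == i)
    for j in range(1, nb):
        x[:, na - 1 + j] = (b == j)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss_add = float(np.sum((y - x @ beta) ** 2))
    df_resid = n - na * nb
    return _TwoWaySS(
        ss_a=max(rss_b - rss_add, 0.0),
        ss_b=max(rss_a - rss_add, 0.0),
        ss_int=max(rss_add - rss_full, 0.0),
        mse=rss_full / df_resid,
        df_a=na - 1, df_b=nb - 1, df_int=(na - 1) * (nb - 1), df_resid=df_resid,
    )


_SS_TOL = 1e-9


def _f_test(ss: float, df_num: int, mse: float, df_den: int, method: str) -> TestResult:
    scale = max(ss, mse, 1.0)
    if ss <= _SS_TOL * scale:
        return TestResult(statistic=0.0, df=(df_num, df_den), p_value=1.0,
                          method=method)
    if mse <= _SS_TOL * scale:
        return TestResult(statistic=float("inf"), df=(df_num, df_den),
                          p_value=0.0, method=method)
    f = (ss / df_num) / mse
    return TestResult(statistic=float(f), df=(df_num, df_den),
                      p_value=float(stats.f.sf(f, df_num, df_den)), method=method)


@dataclass(frozen=True)
class ArtResult:
    """Adjusted-rank-transform results for a two-factor crossed design."""

    factor_a: TestResult
    factor_b: TestResult
    interaction: TestResult
    factor_names: tuple[str, str]


def adjusted_rank_transform(
    y: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    factor_names: tuple[str, str] = ("genotype", "treatment"),
) -> ArtResult:
    """Nonparametric factorial test for two crossed factors.

    Main effects: rank all raw observations (mid-ranks for ties) and run the
    two-way ANOVA on the ranks.  Interaction: remove both estimated main
    effects, Y'_ijk = Y_ijk - Ybar_i. - Ybar_.j + Ybar, rank Y', and test the
    interaction by ANOVA on those ranks with ((a-1)(b-1), N-ab) df.  An
    interaction sum of squares of zero (perfectly additive data) reports
    F = 0.  Unbalanced designs use type-II sums of squares.
    """
    yv = np.asarray(y, dtype=float)
    a_codes, a_levels = pd.factorize(np.asarray(factor_a), sort=True)
    b_codes, b_levels = pd.factorize(np.asarray(factor_b), sort=True)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("both factors need at least 2 levels")
    if not (yv.size == a_codes.size == b_codes.size):
        raise ValueError("y and factor vectors must have equal length")
    cell_counts = np.zeros((na, nb), dtype=int)
    np.add.at(cell_counts, (a_codes, b_codes), 1)
    if (cell_counts < 2).any():
        bad = [(str(a_levels[i]), str(b_levels[j]))
               for i, j in zip(*np.nonzero(cell_counts < 2))]
        raise ValueError(f"every cell needs n >= 2; deficient cells: {bad}")

    r = stats.rankdata(yv)
    ss_main = _two_way_ss(r, a_codes, b_codes, na, nb)
    res_a = _f_test(ss_main.ss_a, ss_main.df_a, ss_main.mse, ss_main.df_resid,
                    "art-main")
    res_b = _f_test(ss_main.ss_b, ss_main.df_b, ss_main.mse, ss_main.df_resid,
                    "art-main")

    grand = yv.mean()
    a_means = np.array([yv[a_codes == i].mean() for i in range(na)])
    b_means = np.array([yv[b_codes == j].mean() for j in range(nb)])
    adj = yv - a_means[a_codes] - b_means[b_codes] + grand
    r_adj = stats.rankdata(adj)
    ss_int = _two_way_ss(r_adj, a_codes, b_codes, na, nb)
    res_int = _f_test(ss_int.ss_int, ss_int.df_int, ss_int.mse, ss_int.df_resid,
                      "art-interaction")
    return ArtResult(factor_a=res_a, factor_b=res_b, interaction=res_int,
                     factor_names=factor_names)


def qpcr_relative_scale(
    expression: pd.DataFrame | Mapping[str, Sequence[float]],
    reference: Sequence[float],
) -> pd.DataFrame:
    """Normalise qRT-PCR values to a reference gene and min-scale per gene.

    Each individual's value is divided by that individual's reference-gene
    value; each gene's normalised values (within one line) are then divided
    by their minimum, so the lowest value is exactly 1.
    """
    df = pd.DataFrame(expression, copy=True).astype(float)
    if isinstance(expression, Mapping):
        df = df.T  # mapping gene -> values gives genes as rows
    ref = np.asarray(reference, dtype=float)
    if ref.size != df.shape[1]:
        raise ValueError(
            f"reference length {ref.size} != number of individuals {df.shape[1]}"
        )
    if ref.size == 0:
        raise ValueError("need at least one individual")
    if ref.min() <= 0:
        raise ValueError("reference-gene values must be positive")
    if df.size and df.to_numpy().min() <= 0:
        raise ValueError("expression values must be positive for min-scaling")
    norm = df.div(ref, axis=1)
    return norm.div(norm.min(axis=1), axis=0)


def frequency_distribution(
    values: Sequence[float], bin_width: float, origin: float = 0.0
) -> tuple[dict[float, int], float | None]:
    """Histogram on half-open bins [origin + i*w, origin + (i+1)*w) plus median.

    Returns counts keyed by bin left edge (non-empty bins only); the median
    follows the midpoint rule for even n.  Empty input gives ({}, None).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {}, None
    idx = np.floor((v - origin) / bin_width).astype(int)
    counts: dict[float, int] = {}
    for i in sorted(np.unique(idx)):
        counts[float(origin + i * bin_width)] = int(np.sum(idx == i))
    return counts, float(np.median(v))
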