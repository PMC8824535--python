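"""qPCR expression normalization and cohort statistics.

Raw cycle-threshold (CT) triplicates are normalized against an exogenous
spike-in (cel-miR-39 style): ``delta_ct = mean(ct) - mean(spike_ct)`` and
relative expression ``2^-delta_ct``, log2-transformed for analysis.  The
statistics layer provides the nonparametric tests used on small endurance
cohorts — Wilcoxon signed-rank (paired pre/post), Mann-Whitney (subgroup
splits at clinical cutoffs), Spearman correlation — with *exact* null
distributions in the small-n regime:

* signed-rank: exact null by enumeration of all 2^n sign patterns for
  n <= 20 (computed by convolution over the doubled mid-ranks, which is the
  same distribution), normal approximation with tie correction above;
* Mann-Whitney: exact over all C(n_a+n_b, n_a) group labelings for
  n_a + n_b <= 16, tie-corrected normal approximation otherwise;
* Spearman: rho is the Pearson correlation of mid-ranks; exact p by full
  permutation enumeration for n <= 8, t approximation otherwise.

Two-sided p-values are twice the smaller tail probability, capped at 1.
Zero paired differences are dropped (classical Wilcoxon convention, the
default of mainstream statistics packages); ties get mid-ranks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CtMeasurement",
    "ExpressionValue",
    "StatResult",
    "relative_expression",
    "expressions_from_ct",
    "paired_test",
    "unpaired_test",
    "spearman_correlation",
    "dichotomize_and_compare",
    "summarize_cohort",
    "choose_location_test",
    "read_ct_table",
    "read_cohort_table",
]

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass
class CtMeasurement:
    """CT triplicates for one (subject, miRNA, timepoint), plus the spike-in
    normalizer triplicates from the same reaction plate.  Missing replicates
    are NaN; a CT channel is usable with >= 1 non-missing replicate."""

    subject_id: str
    mirna: str
    timepoint: str  # "pre" | "post"
    ct_replicates: list[float]
    spike_replicates: list[float]

    def __post_init__(self) -> None:
        if self.timepoint not in {"pre", "post"}:
            raise ValueError(f"timepoint must be pre/post, got {self.timepoint!r}")
        for v in [*self.ct_replicates, *self.spike_replicates]:
            if not math.isnan(v) and not 0 < v < 45:
                raise ValueError(f"CT value {v} outside (0, 45)")


@dataclass
class ExpressionValue:
    subject_id: str
    mirna: str
    timepoint: str
    delta_ct: float
    rel_expr: float  # 2^-delta_ct
    log_expr: float  # log2(rel_expr) == -delta_ct
    detectable: bool


@dataclass
class StatResult:
    test_name: str
    n: int
    statistic: float
    p_value: float
    direction: str = "none"  # increase | decrease | none
    group_sizes: tuple[int, int] | None = None


def relative_expression(m: CtMeasurement) -> ExpressionValue:
    """Spike-in normalized expression 2^-(mean CT - mean spike CT).

    A sample with no usable miRNA replicate is returned non-detectable with
    all numeric fields NaN; a sample with no usable spike replicate is an
    error (the normalizer is required to interpret anything)."""
    spike = np.asarray(m.spike_replicates, dtype=float)
    spike = spike[~np.isnan(spike)]
    if spike.size == 0:
        raise ValueError(f"normalizer missing for {m.subject_id}/{m.mirna}/{m.timepoint}")
    ct = np.asarray(m.ct_replicates, dtype=float)
    ct = ct[~np.isnan(ct)]
    if ct.size == 0:
        return ExpressionValue(
            m.subject_id, m.mirna, m.timepoint,
            float("nan"), float("nan"), float("nan"), detectable=False,
        )
    delta = float(ct.mean() - spike.mean())
    return ExpressionValue(
        m.subject_id, m.mirna, m.timepoint,
        delta, 2.0 ** (-delta), -delta, detectable=True,
    )


def expressions_from_ct(measurements: list[CtMeasurement]) -> pd.DataFrame:
    """Tidy expression table (one row per subject x miRNA x timepoint)."""
    rows = [relative_expression(m).__dict__ for m in measurements]
    return pd.DataFrame(
        rows,
        columns=["subject_id", "mirna", "timepoint", "delta_ct",
                 "rel_expr", "log_expr", "detectable"],
    )


# ---------------------------------------------------------------------------
# Exact nonparametric tests


def _two_sided(p_low: float, p_high: float) -> float:
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _signed_rank_null(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ over all 2^n sign patterns."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    return dist


def paired_test(pre, post, exact_max_n: int = 20) -> StatResult:
    """Two-sided Wilcoxon signed-rank test of post vs pre.

    Pairs with a missing side are dropped, then zero differences are
    dropped.  Exact null for n <= ``exact_max_n`` non-zero differences,
    tie-corrected normal approximation above."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    if ok.sum() < 2:
        raise ValueError("need >= 2 usable pairs")
    d = (post - pre)[ok]
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; no evidence, p=1")
        return StatResult("wilcoxon_signed_rank", 0, 0.0, 1.0, "none")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    direction = "increase" if w_plus > w_minus else ("decrease" if w_plus < w_minus else "none")
    if n <= exact_max_n:
        r2 = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_null(r2)
        w2 = int(round(2 * w_plus))
        cdf = dist.cumsum() / dist.sum()
        p_low = cdf[w2]
        p_high = 1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0)
        p = _two_sided(p_low, p_high)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        if var == 0:
            p = 1.0
        else:
            z = (w_plus - mean) / math.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
    return StatResult("wilcoxon_signed_rank", n, w_plus, p, direction)


def unpaired_test(a, b, exact_max_n: int = 16) -> StatResult:
    """Two-sided Mann-Whitney U test of group a vs group b.

    Exact null over all group labelings for n_a + n_b <= ``exact_max_n``,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float)
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mean_u = na * nb / 2.0
    direction = "increase" if u > mean_u else ("decrease" if u < mean_u else "none")
    n = na + nb
    if np.all(combined == combined[0]):
        logger.warning("all values identical; Mann-Whitney degenerate, p=1")
        return StatResult("mann_whitney", n, u, 1.0, "none", (na, nb))
    if n <= exact_max_n:
        base = na * (na + 1) / 2.0
        us = np.fromiter(
            (sum(c) - base for c in itertools.combinations(ranks, na)),
            dtype=float,
        )
        p_low = float(np.mean(us <= u + 1e-9))
        p_high = float(np.mean(us >= u - 1e-9))
        p = _two_sided(p_low, p_high)
    else:
        _, counts = np.unique(combined, return_counts=True)
        tie = (counts**3 - counts).sum() / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie)
        if var == 0:
            p = 1.0
        else:
            z = (u - mean_u) / math.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
    return StatResult("mann_whitney", n, u, p, direction, (na, nb))


def spearman_correlation(x, y, exact_max_n: int = 8) -> StatResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Exact two-sided p by enumerating all n! rank permutations for
    n <= ``exact_max_n``, t approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    direction = "increase" if rho > 0 else ("decrease" if rho < 0 else "none")
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        denom = math.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.dot(rxc, perm)) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return StatResult("spearman", n, rho, min(p, 1.0), direction)


def choose_location_test(x, y=None, alpha: float = ALPHA) -> str:
    """Shapiro-Wilk normality gate: 'parametric' when every sample passes
    at ``alpha``, else 'nonparametric'.  The miRNA-expression pipeline does
    not consult this gate — it always uses the nonparametric tests."""
    for sample in (x,) if y is None else (x, y):
        s = np.asarray(sample, dtype=float)
        s = s[~np.isnan(s)]
        if s.size < 3 or stats.shapiro(s).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# Cohort-level analyses


def dichotomize_and_compare(
    df: pd.DataFrame, variable: str, threshold: float, value_col: str = "log_expr"
) -> StatResult:
    """Split rows into low (variable <= threshold, inclusive) and high
    groups and Mann-Whitney-compare ``value_col`` between them."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sub = df[[variable, value_col]].dropna()
    low = sub.loc[sub[variable] <= threshold, value_col].to_numpy()
    high = sub.loc[sub[variable] > threshold, value_col].to_numpy()
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"degenerate split: {low.size} low vs {high.size} high at "
            f"{variable} <= {threshold}"
        )
    res = unpaired_test(low, high)
    return StatResult(
        f"mann_whitney[{variable}<= {threshold:g}]".replace("<= ", "<="),
        res.n, res.statistic, res.p_value, res.direction, res.group_sizes,
    )


def _median_iqr(v: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def summarize_cohort(
    cohort: pd.DataFrame,
    expressions: pd.DataFrame,
    biomarkers: list[str] | None = None,
) -> pd.DataFrame:
    """Median (IQR) pre/post and paired-test p per biomarker and per miRNA
    log-expression.

    ``cohort`` is long format (subject_id, timepoint, biomarker columns);
    ``expressions`` as produced by :func:`expressions_from_ct`.  With a
    single subject, medians equal the values and tests are skipped."""
    if cohort["subject_id"].nunique() < 1:
        raise ValueError("empty cohort")
    single = cohort["subject_id"].nunique() == 1
    if single:
        logger.warning("single-subject cohort; paired tests skipped")
    if biomarkers is None:
        biomarkers = [
            c for c in cohort.select_dtypes("number").columns
            if cohort.groupby("subject_id")[c].nunique(dropna=True).max() > 1
        ]

    rows = []
    wide = cohort.pivot_table(
        index="subject_id", columns="timepoint", values=biomarkers, aggfunc="first"
    )
    for var in biomarkers:
        pre = wide[(var, "pre")].to_numpy(dtype=float)
        post = wide[(var, "post")].to_numpy(dtype=float)
        ok = ~(np.isnan(pre) | np.isnan(post))
        row = {"variable": var, "kind": "biomarker", "n": int(ok.sum())}
        if ok.any():
            row["median_pre"], row["q1_pre"], row["q3_pre"] = _median_iqr(pre[ok])
            row["median_post"], row["q1_post"], row["q3_post"] = _median_iqr(post[ok])
        row["p_value"] = (
            float("nan") if single or ok.sum() < 2
            else paired_test(pre[ok], post[ok]).p_value
        )
        rows.append(row)

    for mirna, grp in expressions.groupby("mirna", sort=True):
        det = grp[grp["detectable"]]
        if det.empty:
            logger.warning("miRNA %s not detectable in any sample; excluded", mirna)
            continue
        w = det.pivot_table(index="subject_id", columns="timepoint",
                            values="log_expr", aggfunc="first")
        pre = w["pre"].to_numpy(dtype=float) if "pre" in w else np.array([])
        post = w["post"].to_numpy(dtype=float) if "post" in w else np.array([])
        ok = (
            ~(np.isnan(pre) | np.isnan(post))
            if pre.size == post.size and pre.size
            else np.zeros(0, dtype=bool)
        )
        row = {"variable": mirna, "kind": "mirna_log2_expression", "n": int(ok.sum())}
        if ok.any():
            row["median_pre"], row["q1_pre"], row["q3_pre"] = _median_iqr(pre[ok])
            row["median_post"], row["q1_post"], row["q3_post"] = _median_iqr(post[ok])
        row["p_value"] = (
            float("nan") if single or ok.sum() < 2
            else paired_test(pre[ok], post[ok]).p_value
        )
        rows.append(row)

    cols = ["variable", "kind", "n", "median_pre", "q1_pre", "q3_pre",
            "median_post", "q1_post", "q3_post", "p_value"]
    return pd.DataFrame(rows).reindex(columns=cols)


# ---------------------------------------------------------------------------
# I/O


def read_ct_table(path) -> list[CtMeasurement]:
    """CT TSV: subject_id, mirna, timepoint, ct_1..ct_3, spike_1..spike_3."""
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "mirna", "timepoint"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    sp_cols = [c for c in df.columns if c.startswith("spike_")]
    return [
        CtMeasurement(
            str(r["subject_id"]), str(r["mirna"]), str(r["timepoint"]),
            [float(r[c]) for c in ct_cols],
            [float(r[c]) for c in sp_cols],
        )
        for _, r in df.iterrows()
    ]


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "timepoint"} <= set(df.columns):
        raise ValueError(f"{path}: needs subject_id and timepoint columns")
    return df
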