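"""Site-difference testing and rank correlation.

Three pieces:

* one-way ANOVA (classical between/within sum-of-squares decomposition),
* Duncan's multiple range test with a compact letter display, the post-hoc
  procedure behind the superscript letters in soil-survey tables, and
* pairwise Spearman correlation with two-tailed significance, the basis of
  the co-occurrence network stage.

Duncan's test compares the ordered group means: a pair spanning ``p``
consecutive ranked means differs at level alpha when

    |mean_i - mean_j| > q(1 - (1-alpha)**(p-1), p, df_error) * sqrt(MSE / n_h)

with ``q`` the studentized-range quantile at Duncan's protection level and
``n_h`` the harmonic mean group size (the surveys this serves routinely
have unequal n).  A pair inside a span already found non-significant is
declared non-significant without testing, which gives the letter display
its contiguous structure.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "DuncanResult",
    "duncan_mrt",
    "letters_from_significance",
    "spearman_matrix",
    "spearman_pair",
    "significance_stars",
]


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: pd.Series
    group_sizes: pd.Series
    ms_within: float
    ms_between: float


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA of ``values`` grouped by ``groups``.

    Degenerate inputs follow fixed conventions: zero between-group and zero
    within-group variance gives F = 0 (p = 1); positive between-group with
    zero within-group variance gives F = inf (p = 0).
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups), index=values.index)
    if values.isna().any():
        raise ValidationError("NaN values in ANOVA input")
    sizes = groups.value_counts()
    if (sizes < 1).any() or len(sizes) < 2:
        raise ValidationError("ANOVA needs >=2 groups with >=1 observation each")
    n, k = len(values), len(sizes)
    df_b, df_w = k - 1, n - k
    if df_w < 1:
        raise ValidationError("ANOVA needs at least 1 residual degree of freedom")
    grand = values.mean()
    means = values.groupby(groups).mean()
    ss_b = float((sizes * (means - grand) ** 2).sum())
    ss_w = float(((values - means.loc[groups].values) ** 2).sum())
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    if ms_w == 0.0:
        f = 0.0 if ms_b == 0.0 else math.inf
        p = 1.0 if ms_b == 0.0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=f,
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means=means,
        group_sizes=sizes.loc[means.index],
        ms_within=ms_w,
        ms_between=ms_b,
    )


@dataclass
class DuncanResult:
    """Pairwise significance matrix plus the letter display.

    ``significant`` is a symmetric boolean DataFrame over group labels;
    ``letters`` maps each group to its letter string, 'a' on the largest
    mean.
    """

    significant: pd.DataFrame
    letters: dict
    group_means: pd.Series
    alpha: float


@functools.lru_cache(maxsize=4096)
def _studentized_range_quantile(prob: float, p_span: int, df: int) -> float:
    # scipy's numerical inversion is ~0.1 s per call; quantiles depend only
    # on (prob, span, df) so they are cached across groups and datasets
    return float(sps.studentized_range.ppf(prob, p_span, df))


def _duncan_critical_range(p_span: int, df: int, mse: float, n_h: float, alpha: float) -> float:
    # Duncan's protection level: test each p-mean range at 1-(1-alpha)^(p-1)
    q = _studentized_range_quantile((1.0 - alpha) ** (p_span - 1), p_span, df)
    return float(q * math.sqrt(mse / n_h))


def duncan_mrt(values, groups, alpha: float = 0.05, anova: AnovaResult | None = None) -> DuncanResult:
    """Duncan's multiple range test over all group pairs.

    Unequal group sizes are handled with the harmonic-mean n.  Returns the
    pairwise significance matrix and a compact letter display in which two
    groups share a letter iff they are not significantly different.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if anova is None:
        anova = one_way_anova(values, groups)
    means = anova.group_means.sort_values(ascending=True)
    labels = list(means.index)
    k = len(labels)
    n_h = k / float((1.0 / anova.group_sizes).sum())
    df, mse = anova.df_within, anova.ms_within

    sig = pd.DataFrame(False, index=labels, columns=labels)
    nonsig_spans: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        r_p = _duncan_critical_range(span, df, mse, n_h, alpha)
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            covered = any(l <= lo and hi <= h for l, h in nonsig_spans)
            diff = float(means.iloc[hi] - means.iloc[lo])
            significant = (not covered) and diff > r_p
            if not significant and not covered:
                nonsig_spans.append((lo, hi))
            a, b = labels[lo], labels[hi]
            sig.loc[a, b] = sig.loc[b, a] = significant
    letters = letters_from_significance(sig, anova.group_means)
    return DuncanResult(
        significant=sig, letters=letters, group_means=anova.group_means, alpha=alpha
    )


def letters_from_significance(significant: pd.DataFrame, means: pd.Series) -> dict:
    """Compact letter display from a pairwise significance matrix.

    Insert-and-absorb: start with one letter covering every group; each
    significant pair splits any letter containing both; letters that become
    subsets of another are absorbed.  Letters run 'a', 'b', ... with 'a'
    attached to the largest mean.
    """
    order = list(means.sort_values(ascending=False).index)  # descending mean
    cols: list[set] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if not significant.loc[a, b]:
            continue
        new_cols = []
        for col in cols:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop empties, proper subsets and duplicates
        cols = []
        for c in new_cols:
            if not c or any(c < other for other in new_cols) or c in cols:
                continue
            cols.append(c)
    pos = {g: i for i, g in enumerate(order)}
    cols.sort(key=lambda c: min(pos[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for i, col in enumerate(cols):
        for g in sorted(col, key=pos.get):
            out[g] += alphabet[i]
    return out


def significance_stars(p: float) -> str:
    """Display stars at the conventional 0.05 / 0.01 / 0.001 levels."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-tailed p by full enumeration of the n! orderings of y."""
    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    rx_c = rx - rx.mean()
    denom = rx.std() * ry.std() * len(rx)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = float(np.dot(rx_c, np.asarray(perm) - ry.mean())) / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_pair(x, y, *, method: str = "t") -> tuple[float, float, int]:
    """Spearman rho and two-tailed p for one pair of vectors.

    rho is the product-moment correlation of average ranks (ties get the
    mean of the tied ranks).  ``method="t"`` uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho**2))``; a perfect |rho| = 1 (where the
    t statistic degenerates) is assigned the permutation bound ``2/n!``.
    ``method="exact"`` enumerates all orderings (n <= 9).

    A constant variable has undefined rho, reported as NaN (not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_pair needs two equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValidationError("need >=4 paired observations")
    rho = _rank_rho(x, y)
    if math.isnan(rho):
        return math.nan, math.nan, n
    if method == "exact":
        if n > 9:
            raise ValidationError("exact permutation p limited to n <= 9")
        return rho, _exact_spearman_p(x, y, rho), n
    if method != "t":
        raise ValidationError(f"unknown p-value method {method!r}")
    if abs(rho) >= 1.0 - 1e-12:
        return rho, min(1.0, 2.0 / math.factorial(n)), n
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return rho, min(1.0, p), n


def spearman_matrix(
    table: pd.DataFrame,
    *,
    method: str = "t",
    adjust: str | None = None,
) -> pd.DataFrame:
    """All pairwise Spearman correlations of a samples x variables table.

    Returns a long-format frame (var1, var2, rho, p, n, stars) over the
    upper triangle.  ``adjust="bh"`` applies Benjamini-Hochberg to the
    p-values; the default applies none, matching common practice in
    soil-survey correlation tables.
    """
    num = table.select_dtypes("number")
    n = len(num)
    if n < 4:
        raise ValidationError("need >=4 samples for correlation")
    rows = []
    for a, b in itertools.combinations(num.columns, 2):
        rho, p, _ = spearman_pair(num[a].values, num[b].values, method=method)
        rows.append({"var1": a, "var2": b, "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        mask = out["p"].notna()
        p = out.loc[mask, "p"].values
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out.loc[mask, "p"] = np.minimum(adj, 1.0)
    elif adjust not in (None, "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    out["stars"] = out["p"].map(lambda v: significance_stars(v) if pd.notna(v) else "")
    return out
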