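"""Inter-rater agreement statistics for multi-reader scan studies.

Implements, from their definitions, the statistics used to compare two
reading methods across a fixed panel of raters:

* Cohen's kappa (unweighted and linearly weighted) with the
  Fleiss–Cohen–Everitt large-sample standard error,
* Fleiss' fixed-marginal multirater kappa with the large-sample overall
  standard error ``SE = sqrt(2 / (N m (m-1))) *
  sqrt(P_e - (2m-3) P_e^2 + 2 (m-2) sum_j p_j^3) / (1 - P_e)``,
* the two-way absolute-agreement single-measures intraclass correlation
  ICC(A,1) with its F-distribution confidence bounds,
* concordance-count summaries of binary calls across five raters,
* Pearson chi-squared (no continuity correction) and the paired t test.

Kappa-type point estimates and interval construction are deliberately
hand-built here — they are the analysis this package exists to
reproduce — and are cross-checked against independent implementations in
the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RATINGS_COLUMNS = ["subject", "rater", "method", "score5", "binary", "confidence5"]

#: Table-3-style row order: number of positive calls among five raters.
CONCORDANCE_ORDER = (5, 4, 3, 2, 1, 0)
CONCORDANCE_LABELS = (
    "5/5 positive", "4/5 positive", "3/5 positive",
    "3/5 negative", "4/5 negative", "5/5 negative",
)


class DegenerateAgreementError(ValueError):
    """Chance agreement equals 1; kappa is undefined."""


@dataclass
class AgreementEstimate:
    statistic: str
    value: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int | None = None
    m: int | None = None
    k: int | None = None

    def rounded(self, digits: int = 2) -> tuple[float, float | None, float | None]:
        rnd = lambda v: None if v is None else round(v, digits)
        return round(self.value, digits), rnd(self.ci_low), rnd(self.ci_high)


@dataclass
class ConcordanceCounts:
    """Subject counts by number of positive calls among 5 raters, in
    Table-3 order (5, 4, 3 positive; 3, 4, 5 negative)."""

    counts: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != 6 or any(c < 0 for c in self.counts):
            raise ValueError("need six nonnegative counts")
        self.counts = tuple(int(c) for c in self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def unanimous(self) -> int:
        return self.counts[0] + self.counts[5]

    def to_category_counts(self, m: int = 5) -> np.ndarray:
        """Expand to per-subject [negative, positive] rating counts."""
        rows = []
        for npos, cnt in zip(CONCORDANCE_ORDER, self.counts):
            rows.extend([[m - npos, npos]] * cnt)
        return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# ratings table helpers


def load_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject", "rater", "method"])
    if dup.any():
        raise ValueError("duplicate (subject, rater, method) records")
    return df


def ratings_matrix(df: pd.DataFrame, method: str, scale: str = "binary") -> pd.DataFrame:
    """Pivot long-format ratings to a subjects x raters matrix.

    ``scale``: ``binary`` codes {negative=1, positive=2}; ``score5`` and
    ``confidence5`` pass the 1–5 ordinals through. Missing cells are NaN.
    """
    sub = df[df["method"] == method]
    if scale == "binary":
        values = sub.assign(_v=sub["binary"].astype(float) + 1)
    elif scale in ("score5", "confidence5"):
        values = sub.assign(_v=sub[scale].astype(float))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return values.pivot(index="subject", columns="rater", values="_v")


# ---------------------------------------------------------------------------
# kappas


def _linear_weights(k: int) -> np.ndarray:
    i = np.arange(k)
    if k == 1:
        return np.ones((1, 1))
    return 1.0 - np.abs(i[:, None] - i[None, :]) / (k - 1)


def cohen_kappa(
    x, y, k: int | None = None, weighting: str = "none"
) -> AgreementEstimate:
    """Two-rater chance-corrected agreement on categories 1..k.

    Linear weights ``w_ij = 1 - |i-j|/(k-1)`` credit near-miss ordinal
    disagreements; ``weighting='none'`` uses the identity weight matrix.
    Pairs with a missing entry in either vector are dropped. The SE is
    the Fleiss–Cohen–Everitt large-sample form (not assuming kappa = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 complete rating pairs")
    if k is None:
        k = int(max(x.max(), y.max()))
    if weighting not in ("none", "linear"):
        raise ValueError(f"unknown weighting {weighting!r}")

    n = x.size
    table = np.zeros((k, k))
    for xi, yi in zip(x.astype(int), y.astype(int)):
        table[xi - 1, yi - 1] += 1
    p = table / n
    w = _linear_weights(k) if weighting == "linear" else np.eye(k)
    pi = p.sum(axis=1)  # rater-x marginals
    pj = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if abs(1 - pe) < 1e-12:
        raise DegenerateAgreementError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)

    wbar_row = w @ pj          # E_j[w_ij] over column marginal, per row i
    wbar_col = pi @ w          # per column j
    term = (
        p * (w * (1 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)) ** 2
    ).sum()
    var = (term - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    return AgreementEstimate(
        f"cohen_kappa_{weighting}", kappa, se,
        kappa - 1.96 * se, kappa + 1.96 * se, n=n, m=2, k=k,
    )


def fleiss_kappa_fixed(category_counts, m: int | None = None) -> AgreementEstimate:
    """Fixed-marginal multirater kappa from per-subject category counts.

    ``category_counts`` is an (N, k) array: row i gives how many of the m
    raters placed subject i in each category. Every subject must have
    exactly m ratings (fixed panel design). Per-subject agreement
    ``P_i = sum_j n_ij (n_ij - 1) / (m (m - 1))`` averages to the
    observed agreement; chance agreement comes from the pooled category
    proportions. The 95% CI is kappa +/- 1.96 SE with the large-sample
    overall-kappa SE.
    """
    n = np.asarray(category_counts, dtype=float)
    if n.ndim != 2 or n.shape[0] < 2:
        raise ValueError("need an (N >= 2) x k table of category counts")
    row_sums = n.sum(axis=1)
    if m is None:
        m = int(row_sums[0])
    if m < 2:
        raise ValueError("need at least 2 raters")
    if not np.all(row_sums == m):
        raise ValueError("every subject needs exactly m ratings (fixed panel)")
    N, _ = n.shape
    P_i = (n * (n - 1)).sum(axis=1) / (m * (m - 1))
    P_bar = float(P_i.mean())
    p_j = n.sum(axis=0) / (N * m)
    P_e = float((p_j**2).sum())
    if abs(1 - P_e) < 1e-12:
        raise DegenerateAgreementError("chance agreement is 1; kappa undefined")
    kappa = (P_bar - P_e) / (1 - P_e)
    se = (
        math.sqrt(2.0 / (N * m * (m - 1)))
        * math.sqrt(max(P_e - (2 * m - 3) * P_e**2 + 2 * (m - 2) * float((p_j**3).sum()), 0.0))
        / (1 - P_e)
    )
    return AgreementEstimate(
        "fleiss_kappa_fixed", kappa, se,
        kappa - 1.96 * se, kappa + 1.96 * se, n=N, m=m, k=n.shape[1],
    )


def matrix_to_category_counts(matrix: pd.DataFrame, k: int) -> np.ndarray:
    """Complete-case subjects x categories count table from a rating matrix."""
    complete = matrix.dropna(axis=0)
    values = complete.to_numpy(dtype=int)
    counts = np.zeros((values.shape[0], k), dtype=float)
    for j in range(1, k + 1):
        counts[:, j - 1] = (values == j).sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# ICC


def icc_single_absolute(matrix, alpha: float = 0.05) -> AgreementEstimate:
    """ICC(A,1): two-way absolute-agreement single-measures reliability.

    Rows are subjects, columns raters; complete cases only. Mean squares
    from the two-way layout give
    ``ICC = (MSR - MSE) / (MSR + (m-1) MSE + (m/n)(MSC - MSE))``;
    the confidence bounds use the McGraw & Wong F-distribution
    construction with Satterthwaite degrees of freedom. Sensitive to
    systematic rater offsets (unlike consistency ICCs), matching
    "absolute agreement of the ratings for one typical single rater".
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.dropna(axis=0).to_numpy(dtype=float)
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(data)):
        raise ValueError("ICC requires complete cases")
    n, m = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = m * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (m - 1)
    mse = ss_err / ((n - 1) * (m - 1))
    denom = msr + (m - 1) * mse + (m / n) * (msc - mse)
    if abs(denom) < 1e-15:
        raise ValueError("degenerate input: zero variance everywhere")
    icc = (msr - mse) / denom

    if mse <= 0:
        # perfect within-subject agreement: interval collapses
        return AgreementEstimate("icc_single_absolute", icc, 0.0, icc, icc, n=n, m=m)
    fj = msc / mse
    vn = (m - 1) * (n - 1) * (m * icc * fj + n * (1 + (m - 1) * icc) - m * icc) ** 2
    vd = (n - 1) * m**2 * icc**2 * fj**2 + (n * (1 + (m - 1) * icc) - m * icc) ** 2
    v = vn / vd
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_upper * mse) / (
        f_upper * (m * msc + (m * n - m - n) * mse) + n * msr
    )
    hi = n * (f_lower * msr - mse) / (
        m * msc + (m * n - m - n) * mse + n * f_lower * msr
    )
    return AgreementEstimate("icc_single_absolute", icc, None, lo, hi, n=n, m=m)


# ---------------------------------------------------------------------------
# concordance, chi-squared, paired t


def concordance_counts(matrix) -> ConcordanceCounts:
    """Bin subjects by number of positive calls among exactly 5 raters.

    Accepts a binary rating matrix coded {1=negative, 2=positive} (or
    {0, 1}); rows with missing entries are dropped first.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.dropna(axis=0).to_numpy(dtype=float)
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[1] != 5:
        raise ValueError("Table-3-style concordance needs exactly 5 raters")
    values = set(np.unique(data))
    if values <= {1.0, 2.0}:
        npos = (data == 2).sum(axis=1)
    elif values <= {0.0, 1.0}:
        npos = (data == 1).sum(axis=1)
    else:
        raise ValueError(f"not a binary matrix; values {sorted(values)}")
    counts = [int((npos == p).sum()) for p in CONCORDANCE_ORDER]
    return ConcordanceCounts(tuple(counts))


def unanimity_proportion(counts: ConcordanceCounts) -> tuple[float, float]:
    """Fraction (and percent, 1 decimal) of fully concordant subjects."""
    if counts.total == 0:
        raise ValueError("no subjects")
    frac = counts.unanimous / counts.total
    return frac, round(100 * frac, 1)


def chi2_2x2(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("a marginal of the 2x2 table is zero")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return {"chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, 1))}


def paired_t(x, y) -> dict[str, float]:
    """Paired t test on pairwise-complete observations.

    All-zero differences give t = 0, p = 1. Nonzero constant differences
    (zero variance) are reported with ``zero_variance = 1`` and p -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    sd = d.std(ddof=1)
    result = {"df": n - 1, "mean_x": float(x.mean()), "mean_y": float(y.mean()),
              "zero_variance": 0.0}
    if sd == 0:
        if d.mean() == 0:
            result.update(t=0.0, p=1.0)
        else:
            result.update(t=math.copysign(math.inf, d.mean()), p=0.0, zero_variance=1.0)
        return result
    t = float(d.mean() / (sd / math.sqrt(n)))
    result.update(t=t, p=float(2 * stats.t.sf(abs(t), n - 1)))
    return result


def pairwise_summary(
    matrix: pd.DataFrame, weighting: str = "none", k: int | None = None
) -> dict:
    """Cohen kappas for every unordered rater pair, with median and range.

    Each pair uses its pairwise-complete subjects. Mirrors per-pair
    agreement tables for a five-reader panel (10 pairs).
    """
    raters = list(matrix.columns)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    estimates = {}
    for r1, r2 in itertools.combinations(raters, 2):
        estimates[(r1, r2)] = cohen_kappa(
            matrix[r1].to_numpy(), matrix[r2].to_numpy(), k=k, weighting=weighting
        )
    values = np.array([e.value for e in estimates.values()])
    return {
        "pairs": estimates,
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def median_of(values) -> float:
    """Median of a printed kappa column (plain wrapper for symmetry)."""
    return float(np.median(np.asarray(values, dtype=float)))
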