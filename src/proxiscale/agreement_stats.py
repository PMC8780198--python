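"""Agreement and reliability statistics for multi-rater ordinal grading.

From-scratch implementations of the statistics used to compare expert,
non-expert and machine gradings of the same subjects:

- percent agreement (raw fraction of exact matches, not chance-corrected);
- Bland–Altman mean difference with 95% limits of agreement;
- ICC(2, k): intraclass correlation, two-way random-effects model, average
  measures, with F-based confidence interval and p-value (McGraw–Wong
  conventions);
- Krippendorff's alpha via the coincidence-matrix formulation, with
  nominal / ordinal / interval distance metrics and native missing-data
  handling;
- Fleiss' kappa (category-proportion formulation; applied verbatim also to
  two-rater tables);
- confusion matrices against a reference rater.

Rating tables are subjects × raters matrices (ndarray or DataFrame) with
NaN marking missing ratings where supported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .synthetic_cohort import GradeScale

TableLike = Union[np.ndarray, pd.DataFrame]


def _as_matrix(table: TableLike) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def ratings_long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long ratings table (subject_id, rater_id, rating) to wide."""
    return long.pivot_table(
        index="subject_id", columns="rater_id", values="rating", aggfunc="first"
    )


# ---------------------------------------------------------------------------
# percent agreement
# ---------------------------------------------------------------------------


def percent_agreement(a: Sequence[float], b: Sequence[float]) -> float:
    """Fraction of pairwise-complete cases on which two raters agree exactly."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D with equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no comparable (pairwise-complete) ratings")
    return float(np.mean(a[ok] == b[ok]))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and limits of agreement for paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def bland_altman(
    x: Sequence[float], y: Sequence[float], loa_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland–Altman analysis of two measurement series.

    Differences are ``d = x - y``; limits of agreement are
    ``mean(d) ± loa_multiplier * sd(d)`` with the sample (n−1) s.d.
    The per-pair means and differences are returned as plotting payload.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D with equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - loa_multiplier * sd,
        loa_high=mean + loa_multiplier * sd,
        means=(x + y) / 2.0,
        diffs=d,
    )


# ---------------------------------------------------------------------------
# ICC(2, k)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,k) point estimate with 95% CI and p-value."""

    icc: float
    ci_low: float
    ci_high: float
    p_value: float


def icc_2k(table: TableLike, alpha: float = 0.05) -> ICCResult:
    """ICC(2, k): two-way random effects, absolute agreement, average of k raters.

    Decomposes the complete subjects × raters matrix by two-way ANOVA
    (rows = subjects, columns = raters) and returns

        ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    with the F-based confidence interval and p-value for average-measures
    two-way random ICC.  Missing entries raise (perform listwise deletion
    upstream); zero between-subject variance yields ICC 0 with a warning.
    """
    m = _as_matrix(table)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValueError("icc_2k requires a complete matrix (no missing entries)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if np.allclose(np.var(row_means), 0.0):
        warnings.warn("zero between-subject variance: ICC reported as 0", stacklevel=2)
        return ICCResult(0.0, math.nan, math.nan, 1.0)

    icc2k = (msr - mse) / (msr + (msc - mse) / n)
    # single-measures ICC(2,1), needed for the Satterthwaite CI
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc2 * fj + n * (1 + (k - 1) * icc2) - k * icc2) ** 2
        vd = (n - 1) * k**2 * icc2**2 * fj**2 + (n * (1 + (k - 1) * icc2) - k * icc2) ** 2
        v = vn / vd
        f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        l2 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        u2 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        # Spearman–Brown step up from single to average measures
        l2k = l2 * k / (1 + l2 * (k - 1))
        u2k = u2 * k / (1 + u2 * (k - 1))
    else:
        # zero residual variance: the F-based interval degenerates
        l2k = u2k = icc2k

    f_stat = msr / mse if mse > 0 else math.inf
    p = float(f_dist.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return ICCResult(float(icc2k), float(l2k), float(u2k), p)


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------


def _delta_matrix(values: np.ndarray, n_c: np.ndarray, metric: str) -> np.ndarray:
    if metric == "nominal":
        return 1.0 - np.eye(values.size)
    if metric == "interval":
        return (values[:, None] - values[None, :]) ** 2
    if metric == "ordinal":
        # squared sum of coincidence-frequency mass between the two
        # categories, counting the endpoints at half weight
        cum = np.concatenate([[0.0], np.cumsum(n_c)])
        d = np.zeros((values.size, values.size))
        for c in range(values.size):
            for k in range(values.size):
                lo, hi = min(c, k), max(c, k)
                inner = cum[hi + 1] - cum[lo]
                d[c, k] = (inner - (n_c[lo] + n_c[hi]) / 2.0) ** 2
        return d
    raise ValueError("metric must be 'nominal', 'ordinal' or 'interval'")


def krippendorff_alpha(table: TableLike, metric: str = "nominal") -> float:
    """Krippendorff's alpha from the coincidence matrix of a rating table.

    ``table`` is subjects × raters with NaN for missing ratings; subjects
    with fewer than two ratings are dropped.  ``alpha = 1 - D_o / D_e``
    where ``D_o`` is the observed and ``D_e`` the expected mean pairwise
    distance.  Raises if only a single category is observed (``D_e = 0``).
    """
    m = _as_matrix(table)
    if m.ndim != 2:
        raise ValueError("table must be 2-D (subjects x raters)")
    units = [row[~np.isnan(row)] for row in m]
    units = [u for u in units if u.size >= 2]
    if len(units) < 1:
        raise ValueError("need at least one subject with >= 2 ratings")
    values = np.unique(np.concatenate(units))
    v = values.size
    lookup = {val: i for i, val in enumerate(values)}

    # coincidence matrix: each ordered pair within a unit adds 1/(m_u - 1)
    O = np.zeros((v, v))
    for u in units:
        idx = np.array([lookup[x] for x in u])
        w = 1.0 / (u.size - 1)
        for a in range(idx.size):
            for b in range(idx.size):
                if a != b:
                    O[idx[a], idx[b]] += w
    n_c = O.sum(axis=1)
    n_tot = n_c.sum()
    delta = _delta_matrix(values, n_c, metric)
    d_o = float((O * delta).sum())
    expected = np.outer(n_c, n_c) - np.diag(n_c)  # off-diagonal pair counts
    d_e = float((expected * delta).sum()) / (n_tot - 1.0)
    if d_e == 0.0:
        raise ValueError("expected disagreement is zero (single category observed)")
    return float(1.0 - d_o / d_e)


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------


def fleiss_kappa(table: TableLike) -> float:
    """Fleiss' kappa for a complete subjects × raters table.

    Every subject must be rated by the same number (>= 2) of raters.  The
    formula is applied verbatim also when that number is 2 (which differs
    from Cohen's kappa).  Raises if expected agreement equals 1.
    """
    m = _as_matrix(table)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("table must be 2-D with >= 1 subject")
    if np.isnan(m).any():
        raise ValueError("fleiss_kappa requires a complete table")
    n, k = m.shape
    if k < 2:
        raise ValueError("need >= 2 raters")
    values = np.unique(m)
    counts = np.stack([(m == val).sum(axis=1) for val in values], axis=1)
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (k * (k - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n * k)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1 (single category): kappa undefined")
    return float((p_bar - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------


def confusion_matrix(
    reference: Sequence[int], test: Sequence[int], scale: GradeScale
) -> np.ndarray:
    """M×M counts: ``counts[i, j]`` = subjects with test class i, reference j.

    ``trace / total`` equals :func:`percent_agreement` of the two vectors.
    """
    ref = np.asarray(reference)
    tst = np.asarray(test)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("rating vectors must be 1-D with equal length")
    if ref.size == 0:
        raise ValueError("empty input")
    m = scale.n_classes
    out = np.zeros((m, m), dtype=int)
    for r, t in zip(ref, tst):
        out[scale.index(int(t)), scale.index(int(r))] += 1
    return out


# ---------------------------------------------------------------------------
# reliability report container
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityReport:
    """Manual-vs-ML agreement/reliability summary for one experiment.

    ``manual`` and ``ml`` each hold percent agreements, Krippendorff alphas
    and Fleiss kappas per rater subset plus confusion matrices vs the gold
    standard; ``features`` holds per-feature Bland–Altman and ICC results.
    Every entry is tagged by the rater subset that produced it.
    """

    manual: Dict[str, object] = field(default_factory=dict)
    ml: Optional[Dict[str, object]] = None
    features: Dict[str, object] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "schema_version": 1,
            "meta": self.meta,
            "manual": self.manual,
            "ml": self.ml,
            "features": self.features,
        }


def rater_set_statistics(
    wide: pd.DataFrame,
    gs: str,
    others: Sequence[str],
    scale: GradeScale,
    alpha_metric: str = "nominal",
) -> Dict[str, object]:
    """All rating-level statistics for one gold standard + test rater set.

    Computes pairwise percent agreement and confusion matrices of each test
    rater against ``gs``, plus Krippendorff alpha and Fleiss kappa for every
    pair and for the full set — the cell structure of a multi-rater
    reliability table.
    """
    stats: Dict[str, object] = {
        "raters": [gs, *others],
        "percent_agreement": {},
        "alpha": {},
        "fleiss_kappa": {},
        "confusion_vs_gs": {},
    }
    subsets = [[gs, o] for o in others]
    if len(others) > 1:
        subsets.append([gs, *others])
    for sub in subsets:
        key = "-".join(sub)
        sub_table = wide[sub]
        stats["alpha"][key] = krippendorff_alpha(sub_table, metric=alpha_metric)
        stats["fleiss_kappa"][key] = fleiss_kappa(sub_table)
    for o in others:
        key = f"{gs}-{o}"
        stats["percent_agreement"][key] = percent_agreement(wide[gs], wide[o])
        stats["confusion_vs_gs"][o] = confusion_matrix(
            wide[gs].to_numpy(int), wide[o].to_numpy(int), scale
        ).tolist()
    pa = list(stats["percent_agreement"].values())
    stats["mean_percent_agreement"] = float(np.mean(pa)) if pa else math.nan
    return stats
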