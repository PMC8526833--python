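"""Normalization, detection summaries and expression-variability statistics.

Counts are normalized by median-of-ratios size factors (the negative-binomial
differential-expression stage assumes the same convention, so it is adopted
pipeline-wide; "normalized reads" always means counts / s_j).

Inter-individual variability is summarised by a robust coefficient of
variation, CV = MAD / median of normalized expression, computed only for
miRNAs whose median normalized expression is at least 1.  The MAD is the raw
median absolute deviation about the median, with no 1.4826 consistency
constant; a ``mad_kind="mean"`` switch substitutes the mean absolute
deviation about the median for sensitivity analyses.

Intra-individual stability across repeated samples uses Spearman's rank
correlation per subject and an exact paired Wilcoxon signed-rank test per
miRNA (full sign-assignment null distribution up to n = 25 pairs, then a
tie-corrected normal approximation).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import CountMatrix

logger = logging.getLogger("faecomir")

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 9


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios)
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors, rescaled to geometric mean 1.

    Rows with a positive count in every sample anchor the reference
    (geometric-mean) profile.  If no such row exists, the geometric mean of
    each row is taken over its positive entries only and each sample's median
    ratio runs over its positive cells (with a warning) — the usual fallback
    for sparse matrices.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples for size factors")
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any():
        sub = mat[all_positive]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        logger.warning("no row positive in all samples; "
                       "using positive-subset size-factor rule")
        any_positive = (mat > 0).any(axis=1)
        if not any_positive.any():
            raise ValueError("all-zero count matrix")
        sub = mat[any_positive]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
        log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def attach_size_factors(matrix: CountMatrix) -> CountMatrix:
    """Return the matrix with median-of-ratios size factors attached."""
    return CountMatrix(counts=matrix.counts,
                       size_factors=size_factors(matrix.counts))


def _expression(matrix, use_normalized: bool = True) -> pd.DataFrame:
    if isinstance(matrix, CountMatrix):
        if not use_normalized:
            return matrix.counts.astype(float)
        if matrix.size_factors is None:
            matrix = attach_size_factors(matrix)
        return matrix.normalized
    return pd.DataFrame(matrix).astype(float)


# ---------------------------------------------------------------------------
# Detection summaries
# ---------------------------------------------------------------------------

@dataclass
class DetectionSummary:
    prevalence: pd.Series            # per-miRNA fraction of samples detected
    detected_per_sample: pd.Series   # per-sample number of detected miRNAs
    chromosome_fraction: Optional[pd.Series]  # per-chromosome detected fraction

    @property
    def detected_any(self) -> int:
        return int((self.prevalence > 0).sum())

    @property
    def detected_at_least_half(self) -> int:
        return int((self.prevalence >= 0.5).sum())


def detection_summary(counts: pd.DataFrame, min_reads: int = 1,
                      chromosome: Optional[pd.Series] = None
                      ) -> DetectionSummary:
    """Detection prevalence per miRNA and per-sample/per-chromosome tallies.

    A miRNA is detected in a sample when its raw count is >= *min_reads*.
    The chromosome fraction relates detected mature names to all reference
    mature names annotated on that chromosome.
    """
    detected = counts >= min_reads
    prevalence = detected.mean(axis=1)
    per_sample = detected.sum(axis=0)
    chrom_frac = None
    if chromosome is not None:
        chrom = chromosome.reindex(counts.index)
        detected_any = detected.any(axis=1)
        chrom_frac = detected_any.groupby(chrom).mean()
    return DetectionSummary(prevalence=prevalence,
                            detected_per_sample=per_sample,
                            chromosome_fraction=chrom_frac)


# ---------------------------------------------------------------------------
# Robust coefficient of variation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVRecord:
    mirna: str
    median_expr: float
    mad: float
    cv: float


def robust_cv(normalized_row: Sequence[float], mirna: str = "",
              mad_kind: str = "median") -> CVRecord:
    """CV = MAD/median of one miRNA's normalized expression across samples."""
    x = np.asarray(normalized_row, dtype=float)
    med = float(np.median(x))
    if med < 1:
        raise ValueError("robust_cv requires median expression >= 1 "
                         "(filter rows upstream)")
    dev = np.abs(x - med)
    if mad_kind == "median":
        mad = float(np.median(dev))
    elif mad_kind == "mean":
        mad = float(np.mean(dev))
    else:
        raise ValueError("mad_kind must be 'median' or 'mean'")
    return CVRecord(mirna=mirna, median_expr=med, mad=mad, cv=mad / med)


def cv_ranking(normalized: pd.DataFrame, min_median: float = 1.0,
               mad_kind: str = "median") -> pd.DataFrame:
    """Rank miRNAs by expression variability (ascending CV).

    miRNAs whose median normalized expression is below *min_median* are
    excluded; ties in CV are broken by miRNA name for determinism.
    """
    rows = []
    medians = normalized.median(axis=1)
    for name in normalized.index[medians >= min_median]:
        rec = robust_cv(normalized.loc[name].to_numpy(), mirna=name,
                        mad_kind=mad_kind)
        rows.append((rec.mirna, rec.median_expr, rec.mad, rec.cv))
    out = pd.DataFrame(rows, columns=["mirna", "median_expr", "mad", "cv"])
    out = out.sort_values(["cv", "mirna"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = EXACT_SPEARMAN_MAX_N) -> Tuple[float, float]:
    """Spearman correlation with average ranks for ties.

    p-value by the t approximation; for n <= *exact_max_n* the exact
    two-sided permutation p over all n! orderings is used instead.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = xa.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan  # flagged: correlation undefined
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rx_c = rx - rx.mean()
    perms_c = perms - perms.mean(axis=1, keepdims=True)
    num = perms_c @ rx_c
    den = math.sqrt((rx_c ** 2).sum()) * np.sqrt((perms_c ** 2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float],
                         exact_max_n: int = EXACT_WILCOXON_MAX_N) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped.  Up to *exact_max_n* informative pairs the
    p-value comes from the exact null distribution of the positive-rank sum
    over all 2^n sign assignments (tie-aware, computed by convolution, which
    enumerates the same distribution); above that, a tie-corrected normal
    approximation with continuity correction is used.  All differences zero
    gives p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need equal-length 1-D paired vectors")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0  # flagged: no informative pairs
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _wilcoxon_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4
    _uniq, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2 * sps.norm.sf(z)))


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    # integer doubled ranks keep tied (half-integer) ranks exact
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


# ---------------------------------------------------------------------------
# Repeated-sample stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    per_subject: pd.DataFrame  # subject_id, scc, scc_p
    per_mirna: pd.DataFrame    # mirna, wilcoxon_p


def stability_report(matrix_t1, matrix_t2,
                     mirna_subset: Optional[Iterable[str]] = None,
                     use_normalized: bool = True) -> StabilityReport:
    """Intra-individual stability between two sampling time points.

    Per shared subject, the Spearman correlation between the two expression
    profiles; per miRNA of *mirna_subset* (default: all shared miRNAs), a
    paired Wilcoxon signed-rank test across subjects.
    """
    e1 = _expression(matrix_t1, use_normalized)
    e2 = _expression(matrix_t2, use_normalized)
    shared_subjects = [s for s in e1.columns if s in set(e2.columns)]
    if not shared_subjects:
        raise ValueError("no shared subjects between time points")
    shared_mirnas = e1.index.intersection(e2.index)
    e1 = e1.loc[shared_mirnas, shared_subjects]
    e2 = e2.loc[shared_mirnas, shared_subjects]

    subject_rows = []
    for s in shared_subjects:
        rho, p = spearman(e1[s].to_numpy(), e2[s].to_numpy())
        subject_rows.append((s, rho, p))
    per_subject = pd.DataFrame(subject_rows, columns=["subject_id", "scc", "scc_p"])

    subset = list(mirna_subset) if mirna_subset is not None else list(shared_mirnas)
    mirna_rows = []
    for m in subset:
        if m not in e1.index:
            raise ValueError(f"miRNA {m!r} absent from both matrices")
        p = wilcoxon_signed_rank(e1.loc[m].to_numpy(), e2.loc[m].to_numpy())
        mirna_rows.append((m, p))
    per_mirna = pd.DataFrame(mirna_rows, columns=["mirna", "wilcoxon_p"])
    return StabilityReport(per_subject=per_subject, per_mirna=per_mirna)
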