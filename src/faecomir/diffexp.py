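"""Covariate-adjusted negative-binomial Wald differential expression.

Per miRNA, counts are modelled as NB with a log link and a per-sample offset
log(s_j) (median-of-ratios size factor), so that

    y_ij ~ NB(mu_ij, alpha_i),   log mu_ij = log s_j + x_j' beta_i,
    Var(y) = mu + alpha * mu^2.

The design holds an intercept, the two-level contrast indicator (test vs
reference), adjustment covariates (sex and age in the full-cohort model, age
only in sex-stratified runs) and library-pool batch dummies as fixed effects.
The contrast coefficient divided by ln 2 is the log2 fold change; the Wald
statistic W = log2FC / SE is referred to a standard normal for the two-sided
p-value, and p-values are Benjamini-Hochberg adjusted within each contrast.

A miRNA is called differentially expressed when q < 0.05 AND its median
normalized count is at least 10 in at least one of the two contrast groups.

The dispersion alpha_i is a method-of-moments estimate on normalized counts
within design cells (the categorical strata of the design), optionally
shrunk toward a mean-dispersion trend fitted across all miRNAs.  This is a
deliberately simplified stand-in for a full empirical-Bayes dispersion
pipeline: agreement with reference DE tools is sought at the level of
operating characteristics (type-I error, power), not numerics.

Continuous covariates (age, BMI) are additionally analysed by Spearman
correlation of normalized expression, with the +/-0.2 SCC bands classifying
each miRNA as increasing / unaltered / decreasing; band membership and BH
significance are independent axes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .quantify import CountMatrix
from .variability import size_factors as compute_size_factors

logger = logging.getLogger("faecomir")

LN2 = math.log(2.0)
ALPHA_FLOOR = 1e-8
ALPHA_CAP = 10.0
DE_Q_THRESHOLD = 0.05
DE_MIN_GROUP_MEDIAN = 10.0
SCC_BAND = 0.2
MAX_IRLS_ITER = 100


@dataclass
class DesignSpec:
    """One two-level contrast plus its adjustment and batch structure."""

    contrast_variable: str
    reference_level: str
    test_level: str
    adjustment_covariates: List[str] = field(default_factory=list)
    batch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.contrast_variable in self.adjustment_covariates:
            raise ValueError("contrast variable cannot also adjust itself")
        if self.reference_level == self.test_level:
            raise ValueError("contrast levels must differ")


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersion(counts_row: np.ndarray, cells: pd.Series,
                        size_factors: pd.Series,
                        floor: float = ALPHA_FLOOR,
                        cap: float = ALPHA_CAP,
                        warn: bool = True) -> float:
    """Method-of-moments NB dispersion from normalized counts within cells.

    For each design cell with >= 2 samples, alpha is solved from the NB
    moment identity on normalized counts z = y/s (Var z ~ mean(z)/s_bar +
    alpha * mean(z)^2) and the per-cell estimates are combined weighted by
    their degrees of freedom.  Degenerate designs (every cell below 2
    samples) fall back to a pooled single-cell estimate with a warning.
    """
    y = np.asarray(counts_row, dtype=float)
    s = size_factors.to_numpy(dtype=float)
    z = y / s
    labels = pd.Series(cells).to_numpy()

    def _cell_alpha(idx: np.ndarray) -> Optional[Tuple[float, float]]:
        if idx.sum() < 2:
            return None
        zc, sc = z[idx], s[idx]
        m = zc.mean()
        if m <= 0:
            return None
        v = zc.var(ddof=1)
        a = (v - m / sc.mean()) / (m * m)
        return a, float(idx.sum() - 1)

    estimates = []
    degenerate_cells = False
    for lab in pd.unique(labels):
        idx = labels == lab
        if idx.sum() < 2:
            degenerate_cells = True
        res = _cell_alpha(idx)
        if res is not None:
            estimates.append(res)
    if not estimates:
        if degenerate_cells and warn:
            logger.warning("degenerate design cells; pooled dispersion estimate")
        res = _cell_alpha(np.ones_like(y, dtype=bool))
        estimates = [res] if res is not None else [(floor, 1.0)]
    alphas = np.array([a for a, _w in estimates])
    weights = np.array([w for _a, w in estimates])
    alpha = float(np.average(alphas, weights=weights))
    return float(np.clip(alpha, floor, cap))


def dispersion_trend(alphas: np.ndarray, means: np.ndarray,
                     shrink_weight: float = 0.5) -> np.ndarray:
    """Shrink per-miRNA dispersions toward a log-log mean-dispersion trend."""
    ok = (means > 0) & (alphas > ALPHA_FLOOR * 10)
    if ok.sum() < 10:
        return alphas
    lx = np.log(means[ok])
    ly = np.log(alphas[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    out = alphas.copy()
    with np.errstate(divide="ignore"):
        trend = np.exp(intercept + slope * np.log(np.maximum(means, 1e-8)))
    pos = alphas > 0
    out[pos] = np.exp((1 - shrink_weight) * np.log(alphas[pos])
                      + shrink_weight * np.log(np.maximum(trend[pos], ALPHA_FLOOR)))
    return np.clip(out, ALPHA_FLOOR, ALPHA_CAP)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def _design_matrix(cohort: pd.DataFrame, design: DesignSpec) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Subset the cohort to the contrast and build the model matrix.

    Returns (X, contrast indicator, cell labels).  Subjects outside the two
    contrast levels or missing any adjustment/batch covariate are dropped
    from this contrast only.
    """
    var = design.contrast_variable
    if var not in cohort.columns:
        raise ValueError(f"contrast variable {var!r} not in cohort")
    needed = [var] + design.adjustment_covariates
    if design.batch is not None:
        needed.append(design.batch)
    sub = cohort[cohort[var].isin([design.reference_level, design.test_level])]
    sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
    sub = sub[~sub[needed].isin(["missing"]).any(axis=1)]
    for level in (design.reference_level, design.test_level):
        if not (sub[var] == level).any():
            raise ValueError(f"contrast level {level!r} has no subjects")

    indicator = (sub[var] == design.test_level).astype(float)
    cols = {"intercept": np.ones(len(sub)), "contrast": indicator.to_numpy()}
    cell_parts = [sub[var].astype(str)]
    for cov in design.adjustment_covariates:
        series = sub[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols[cov] = (series - series.mean()).to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=cov,
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
            cell_parts.append(series.astype(str))
    if design.batch is not None:
        batches = sub[design.batch].astype(str)
        dummies = pd.get_dummies(batches, prefix="batch", drop_first=True,
                                 dtype=float)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy()
        cell_parts.append(batches)
    X = pd.DataFrame(cols, index=sub.index)
    cells = cell_parts[0].str.cat(cell_parts[1:], sep="|") if len(cell_parts) > 1 \
        else cell_parts[0]
    return X, indicator, cells


# ---------------------------------------------------------------------------
# Per-miRNA NB Wald fit
# ---------------------------------------------------------------------------

def nb_wald_row(y: np.ndarray, X: pd.DataFrame, offset: np.ndarray,
                alpha_hat: float) -> Dict[str, float]:
    """Fit one NB log-link regression at fixed dispersion; Wald on the contrast."""
    flag = ""
    contrast_col = list(X.columns).index("contrast")
    in_test = X["contrast"].to_numpy() > 0
    if y[in_test].sum() == 0 or y[~in_test].sum() == 0:
        flag = "separated"
    family = sm.families.NegativeBinomial(alpha=max(alpha_hat, ALPHA_FLOOR))
    try:
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X.to_numpy(), family=family, offset=offset).fit(
                maxiter=MAX_IRLS_ITER, tol=1e-8,
            )
        if not fit.converged:
            flag = flag or "nonconverged"
        beta = fit.params[contrast_col]
        se_nat = fit.bse[contrast_col]
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return {"log2fc": math.nan, "se": math.nan, "wald": math.nan,
                "p": math.nan, "flag": "fit_error"}
    log2fc = beta / LN2
    se = se_nat / LN2
    if flag == "nonconverged":
        return {"log2fc": log2fc, "se": se, "wald": math.nan,
                "p": math.nan, "flag": flag}
    if se == 0 or not math.isfinite(se):
        return {"log2fc": log2fc, "se": se, "wald": math.nan,
                "p": math.nan, "flag": flag or "degenerate_se"}
    wald = log2fc / se
    p = float(2 * sps.norm.sf(abs(wald)))
    return {"log2fc": log2fc, "se": se, "wald": wald, "p": p, "flag": flag}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing p stays missing."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def run_de(matrix: CountMatrix, cohort: pd.DataFrame, design: DesignSpec,
           shrink_dispersion: bool = True,
           shrink_weight: float = 0.5) -> pd.DataFrame:
    """Differential expression for one contrast over every miRNA.

    Returns a table with log2fc, se, wald, p, q, per-group medians of
    normalized counts, the dispersion estimate and the DE call flag.
    """
    cohort = cohort.set_index(cohort["subject_id"].astype(str), drop=False) \
        if "subject_id" in cohort.columns and not cohort.index.astype(str).equals(
            cohort["subject_id"].astype(str)) else cohort
    shared = [s for s in matrix.sample_ids if s in set(cohort.index.astype(str))]
    if not shared:
        raise ValueError("no overlap between count-matrix samples and cohort")
    sub_cohort = cohort.loc[shared]
    X, indicator, cells = _design_matrix(sub_cohort, design)
    keep = list(X.index.astype(str))
    if matrix.size_factors is None:
        matrix = CountMatrix(matrix.counts,
                             size_factors=compute_size_factors(matrix.counts))
    sf = matrix.size_factors.loc[keep]
    counts = matrix.counts.loc[:, keep]
    normalized = counts / sf
    offset = np.log(sf.to_numpy(dtype=float))

    test_ids = [s for s, t in zip(keep, indicator) if t > 0]
    ref_ids = [s for s in keep if s not in set(test_ids)]

    cell_sizes = cells.value_counts()
    if (cell_sizes < 2).any():
        logger.info("%d design cells with < 2 samples; sparse rows use the "
                    "pooled dispersion estimate", int((cell_sizes < 2).sum()))
    alphas = np.array([
        estimate_dispersion(counts.loc[m].to_numpy(), cells, sf, warn=False)
        for m in counts.index
    ])
    if shrink_dispersion:
        row_means = normalized.mean(axis=1).to_numpy()
        alphas = dispersion_trend(alphas, row_means, shrink_weight)

    rows = []
    Xn = X.copy()
    for i, m in enumerate(counts.index):
        y = counts.loc[m].to_numpy(dtype=float)
        res = nb_wald_row(y, Xn, offset, alphas[i])
        rows.append(res)
    out = pd.DataFrame(rows, index=counts.index)
    out.insert(0, "mirna", counts.index)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["median_ref"] = normalized[ref_ids].median(axis=1)
    out["median_test"] = normalized[test_ids].median(axis=1)
    out["alpha_hat"] = alphas
    out = call_demirnas(out)
    out.attrs["design"] = design
    out.attrs["n_ref"] = len(ref_ids)
    out.attrs["n_test"] = len(test_ids)
    return out


def call_demirnas(results: pd.DataFrame,
                  q_threshold: float = DE_Q_THRESHOLD,
                  min_group_median: float = DE_MIN_GROUP_MEDIAN) -> pd.DataFrame:
    """Apply the dual DE criterion: q < 0.05 and >= 10 median normalized
    reads in at least one contrast group; direction is up/down in the test
    level."""
    out = results.copy()
    max_median = out[["median_ref", "median_test"]].max(axis=1)
    out["is_de"] = (out["q"] < q_threshold) & (max_median >= min_group_median)
    out["is_de"] = out["is_de"].fillna(False)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.loc[~out["is_de"], "direction"] = ""
    return out


# ---------------------------------------------------------------------------
# Continuous-covariate Spearman analysis
# ---------------------------------------------------------------------------

def continuous_scc(matrix: CountMatrix, covariate: pd.Series,
                   min_median: float = DE_MIN_GROUP_MEDIAN,
                   band: float = SCC_BAND) -> pd.DataFrame:
    """Spearman correlation of each abundant miRNA with a continuous covariate.

    Only miRNAs with median normalized reads >= *min_median* are tested;
    missing covariate values are dropped pairwise; q is BH across the tested
    miRNAs; categories at the +/-band thresholds (strict inequalities).
    """
    if matrix.size_factors is None:
        matrix = CountMatrix(matrix.counts,
                             size_factors=compute_size_factors(matrix.counts))
    normalized = matrix.normalized
    cov = covariate.reindex(normalized.columns).astype(float)
    complete = cov.notna()
    if complete.sum() < 4:
        raise ValueError("fewer than 4 subjects with covariate values")
    normalized = normalized.loc[:, complete]
    cov = cov[complete]
    medians = normalized.median(axis=1)
    tested = normalized.loc[medians >= min_median]

    n = tested.shape[1]
    cov_rank = sps.rankdata(cov.to_numpy())
    cov_c = cov_rank - cov_rank.mean()
    cov_norm = math.sqrt((cov_c ** 2).sum())
    rows = []
    for m in tested.index:
        expr = tested.loc[m].to_numpy()
        r = sps.rankdata(expr)
        rc = r - r.mean()
        denom = math.sqrt((rc ** 2).sum()) * cov_norm
        if denom == 0:
            rows.append((m, math.nan, math.nan, "skipped"))
            continue
        rho = float((rc @ cov_c) / denom)
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
        rows.append((m, rho, p, ""))
    out = pd.DataFrame(rows, columns=["mirna", "scc", "p", "flag"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["category"] = "unaltered"
    out.loc[out["scc"] > band, "category"] = "increasing"
    out.loc[out["scc"] < -band, "category"] = "decreasing"
    out.loc[out["scc"].isna(), "category"] = ""
    return out


# ---------------------------------------------------------------------------
# Heatmap transform
# ---------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: List[str]
    col_order: List[str]
    degenerate_rows: List[str]


def heatmap_matrix(matrix: CountMatrix, mirnas: Sequence[str],
                   method: str = "complete",
                   metric: str = "euclidean") -> HeatmapMatrix:
    """Per-miRNA z-scores of log10 normalized counts, hierarchically clustered.

    Rows are z-scored log10(normalized + 1); zero-variance rows become
    all-zero and are flagged.  Agglomerative clustering with the given
    linkage/metric yields deterministic row and column leaf orders.
    """
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("no miRNAs selected for the heatmap")
    if matrix.size_factors is None:
        matrix = CountMatrix(matrix.counts,
                             size_factors=compute_size_factors(matrix.counts))
    expr = np.log10(matrix.normalized.loc[mirnas] + 1.0)
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    degenerate = list(expr.index[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    z = expr.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[degenerate] = 0.0

    row_link = linkage(z.to_numpy(), method=method, metric=metric)
    col_link = linkage(z.to_numpy().T, method=method, metric=metric)
    row_order = [z.index[i] for i in leaves_list(row_link)]
    col_order = [z.columns[i] for i in leaves_list(col_link)]
    return HeatmapMatrix(zscores=z, row_linkage=row_link, col_linkage=col_link,
                         row_order=row_order, col_order=col_order,
                         degenerate_rows=degenerate)
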