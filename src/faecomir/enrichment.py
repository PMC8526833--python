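"""miRNA-target gene-set enrichment by logistic regression.

Differential-expression statistics are first mapped onto target genes: each
gene g accumulates, over the (by default DE-called) miRNAs that target it,

    S_g = sum_m [ -sign(log2FC_m) * (-log10 q_m) ]

The negation encodes repression — an up-regulated miRNA predicts its targets
down.  A gene set is then tested by a logistic regression of the membership
indicator on the standardized gene scores; the slope's sign gives the
predicted direction of the process (positive = up-regulated), its Wald test
the p-value, and q-values are BH-adjusted within each gene-set library.

The score aggregation is isolated in :func:`gene_scores` so alternative
schemes (raw-p weighting, Fisher combination) can be swapped in; switches
for raw vs adjusted p are exposed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .diffexp import bh_adjust
from .io_formats import GeneSetLibrary, TargetMap

logger = logging.getLogger("faecomir")

Q_FLOOR = 1e-300
RIDGE_LAMBDA = 1e-4


# ---------------------------------------------------------------------------
# Gene-level score aggregation
# ---------------------------------------------------------------------------

def gene_scores(de_results: pd.DataFrame, target_map: TargetMap,
                only_de: bool = True,
                use_adjusted_p: bool = True) -> pd.DataFrame:
    """Aggregate per-miRNA DE statistics into signed per-gene scores.

    Genes in the target map that no contributing miRNA targets keep score 0.
    Target-map miRNAs absent from the DE table are ignored (tallied in the
    log).
    """
    de = de_results
    if only_de and "is_de" in de.columns:
        de = de[de["is_de"]]
    pcol = "q" if use_adjusted_p else "p"
    stat = {}
    for mirna, lfc, pval in zip(de["mirna"], de["log2fc"], de[pcol]):
        if not (math.isfinite(lfc) and not pd.isna(pval)):
            continue
        stat[mirna] = (lfc, max(float(pval), Q_FLOOR))

    scores: Dict[str, float] = {g: 0.0 for g in target_map.genes()}
    n_targeting: Dict[str, int] = {g: 0 for g in scores}
    unknown_mirnas = set()
    for mirna, gene in target_map.pairs:
        if mirna not in stat:
            unknown_mirnas.add(mirna)
            continue
        lfc, pval = stat[mirna]
        scores[gene] += -np.sign(lfc) * (-math.log10(pval))
        n_targeting[gene] += 1
    if unknown_mirnas:
        logger.info("gene_scores: %d target-map miRNAs without DE statistics",
                    len(unknown_mirnas))
    out = pd.DataFrame({
        "gene": list(scores),
        "score": [scores[g] for g in scores],
        "n_targeting_mirnas": [n_targeting[g] for g in scores],
    }).set_index("gene", drop=False)
    return out.sort_index()


# ---------------------------------------------------------------------------
# Per-set logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    coefficient: float
    se: float
    p: float
    n_members: int
    direction: str
    flag: str = ""


def _ridge_logistic(X: np.ndarray, y: np.ndarray,
                    lam: float = RIDGE_LAMBDA,
                    maxiter: int = 200) -> Tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic IRLS; returns (beta, se from penalized info).

    Fallback for perfectly separated designs where the unpenalized MLE
    diverges; the intercept is not penalized.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = lam * np.eye(k)
    pen[0, 0] = 0.0
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        info = X.T @ (X * w[:, None]) + pen
        grad = X.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None]) + pen
    cov = np.linalg.inv(info)
    return beta, np.sqrt(np.diag(cov))


def gene_set_test(scores: pd.Series, member_genes: Iterable[str],
                  set_name: str = "") -> EnrichmentRecord:
    """Logistic regression of set membership on standardized gene scores."""
    members = set(member_genes)
    y = np.asarray([g in members for g in scores.index], dtype=float)
    n_members = int(y.sum())
    if n_members == 0 or n_members == len(y):
        raise ValueError(
            f"gene set {set_name!r}: membership must be a proper subset of "
            "scored genes")
    s = scores.to_numpy(dtype=float)
    sd = s.std(ddof=0)
    if sd == 0:
        return EnrichmentRecord(set_name, 0.0, math.nan, 1.0, n_members,
                                "up", flag="constant_scores")
    z = (s - s.mean()) / sd
    X = np.column_stack([np.ones_like(z), z])

    flag = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        b, se = fit.params[1], fit.bse[1]
        # (quasi-)separation: the MLE runs off to the boundary and the Wald
        # SE explodes; standardized scores keep legitimate slopes far smaller
        if not fit.converged or abs(b) > 15 or se > 50 or not np.isfinite(se):
            raise ValueError("divergent logistic fit")
    except Exception:
        beta, ses = _ridge_logistic(X, y)
        b, se = beta[1], ses[1]
        flag = "ridge_fallback"
    wald = b / se
    p = float(2 * sps.norm.sf(abs(wald)))
    return EnrichmentRecord(set_name=set_name, coefficient=float(b),
                            se=float(se), p=p, n_members=n_members,
                            direction="up" if b > 0 else "down", flag=flag)


def enrich_all(scores: pd.DataFrame | pd.Series,
               library: GeneSetLibrary,
               q_threshold: float = 0.05) -> pd.DataFrame:
    """Test every set of a library; BH-adjust q within the library."""
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    records = []
    for name, members in library.sets.items():
        rec = gene_set_test(s, members, set_name=name)
        records.append(rec)
    out = pd.DataFrame([{
        "set_name": r.set_name,
        "coefficient": r.coefficient,
        "se": r.se,
        "p": r.p,
        "n_members": r.n_members,
        "direction": r.direction,
        "flag": r.flag,
    } for r in records])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    out["library"] = library.library_label
    return out


def dot_plot_table(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table (term, gene count, coefficient, q), most significant
    first."""
    cols = ["set_name", "n_members", "coefficient", "q"]
    return enrichment[cols].sort_values("q", kind="mergesort").reset_index(drop=True)
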