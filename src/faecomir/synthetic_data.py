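"""Synthetic references, cohorts, counts and alignments with planted effects.

The generators emulate the statistical structure the downstream analysis
assumes for a 335-subject stool small-RNA-seq study: hairpin precursors with
(or without) annotated 5p/3p mature arms, a questionnaire cohort whose
category frequencies match the published study population, mature-miRNA
counts that are negative-binomial around long-tailed log-normal baseline
abundances with per-sample library-size factors (defaults: 10.3 million
reads/sample with 0.92% assigned to miRNAs), planted log2-fold-change
effects per covariate recorded in a first-class truth ledger, and repeated
samples for a subject subset with log-normal latent drift.

Every generator is a pure function of its explicit seed (one RNG stream per
call, no global state), so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import STUDY_COHORT_COUNTS, STUDY_MIRNOME_COUNTS
from .io_formats import (
    AlignmentRecord,
    ArmAnnotation,
    MiRNAReference,
    Precursor,
)
from .quantify import CountMatrix

DEFAULT_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

_C = STUDY_COHORT_COUNTS


def _normalize(d: Mapping[str, float]) -> Dict[str, float]:
    total = float(sum(d.values()))
    return {k: v / total for k, v in d.items()}


#: Default covariate category frequencies, renormalised over non-missing
#: categories of the emulated study population.
DEFAULT_MARGINALS: Dict[str, Dict[str, float]] = {
    "sex": _normalize(_C["sex"]),
    "bmi_class": _normalize(_C["bmi_class"]),
    "smoking": _normalize(_C["smoking"]),
    "alcohol_class": _normalize(_C["alcohol_class"]),
    "coffee_class": _normalize(_C["coffee_class"]),
    # occupational marginals are not published; realistic desk defaults
    "occupational": {"sedentary": 0.45, "standing": 0.25, "manual": 0.06,
                     "heavy_manual": 0.04, "unemployed": 0.20},
}

AGE_MEAN, AGE_SD = 44.7, 14.7
AGE_RANGE = (18.0, 81.0)
MENOPAUSE_AGE = 50.0
LIBRARY_POOL_SIZE = 24  # samples multiplexed per sequencing pool


@dataclass
class EffectSpec:
    """A planted association between a covariate and a set of miRNAs."""

    variable: str
    contrast: Union[Tuple[str, str], str]  # (reference, test) or "continuous"
    affected_mirnas: List[str]
    log2fc: List[float]

    def __post_init__(self) -> None:
        if len(self.affected_mirnas) != len(self.log2fc):
            raise ValueError("affected_mirnas and log2fc must be parallel")
        if not all(np.isfinite(self.log2fc)):
            raise ValueError("log2fc must be finite")

    def items(self):
        return zip(self.affected_mirnas, self.log2fc)


@dataclass
class SimulationConfig:
    """Count-simulation parameters (defaults follow the emulated study)."""

    n_subjects: int = 60
    seed: int = 0
    library_size_mean: float = STUDY_MIRNOME_COUNTS["mean_library_reads"]
    mirna_fraction: float = STUDY_MIRNOME_COUNTS["mirna_read_fraction"]
    dispersion: Union[float, np.ndarray] = 0.3
    baseline_abundance: Optional[np.ndarray] = None
    baseline_log_sigma: float = 2.5
    library_size_log_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not (0 <= self.mirna_fraction <= 1):
            raise ValueError("mirna_fraction must lie in [0, 1]")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimulationResult:
    matrix: CountMatrix
    truth: pd.DataFrame                  # one row per planted (miRNA, effect)
    latent_mean: pd.DataFrame            # NB mean per cell (before noise)
    baseline: pd.Series                  # relative abundance per mature name
    true_size_factors: pd.Series


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(n_precursors: int, annotated_fraction: float,
                       seed: int,
                       chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES
                       ) -> MiRNAReference:
    """Random hairpin precursors, a fraction with annotated 5p/3p arms.

    Precursors are 60-120 nt; annotated arms are 18-25 nt intervals anchored
    near the hairpin ends; chromosomes are assigned round-robin.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    if not (0 <= annotated_fraction <= 1):
        raise ValueError("annotated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(n_precursors))
    n_annotated = int(round(annotated_fraction * n_precursors))
    annotated = set(rng.choice(n_precursors, size=n_annotated, replace=False))

    precursors, arms = [], {}
    for i in range(n_precursors):
        pid = f"mir-{i + 1:0{width}d}"
        length = int(rng.integers(60, 121))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        precursors.append(Precursor(pid, seq, chromosomes[i % len(chromosomes)]))
        if i in annotated:
            s5 = int(rng.integers(0, 4))
            l5 = int(rng.integers(18, 26))
            e3 = length - int(rng.integers(0, 4))
            l3 = int(rng.integers(18, 26))
            arms[pid] = ArmAnnotation(arm5p=(s5, s5 + l5), arm3p=(e3 - l3, e3))
    return MiRNAReference(precursors=precursors, arms=arms)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _check_marginals(marginals: Mapping[str, Mapping[str, float]]) -> None:
    for var, dist in marginals.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"marginals for {var!r} sum to {total}, not 1")


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= low) & (draw <= high)]
        take = min(size - filled, ok.size)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out

_BMI_RANGES = {"underweight": (16.0, 18.4), "normal": (18.5, 24.9),
               "overweight": (25.0, 29.9), "obese": (30.0, 38.0)}


def simulate_cohort(n_subjects: int,
                    marginals: Optional[Mapping[str, Mapping[str, float]]] = None,
                    seed: int = 0) -> pd.DataFrame:
    """Raw questionnaire covariates for a synthetic cohort.

    Continuous values are drawn consistently with the categorical marginals
    (e.g. alcohol g/day within its class's sex-specific band) so that
    re-categorization reproduces the drawn classes.  Menopausal status is
    derived from age (post above 50) for females only.  A ``library_pool``
    column assigns consecutive subjects to 24-plex sequencing pools, serving
    as the batch covariate downstream.
    """
    marg = {**DEFAULT_MARGINALS, **(dict(marginals) if marginals else {})}
    _check_marginals(marg)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_subjects)))
    ids = [f"S{i + 1:0{width}d}" for i in range(n_subjects)]

    def draw(var):
        cats = list(marg[var])
        probs = [marg[var][c] for c in cats]
        return rng.choice(cats, size=n_subjects, p=probs)

    sex = draw("sex")
    age = np.round(_truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE,
                                     size=n_subjects), 1)

    bmi_cls = draw("bmi_class")
    bmi = np.array([rng.uniform(*_BMI_RANGES[c]) for c in bmi_cls])
    height = np.where(sex == "female", rng.normal(163, 6, n_subjects),
                      rng.normal(176, 7, n_subjects))
    weight = bmi * (height / 100.0) ** 2

    smoking = draw("smoking")
    status = np.select(
        [smoking == "never", smoking == "former"],
        ["never", "former"], default="current",
    )
    cigs = np.zeros(n_subjects)
    light = smoking == "light_current"
    heavy = smoking == "heavy_current"
    cigs[light] = rng.uniform(1, 15.9, light.sum())
    cigs[heavy] = rng.uniform(16, 40, heavy.sum())

    alcohol_cls = draw("alcohol_class")
    alcohol = np.zeros(n_subjects)
    for i, (cls, sx) in enumerate(zip(alcohol_cls, sex)):
        limit = 24.0 if sx == "male" else 12.0
        if cls == "low":
            alcohol[i] = rng.uniform(0.1, limit)
        elif cls == "high":
            alcohol[i] = rng.uniform(limit + 0.1, limit * 3)

    coffee_cls = draw("coffee_class")
    coffee = np.zeros(n_subjects)
    coffee[coffee_cls == "low"] = rng.uniform(0.5, 8.0, (coffee_cls == "low").sum())
    coffee[coffee_cls == "high"] = rng.uniform(8.5, 40.0,
                                               (coffee_cls == "high").sum())

    recreational = np.round(rng.lognormal(np.log(20), 0.8, n_subjects), 1)
    household = np.round(rng.lognormal(np.log(25), 0.9, n_subjects), 1)
    occupational = draw("occupational")

    menopausal = np.where(
        (sex == "female") & (age >= MENOPAUSE_AGE), "post",
        np.where(sex == "female", "pre", None),
    )
    pools = [f"pool{(i // LIBRARY_POOL_SIZE) + 1:02d}" for i in range(n_subjects)]

    df = pd.DataFrame({
        "subject_id": ids,
        "age": age,
        "sex": sex,
        "height_cm": np.round(height, 1),
        "weight_kg": np.round(weight, 1),
        "smoking_status": status,
        "cigs_per_day": np.round(cigs, 1),
        "alcohol_g_day": np.round(alcohol, 2),
        "coffee_g_day": np.round(coffee, 2),
        "recreational_met_h": recreational,
        "household_met_h": household,
        "occupational": occupational,
        "menopausal": menopausal,
        "library_pool": pools,
    })
    return df.set_index(df["subject_id"], drop=False)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def draw_baseline(n_features: int, sigma: float = 2.5,
                  seed: int = 0) -> np.ndarray:
    """Long-tailed log-normal baseline abundances (relative, unnormalised)."""
    rng = np.random.default_rng(seed)
    return rng.lognormal(0.0, sigma, n_features)


def expressed_mature_names(reference: MiRNAReference, baseline: np.ndarray,
                           config: SimulationConfig,
                           min_mean: float = 10.0) -> List[str]:
    """Mature names whose expected per-sample count is at least *min_mean*.

    Effects planted on these features are recoverable by a DE stage whose
    calling criterion includes an abundance filter; effects planted in the
    undetectable tail are not, by design.
    """
    mu_rel = np.asarray(baseline, dtype=float)
    mu_rel = mu_rel / mu_rel.sum()
    depth = config.library_size_mean * config.mirna_fraction
    return [n for n, m in zip(reference.mature_names, mu_rel * depth)
            if m >= min_mean]


def _effect_design(cohort: pd.DataFrame, effect: EffectSpec) -> np.ndarray:
    if effect.variable not in cohort.columns:
        raise ValueError(f"effect on missing covariate {effect.variable!r}")
    col = cohort[effect.variable]
    if effect.contrast == "continuous":
        vals = col.astype(float)
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {effect.variable!r} is constant")
        return ((vals - vals.mean()) / sd).to_numpy()
    _ref, test = effect.contrast
    return (col == test).astype(float).to_numpy()


def simulate_counts(reference: MiRNAReference, cohort: pd.DataFrame,
                    effects: Sequence[EffectSpec],
                    config: SimulationConfig) -> SimulationResult:
    """NB count matrix over the reference mature-name space, with planted
    effects.

    y_ij ~ NB(mean = s_j * mu_i * 2^(x_j * log2fc_i), dispersion alpha_i)
    where mu_i are log-normal relative abundances, s_j log-normal library
    depths around library_size_mean * mirna_fraction, and x_j the effect
    design column.  The truth ledger lists every planted (miRNA, variable,
    log2fc).
    """
    rng = np.random.default_rng(config.seed)
    names = reference.mature_names
    n_feat, n_sub = len(names), len(cohort)

    if config.baseline_abundance is not None:
        mu = np.asarray(config.baseline_abundance, dtype=float)
        if mu.shape != (n_feat,):
            raise ValueError("baseline_abundance length mismatch")
    else:
        mu = rng.lognormal(mean=0.0, sigma=config.baseline_log_sigma,
                           size=n_feat)
    mu_rel = mu / mu.sum()

    depth = config.library_size_mean * config.mirna_fraction
    s = depth * rng.lognormal(-config.library_size_log_sd ** 2 / 2,
                              config.library_size_log_sd, size=n_sub)

    log2_shift = np.zeros((n_feat, n_sub))
    truth_rows = []
    name_pos = {n: i for i, n in enumerate(names)}
    for eff in effects:
        x = _effect_design(cohort, eff)
        for mirna, lfc in eff.items():
            if mirna not in name_pos:
                raise ValueError(f"planted miRNA {mirna!r} not in reference")
            log2_shift[name_pos[mirna]] += lfc * x
            contrast = (eff.contrast if isinstance(eff.contrast, str)
                        else f"{eff.contrast[0]}_vs_{eff.contrast[1]}")
            truth_rows.append((mirna, eff.variable, contrast, lfc))

    mean = np.outer(mu_rel, s) * np.exp2(log2_shift)
    alpha = np.asarray(config.dispersion, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(n_feat, float(alpha))
    counts = np.empty((n_feat, n_sub), dtype=int)
    pos = alpha > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam = rng.gamma(shape[:, None],
                        alpha[pos][:, None] * mean[pos, :])
        counts[pos, :] = rng.poisson(lam)
    if (~pos).any():
        counts[~pos, :] = rng.poisson(mean[~pos, :])

    index = pd.Index(names, name="mirna")
    columns = pd.Index(cohort["subject_id"].astype(str), name="sample")
    matrix = CountMatrix(pd.DataFrame(counts, index=index, columns=columns))
    truth = pd.DataFrame(truth_rows,
                         columns=["mirna", "variable", "contrast", "log2fc"])
    return SimulationResult(
        matrix=matrix,
        truth=truth,
        latent_mean=pd.DataFrame(mean, index=index, columns=columns),
        baseline=pd.Series(mu_rel, index=index, name="relative_abundance"),
        true_size_factors=pd.Series(s / np.exp(np.mean(np.log(s))),
                                    index=columns, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# Alignments (inverse of the quantification stage)
# ---------------------------------------------------------------------------

def simulate_alignments(counts_for_sample: Mapping[str, int],
                        reference: MiRNAReference, seed: int,
                        read_prefix: str = "r") -> List[AlignmentRecord]:
    """One alignment per count unit, placed so quantification recovers the
    input counts exactly.

    Annotated precursors receive reads inside the requested arm interval;
    unannotated precursors receive reads strictly inside the corresponding
    hairpin half (read midpoint strictly on the requested side of the
    precursor midpoint).
    """
    rng = np.random.default_rng(seed)
    records: List[AlignmentRecord] = []
    serial = 0
    items = counts_for_sample.items() if hasattr(counts_for_sample, "items") \
        else counts_for_sample
    for mature_name, n in items:
        n = int(n)
        if n <= 0:
            continue
        if not (mature_name.endswith("-5p") or mature_name.endswith("-3p")):
            raise ValueError(f"not a mature name: {mature_name!r}")
        pid, arm = mature_name[:-3], mature_name[-2:]
        length = reference.length(pid)
        ann = reference.arm_annotation(pid)
        for _ in range(n):
            if ann is not None:
                iv = ann.arm5p if arm == "5p" else ann.arm3p
                if iv is None:
                    raise ValueError(
                        f"{pid}: {arm} arm not annotated; cannot place read")
                a_start, a_end = iv
                l = int(rng.integers(14, a_end - a_start + 1))
                start = int(rng.integers(a_start, a_end - l + 1))
            else:
                half = length // 2
                l = int(rng.integers(14, min(24, half) + 1))
                if arm == "5p":
                    start = int(rng.integers(0, half - l + 1))
                else:
                    start = int(rng.integers(length - half, length - l + 1))
            serial += 1
            records.append(AlignmentRecord(
                read_id=f"{read_prefix}{serial:07d}",
                precursor_id=pid, start=start, end=start + l,
            ))
    return records


# ---------------------------------------------------------------------------
# Repeated samples
# ---------------------------------------------------------------------------

def simulate_repeated_samples(cohort: pd.DataFrame,
                              sim: SimulationResult,
                              n_repeat_subjects: int = _C["n_repeat_subjects"],
                              drift_sd: float = 0.1,
                              seed: int = 0) -> CountMatrix:
    """Second-time-point counts for a subject subset.

    Each repeat subject's latent means are perturbed cell-wise by log-normal
    drift of scale *drift_sd* and counts are re-drawn NB (Poisson-gamma with
    the per-feature dispersions implied by the original simulation is not
    retained; a shared dispersion of 0.3 matches the generator default).
    """
    if n_repeat_subjects > len(cohort):
        raise ValueError("n_repeat_subjects exceeds cohort size")
    rng = np.random.default_rng(seed)
    subjects = list(cohort["subject_id"].astype(str)[:n_repeat_subjects])
    means = sim.latent_mean.loc[:, subjects].to_numpy()
    if drift_sd > 0:
        drift = rng.lognormal(-drift_sd ** 2 / 2, drift_sd, size=means.shape)
        means = means * drift
    alpha = 0.3
    lam = rng.gamma(1.0 / alpha, alpha * means)
    counts = rng.poisson(lam)
    return CountMatrix(pd.DataFrame(
        counts, index=sim.latent_mean.index,
        columns=pd.Index(subjects, name="sample"),
    ))
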