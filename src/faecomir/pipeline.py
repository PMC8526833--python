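"""End-to-end orchestration of the stool-miRNome analysis from one YAML config.

Stage order follows the study workflow: quantify (or ingest a count matrix)
-> cohort categorization -> normalization/variability -> differential
expression per configured contrast (full cohort, then sex-stratified) ->
target-gene enrichment.  Every output TSV is accompanied by a JSON manifest
recording input checksums, parameters, the global seed and the package
version, which is sufficient to reproduce the output.  On stage failure the
partial outputs are moved under ``failed/`` and the failing stage is named.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import diffexp, enrichment, io_formats, quantify, synthetic_data, variability
from .quantify import CountMatrix

logger = logging.getLogger("faecomir")

#: (variable, reference level, test level) triples analysed when the config
#: does not narrow them: every categorical comparison of the study design.
DEFAULT_CONTRASTS: List[Tuple[str, str, str]] = [
    ("sex", "female", "male"),
    ("age_tertile", "t1", "t2"),
    ("age_tertile", "t1", "t3"),
    ("age_tertile", "t2", "t3"),
    ("menopausal", "pre", "post"),
    ("bmi_class", "normal", "underweight"),
    ("bmi_class", "normal", "overweight"),
    ("bmi_class", "normal", "obese"),
    ("smoking", "never", "former"),
    ("smoking", "never", "light_current"),
    ("smoking", "never", "heavy_current"),
    ("alcohol_class", "non_drinker", "low"),
    ("alcohol_class", "non_drinker", "high"),
    ("coffee_class", "non_drinker", "low"),
    ("coffee_class", "non_drinker", "high"),
    ("pai", "active", "moderately_active"),
    ("pai", "active", "moderately_inactive"),
    ("pai", "active", "inactive"),
]


def demo_config(seed: int = 7, outdir: str = "faecomir_demo") -> dict:
    """The standard end-to-end demonstration: 200 precursors, 60 subjects,
    three planted contrasts on well-populated strata."""
    return {
        "seed": int(seed),
        "outdir": str(outdir),
        "simulate": {
            "n_precursors": 200,
            "annotated_fraction": 0.7,
            "n_subjects": 60,
            "library_size_mean": 1.0e6,
            "mirna_fraction": 0.01,
            "dispersion": 0.3,
            "effects": [
                {"variable": "sex", "reference": "female", "test": "male",
                 "n_mirnas": 6, "log2fc": 2.0},
                {"variable": "smoking", "reference": "never", "test": "former",
                 "n_mirnas": 6, "log2fc": 2.0},
                {"variable": "coffee_class", "reference": "non_drinker",
                 "test": "high", "n_mirnas": 6, "log2fc": 2.0},
            ],
        },
        "diffexp": {
            "contrasts": [
                ["sex", "female", "male"],
                ["smoking", "never", "former"],
                ["coffee_class", "non_drinker", "high"],
            ],
            "adjust": ["sex", "age"],
        },
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as handle:
        cfg = yaml.safe_load(handle) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "faecomir_out")
    paths = cfg.get("paths", {})
    for key, p in paths.items():
        if key in ("reference", "arms", "counts", "questionnaire",
                   "target_map", "sam_dir") and p is not None:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path {key}={p} does not exist")
    for p in paths.get("gene_sets", []) or []:
        if not Path(p).exists():
            raise FileNotFoundError(f"configured gene-set library {p} missing")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(out_path: Path, inputs: Sequence[Path], params: dict,
              seed: int) -> None:
    manifest = {
        "output": out_path.name,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "parameters": params,
        "seed": seed,
        "tool_version": __version__,
    }
    out_path.with_suffix(out_path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# simulate: write a full synthetic input bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: dict, outdir: Optional[Path] = None) -> Dict[str, Path]:
    """Generate reference, arm table, per-sample SAM files, questionnaire,
    toy target map/gene sets and the truth ledger, per the ``simulate:``
    config block."""
    sim = config.get("simulate", {})
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "faecomir_out")) / "inputs"
    outdir.mkdir(parents=True, exist_ok=True)

    n_prec = int(sim.get("n_precursors", 200))
    annotated_fraction = float(sim.get("annotated_fraction", 0.7))
    n_subjects = int(sim.get("n_subjects", 60))
    reference = synthetic_data.simulate_reference(n_prec, annotated_fraction,
                                                  seed=seed)
    cohort_raw = synthetic_data.simulate_cohort(n_subjects, seed=seed + 1)
    cohort_cat = cohort_mod.categorize_cohort(cohort_raw)

    import numpy as np
    rng = np.random.default_rng(seed + 2)
    sim_config = synthetic_data.SimulationConfig(
        n_subjects=n_subjects, seed=seed + 3,
        library_size_mean=float(sim.get("library_size_mean", 1.0e6)),
        mirna_fraction=float(sim.get("mirna_fraction", 0.01)),
        dispersion=float(sim.get("dispersion", 0.3)),
        baseline_log_sigma=float(sim.get("baseline_log_sigma", 2.5)),
    )
    baseline = synthetic_data.draw_baseline(
        len(reference.mature_names), sigma=sim_config.baseline_log_sigma,
        seed=seed + 4)
    sim_config.baseline_abundance = baseline
    # plant effects on detectable miRNAs so recovery is meaningful
    expressed = synthetic_data.expressed_mature_names(reference, baseline,
                                                      sim_config)
    effects = []
    for block in sim.get("effects", []):
        n_mirnas = int(block.get("n_mirnas", 5))
        chosen = list(rng.choice(expressed, size=n_mirnas, replace=False))
        lfc = float(block.get("log2fc", 2.0))
        signs = rng.choice([-1.0, 1.0], size=n_mirnas)
        effects.append(synthetic_data.EffectSpec(
            variable=block["variable"],
            contrast=(block["reference"], block["test"]),
            affected_mirnas=chosen,
            log2fc=list(signs * lfc),
        ))
    result = synthetic_data.simulate_counts(reference, cohort_cat, effects,
                                            sim_config)

    paths: Dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    paths["arms"] = outdir / "arms.tsv"
    io_formats.write_reference(reference, paths["reference"], paths["arms"])
    paths["questionnaire"] = outdir / "questionnaire.csv"
    io_formats.write_questionnaire(cohort_raw, paths["questionnaire"])
    paths["truth"] = outdir / "truth_ledger.tsv"
    result.truth.to_csv(paths["truth"], sep="\t", index=False)

    sam_dir = outdir / "sam"
    sam_dir.mkdir(exist_ok=True)
    for j, sample in enumerate(result.matrix.sample_ids):
        vec = result.matrix.counts[sample]
        records = synthetic_data.simulate_alignments(
            vec[vec > 0].items(), reference, seed=seed + 10 + j,
            read_prefix=f"{sample}_")
        io_formats.write_sam(records, reference, sam_dir / f"{sample}.sam")
    paths["sam_dir"] = sam_dir

    # toy target map + gene-set library so the enrichment stage is exercised
    genes = [f"G{i + 1:04d}" for i in range(300)]
    pairs = set()
    for m in reference.mature_names:
        for g in rng.choice(genes, size=3, replace=False):
            pairs.add((m, g))
    paths["target_map"] = outdir / "target_map.tsv"
    io_formats.write_target_map(io_formats.TargetMap(pairs=pairs),
                                paths["target_map"])
    sets = {f"SET_{k + 1:02d}": set(rng.choice(genes, size=25, replace=False))
            for k in range(12)}
    paths["gene_sets"] = outdir / "sets.gmt"
    io_formats.write_gmt(io_formats.GeneSetLibrary(sets=sets), paths["gene_sets"])
    return paths


# ---------------------------------------------------------------------------
# run: full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict) -> Path:
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "faecomir_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: Path(v) if not isinstance(v, list) and v is not None else v
             for k, v in config.get("paths", {}).items()}
    stages = config.get("stages", {})
    current_stage = "setup"
    try:
        # --- quantify -----------------------------------------------------
        current_stage = "quantify"
        reference = None
        if paths.get("reference"):
            reference = io_formats.read_reference(paths["reference"],
                                                  paths.get("arms"))
        if paths.get("counts"):
            matrix = io_formats.read_count_matrix(paths["counts"])
        else:
            if reference is None:
                raise ValueError("need either paths.counts or paths.reference"
                                 " + paths.sam_dir")
            sam_files = sorted(Path(paths["sam_dir"]).glob("*.sam"))
            per_sample, logs = [], {}
            for sam in sam_files:
                stats: dict = {}
                alignments = io_formats.read_alignments(sam, reference, stats)
                vec, log = quantify.quantify_sample(alignments, reference)
                per_sample.append((sam.stem, vec[vec > 0].to_dict()))
                logs[sam.stem] = {**log, **stats}
            matrix = quantify.build_count_matrix(per_sample, reference)
            (outdir / "assignment_log.json").write_text(
                json.dumps(logs, indent=2, sort_keys=True) + "\n")
        counts_path = outdir / "counts.tsv"
        io_formats.write_count_matrix(matrix, counts_path)
        _manifest(counts_path, [p for p in [paths.get("reference"),
                                            paths.get("arms")] if p],
                  {"n_samples": len(matrix.sample_ids)}, seed)
        logger.info("quantify: %d miRNAs x %d samples",
                    len(matrix.mature_names), len(matrix.sample_ids))

        # --- cohort -------------------------------------------------------
        current_stage = "cohort"
        raw = io_formats.read_questionnaire(paths["questionnaire"])
        cohort_cfg = config.get("cohort", {})
        cohort_df = cohort_mod.categorize_cohort(
            raw,
            coffee_cutoff=float(cohort_cfg.get("coffee_cutoff",
                                               cohort_mod.COFFEE_CUTOFF_G_DAY)),
            heavy_smoking_threshold=float(
                cohort_cfg.get("heavy_smoking_threshold",
                               cohort_mod.SMOKING_HEAVY_CIGS)),
        )
        cohort_path = outdir / "cohort.tsv"
        io_formats.write_cohort_table(cohort_df, cohort_path)
        _manifest(cohort_path, [paths["questionnaire"]], cohort_cfg, seed)

        # --- variability ----------------------------------------------------
        current_stage = "variability"
        matrix = variability.attach_size_factors(matrix)
        var_cfg = config.get("variability", {})
        chrom = reference.chromosome_of_mature() if reference is not None else None
        det = variability.detection_summary(
            matrix.counts, min_reads=int(var_cfg.get("min_reads", 1)),
            chromosome=chrom)
        det_path = outdir / "detection_summary.tsv"
        pd.DataFrame({"prevalence": det.prevalence}).to_csv(det_path, sep="\t")
        cv = variability.cv_ranking(
            matrix.normalized,
            min_median=float(var_cfg.get("cv_min_median", 1.0)),
            mad_kind=var_cfg.get("mad_kind", "median"))
        cv_path = outdir / "cv_ranking.tsv"
        cv.to_csv(cv_path, sep="\t", index=False)
        _manifest(cv_path, [counts_path], var_cfg, seed)

        # --- differential expression ---------------------------------------
        current_stage = "diffexp"
        de_cfg = config.get("diffexp", {})
        contrasts = [tuple(c) for c in de_cfg.get("contrasts", [])] or \
            DEFAULT_CONTRASTS
        batch = de_cfg.get("batch", "library_pool"
                           if "library_pool" in cohort_df.columns else None)
        adjust_full = de_cfg.get("adjust", ["sex", "age"])
        stratify = bool(de_cfg.get("sex_stratified", False))
        de_tables: Dict[str, pd.DataFrame] = {}
        for var, ref_level, test_level in contrasts:
            if var not in cohort_df.columns:
                logger.warning("skipping contrast on missing variable %r", var)
                continue
            adjust = [a for a in adjust_full if a != var]
            if var == "menopausal":
                adjust = [a for a in adjust if a != "sex"]
            design = diffexp.DesignSpec(var, ref_level, test_level,
                                        adjustment_covariates=adjust,
                                        batch=batch)
            try:
                res = diffexp.run_de(matrix, cohort_df, design)
            except ValueError as exc:
                logger.warning("contrast %s %s vs %s skipped: %s",
                               var, test_level, ref_level, exc)
                continue
            key = f"{var}_{test_level}_vs_{ref_level}"
            de_tables[key] = res
            de_path = outdir / f"de_{key}.tsv"
            res.drop(columns=["mirna"]).to_csv(de_path, sep="\t")
            _manifest(de_path, [counts_path, cohort_path],
                      {"contrast": [var, ref_level, test_level],
                       "adjust": adjust, "batch": batch}, seed)
            if stratify:
                for sex in ("female", "male"):
                    strat = cohort_df[cohort_df["sex"] == sex]
                    strat_design = diffexp.DesignSpec(
                        var, ref_level, test_level,
                        adjustment_covariates=[a for a in adjust if a != "sex"],
                        batch=batch)
                    try:
                        sres = diffexp.run_de(
                            matrix.subset_samples(
                                [s for s in matrix.sample_ids
                                 if s in set(strat.index.astype(str))]),
                            strat, strat_design)
                    except ValueError as exc:
                        logger.warning("stratified %s (%s) skipped: %s",
                                       key, sex, exc)
                        continue
                    sres.drop(columns=["mirna"]).to_csv(
                        outdir / f"de_{key}_{sex}.tsv", sep="\t")
        for cov in de_cfg.get("continuous", ["age", "bmi"]):
            if cov not in cohort_df.columns:
                continue
            scc = diffexp.continuous_scc(
                matrix, cohort_df.set_index(
                    cohort_df["subject_id"].astype(str))[cov])
            scc.to_csv(outdir / f"scc_{cov}.tsv", sep="\t", index=False)

        # --- enrichment -----------------------------------------------------
        current_stage = "enrichment"
        if paths.get("target_map") and paths.get("gene_sets"):
            target_map = io_formats.read_target_map(paths["target_map"])
            libraries = [io_formats.read_gmt(p) for p in paths["gene_sets"]]
            for key, res in de_tables.items():
                if not res["is_de"].any():
                    continue
                scores = enrichment.gene_scores(res, target_map)
                for lib in libraries:
                    enr = enrichment.enrich_all(scores, lib)
                    enr_path = outdir / f"enrichment_{key}.tsv"
                    enr.to_csv(enr_path, sep="\t", index=False)
                    _manifest(enr_path, [Path(paths["target_map"])], {}, seed)
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(outdir.iterdir()):
            if item.name != "failed" and item.is_file():
                shutil.move(str(item), failed / item.name)
        raise StageError(current_stage, exc) from exc
    return outdir
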