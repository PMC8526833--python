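"""Readers and writers for the on-disk formats the pipeline touches.

All in-memory coordinates are 0-based half-open; SAM positions are converted
once at the boundary.  Only plain-text formats are supported: FASTA for
precursor sequences, a 5-column TSV for arm annotations, SAM for read
alignments (FLAG, RNAME, POS and CIGAR are the only fields consumed), TSV for
count matrices and miRNA->gene target maps, GMT for gene-set libraries and CSV
for the subject questionnaire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("faecomir")

NUCLEOTIDES = set("ACGTUN")

ARM_TABLE_COLUMNS = ["precursor_id", "arm", "start", "end", "chromosome"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


Interval = Tuple[int, int]  # 0-based half-open


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Precursor:
    precursor_id: str
    sequence: str
    chromosome: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ArmAnnotation:
    """Annotated 5p/3p mature-arm intervals on a precursor hairpin."""

    arm5p: Optional[Interval] = None
    arm3p: Optional[Interval] = None


@dataclass
class MiRNAReference:
    """Precursor hairpins plus optional mature-arm annotations.

    Every precursor contributes exactly two mature names (``<id>-5p`` and
    ``<id>-3p``) to the mature-name space, whether or not its arms are
    annotated; the count matrix therefore always has 2 x n_precursors rows.
    """

    precursors: List[Precursor]
    arms: Dict[str, ArmAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {p.precursor_id: p for p in self.precursors}
        if len(self._index) != len(self.precursors):
            raise ValidationError("duplicate precursor ids in reference")
        for prec in self.precursors:
            bad = set(prec.sequence.upper()) - NUCLEOTIDES
            if bad:
                raise ValidationError(
                    f"precursor {prec.precursor_id}: invalid characters {sorted(bad)}"
                )
        for pid, ann in self.arms.items():
            if pid not in self._index:
                raise ValidationError(f"arm annotation for unknown precursor {pid}")
            length = len(self._index[pid])
            for name, iv in (("5p", ann.arm5p), ("3p", ann.arm3p)):
                if iv is None:
                    continue
                start, end = iv
                if not (0 <= start < end <= length):
                    raise ValidationError(
                        f"precursor {pid}: {name} arm [{start},{end}) outside "
                        f"[0,{length})"
                    )
            if ann.arm5p is not None and ann.arm3p is not None:
                if ann.arm5p[1] > ann.arm3p[0]:
                    raise ValidationError(
                        f"precursor {pid}: 5p arm ends after 3p arm starts"
                    )

    def __contains__(self, precursor_id: str) -> bool:
        return precursor_id in self._index

    def precursor(self, precursor_id: str) -> Precursor:
        try:
            return self._index[precursor_id]
        except KeyError:
            raise ValidationError(f"unknown precursor {precursor_id}") from None

    def length(self, precursor_id: str) -> int:
        return len(self.precursor(precursor_id))

    def arm_annotation(self, precursor_id: str) -> Optional[ArmAnnotation]:
        """Arm intervals for a precursor, or None if it is unannotated."""
        ann = self.arms.get(precursor_id)
        if ann is None or (ann.arm5p is None and ann.arm3p is None):
            return None
        return ann

    @property
    def precursor_ids(self) -> List[str]:
        return [p.precursor_id for p in self.precursors]

    @property
    def mature_names(self) -> List[str]:
        names = []
        for p in self.precursors:
            names.append(p.precursor_id + "-5p")
            names.append(p.precursor_id + "-3p")
        return names

    def chromosome_of_mature(self) -> pd.Series:
        chrom = {}
        for p in self.precursors:
            chrom[p.precursor_id + "-5p"] = p.chromosome
            chrom[p.precursor_id + "-3p"] = p.chromosome
        return pd.Series(chrom, name="chromosome")


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary read alignment against a precursor (0-based half-open)."""

    read_id: str
    precursor_id: str
    start: int
    end: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"alignment {self.read_id}: bad interval [{self.start},{self.end})"
            )


@dataclass
class TargetMap:
    """Validated (mature miRNA, target gene) pairs."""

    pairs: Set[Tuple[str, str]]

    def __post_init__(self) -> None:
        for mirna, _gene in self.pairs:
            if not _valid_mature_name(mirna):
                raise ValidationError(f"syntactically invalid miRNA name: {mirna!r}")

    def targets_of(self, mirna: str) -> Set[str]:
        return {g for m, g in self.pairs if m == mirna}

    def genes(self) -> Set[str]:
        return {g for _m, g in self.pairs}

    def mirnas(self) -> Set[str]:
        return {m for m, _g in self.pairs}


@dataclass
class GeneSetLibrary:
    sets: Dict[str, Set[str]]
    library_label: str = "custom"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _valid_mature_name(name: str) -> bool:
    # mature names end in -5p/-3p; a bare precursor name is also tolerated
    return bool(name) and not name.isspace()


# ---------------------------------------------------------------------------
# Reference FASTA + arm table
# ---------------------------------------------------------------------------

def read_reference(fasta_path, arm_table_path=None) -> MiRNAReference:
    """Load precursors from FASTA and optional arm annotations from TSV.

    The FASTA description may carry a ``chrom=<label>`` token; otherwise the
    chromosome is taken from the arm table, and defaults to ``"un"`` (unknown)
    for precursors mentioned in neither.
    """
    precursors: List[Tuple[str, str, Optional[str]]] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if not record.id:
            raise FormatError(f"{fasta_path}: FASTA record with empty header")
        chrom = None
        for token in record.description.split():
            if token.startswith("chrom="):
                chrom = token[len("chrom="):]
        precursors.append((record.id, str(record.seq).upper(), chrom))
    if not precursors:
        raise FormatError(f"{fasta_path}: no FASTA records")

    arm_rows = pd.DataFrame(columns=ARM_TABLE_COLUMNS)
    if arm_table_path is not None:
        arm_rows = pd.read_csv(arm_table_path, sep="\t", dtype={"precursor_id": str})
        missing = set(ARM_TABLE_COLUMNS) - set(arm_rows.columns)
        if missing:
            raise FormatError(f"{arm_table_path}: missing columns {sorted(missing)}")

    chrom_from_arms: Dict[str, str] = {}
    arms: Dict[str, ArmAnnotation] = {}
    by_prec: Dict[str, Dict[str, Interval]] = {}
    for row in arm_rows.itertuples(index=False):
        if row.arm not in ("5p", "3p"):
            raise FormatError(f"arm table: arm must be 5p or 3p, got {row.arm!r}")
        by_prec.setdefault(row.precursor_id, {})[row.arm] = (int(row.start), int(row.end))
        chrom_from_arms[row.precursor_id] = str(row.chromosome)
    for pid, d in by_prec.items():
        arms[pid] = ArmAnnotation(arm5p=d.get("5p"), arm3p=d.get("3p"))

    final = [
        Precursor(pid, seq, chrom or chrom_from_arms.get(pid, "un"))
        for pid, seq, chrom in precursors
    ]
    return MiRNAReference(precursors=final, arms=arms)


def write_reference(reference: MiRNAReference, fasta_path, arm_table_path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.precursor_id,
                  description=f"chrom={p.chromosome}")
        for p in reference.precursors
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for pid, ann in reference.arms.items():
        chrom = reference.precursor(pid).chromosome
        for arm, iv in (("5p", ann.arm5p), ("3p", ann.arm3p)):
            if iv is not None:
                rows.append((pid, arm, iv[0], iv[1], chrom))
    pd.DataFrame(rows, columns=ARM_TABLE_COLUMNS).to_csv(
        arm_table_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

def read_alignments(sam_path, reference: MiRNAReference,
                    stats: Optional[dict] = None) -> Iterator[AlignmentRecord]:
    """Stream primary mapped alignments from a SAM file.

    SAM 1-based POS is converted to a 0-based start; end = start + reference
    span from the CIGAR.  Unmapped, secondary and supplementary records are
    skipped and tallied in *stats* (and the log).
    """
    if stats is None:
        stats = {}
    stats.setdefault("yielded", 0)
    stats.setdefault("unmapped", 0)
    stats.setdefault("secondary", 0)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                stats["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats["secondary"] += 1
                continue
            rname = aln.reference_name
            if rname not in reference:
                raise ValidationError(
                    f"{sam_path}: alignment to unknown precursor {rname!r}"
                )
            stats["yielded"] += 1
            yield AlignmentRecord(
                read_id=aln.query_name,
                precursor_id=rname,
                start=aln.reference_start,
                end=aln.reference_end,
                is_primary=True,
            )
    skipped = stats["unmapped"] + stats["secondary"]
    if skipped:
        logger.info("%s: skipped %d non-primary/unmapped records", sam_path, skipped)


def write_sam(alignments: Iterable[AlignmentRecord], reference: MiRNAReference,
              sam_path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": p.precursor_id, "LN": len(p)} for p in reference.precursors
        ],
    }
    tid = {p.precursor_id: i for i, p in enumerate(reference.precursors)}
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for rec in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.precursor_id]
            a.reference_start = rec.start
            a.cigarstring = f"{rec.end - rec.start}M"
            a.flag = 0
            a.mapping_quality = 37
            a.query_sequence = reference.precursor(rec.precursor_id).sequence[
                rec.start:rec.end
            ].replace("U", "T")
            out.write(a)


# ---------------------------------------------------------------------------
# GMT gene-set libraries and target maps
# ---------------------------------------------------------------------------

def read_gmt(path, library_label: str = "custom") -> GeneSetLibrary:
    sets: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with no genes")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    lib = GeneSetLibrary(sets=sets, library_label=library_label)
    lib.descriptions = descriptions  # type: ignore[attr-defined]
    return lib


def write_gmt(library: GeneSetLibrary, path) -> None:
    descriptions = getattr(library, "descriptions", {})
    with open(path, "w") as handle:
        for name, members in library.sets.items():
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_target_map(path) -> TargetMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: target map needs >= 2 columns")
    pairs_list = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    pairs = set(pairs_list)
    if len(pairs) != len(pairs_list):
        logger.warning("%s: %d duplicate target pairs collapsed",
                       path, len(pairs_list) - len(pairs))
    return TargetMap(pairs=pairs)


def write_target_map(target_map: TargetMap, path) -> None:
    df = pd.DataFrame(sorted(target_map.pairs), columns=["mirna", "gene"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix round-trip (TSV; miRNA rows x sample columns)
# ---------------------------------------------------------------------------

def read_count_matrix(path):
    """Read an integer count matrix TSV into a CountMatrix."""
    from .quantify import CountMatrix  # deferred: quantify imports this module

    df = pd.read_csv(path, sep="\t", index_col=0)
    float_view = df.to_numpy()
    if not (float_view == float_view.astype(int)).all():
        raise FormatError(f"{path}: non-integer count cell")
    if (float_view < 0).any():
        raise FormatError(f"{path}: negative count cell")
    df = df.astype(int)
    df.index = df.index.astype(str)
    return CountMatrix(counts=df)


def write_count_matrix(matrix, path) -> None:
    counts = getattr(matrix, "counts", matrix)
    counts.to_csv(path, sep="\t", index_label="mirna")


# ---------------------------------------------------------------------------
# Questionnaire / cohort tables
# ---------------------------------------------------------------------------

def read_questionnaire(path) -> pd.DataFrame:
    """Read the subject questionnaire CSV (raw covariates, one row/subject)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: questionnaire needs a subject_id column")
    if df["subject_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject ids")
    return df.set_index(df["subject_id"].astype(str), drop=False)


def write_questionnaire(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df["subject_id"].astype(str), drop=False)
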