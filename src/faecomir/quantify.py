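"""Mature-miRNA annotation and quantification from precursor alignments.

Two assignment paths mirror how mature annotations are (or are not) available
for a hairpin precursor:

* knowledge-based — the 5p/3p arm intervals are annotated; a read is assigned
  to the arm with the larger base-pair overlap.
* position-based — no arm annotation; the read midpoint relative to the
  precursor midpoint decides the ``-5p`` / ``-3p`` suffix.

Reads overlapping neither arm, or splitting ties exactly, are dropped as
unassigned (never double-counted), so per-sample read accounting is exact:
assigned + unassigned = input alignments.

The module also carries the read pre-processing step (3' adapter removal by
an exhaustive cut-point edit-distance scan, with a minimum insert length) and
the merge of per-sample count vectors into a single mature count matrix over
the full reference mature-name space (two rows per precursor).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    MiRNAReference,
    ValidationError,
)

DEFAULT_MIN_READ_LENGTH = 14
DEFAULT_MAX_ERROR_RATE = 0.15


# ---------------------------------------------------------------------------
# Read trimming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimResult:
    sequence: str
    kept: bool


def _edit_distances_to_suffix(adapter: str, suffix: str) -> List[int]:
    """dist[L] = Levenshtein distance between adapter[:L] and the whole suffix."""
    m, n = len(adapter), len(suffix)
    prev = list(range(n + 1))
    out = [prev[n]]  # L = 0
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = adapter[i - 1]
        for j in range(1, n + 1):
            cost = 0 if ai == suffix[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        out.append(cur[n])
        prev = cur
    return out


def trim_adapter(read_seq: str, adapter_seq: str,
                 max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
                 min_length: int = DEFAULT_MIN_READ_LENGTH) -> TrimResult:
    """Remove a 3' adapter occurrence and everything downstream of it.

    Every cut point is scanned; at cut ``i`` the read suffix must be explained
    by a prefix of the adapter (the adapter may run off the 3' end) within an
    edit distance of ``floor(max_error_rate * matched_adapter_length)``
    counting mismatches, insertions and deletions.  Among acceptable
    occurrences the one explaining the most adapter bases net of errors wins
    (ties broken by fewest errors, then leftmost cut), so a full-length exact
    occurrence beats a short spurious suffix match.  Reads whose insert
    falls below *min_length* are flagged not kept.
    """
    if not adapter_seq:
        raise ValueError("adapter sequence must be non-empty")
    if not (0 <= max_error_rate < 1):
        raise ValueError("max_error_rate must be in [0, 1)")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")

    read = read_seq.upper()
    adapter = adapter_seq.upper()
    # candidate key: (-(L - dist), dist, i) minimized
    best: Optional[Tuple[int, int, int]] = None
    for i in range(len(read)):
        dists = _edit_distances_to_suffix(adapter, read[i:])
        for L in range(1, len(adapter) + 1):
            if dists[L] <= int(max_error_rate * L):
                key = (-(L - dists[L]), dists[L], i)
                if best is None or key < best:
                    best = key
    trimmed = read if best is None else read[:best[2]]
    return TrimResult(sequence=trimmed, kept=len(trimmed) >= min_length)


# ---------------------------------------------------------------------------
# Read -> mature-arm assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureAssignment:
    mature_name: Optional[str]
    method: Optional[str] = None          # "knowledge" | "position"
    unassigned_reason: Optional[str] = None  # "no_overlap" | "ambiguous"

    def __post_init__(self) -> None:
        if (self.mature_name is None) == (self.unassigned_reason is None):
            raise ValidationError(
                "exactly one of mature_name / unassigned_reason must be set"
            )


def _overlap(a_start: int, a_end: int, b: Optional[Tuple[int, int]]) -> int:
    if b is None:
        return 0
    return max(0, min(a_end, b[1]) - max(a_start, b[0]))


def assign_read(alignment: AlignmentRecord,
                reference: MiRNAReference) -> MatureAssignment:
    """Assign an aligned read to a mature arm of its precursor."""
    pid = alignment.precursor_id
    length = reference.length(pid)  # raises on unknown precursor
    ann = reference.arm_annotation(pid)
    if ann is not None:
        ov5 = _overlap(alignment.start, alignment.end, ann.arm5p)
        ov3 = _overlap(alignment.start, alignment.end, ann.arm3p)
        if ov5 == ov3 == 0:
            return MatureAssignment(None, unassigned_reason="no_overlap")
        if ov5 == ov3:
            return MatureAssignment(None, unassigned_reason="ambiguous")
        arm = "5p" if ov5 > ov3 else "3p"
        return MatureAssignment(f"{pid}-{arm}", method="knowledge")
    # position-based: compare midpoints (x2 to stay in integers)
    read_mid2 = alignment.start + alignment.end
    prec_mid2 = length
    if read_mid2 == prec_mid2:
        return MatureAssignment(None, unassigned_reason="ambiguous")
    arm = "5p" if read_mid2 < prec_mid2 else "3p"
    return MatureAssignment(f"{pid}-{arm}", method="position")


def quantify_sample(alignments: Iterable[AlignmentRecord],
                    reference: MiRNAReference) -> Tuple[pd.Series, Dict[str, int]]:
    """Count primary alignments per mature name for one sample.

    Returns the count vector over the full reference mature-name space and a
    log of totals: assigned reads plus per-reason unassigned tallies.
    """
    counts: Counter = Counter()
    log = {"assigned": 0, "no_overlap": 0, "ambiguous": 0}
    for aln in alignments:
        assignment = assign_read(aln, reference)
        if assignment.mature_name is None:
            log[assignment.unassigned_reason] += 1
        else:
            counts[assignment.mature_name] += 1
            log["assigned"] += 1
    vec = pd.Series(0, index=pd.Index(reference.mature_names, name="mirna"),
                    dtype=int)
    for name, n in counts.items():
        vec.loc[name] = n
    return vec, log


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer mature-miRNA x sample count matrix with optional normalization.

    ``normalized[i, j] = counts[i, j] / size_factors[j]`` once size factors
    have been attached (see :func:`faecomir.variability.size_factors`).
    """

    counts: pd.DataFrame
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate mature names")

    @property
    def mature_names(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValidationError("size factors not computed")
        return self.counts / self.size_factors

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        sf = None
        if self.size_factors is not None:
            sf = self.size_factors.loc[list(sample_ids)]
        return CountMatrix(self.counts.loc[:, list(sample_ids)], size_factors=sf)


def build_count_matrix(per_sample_counts: Mapping[str, Mapping[str, int]] |
                       Sequence[Tuple[str, Mapping[str, int]]],
                       reference: MiRNAReference) -> CountMatrix:
    """Merge per-sample count vectors into one matrix.

    Rows span the full reference mature-name space (2 x n_precursors) with
    zeros for undetected names; column order follows the input manifest.
    """
    if isinstance(per_sample_counts, Mapping):
        items = list(per_sample_counts.items())
    else:
        items = list(per_sample_counts)
    sample_ids = [sid for sid, _ in items]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample id in manifest")
    index = pd.Index(reference.mature_names, name="mirna")
    data = np.zeros((len(index), len(items)), dtype=int)
    pos = {name: i for i, name in enumerate(index)}
    for j, (_sid, vec) in enumerate(items):
        vec_items = vec.items() if hasattr(vec, "items") else vec
        for name, n in vec_items:
            if name not in pos:
                raise ValidationError(f"mature name {name!r} not in reference")
            data[pos[name], j] = int(n)
    return CountMatrix(counts=pd.DataFrame(data, index=index, columns=sample_ids))
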