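"""Per-nucleotide mutation-event counting from aligned MaP reads.

Reverse transcription across a SHAPE adduct leaves mismatches and small
indels in the cDNA.  This module parses each aligned read's CIGAR and
bases against the reference, classifies events into eight classes
(mismatch, insertion, deletion, their multi- variants, and two complex
classes for mixed merged events), and accumulates per-position event
counts and coverage.

Conventions
-----------
* Primitive events separated by at most ``merge_spacer`` (default 2)
  matched reference bases are merged: homogeneous groups become
  ``multi-*``; mixed groups are labelled by their net reference-length
  change (net loss -> complex-deletion, net gain -> complex-insertion,
  net zero -> multi-mismatch).
* Every event is anchored at its 3'-most reference position, the
  nucleotide the RT enzyme was traversing when it erred; insertions
  (which consume no reference) anchor at the base 5' of the inserted
  bases.
* Ambiguous deletions inside repeats are right-aligned (3'-most
  equivalent placement) before classification.
* Reads that are unmapped, secondary, supplementary, or have mapping
  quality 0 are excluded.  Soft-clipped bases contribute neither events
  nor coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUTATION_TYPES = (
    "mismatch", "insertion", "deletion",
    "multi-mismatch", "multi-insertion", "multi-deletion",
    "complex-insertion", "complex-deletion",
)

DEFAULT_MERGE_SPACER = 2

# CIGAR op codes (pysam numbering)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H = 0, 1, 2, 3, 4, 5
_OP_EQ, _OP_X = 7, 8


@dataclass(frozen=True)
class MutationEvent:
    """One (possibly merged) mutation event on a read.

    ``ref_position`` is the 1-based 3'-most reference position involved;
    ``ref_span`` the number of reference bases covered (0 for pure
    insertions); ``read_bases`` the read bases the event contributed.
    """

    ref_position: int
    mtype: str
    ref_span: int
    read_bases: str

    def __post_init__(self):
        if self.mtype not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mtype!r}")


def _dna(seq: str) -> str:
    """Normalize to the DNA alphabet (T == U): SAM stores reads as DNA."""
    return seq.upper().replace("U", "T")


@dataclass
class _Primitive:
    kind: str            # 'mismatch' | 'deletion' | 'insertion'
    ref_start: int       # 1-based; for insertions the 5' anchor base
    ref_end: int
    read_bases: str


@dataclass
class MutationCounts:
    """Per-position event counts by class plus aligned coverage."""

    transcript: str
    length: int
    coverage: np.ndarray = field(default=None)
    counts: dict[str, np.ndarray] = field(default=None)

    def __post_init__(self):
        if self.coverage is None:
            self.coverage = np.zeros(self.length, dtype=np.int64)
        if self.counts is None:
            self.counts = {m: np.zeros(self.length, dtype=np.int64)
                           for m in MUTATION_TYPES}

    @property
    def total_events(self) -> np.ndarray:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "transcript": self.transcript,
            "position": np.arange(1, self.length + 1),
            "coverage": self.coverage,
        })
        for m in MUTATION_TYPES:
            df[m] = self.counts[m]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationCounts":
        df = df.sort_values("position")
        out = cls(transcript=str(df["transcript"].iloc[0]), length=len(df))
        out.coverage = df["coverage"].to_numpy(np.int64)
        out.counts = {m: df[m].to_numpy(np.int64) for m in MUTATION_TYPES}
        return out

    def __add__(self, other: "MutationCounts") -> "MutationCounts":
        if self.length != other.length:
            raise ValueError("cannot combine counts of different lengths")
        out = MutationCounts(self.transcript, self.length)
        out.coverage = self.coverage + other.coverage
        out.counts = {m: self.counts[m] + other.counts[m]
                      for m in MUTATION_TYPES}
        return out


def _right_align_deletion(prim: _Primitive, reference: str) -> _Primitive:
    """Shift a deletion to its 3'-most equivalent placement in a repeat."""
    start, end = prim.ref_start, prim.ref_end
    while end < len(reference) and reference[start - 1] == reference[end]:
        start += 1
        end += 1
    if start == prim.ref_start:
        return prim
    return _Primitive("deletion", start, end, "")


def _extract_primitives(reference_start: int, cigartuples, query_sequence: str,
                        reference: str, read_name: str) -> list[_Primitive]:
    prims: list[_Primitive] = []
    ref_pos = reference_start  # 0-based
    read_pos = 0
    for op, length in cigartuples:
        if op in (_OP_M, _OP_EQ, _OP_X):
            if read_pos + length > len(query_sequence) \
                    or ref_pos + length > len(reference):
                raise ValueError(
                    f"read {read_name!r}: CIGAR/sequence length mismatch")
            for k in range(length):
                if query_sequence[read_pos + k] != reference[ref_pos + k]:
                    prims.append(_Primitive(
                        "mismatch", ref_pos + k + 1, ref_pos + k + 1,
                        query_sequence[read_pos + k]))
            ref_pos += length
            read_pos += length
        elif op == _OP_D:
            prims.append(_right_align_deletion(
                _Primitive("deletion", ref_pos + 1, ref_pos + length, ""),
                reference))
            ref_pos += length
        elif op == _OP_I:
            anchor = max(ref_pos, 1)  # base 5' of the insertion, 1-based
            prims.append(_Primitive(
                "insertion", anchor, anchor,
                query_sequence[read_pos:read_pos + length]))
            read_pos += length
        elif op == _OP_S:
            read_pos += length
        elif op == _OP_H:
            pass
        elif op == _OP_N:
            raise ValueError(
                f"read {read_name!r}: spliced (N) alignments are unsupported "
                "for small-RNA references")
        else:
            raise ValueError(f"read {read_name!r}: unsupported CIGAR op {op}")
    if read_pos != len(query_sequence):
        raise ValueError(
            f"read {read_name!r}: CIGAR consumes {read_pos} query bases "
            f"but sequence has {len(query_sequence)}")
    if ref_pos > len(reference):
        raise ValueError(f"read {read_name!r}: alignment runs off the reference")
    prims.sort(key=lambda p: (p.ref_start, p.ref_end))
    return prims


def _classify_group(group: list[_Primitive]) -> MutationEvent:
    kinds = {p.kind for p in group}
    ref_position = max(p.ref_end for p in group)
    pure_insertion = kinds == {"insertion"}
    ref_span = 0 if pure_insertion else (
        ref_position - min(p.ref_start for p in group) + 1)
    read_bases = "".join(p.read_bases for p in group)

    if len(kinds) == 1:
        kind = next(iter(kinds))
        if kind == "mismatch":
            n = len(group)
            mtype = "mismatch" if n == 1 else "multi-mismatch"
        elif kind == "deletion":
            span = sum(p.ref_end - p.ref_start + 1 for p in group)
            mtype = "deletion" if span == 1 and len(group) == 1 else "multi-deletion"
        else:
            n_ins = sum(len(p.read_bases) for p in group)
            mtype = "insertion" if n_ins == 1 and len(group) == 1 else "multi-insertion"
    else:
        # mixed classes: label by net reference-length change
        deleted = sum(p.ref_end - p.ref_start + 1
                      for p in group if p.kind == "deletion")
        inserted = sum(len(p.read_bases)
                       for p in group if p.kind == "insertion")
        if deleted > inserted:
            mtype = "complex-deletion"
        elif inserted > deleted:
            mtype = "complex-insertion"
        else:
            mtype = "multi-mismatch"
    return MutationEvent(ref_position, mtype, ref_span, read_bases)


def parse_read_mutations(read, reference: str,
                         merge_spacer: int = DEFAULT_MERGE_SPACER
                         ) -> list[MutationEvent]:
    """Parse one aligned read into classified mutation events (5'->3').

    ``read`` needs the pysam ``AlignedSegment`` attributes
    ``reference_start``, ``cigartuples``, ``query_sequence`` and
    ``query_name``; a perfect-match read yields an empty list.
    """
    prims = _extract_primitives(read.reference_start, read.cigartuples,
                                _dna(read.query_sequence), _dna(reference),
                                read.query_name)
    if not prims:
        return []
    groups: list[list[_Primitive]] = [[prims[0]]]
    for prim in prims[1:]:
        gap = prim.ref_start - groups[-1][-1].ref_end - 1
        if gap <= merge_spacer:
            groups[-1].append(prim)
        else:
            groups.append([prim])
    return [_classify_group(g) for g in groups]


def _aligned_reference_span(read) -> tuple[int, int]:
    """0-based half-open reference interval consumed by the alignment."""
    start = read.reference_start
    span = sum(ln for op, ln in read.cigartuples
               if op in (_OP_M, _OP_EQ, _OP_X, _OP_D, _OP_N))
    return start, start + span


def _read_is_usable(read, min_mapq: int) -> bool:
    if getattr(read, "is_unmapped", False):
        return False
    if getattr(read, "is_secondary", False) or getattr(read, "is_supplementary", False):
        return False
    return read.mapping_quality >= min_mapq


def count_mutations(reads, reference: str, transcript: str = "ref",
                    merge_spacer: int = DEFAULT_MERGE_SPACER,
                    min_mapq: int = 1) -> MutationCounts:
    """Accumulate per-position event counts and coverage over a read set.

    Coverage at a position is the number of usable reads whose alignment
    spans it (deleted positions included), so the summed coverage equals
    the summed aligned reference length over reads, exactly.
    """
    counts = MutationCounts(transcript, len(reference))
    for read in reads:
        if not _read_is_usable(read, min_mapq):
            continue
        start, end = _aligned_reference_span(read)
        counts.coverage[start:end] += 1
        for event in parse_read_mutations(read, reference, merge_spacer):
            counts.counts[event.mtype][event.ref_position - 1] += 1
    return counts


def count_mutations_sam(sam_path, references: dict[str, str],
                        merge_spacer: int = DEFAULT_MERGE_SPACER,
                        min_mapq: int = 1) -> dict[str, MutationCounts]:
    """Profile every reference in a SAM file (coordinate- or name-sorted)."""
    import pysam

    out = {name: MutationCounts(name, len(seq))
           for name, seq in references.items()}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.reference_name not in references:
                continue
            if not _read_is_usable(read, min_mapq):
                continue
            ref = references[read.reference_name]
            counts = out[read.reference_name]
            start, end = _aligned_reference_span(read)
            counts.coverage[start:end] += 1
            for event in parse_read_mutations(read, ref, merge_spacer):
                counts.counts[event.mtype][event.ref_position - 1] += 1
    return out


def mutation_rate(counts: MutationCounts, min_coverage: int = 1
                  ) -> np.ndarray:
    """Per-position mutation rate: all-class events over coverage.

    Positions below ``min_coverage`` are NaN (masked).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    cov = counts.coverage.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts.total_events / cov
    rate[counts.coverage < min_coverage] = np.nan
    return rate
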