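"""Secondary-structure container, feature extraction, and comparison.

A :class:`SecondaryStructure` holds a sequence plus a 1-based pair table
(0 = unpaired) and must be a pseudoknot-free involution with hairpin
loops of at least 3 nt.  Feature extraction identifies the terminal
(central) hairpin loop, classifies every internal single-stranded run as
terminal loop / internal loop / bulge, and assigns runs to the 5p or 3p
arm relative to the terminal loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_HAIRPIN_LOOP = 3

DIFF_IDENTICAL = "identical"
DIFF_SS_IN_A = "ss-in-a-paired-in-b"
DIFF_SS_IN_B = "paired-in-a-ss-in-b"
DIFF_DIFFERENT_PARTNER = "both-paired-different-partner"


def pair_table_from_dotbracket(db: str) -> np.ndarray:
    pt = np.zeros(len(db), dtype=int)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            pt[i] = j + 1
            pt[j] = i + 1
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pt


@dataclass
class SecondaryStructure:
    sequence: str
    pair_table: np.ndarray  # 1-based partner, 0 = unpaired

    def __post_init__(self):
        self.pair_table = np.asarray(self.pair_table, dtype=int)
        n = len(self.sequence)
        if len(self.pair_table) != n:
            raise ValueError("pair table length must match sequence")
        for i in range(n):
            j = self.pair_table[i]
            if j == 0:
                continue
            if not (1 <= j <= n) or j == i + 1:
                raise ValueError(f"invalid partner {j} at position {i + 1}")
            if self.pair_table[j - 1] != i + 1:
                raise ValueError(f"pairing is not an involution at {i + 1}")
            if abs(j - (i + 1)) - 1 < MIN_HAIRPIN_LOOP and j > i + 1:
                raise ValueError(
                    f"hairpin loop below {MIN_HAIRPIN_LOOP} nt at {i + 1}")
        # pseudoknot-free check via dot-bracket round trip
        self.to_dotbracket()

    @classmethod
    def from_dotbracket(cls, sequence: str, db: str) -> "SecondaryStructure":
        if len(sequence) != len(db):
            raise ValueError("sequence/structure length mismatch")
        return cls(sequence, pair_table_from_dotbracket(db))

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_table, start=1):
            if j == 0:
                out.append(".")
            elif j > i:
                out.append("(")
            else:
                out.append(")")
        db = "".join(out)
        # crossing pairs would fail to re-parse to the same table
        if not np.array_equal(pair_table_from_dotbracket(db), self.pair_table):
            raise ValueError("structure contains crossing pairs (pseudoknot)")
        return db

    def __len__(self) -> int:
        return len(self.sequence)

    def is_unpaired(self, pos: int) -> bool:
        """1-based query."""
        return self.pair_table[pos - 1] == 0

    # -- loops ------------------------------------------------------------

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """1-based inclusive spans of hairpin loops (closed unpaired runs)."""
        loops = []
        n = len(self.sequence)
        for i in range(1, n + 1):
            j = self.pair_table[i - 1]
            if j > i and np.all(self.pair_table[i:j - 1] == 0):
                loops.append((i + 1, j - 1))
        return loops

    def central_loop(self) -> tuple[int, int]:
        """The hairpin loop whose centre is nearest the sequence midpoint.

        Ties break toward the larger loop, then the 5'-most; raises when
        the structure has no hairpin loop at all.
        """
        loops = self.hairpin_loops()
        if not loops:
            raise ValueError("structure has no hairpin loop")
        mid = (len(self.sequence) + 1) / 2.0
        return min(loops, key=lambda sp: (abs((sp[0] + sp[1]) / 2.0 - mid),
                                          -(sp[1] - sp[0] + 1), sp[0]))

    def central_loop_center(self) -> int:
        """1-based centre of the central loop (floor midpoint for even sizes)."""
        start, end = self.central_loop()
        return start + (end - start) // 2


@dataclass
class SingleStrandedRegion:
    start: int   # 1-based inclusive
    end: int
    kind: str    # 'terminal-loop' | 'internal-loop' | 'bulge'
    arm: str     # '5p-arm' | '3p-arm' | 'loop'

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class StructureFeatures:
    terminal_loop: tuple[int, int]
    terminal_loop_size: int
    single_stranded_regions: list[SingleStrandedRegion]

    def bulges(self) -> list[SingleStrandedRegion]:
        return [r for r in self.single_stranded_regions if r.kind == "bulge"]


def extract_features(structure: SecondaryStructure) -> StructureFeatures:
    """Classify single-stranded runs and locate the terminal loop.

    The terminal loop is the central-loop-rule hairpin loop.  Each
    maximal internal unpaired run is a bulge when the flanking helices
    are directly stacked on the other strand (no unpaired opposite), a
    terminal loop when its flanks pair with each other, and an internal
    loop otherwise.  Exterior (dangling-end) runs are not listed.
    """
    pt = structure.pair_table
    n = len(structure)
    term = structure.central_loop()
    tstart, tend = term

    regions: list[SingleStrandedRegion] = []
    i = 1
    while i <= n:
        if pt[i - 1] != 0:
            i += 1
            continue
        start = i
        while i <= n and pt[i - 1] == 0:
            i += 1
        end = i - 1
        if start == 1 or end == n:
            continue  # exterior overhang
        left, right = pt[start - 2], pt[end]  # partners of flanking bases
        if left == end + 1:
            kind = "terminal-loop"
        elif right + 1 == left:
            kind = "bulge"
        else:
            kind = "internal-loop"
        if end < tstart:
            arm = "5p-arm"
        elif start > tend:
            arm = "3p-arm"
        else:
            arm = "loop"
        regions.append(SingleStrandedRegion(start, end, kind, arm))

    return StructureFeatures(term, tend - tstart + 1, regions)


def compare_structures(a: SecondaryStructure, b: SecondaryStructure
                       ) -> list[str]:
    """Per-position difference class between two structures.

    Classes partition the positions: identical (same pairing status and,
    when paired, the same partner), single-stranded in a / paired in b,
    the converse, and paired in both with different partners.
    """
    if len(a) != len(b):
        raise ValueError("structures differ in length")
    out = []
    for pa, pb in zip(a.pair_table, b.pair_table):
        if pa == pb:
            out.append(DIFF_IDENTICAL)
        elif pa == 0:
            out.append(DIFF_SS_IN_A)
        elif pb == 0:
            out.append(DIFF_SS_IN_B)
        else:
            out.append(DIFF_DIFFERENT_PARTNER)
    return out
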