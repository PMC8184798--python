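"""Synthetic data generators for the whole pipeline.

Everything the pipeline consumes can be generated here with known ground
truth: hairpin references with their true structures, full-length MaP
reads carrying structure-dependent mutation rates (NAI-treated vs DMSO
control), two-condition count tables with planted log2 effects, idealized
helical coordinate models, and reactivity-profile archetypes for the
clustering stage.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import CoordinateModel

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
BASES = ("A", "C", "G", "U")

# mutation-type mixture for simulated events: mismatches dominate observed
# MaP signal; indels are kept rare and 1-nt (the parser's multi-nt and
# complex classes are exercised by hand-built reads, not by this model)
MUT_TYPE_PROBS = {"mismatch": 0.70, "deletion": 0.15, "insertion": 0.15}


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the synthetic MaP cohort.

    Rates are per-nucleotide event probabilities: ``mod_rate_ss`` at
    single-stranded positions and ``mod_rate_ds`` at paired positions in
    the NAI library (on top of ``background_rate``, which is all the DMSO
    library carries).
    """

    n_transcripts: int = 50
    stem_len: int = 15
    loop_len: int = 9
    mod_rate_ss: float = 0.02
    mod_rate_ds: float = 0.002
    background_rate: float = 0.002
    depth: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.background_rate <= self.mod_rate_ds
                <= self.mod_rate_ss <= 1.0):
            raise ValueError(
                "require 0 <= background_rate <= mod_rate_ds <= mod_rate_ss <= 1"
            )
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.loop_len < 3:
            raise ValueError("hairpin loops need at least 3 nt")
        if self.stem_len < 1 or self.n_transcripts < 1:
            raise ValueError("stem_len and n_transcripts must be >= 1")


@dataclass(frozen=True)
class HelixSpec:
    """Idealized double-helix geometry (A-form-like defaults).

    These are test-fixture constants describing a regular cylinder
    model, not a claim about real RNA geometry.
    """

    n_bp: int = 22
    rise: float = 2.81
    twist: float = 32.7
    radius: float = 9.0
    phase_deg: float = 150.0  # strand-2 angular offset; arbitrary, recorded

    def __post_init__(self):
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")
        if not (0.0 < self.twist < 180.0):
            raise ValueError("twist must be in (0, 180) degrees")

    def chord_distance(self, n_steps: int) -> float:
        """Closed-form distance between cylinder points n steps apart."""
        theta = np.deg2rad(self.twist) * n_steps / 2.0
        return float(np.hypot(n_steps * self.rise,
                              2.0 * self.radius * np.sin(theta)))


def make_hairpin_set(spec: SimSpec) -> list[tuple[str, str, str]]:
    """Generate hairpin references as (name, sequence, dot-bracket) triples.

    Each hairpin is a perfect Watson-Crick stem of ``stem_len`` closed by
    an unpaired loop of ``loop_len``.  Loop bases are drawn from {A, C}
    only, so the loop cannot base-pair and each sequence folds to its
    emitted dot-bracket by construction.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    db = "(" * spec.stem_len + "." * spec.loop_len + ")" * spec.stem_len
    for t in range(spec.n_transcripts):
        stem5 = rng.choice(BASES, size=spec.stem_len)
        loop = rng.choice(["A", "C"], size=spec.loop_len)
        stem3 = [WC_COMPLEMENT[b] for b in stem5[::-1]]
        seq = "".join(stem5) + "".join(loop) + "".join(stem3)
        out.append((f"hairpin_{t + 1:04d}", seq, db))
    return out


class SimulatedRead:
    """A full-length aligned read, attribute-compatible with the parser.

    Exposes the subset of the pysam ``AlignedSegment`` interface the
    mutation parser consumes, so simulated reads can be profiled without
    a round-trip through a SAM file (writing one is still supported).
    """

    # pysam CIGAR op codes
    CIGAR_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}
    _OP_CHARS = {v: k for k, v in CIGAR_OPS.items()}

    def __init__(self, query_name: str, reference_name: str,
                 reference_start: int, cigartuples: list[tuple[int, int]],
                 query_sequence: str, mapping_quality: int = 60, flag: int = 0):
        self.query_name = query_name
        self.reference_name = reference_name
        self.reference_start = reference_start
        self.cigartuples = list(cigartuples)
        self.query_sequence = query_sequence
        self.mapping_quality = mapping_quality
        self.flag = flag

    @property
    def is_unmapped(self):
        return bool(self.flag & 0x4)

    @property
    def is_secondary(self):
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self):
        return bool(self.flag & 0x800)

    @property
    def cigarstring(self) -> str:
        return "".join(f"{ln}{self._OP_CHARS[op]}" for op, ln in self.cigartuples)


def _append_op(cigar: list[tuple[int, int]], op: int, length: int = 1) -> None:
    if cigar and cigar[-1][0] == op:
        cigar[-1] = (op, cigar[-1][1] + length)
    else:
        cigar.append((op, length))


def simulate_map_reads(reference: str, structure: str, spec: SimSpec,
                       condition: str, name: str = "ref",
                       rng: np.random.Generator | None = None,
                       depth: int | None = None) -> list[SimulatedRead]:
    """Simulate full-length MaP reads over one reference.

    Per-position event probability is ``mod_rate`` (ss or ds by the
    position's pairedness) plus ``background_rate`` under NAI, and
    ``background_rate`` alone under DMSO.  Event types follow the fixed
    mixture 70% mismatch / 15% 1-nt deletion / 15% 1-nt insertion, with
    insertions placed immediately 3' of the event position.
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    if len(structure) != len(reference):
        raise ValueError("structure length must equal sequence length")
    if condition not in ("NAI", "DMSO"):
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        # decorrelate transcripts and conditions under one spec seed
        salt = zlib.crc32(f"{name}/{condition}".encode()) % (2 ** 20)
        rng = np.random.default_rng((spec.seed, salt))
    depth = spec.depth if depth is None else depth

    length = len(reference)
    unpaired = np.array([c == "." for c in structure])
    if condition == "NAI":
        p = np.where(unpaired, spec.mod_rate_ss, spec.mod_rate_ds) \
            + spec.background_rate
    else:
        p = np.full(length, spec.background_rate)
    p = np.clip(p, 0.0, 1.0)

    type_names = list(MUT_TYPE_PROBS)
    type_probs = np.array([MUT_TYPE_PROBS[t] for t in type_names])

    reads = []
    mutated = rng.random((depth, length)) < p[None, :]
    for ridx in range(depth):
        positions = np.nonzero(mutated[ridx])[0]
        if positions.size == 0:
            reads.append(SimulatedRead(
                f"{name}/{condition}/{ridx + 1}", name, 0,
                [(0, length)], reference))
            continue
        posset = set(positions.tolist())
        seq_parts: list[str] = []
        cigar: list[tuple[int, int]] = []
        for i, base in enumerate(reference):
            if i not in posset:
                seq_parts.append(base)
                _append_op(cigar, 0)
                continue
            mtype = type_names[rng.choice(len(type_names), p=type_probs)]
            if mtype == "mismatch":
                alt = BASES[rng.integers(4)]
                while alt == base:
                    alt = BASES[rng.integers(4)]
                seq_parts.append(alt)
                _append_op(cigar, 0)
            elif mtype == "deletion":
                _append_op(cigar, 2)
            else:  # insertion anchored 5' at this position
                seq_parts.append(base)
                _append_op(cigar, 0)
                seq_parts.append(BASES[rng.integers(4)])
                _append_op(cigar, 1)
        reads.append(SimulatedRead(
            f"{name}/{condition}/{ridx + 1}", name, 0, cigar,
            "".join(seq_parts)))
    return reads


def write_sam(path, references: dict[str, str],
              reads: list[SimulatedRead]) -> None:
    """Write simulated reads as a plain-text SAM file with @SQ header lines."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in references.items()],
    }
    tid = {n: i for i, n in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.query_name
            a.query_sequence = read.query_sequence
            a.flag = read.flag
            a.reference_id = tid[read.reference_name]
            a.reference_start = read.reference_start
            a.mapping_quality = read.mapping_quality
            a.cigartuples = read.cigartuples
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(read.query_sequence))
            out.write(a)


def simulate_count_tables(n_transcripts: int, planted_log2_effects,
                          total_reads: int, seed: int,
                          proportions=None) -> pd.DataFrame:
    """Two-condition multinomial count table with planted log2 effects.

    Condition-B transcript proportions equal condition-A proportions
    scaled by ``2**effect`` and renormalized; both conditions are then
    sampled multinomially at ``total_reads``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    effects = np.asarray(planted_log2_effects, dtype=float)
    if effects.shape != (n_transcripts,):
        raise ValueError("planted_log2_effects must have one value per transcript")
    if not np.all(np.isfinite(effects)):
        raise ValueError("planted effects must be finite")

    rng = np.random.default_rng(seed)
    if proportions is None:
        props_a = rng.dirichlet(np.ones(n_transcripts))
    else:
        props_a = np.asarray(proportions, dtype=float)
        props_a = props_a / props_a.sum()
    props_b = props_a * np.exp2(effects)
    props_b = props_b / props_b.sum()

    return pd.DataFrame({
        "transcript": [f"tx_{i + 1:04d}" for i in range(n_transcripts)],
        "count_a": rng.multinomial(total_reads, props_a),
        "count_b": rng.multinomial(total_reads, props_b),
        "true_log2_effect": effects,
    })


def build_helix_coordinates(spec: HelixSpec,
                            energy: float | None = None) -> CoordinateModel:
    """Place one tracked point per residue per strand on a cylinder.

    Strand 1 residue k sits at angle (k-1)*twist and height (k-1)*rise;
    strand 2 is antiparallel (chain numbering continues 3'->5' down the
    helix) with a fixed ``phase_deg`` angular offset.  C5' and O3' of a
    residue are coincident at the tracked point, so chord distances
    between residues n steps apart on one strand follow
    d(n) = sqrt((n*rise)^2 + (2*radius*sin(n*twist/2))^2) exactly.
    """
    model = CoordinateModel(name="ideal_helix", energy=energy)
    twist = np.deg2rad(spec.twist)
    phase = np.deg2rad(spec.phase_deg)
    n = spec.n_bp
    for k in range(1, n + 1):
        theta = (k - 1) * twist
        z = (k - 1) * spec.rise
        xyz = (spec.radius * np.cos(theta), spec.radius * np.sin(theta), z)
        model.set_atom(k, "C5'", xyz)
        model.set_atom(k, "O3'", xyz)
        # strand-2 partner of k, chain index continues antiparallel
        r2 = 2 * n + 1 - k
        xyz2 = (spec.radius * np.cos(theta + phase),
                spec.radius * np.sin(theta + phase), z)
        model.set_atom(r2, "C5'", xyz2)
        model.set_atom(r2, "O3'", xyz2)
    return model


def make_model_ensemble(spec: HelixSpec, n_models: int, sigma: float,
                        seed: int) -> list[CoordinateModel]:
    """Jittered copies of the ideal helix, ranked by a synthetic energy.

    Stands in for an ensemble of predicted tertiary models: model i gets
    energy -n_models + i so the ranking is well-defined and the first
    models are the 'lowest-energy' ones.
    """
    rng = np.random.default_rng(seed)
    base = build_helix_coordinates(spec)
    out = []
    for i in range(n_models):
        m = base.jittered(sigma, rng)
        m.name = f"model_{i + 1}"
        m.energy = float(-n_models + i)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# reactivity-profile archetypes for the clustering stage

ARCHETYPES = ("hairpin-like", "loose-stem", "chessboard")


def _archetype_window(kind: str) -> np.ndarray:
    """60-value archetype over loop-centred columns -30..-1, +1..+30."""
    offsets = np.array(list(range(-30, 0)) + list(range(1, 31)))
    if kind == "hairpin-like":
        # high reactivity in the central +/-5, near-paired flanks
        return np.where(np.abs(offsets) <= 5, 1.5, 0.1)
    if kind == "loose-stem":
        return np.where(np.abs(offsets) <= 8, 0.8, 0.5)
    if kind == "chessboard":
        return np.where(offsets % 2 == 0, 1.2, 0.1)
    raise ValueError(f"unknown archetype {kind!r}")


def simulate_profile_archetypes(n_per: int = 60, noise: float = 0.2,
                                seed: int = 0):
    """Transcripts realizing the three structure-profile archetypes.

    Returns ``(records, labels)`` where each record is
    ``(name, sequence, dot_bracket, scores)`` for a 75-nt hairpin whose
    central loop centre sits at position 38, so the loop-centred 60-nt
    window is fully inside the transcript; ``labels`` are archetype
    indices 0/1/2.  Scores are the archetype window plus N(0, noise).
    """
    rng = np.random.default_rng(seed)
    stem, loop = 33, 9
    db = "(" * stem + "." * loop + ")" * stem
    center = stem + (loop - 1) // 2 + 1  # 1-based = 38
    cols = np.array(list(range(-30, 0)) + list(range(1, 31))) + center - 1

    records, labels = [], []
    for kind_idx, kind in enumerate(ARCHETYPES):
        window = _archetype_window(kind)
        for t in range(n_per):
            stem5 = rng.choice(BASES, size=stem)
            seq = ("".join(stem5) + "".join(rng.choice(["A", "C"], size=loop))
                   + "".join(WC_COMPLEMENT[b] for b in stem5[::-1]))
            scores = np.full(len(seq), 0.2)
            scores[cols] = window
            scores = scores + rng.normal(0.0, noise, size=len(seq))
            records.append((f"{kind}_{t + 1:03d}", seq, db, scores))
            labels.append(kind_idx)
    return records, np.array(labels)
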