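"""Dicer cleavage-site rule classification on pre-miRNA hairpins.

Three cleavage-site selection rules are evaluated per annotated
pre-miRNA:

* loop counting — the first nucleotide of the 3p miRNA lies exactly two
  paired nucleotides downstream of a single-stranded bulge/loop on the
  3p arm (operationalized: positions p-1 and p-2 paired, p-3
  single-stranded); the 5p variant asks for the position immediately 3'
  of the 5p miRNA's last nucleotide to be single-stranded (the "0 nt"
  case of the same family);
* 3' counting — the spatial distance D_3p_miRNA from the C5' atom of
  the 3p miRNA's first nucleotide to the O3' atom of the pre-miRNA's
  last nucleotide lies within 59 +/- 1 Angstrom (the span of Dicer's
  PAZ-to-RNase IIIa arm in the cryo-EM complex motivates the target);
* 5' counting — likewise for D_5p_miRNA, C5' of nucleotide 1 to O3' of
  the 5p miRNA's last nucleotide.

Distances are medians over an ensemble of coordinate models (the 50
lowest-energy models when more are supplied).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import CoordinateModel
from .secondary import SecondaryStructure

logger = logging.getLogger(__name__)

DEFAULT_TARGET = 59.0  # Angstrom
DEFAULT_TOL = 1.0
MAX_MODELS = 50


@dataclass(frozen=True)
class MirnaAnnotation:
    """A pre-miRNA with its mature 5p/3p spans (1-based inclusive)."""

    name: str
    sequence: str
    span_5p: tuple[int, int]
    span_3p: tuple[int, int]
    isoform_offsets: tuple[int, ...] = (-1, 0, 1)

    def __post_init__(self):
        n = len(self.sequence)
        for span in (self.span_5p, self.span_3p):
            if not (1 <= span[0] <= span[1] <= n):
                raise ValueError(f"{self.name}: span {span} outside sequence")
        if self.span_5p[1] >= self.span_3p[0]:
            raise ValueError(f"{self.name}: 5p span must lie 5' of the 3p span")


@dataclass
class DicingDistances:
    """Median C5'->O3' distances (Angstrom) over the model ensemble."""

    d_5p_mirna: float
    d_3p_mirna: float
    d_5p_arm: float = field(default=np.nan)
    d_3p_arm: float = field(default=np.nan)


def terminus_distance(model: CoordinateModel, from_residue: int,
                      to_residue: int) -> float:
    """Euclidean distance from C5' of ``from_residue`` to O3' of
    ``to_residue``, in Angstrom."""
    try:
        a = model.atom(from_residue, "C5'")
        b = model.atom(to_residue, "O3'")
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    return float(np.linalg.norm(a - b))


def _select_models(models: list[CoordinateModel]) -> list[CoordinateModel]:
    if len(models) <= MAX_MODELS:
        return models
    if any(m.energy is None for m in models):
        warnings.warn("model energies absent; using all models instead of "
                      f"the {MAX_MODELS} lowest-energy ones")
        return models
    return sorted(models, key=lambda m: m.energy)[:MAX_MODELS]


def dicing_distances(models: list[CoordinateModel],
                     annotation: MirnaAnnotation,
                     structure: SecondaryStructure | None = None
                     ) -> DicingDistances:
    """Median dicing distances over a model ensemble.

    D_5p_miRNA: C5' of pre-miRNA nt 1 -> O3' of the 5p span's last nt.
    D_3p_miRNA: C5' of the 3p span's first nt -> O3' of the last pre-miRNA nt.
    Arm distances use the nucleotides bordering the terminal loop and
    need ``structure``; they are NaN when it is absent.
    """
    if not models:
        raise ValueError("need at least one coordinate model")
    models = _select_models(models)
    length = len(annotation.sequence)
    d5 = [terminus_distance(m, 1, annotation.span_5p[1]) for m in models]
    d3 = [terminus_distance(m, annotation.span_3p[0], length) for m in models]
    out = DicingDistances(float(np.median(d5)), float(np.median(d3)))
    if structure is not None:
        loop_start, loop_end = structure.central_loop()
        d5a = [terminus_distance(m, 1, loop_start - 1) for m in models]
        d3a = [terminus_distance(m, loop_end + 1, length) for m in models]
        out.d_5p_arm = float(np.median(d5a))
        out.d_3p_arm = float(np.median(d3a))
    return out


def loop_counting_check(structure: SecondaryStructure,
                        annotation: MirnaAnnotation) -> dict[str, bool]:
    """Evaluate the loop counting rule on both arms.

    ``rule_3p``: for p = first nt of the 3p span, p-1 and p-2 are paired
    and p-3 is single-stranded — exactly two paired nucleotides between
    the nearest upstream single-stranded region and the cleavage site.
    ``rule_5p``: the position immediately 3' of the 5p span's last nt is
    single-stranded (the zero-spacing member of the same family).
    """
    if len(structure) != len(annotation.sequence):
        raise ValueError("structure and annotation sequence lengths differ")
    p = annotation.span_3p[0]
    if p - 3 < 1:
        logger.info("%s: 3p span too close to the 5' end for the rule",
                    annotation.name)
        rule_3p = False
    else:
        rule_3p = (not structure.is_unpaired(p - 1)
                   and not structure.is_unpaired(p - 2)
                   and structure.is_unpaired(p - 3))
    q = annotation.span_5p[1]
    if q + 1 > len(structure):
        logger.info("%s: 5p span touches the sequence end", annotation.name)
        rule_5p = False
    else:
        rule_5p = structure.is_unpaired(q + 1)
    return {"rule_3p": bool(rule_3p), "rule_5p": bool(rule_5p)}


def classify_rules(distances: DicingDistances, loop_check: dict[str, bool],
                   target: float = DEFAULT_TARGET,
                   tol: float = DEFAULT_TOL) -> dict[str, bool]:
    """Venn-cell membership across the three cleavage-site rules."""
    return {
        "loop_counting": bool(loop_check["rule_3p"]),
        "three_prime": bool(abs(distances.d_3p_mirna - target) <= tol),
        "five_prime": bool(abs(distances.d_5p_mirna - target) <= tol),
    }


def compare_isoforms(models_by_offset: dict[int, list[CoordinateModel]],
                     annotation: MirnaAnnotation,
                     counts_by_offset: dict[int, float],
                     target: float = DEFAULT_TARGET,
                     tol: float = DEFAULT_TOL):
    """Rank 3p-end isoforms by |D_3p_miRNA - target| vs expression share.

    Each offset shifts the 3p miRNA's annotated 5' end (the Dicer
    cleavage site); its D_3p_miRNA is measured on that offset's model
    ensemble.  Returns ``(table, summary)`` where the summary reports
    whether the annotated (offset 0) isoform minimizes the deviation and
    the total expression share of isoforms within target +/- tol.
    """
    offsets = sorted(models_by_offset)
    if len(offsets) < 2:
        raise ValueError("need at least two isoforms")
    total = float(sum(counts_by_offset.get(o, 0.0) for o in offsets))
    if total <= 0:
        raise ValueError("zero total isoform counts")
    length = len(annotation.sequence)
    rows = []
    for offset in offsets:
        p = annotation.span_3p[0] + offset
        if not (1 <= p <= length):
            raise ValueError(f"offset {offset} moves the 3p start off-sequence")
        models = _select_models(models_by_offset[offset])
        d3 = float(np.median([terminus_distance(m, p, length) for m in models]))
        rows.append({
            "offset": offset,
            "d_3p_mirna": d3,
            "abs_deviation": abs(d3 - target),
            "share": counts_by_offset.get(offset, 0.0) / total,
        })
    table = pd.DataFrame(rows)
    best = table.loc[table["abs_deviation"].idxmin(), "offset"]
    in_range = table["abs_deviation"] <= tol
    summary = {
        "annotated_is_closest": bool(best == 0),
        "in_range_share": float(table.loc[in_range, "share"].sum()),
    }
    return table, summary


def rule_table(entries, target: float = DEFAULT_TARGET,
               tol: float = DEFAULT_TOL) -> pd.DataFrame:
    """Per-pre-miRNA rule table from (annotation, structure, models) triples."""
    rows = []
    for annotation, structure, models in entries:
        dist = dicing_distances(models, annotation, structure)
        loop = loop_counting_check(structure, annotation)
        rules = classify_rules(dist, loop, target, tol)
        rows.append({
            "pre_mirna": annotation.name,
            "d_5p_mirna": dist.d_5p_mirna,
            "d_3p_mirna": dist.d_3p_mirna,
            "d_5p_arm": dist.d_5p_arm,
            "d_3p_arm": dist.d_3p_arm,
            "rule_3p_loop": loop["rule_3p"],
            "rule_5p_loop": loop["rule_5p"],
            **rules,
        })
    return pd.DataFrame(rows)
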