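"""File-format helpers shared across the pipeline.

Plain-text dialects only: FASTA references, dot-bracket files, CT files,
SHAPE reactivity files (``position score``, null encoded as -999), and
TSV tables with ``#``-prefixed metadata headers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SHAPE_NULL = -999.0


def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_dotbracket(path) -> dict[str, tuple[str, str]]:
    """Read a multi-record dot-bracket file (>name / sequence / structure)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1} of {path}")
        name = lines[i][1:].split()[0]
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(f"sequence/structure length mismatch for {name}")
        out[name] = (seq, db)
        i += 3
    return out


def write_dotbracket(path, records: Mapping[str, tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, (seq, db) in records.items():
            fh.write(f">{name}\n{seq}\n{db}\n")


def write_shape(path, scores) -> None:
    """Write a SHAPE reactivity file: 1-based position, score, null as -999."""
    scores = np.asarray(scores, dtype=float)
    with open(path, "w") as fh:
        for i, s in enumerate(scores, start=1):
            val = SHAPE_NULL if not np.isfinite(s) else s
            fh.write(f"{i}\t{val:.6f}\n")


def read_shape(path) -> np.ndarray:
    pos: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            pos.append(int(parts[0]))
            vals.append(float(parts[1]))
    n = max(pos) if pos else 0
    out = np.full(n, np.nan)
    for p, v in zip(pos, vals):
        out[p - 1] = np.nan if v <= SHAPE_NULL else v
    return out


def write_ct(path, name: str, sequence: str, pair_table) -> None:
    """Write a CT file; pair_table is 1-based partner indices, 0 = unpaired."""
    n = len(sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\t{name}\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i}\t{sequence[i - 1]}\t{i - 1}\t{(i + 1) % (n + 1)}\t"
                f"{int(pair_table[i - 1])}\t{i}\n"
            )


def read_ct(path) -> tuple[str, str, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        name = header[1] if len(header) > 1 else ""
        seq = []
        pt = np.zeros(n, dtype=int)
        for _ in range(n):
            parts = fh.readline().split()
            idx = int(parts[0])
            seq.append(parts[1])
            pt[idx - 1] = int(parts[4])
    return name, "".join(seq), pt


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """Write a TSV with '#'-prefixed metadata header lines (no timestamps)."""
    buf = _io.StringIO()
    for key, value in (meta or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=index, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
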