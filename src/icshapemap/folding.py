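"""SHAPE-constrained minimum-free-energy secondary-structure prediction.

A self-contained nearest-neighbor energy model with a Zuker-style
dynamic program.  The model is deliberately simplified — Watson-Crick
and GU wobble stack free energies from the standard published tables,
hairpin / bulge / internal-loop initiation by declared lookups with
logarithmic extrapolation, linear multiloop penalties, no dangles, no
coaxial stacking, 37 C, kcal/mol — because the contribution it carries
is the reactivity constraint: each paired nucleotide i adds the Deigan
pseudo-energy

    dG_SHAPE(i) = m * ln(s_i + 1) + b        (m = 1.8, b = -0.6)

with negative s_i treated as 0 and null s_i contributing 0.  With no
profile the fold reduces to the unconstrained MFE.  The DP and the
independent re-scorer :func:`score_structure` implement the identical
model, so exhaustive enumeration over small sequences is an exact
oracle for the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .secondary import MIN_HAIRPIN_LOOP, SecondaryStructure

INF = float("inf")
MAXLOOP = 30          # max unpaired nt in a bulge/internal loop
_LOG_EXTRAP = 1.078   # ~1.75 * R * T at 37 C, kcal/mol

ALLOWED_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}

# stack step free energies, key (pair_ij, pair_kl) where pair_ij = s_i s_j
# closes the stack and pair_kl = s_{i+1} s_{j-1} continues the helix;
# Watson-Crick values follow the standard published set, wobble values a
# declared table; closed under the duplex rotation symmetry
# (p, q) == (reverse(q), reverse(p)).
_STACK_SEED = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24,
    ("CG", "CG"): -3.26, ("CG", "GC"): -2.36, ("GC", "CG"): -3.42,
    ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.27, ("UA", "UG"): -1.00,
    ("CG", "GU"): -1.41, ("CG", "UG"): -2.11,
    ("GC", "GU"): -2.51, ("GC", "UG"): -1.53,
    ("GU", "GU"): -0.50, ("GU", "UG"): +0.47, ("UG", "GU"): -0.30,
}


def _build_stack_table() -> dict[tuple[str, str], float]:
    table = dict(_STACK_SEED)
    for (p, q), e in _STACK_SEED.items():
        table[(q[::-1], p[::-1])] = e
    for p in ALLOWED_PAIRS:
        for q in ALLOWED_PAIRS:
            if (p, q) not in table:
                raise AssertionError(f"stack table incomplete: {(p, q)}")
    return table

STACK = _build_stack_table()

HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}

MULTI_CLOSE = 3.4     # multiloop closing penalty (a)
MULTI_BRANCH = 0.4    # per interior branch (b)
MULTI_UNPAIRED = 0.0  # per unpaired multiloop nt (c)


def _loop_energy(table: dict[int, float], n: int) -> float:
    nmax = max(table)
    if n <= nmax:
        return table[n]
    return table[nmax] + _LOG_EXTRAP * math.log(n / nmax)


def hairpin_energy(n_unpaired: int) -> float:
    return _loop_energy(HAIRPIN_INIT, n_unpaired)


def bulge_energy(n_unpaired: int) -> float:
    return _loop_energy(BULGE_INIT, n_unpaired)


def internal_energy(n_unpaired: int) -> float:
    return _loop_energy(INTERNAL_INIT, n_unpaired)


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Deigan pseudo-energy slope/intercept, kcal/mol."""

    slope: float = 1.8
    intercept: float = -0.6

    def energy(self, score: float) -> float:
        """Per-paired-nucleotide penalty; null (NaN) contributes 0."""
        if score is None or not np.isfinite(score):
            return 0.0
        return self.slope * math.log(max(score, 0.0) + 1.0) + self.intercept


def _shape_vector(n: int, profile, params: PseudoEnergyParams) -> np.ndarray:
    if profile is None:
        return np.zeros(n)
    scores = profile.scores if hasattr(profile, "scores") else np.asarray(profile, float)
    if len(scores) != n:
        raise ValueError("profile length must match sequence length")
    return np.array([params.energy(s) for s in scores])


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def can_pair(a: str, b: str) -> bool:
    return a + b in ALLOWED_PAIRS


# ---------------------------------------------------------------------------
# independent re-scorer (shared energy model, no DP)


def score_structure(structure: SecondaryStructure, profile=None,
                    params: PseudoEnergyParams = PseudoEnergyParams()
                    ) -> float:
    """Total free energy of a given structure under the module's model.

    Decomposes the structure into loops (hairpin, stack, bulge, internal,
    multiloop, exterior) and sums their terms plus one pseudo-energy per
    paired nucleotide.  Independent of the folding recursions.
    """
    seq = _normalize_sequence(structure.sequence)
    pt = structure.pair_table
    n = len(seq)
    sh = _shape_vector(n, profile, params)

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if pt[k - 1] == 0:
                unpaired += 1
                k += 1
            else:
                kids.append((k, int(pt[k - 1])))
                k = int(pt[k - 1]) + 1
        return kids, unpaired

    energy = 0.0
    for i in range(1, n + 1):
        j = int(pt[i - 1])
        if j <= i:
            continue
        if not can_pair(seq[i - 1], seq[j - 1]):
            return INF
        energy += sh[i - 1] + sh[j - 1]
        kids, unpaired = children_of(i, j)
        if not kids:
            energy += hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                energy += STACK[(seq[i - 1] + seq[j - 1],
                                 seq[k - 1] + seq[l - 1])]
            elif n1 == 0 or n2 == 0:
                energy += bulge_energy(n1 + n2)
            else:
                energy += internal_energy(n1 + n2)
        else:
            energy += (MULTI_CLOSE + MULTI_BRANCH * len(kids)
                       + MULTI_UNPAIRED * unpaired)
    return energy


# ---------------------------------------------------------------------------
# the dynamic program


class _Fold:
    def __init__(self, seq: str, sh: np.ndarray):
        self.seq = seq
        self.sh = sh
        n = self.n = len(seq)
        self.V = np.full((n, n), INF)
        self.WM = np.full((n, n), INF)    # >=1 branch inside a multiloop
        self.WM2 = np.full((n, n), INF)   # >=2 branches
        self.W = np.zeros(n)
        self.pairable = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                self.pairable[i, j] = can_pair(seq[i], seq[j])
        self._fill()

    # V candidates ------------------------------------------------------

    def _v_candidates(self, i: int, j: int):
        """Yield (energy, kind, payload) options for pair (i, j), 0-based."""
        base = self.sh[i] + self.sh[j]
        yield base + hairpin_energy(j - i - 1), "hairpin", None
        for k in range(i + 1, j):
            n1 = k - i - 1
            if n1 > MAXLOOP:
                break
            for l in range(j - 1, k, -1):
                n2 = j - l - 1
                if n1 + n2 > MAXLOOP:
                    break
                if not self.pairable[k, l] or self.V[k, l] == INF:
                    continue
                if n1 == 0 and n2 == 0:
                    e = STACK[(self.seq[i] + self.seq[j],
                               self.seq[k] + self.seq[l])]
                elif n1 == 0 or n2 == 0:
                    e = bulge_energy(n1 + n2)
                else:
                    e = internal_energy(n1 + n2)
                yield base + e + self.V[k, l], "interior", (k, l)
        if j - i >= 2 and self.WM2[i + 1, j - 1] < INF:
            yield (base + MULTI_CLOSE + self.WM2[i + 1, j - 1],
                   "multi", None)

    def _wm_candidates(self, i: int, j: int):
        if i + 1 <= j:
            yield self.WM[i + 1, j] + MULTI_UNPAIRED, "unpaired", None
        for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not self.pairable[i, l] or self.V[i, l] == INF:
                continue
            branch = self.V[i, l] + MULTI_BRANCH
            tail = MULTI_UNPAIRED * (j - l)
            yield branch + tail, "branch", (l, False)
            if l + 1 <= j and self.WM[l + 1, j] < INF:
                yield branch + self.WM[l + 1, j], "branch", (l, True)

    def _wm2_candidates(self, i: int, j: int):
        if i + 1 <= j:
            yield self.WM2[i + 1, j] + MULTI_UNPAIRED, "unpaired", None
        for l in range(i + MIN_HAIRPIN_LOOP + 1, j):
            if not self.pairable[i, l] or self.V[i, l] == INF:
                continue
            if self.WM[l + 1, j] < INF:
                yield (self.V[i, l] + MULTI_BRANCH + self.WM[l + 1, j],
                       "branch", l)

    def _fill(self):
        n = self.n
        for span in range(MIN_HAIRPIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                if self.pairable[i, j]:
                    self.V[i, j] = min(e for e, _, _ in
                                       self._v_candidates(i, j))
                self.WM[i, j] = min(
                    (e for e, _, _ in self._wm_candidates(i, j)),
                    default=INF)
                self.WM2[i, j] = min(
                    (e for e, _, _ in self._wm2_candidates(i, j)),
                    default=INF)
        # exterior loop
        for j in range(n):
            best = self.W[j - 1] if j > 0 else 0.0
            for i in range(0, j - MIN_HAIRPIN_LOOP):
                if self.V[i, j] < INF:
                    prev = self.W[i - 1] if i > 0 else 0.0
                    best = min(best, prev + self.V[i, j])
            self.W[j] = best

    # traceback ---------------------------------------------------------

    def traceback(self) -> np.ndarray:
        pt = np.zeros(self.n, dtype=int)
        stack: list[tuple[str, int, int]] = [("W", 0, self.n - 1)]
        eps = 1e-9
        while stack:
            matrix, i, j = stack.pop()
            if i > j:
                continue
            if matrix == "W":
                target = self.W[j]
                if j > 0 and abs(self.W[j - 1] - target) < eps:
                    stack.append(("W", 0, j - 1))
                    continue
                done = False
                for k in range(0, j - MIN_HAIRPIN_LOOP):
                    prev = self.W[k - 1] if k > 0 else 0.0
                    if self.V[k, j] < INF and abs(prev + self.V[k, j] - target) < eps:
                        pt[k], pt[j] = j + 1, k + 1
                        stack.append(("V", k, j))
                        if k > 0:
                            stack.append(("W", 0, k - 1))
                        done = True
                        break
                if not done and j > 0:
                    stack.append(("W", 0, j - 1))
            elif matrix == "V":
                target = self.V[i, j]
                for e, kind, payload in self._v_candidates(i, j):
                    if abs(e - target) >= eps:
                        continue
                    if kind == "interior":
                        k, l = payload
                        pt[k], pt[l] = l + 1, k + 1
                        stack.append(("V", k, l))
                    elif kind == "multi":
                        stack.append(("WM2", i + 1, j - 1))
                    break
            elif matrix in ("WM", "WM2"):
                target = self.WM[i, j] if matrix == "WM" else self.WM2[i, j]
                cands = (self._wm_candidates(i, j) if matrix == "WM"
                         else self._wm2_candidates(i, j))
                for e, kind, payload in cands:
                    if abs(e - target) >= eps:
                        continue
                    if kind == "unpaired":
                        stack.append((matrix, i + 1, j))
                    elif matrix == "WM":
                        l, has_tail = payload
                        pt[i], pt[l] = l + 1, i + 1
                        stack.append(("V", i, l))
                        if has_tail:
                            stack.append(("WM", l + 1, j))
                    else:
                        l = payload
                        pt[i], pt[l] = l + 1, i + 1
                        stack.append(("V", i, l))
                        stack.append(("WM", l + 1, j))
                    break
        return pt


def fold_constrained(sequence: str, profile=None,
                     params: PseudoEnergyParams = PseudoEnergyParams()
                     ) -> tuple[SecondaryStructure, float]:
    """Fold a sequence into its MFE structure, optionally SHAPE-constrained.

    Returns ``(structure, energy)`` where the energy includes the
    pseudo-energy terms.  Deterministic; ties resolve to a fixed
    candidate order.  Sequences shorter than 8 nt are rejected (no
    foldable structure of interest).
    """
    seq = _normalize_sequence(sequence)
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt has no foldable structure")
    sh = _shape_vector(len(seq), profile, params)
    dp = _Fold(seq, sh)
    pt = dp.traceback()
    structure = SecondaryStructure(sequence, pt)
    return structure, float(dp.W[-1])


def mfe_energy(sequence: str, profile=None,
               params: PseudoEnergyParams = PseudoEnergyParams()) -> float:
    """Optimal energy only (no traceback)."""
    seq = _normalize_sequence(sequence)
    sh = _shape_vector(len(seq), profile, params)
    return float(_Fold(seq, sh).W[-1])
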