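"""Minimum-free-energy RNA secondary structure prediction.

Implements a Zuker-style dynamic program over a deliberately simplified
nearest-neighbour energy model:

* stacking energies for the 36 combinations of Watson-Crick / G:U pair on
  pair (Turner-like magnitudes, kcal/mol);
* linear loop penalties for hairpins (minimum loop 3 nt), bulges and
  interior loops (at most 30 unpaired bases per loop);
* an affine multiloop penalty (closing + per-branch + per-unpaired terms);
* exterior bases are free.

The model is small enough that the optimum can be cross-checked by
exhaustive enumeration of all nested structures on short sequences, yet it
reproduces the qualitative behaviour needed for hairpin screening: long
complementary stems fold with strongly negative energies, random sequence
does not.  ``structure_energy`` scores an explicit structure by direct
loop decomposition under the same model and is the single source of truth
for what a structure costs.

The DP inner loops are JIT-compiled with numba when available and fall
back to pure Python otherwise (same code path, just slower).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


INF = 1e9
MIN_HAIRPIN = 3
MAX_LOOP = 30

# base codes: A=0 C=1 G=2 T/U=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair types: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5, -1 = not pairable
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _i, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_TYPE[_a, _b] = _i

# stacking energy of pair (i+1, j-1) on closing pair (i, j), kcal/mol
#                 on:   AU     UA     CG     GC     GU     UG
_STACK = np.array(
    [
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # UA
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],  # CG
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],  # GC
        [-1.3, -1.4, -2.5, -2.1, -0.5, -0.4],  # GU
        [-1.0, -0.6, -1.4, -1.5, -0.2, -0.5],  # UG
    ]
)

# linear loop parameters (initiation, per-unpaired) and multiloop affine terms
HAIRPIN_A, HAIRPIN_B = 5.0, 0.30
BULGE_A, BULGE_B = 3.6, 0.30
INTERIOR_A, INTERIOR_B = 2.0, 0.30
MULTI_A, MULTI_B, MULTI_C = 3.4, 0.40, 0.10


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA sequence as integer base codes."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU character in sequence: {exc}") from None


def hairpin_energy(size: int) -> float:
    return HAIRPIN_A + HAIRPIN_B * (size - MIN_HAIRPIN)


def bulge_energy(size: int) -> float:
    return BULGE_A + BULGE_B * size


def interior_energy(s1: int, s2: int) -> float:
    return INTERIOR_A + INTERIOR_B * (s1 + s2)


@dataclass
class HairpinStructure:
    """A nested secondary structure: dot-bracket string, MFE, pair table."""

    dotbracket: str
    mfe: float
    pairs: Dict[int, int]  # 1-based, symmetric

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def partner(self, pos: int) -> Optional[int]:
        """1-based pairing partner of ``pos``, or None if unpaired."""
        return self.pairs.get(pos)


# ---------------------------------------------------------------------------
# DP fill (numba-jittable)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fill(codes, pair_type, stack):  # pragma: no cover - jitted
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    W = np.zeros(n)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt_ij = pair_type[codes[i], codes[j]]
            if pt_ij >= 0:
                # hairpin
                best = HAIRPIN_A + HAIRPIN_B * (span - 1 - MIN_HAIRPIN)
                # stack / bulge / interior via inner pair (p, q)
                for p in range(i + 1, min(i + MAX_LOOP + 2, j - MIN_HAIRPIN - 1)):
                    s1 = p - i - 1
                    q_min = p + MIN_HAIRPIN + 1
                    q_lo = j - 1 - (MAX_LOOP - s1)
                    if q_lo > q_min:
                        q_min = q_lo
                    for q in range(q_min, j):
                        if V[p, q] >= INF:
                            continue
                        s2 = j - q - 1
                        if s1 == 0 and s2 == 0:
                            cost = stack[pt_ij, pair_type[codes[p], codes[q]]]
                        elif s1 == 0 or s2 == 0:
                            cost = BULGE_A + BULGE_B * (s1 + s2)
                        else:
                            cost = INTERIOR_A + INTERIOR_B * (s1 + s2)
                        cand = V[p, q] + cost
                        if cand < best:
                            best = cand
                # multiloop: closing pair + >= 2 branches inside
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = MULTI_A + MULTI_B + WM[i + 1, k] + WM[k + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM: at least one branch in i..j
            best = INF
            if i + 1 <= j and WM[i + 1, j] < INF:
                best = WM[i + 1, j] + MULTI_C
            if j - 1 >= i and WM[i, j - 1] < INF:
                cand = WM[i, j - 1] + MULTI_C
                if cand < best:
                    best = cand
            if V[i, j] < INF:
                cand = V[i, j] + MULTI_B
                if cand < best:
                    best = cand
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    # external loop
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if V[i, j] < INF:
                left = W[i - 1] if i > 0 else 0.0
                cand = left + V[i, j]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, W


# ---------------------------------------------------------------------------
# traceback (pure Python; re-derives the argmin decisions)
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _trace(codes: np.ndarray, V, WM, W) -> List[Tuple[int, int]]:
    n = codes.shape[0]
    pairs: List[Tuple[int, int]] = []
    stack_: List[Tuple[str, int, int]] = []
    # external
    j = n - 1
    while j >= 0:
        if j == 0 or abs(W[j] - W[j - 1]) < _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j):
            if V[i, j] >= INF:
                continue
            left = W[i - 1] if i > 0 else 0.0
            if abs(W[j] - (left + V[i, j])) < _EPS:
                stack_.append(("V", i, j))
                j = i - 1
                found = True
                break
        if not found:  # numerical safety: treat as unpaired
            j -= 1

    while stack_:
        kind, i, j = stack_.pop()
        if kind == "V":
            pairs.append((i, j))
            span = j - i
            hp = HAIRPIN_A + HAIRPIN_B * (span - 1 - MIN_HAIRPIN)
            if abs(V[i, j] - hp) < _EPS:
                continue
            done = False
            pt_ij = _PAIR_TYPE[codes[i], codes[j]]
            for p in range(i + 1, min(i + MAX_LOOP + 2, j - MIN_HAIRPIN - 1)):
                s1 = p - i - 1
                for q in range(max(p + MIN_HAIRPIN + 1, j - 1 - (MAX_LOOP - s1)), j):
                    if V[p, q] >= INF:
                        continue
                    s2 = j - q - 1
                    if s1 == 0 and s2 == 0:
                        cost = _STACK[pt_ij, _PAIR_TYPE[codes[p], codes[q]]]
                    elif s1 == 0 or s2 == 0:
                        cost = bulge_energy(s1 + s2)
                    else:
                        cost = interior_energy(s1, s2)
                    if abs(V[i, j] - (V[p, q] + cost)) < _EPS:
                        stack_.append(("V", p, q))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                    if abs(V[i, j] - (MULTI_A + MULTI_B + WM[i + 1, k] + WM[k + 1, j - 1])) < _EPS:
                        stack_.append(("M", i + 1, k))
                        stack_.append(("M", k + 1, j - 1))
                        break
        else:  # WM
            if V[i, j] < INF and abs(WM[i, j] - (V[i, j] + MULTI_B)) < _EPS:
                stack_.append(("V", i, j))
                continue
            if i + 1 <= j and WM[i + 1, j] < INF and abs(WM[i, j] - (WM[i + 1, j] + MULTI_C)) < _EPS:
                stack_.append(("M", i + 1, j))
                continue
            if j - 1 >= i and WM[i, j - 1] < INF and abs(WM[i, j] - (WM[i, j - 1] + MULTI_C)) < _EPS:
                stack_.append(("M", i, j - 1))
                continue
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    if abs(WM[i, j] - (WM[i, k] + WM[k + 1, j])) < _EPS:
                        stack_.append(("M", i, k))
                        stack_.append(("M", k + 1, j))
                        break
    return pairs


def fold_mfe(sequence: str) -> HairpinStructure:
    """Fold a sequence into its minimum-free-energy nested structure.

    Deterministic for a fixed input; ties between co-optimal structures
    break by the fixed traceback order.  A sequence admitting no pairs
    (e.g. a homopolymer) returns the open structure with MFE 0.
    """
    codes = encode(sequence)
    n = codes.shape[0]
    if n < MIN_HAIRPIN + 2:
        return HairpinStructure("." * n, 0.0, {})
    V, WM, W = _fill(codes, _PAIR_TYPE, _STACK)
    mfe = float(min(0.0, W[n - 1]))
    if mfe >= 0.0:
        return HairpinStructure("." * n, 0.0, {})
    pairs0 = _trace(codes, V, WM, W)
    db = ["."] * n
    table: Dict[int, int] = {}
    for i, j in pairs0:
        db[i], db[j] = "(", ")"
        table[i + 1] = j + 1
        table[j + 1] = i + 1
    return HairpinStructure("".join(db), mfe, table)


# ---------------------------------------------------------------------------
# explicit-structure energy (loop decomposition)
# ---------------------------------------------------------------------------

def parse_dotbracket(db: str) -> List[Tuple[int, int]]:
    """0-based pair list from a dot-bracket string."""
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def structure_energy(sequence: str, pairs: Sequence[Tuple[int, int]]) -> float:
    """Energy of an explicit nested structure under the package model.

    ``pairs`` are 0-based (i, j) with i < j.  Returns +inf for structures
    the model forbids (non-canonical pairs, hairpin loops < 3 nt, or
    bulge/interior loops with more than 30 unpaired bases).  Computed by
    direct loop decomposition, independently of the DP recurrences.
    """
    codes = encode(sequence)
    n = len(sequence)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i}, {j}) out of range")
        if i in partner or j in partner:
            raise ValueError("position paired twice")
        partner[i] = j
        partner[j] = i
    ordered = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for (i1, j1), (i2, j2) in zip(ordered, ordered[1:]):
        if i1 < i2 < j1 < j2:
            raise ValueError("pseudoknotted structure")

    def children(lo: int, hi: int) -> Tuple[List[Tuple[int, int]], int]:
        """Directly-enclosed pairs and unpaired count in the open interval."""
        kids, unpaired, k = [], 0, lo
        while k <= hi:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                if k in partner:
                    raise ValueError("pseudoknotted structure")
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    work: List[Tuple[int, int]] = list(children(0, n - 1)[0])
    while work:
        i, j = work.pop()
        if _PAIR_TYPE[codes[i], codes[j]] < 0:
            return INF
        kids, unpaired = children(i + 1, j - 1)
        if not kids:
            if j - i - 1 < MIN_HAIRPIN:
                return INF
            total += hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            p, q = kids[0]
            s1, s2 = p - i - 1, j - q - 1
            if s1 + s2 > MAX_LOOP:
                return INF
            if s1 == 0 and s2 == 0:
                if _PAIR_TYPE[codes[p], codes[q]] < 0:
                    return INF
                total += float(_STACK[_PAIR_TYPE[codes[i], codes[j]], _PAIR_TYPE[codes[p], codes[q]]])
            elif s1 == 0 or s2 == 0:
                total += bulge_energy(s1 + s2)
            else:
                total += interior_energy(s1, s2)
        else:
            total += MULTI_A + MULTI_B * (len(kids) + 1) + MULTI_C * unpaired
        work.extend(kids)
    return total
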