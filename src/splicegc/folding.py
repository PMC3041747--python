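"""Minimum-free-energy folding of junction windows.

A simplified Zuker-style nearest-neighbor model: Watson-Crick and GU wobble
stacking terms (enthalpy/entropy split so that temperature can be varied),
size-dependent hairpin/bulge/internal loop penalties treated as purely
entropic, and an affine multiloop score.  Dangling ends and coaxial stacking
are deliberately omitted.  The dynamic program is validated against an
exhaustive structure enumeration (:func:`enumerate_structures`) that scores
candidate structures with the identical, independently written energy
function.

Energies are kcal/mol; an open chain scores 0, so the MFE is always <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


INF = 1e9
MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop
MAX_INTERIOR = 30  # DP cap on bulge/internal loop size (never binds for n<=32)
_T37 = 310.15
_GAS_R = 1.987e-3  # kcal/(mol*K)

# base encoding: A C G U(=T) N
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair codes: 0 = unpairable, then AU UA CG GC GU UG
_PAIR_CODE = np.zeros((5, 5), dtype=np.int8)
for _idx, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)], 1):
    _PAIR_CODE[_a, _b] = _idx

# Turner-like stacking parameters for the 16 WC-on-WC combinations,
# rows/cols ordered AU, CG, GC, UA (outer pair over inner pair).
_WC_ORDER = (1, 3, 4, 2)
_STACK_DG37_WC = [
    [-0.93, -2.24, -2.08, -1.10],
    [-2.11, -3.26, -2.36, -2.08],
    [-2.35, -3.42, -3.26, -2.24],
    [-1.33, -2.35, -2.11, -0.93],
]
_STACK_DH_WC = [
    [-6.82, -11.40, -10.48, -9.38],
    [-10.44, -13.39, -10.64, -10.48],
    [-12.44, -14.88, -13.39, -11.40],
    [-7.69, -12.44, -10.44, -6.82],
]
# single flat term for any stack involving a GU/UG wobble pair
_STACK_DG37_GU = -1.30
_STACK_DH_GU = -8.50

# loop initiation penalties at 37 C (kcal/mol), by number of unpaired bases
_HAIRPIN37 = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE37 = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL37 = {2: 1.5, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
_ML_INIT37 = 3.4
_ML_BRANCH37 = 0.4
_ML_UNPAIRED37 = 0.0


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string (ACGU/T, N) as int8 codes."""
    try:
        return np.array([_BASE_CODE[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def _loop37(table: dict[int, float], size: int) -> float:
    """37 C penalty with Jacobson-Stockmayer extrapolation past the table."""
    mx = max(table)
    if size <= mx:
        return table[size]
    return table[mx] + 1.75 * _GAS_R * _T37 * math.log(size / mx)


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameters evaluated at a fixed temperature.

    ``stack_dg[p][q]`` is the free energy of inner pair ``q`` stacked under
    outer pair ``p`` (pair codes as in :data:`_PAIR_CODE`).  Loop penalties
    are scaled by T/310.15 (entropic); stacks use dG(T) = dH - T*dS.
    """

    temperature_c: float
    stack_dg: np.ndarray = field(repr=False)
    ml_init: float
    ml_branch: float
    ml_unpaired: float

    @property
    def t_kelvin(self) -> float:
        return self.temperature_c + 273.15

    @property
    def _scale(self) -> float:
        return self.t_kelvin / _T37

    def hairpin_energy(self, size: int) -> float:
        if size < MIN_LOOP:
            return INF
        return _loop37(_HAIRPIN37, size) * self._scale

    def bulge_energy(self, size: int) -> float:
        return _loop37(_BULGE37, size) * self._scale

    def internal_energy(self, size: int) -> float:
        return _loop37(_INTERNAL37, max(size, 2)) * self._scale

    def loop_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Precomputed hairpin/bulge/internal penalty arrays up to size n."""
        hp = np.full(n + 1, INF)
        bl = np.full(n + 1, INF)
        il = np.full(n + 1, INF)
        for s in range(MIN_LOOP, n + 1):
            hp[s] = self.hairpin_energy(s)
        for s in range(1, n + 1):
            bl[s] = self.bulge_energy(s)
        for s in range(2, n + 1):
            il[s] = self.internal_energy(s)
        return hp, bl, il

    def to_table_text(self) -> str:
        """Serialize the parameter set as a plain-text table."""
        lines = [f"# energy model at {self.temperature_c} C (kcal/mol)"]
        names = {1: "AU", 2: "UA", 3: "CG", 4: "GC", 5: "GU", 6: "UG"}
        lines.append("section\tkey\tvalue")
        for p in range(1, 7):
            for q in range(1, 7):
                lines.append(f"stack\t{names[p]}/{names[q]}\t{self.stack_dg[p, q]:.4f}")
        for s in range(MIN_LOOP, 10):
            lines.append(f"hairpin\t{s}\t{self.hairpin_energy(s):.4f}")
        for s in range(1, 7):
            lines.append(f"bulge\t{s}\t{self.bulge_energy(s):.4f}")
        for s in range(2, 7):
            lines.append(f"internal\t{s}\t{self.internal_energy(s):.4f}")
        lines.append(f"multiloop\tinit\t{self.ml_init:.4f}")
        lines.append(f"multiloop\tbranch\t{self.ml_branch:.4f}")
        lines.append(f"multiloop\tunpaired\t{self.ml_unpaired:.4f}")
        return "\n".join(lines) + "\n"


def make_model(temperature_c: float = 37.0) -> EnergyModel:
    """Build an :class:`EnergyModel` for the given temperature (0-100 C)."""
    if not 0.0 < temperature_c < 100.0:
        raise ValueError(f"temperature out of range (0, 100): {temperature_c}")
    t_k = temperature_c + 273.15
    scale = t_k / _T37
    stack = np.full((7, 7), INF)
    for i, p in enumerate(_WC_ORDER):
        for j, q in enumerate(_WC_ORDER):
            dg37 = _STACK_DG37_WC[i][j]
            dh = _STACK_DH_WC[i][j]
            ds = (dh - dg37) / _T37
            stack[p, q] = dh - t_k * ds
    ds_gu = (_STACK_DH_GU - _STACK_DG37_GU) / _T37
    gu_dg = _STACK_DH_GU - t_k * ds_gu
    for p in range(1, 7):
        for q in range(1, 7):
            if p >= 5 or q >= 5:
                stack[p, q] = gu_dg
    return EnergyModel(
        temperature_c=temperature_c,
        stack_dg=stack,
        ml_init=_ML_INIT37 * scale,
        ml_branch=_ML_BRANCH37 * scale,
        ml_unpaired=_ML_UNPAIRED37 * scale,
    )


@dataclass(frozen=True)
class FoldResult:
    """MFE prediction for one sequence at one temperature."""

    mfe: float
    structure: str
    temperature_c: float


# ---------------------------------------------------------------------------
# structure utilities


def parse_pairs(structure: str) -> list[tuple[int, int]]:
    """Dot-bracket -> sorted base-pair list; raises on unbalanced input."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def pairs_to_structure(pairs: list[tuple[int, int]], n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def validate_structure(sequence: str, structure: str, min_loop: int = MIN_LOOP) -> None:
    """Assert balancing, pair legality and the hairpin-size constraint."""
    if len(sequence) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    seq = encode(sequence)
    pairs = parse_pairs(structure)
    for i, j in pairs:
        if _PAIR_CODE[seq[i], seq[j]] == 0:
            raise ValueError(f"illegal pair ({i},{j}): {sequence[i]}-{sequence[j]}")
        inner = [p for p in pairs if i < p[0] and p[1] < j]
        if not inner and j - i - 1 < min_loop:
            raise ValueError(f"hairpin loop smaller than {min_loop} at pair ({i},{j})")


def structure_energy(sequence: str, structure: str, model: EnergyModel) -> float:
    """Score a dot-bracket structure under the model (independent of the DP).

    Walks the pair tree: each pair closes either a hairpin, a stack, a
    bulge/internal loop, or a multiloop.  The exterior loop is free.
    """
    seq = encode(sequence)
    pairs = parse_pairs(structure)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    for i, j in pairs:
        p = _PAIR_CODE[seq[i], seq[j]]
        if p == 0:
            raise ValueError(f"illegal pair ({i},{j})")
        kids, unpaired = children(i, j)
        if not kids:
            total += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                total += model.stack_dg[p, _PAIR_CODE[seq[k], seq[l]]]
            elif u1 == 0 or u2 == 0:
                total += model.bulge_energy(u1 + u2)
            else:
                total += model.internal_energy(u1 + u2)
        else:
            total += (
                model.ml_init
                + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_structures(
    sequence: str, model: EnergyModel, max_len: int = 18
) -> tuple[float, str]:
    """Exhaustively enumerate pseudoknot-free structures and return the best.

    Refuses sequences longer than ``max_len``.  Serves as the independent
    oracle for :func:`fold_mfe`; shares only :func:`structure_energy`.
    """
    n = len(sequence)
    if n > max_len:
        raise ValueError(f"sequence length {n} exceeds oracle limit {max_len}")
    seq = encode(sequence)

    def region(i: int, j: int) -> list[list[tuple[int, int]]]:
        # all pair sets over seq[i..j]
        if i >= j:
            return [[]]
        out = list(region(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _PAIR_CODE[seq[i], seq[k]]:
                for left in region(i + 1, k - 1):
                    for right in region(k + 1, j):
                        out.append([(i, k)] + left + right)
        return out

    best_e = 0.0
    best_s = "." * n
    for pairs in region(0, n - 1):
        if not pairs:
            continue
        db = pairs_to_structure(sorted(pairs), n)
        e = structure_energy(sequence, db, model)
        if e < best_e - 1e-12 or (abs(e - best_e) <= 1e-12 and db < best_s):
            best_e, best_s = e, db
    return best_e, best_s


# ---------------------------------------------------------------------------
# dynamic program


@njit(cache=False)
def _fill(seq, pair_code, stack, hp, bl, il, ml_a, ml_b, ml_c):  # pragma: no cover
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            p = pair_code[seq[i], seq[j]]
            if p > 0 and d > MIN_LOOP:
                best = hp[d - 1]
                kmax = min(i + MAX_INTERIOR + 1, j - MIN_LOOP - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERIOR - u1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            q = pair_code[seq[k], seq[l]]
                            e = stack[p, q]
                        elif u1 == 0 or u2 == 0:
                            e = bl[u1 + u2]
                        else:
                            e = il[u1 + u2]
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                for m in range(i + 1, j - 1):
                    cand = ml_a + ml_b + WM[i + 1, m] + WM[m + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            w = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < w:
                w = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < w:
                w = WM[i, j - 1] + ml_c
            for m in range(i, j):
                cand = WM[i, m] + WM[m + 1, j]
                if cand < w:
                    w = cand
            WM[i, j] = w
    W = np.zeros(n + 1)
    for j in range(n):
        w = W[j]
        for i in range(0, j):
            if V[i, j] < INF and W[i] + V[i, j] < w:
                w = W[i] + V[i, j]
        W[j + 1] = w
    return V, WM, W


def _fill_matrices(seq: np.ndarray, model: EnergyModel):
    n = len(seq)
    hp, bl, il = model.loop_tables(n)
    return _fill(
        seq,
        _PAIR_CODE,
        model.stack_dg,
        hp,
        bl,
        il,
        model.ml_init,
        model.ml_branch,
        model.ml_unpaired,
    )


_EPS = 1e-7


def _trace(seq: np.ndarray, model: EnergyModel, V, WM, W) -> list[tuple[int, int]]:
    n = len(seq)
    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i, j]
        p = _PAIR_CODE[seq[i], seq[j]]
        if abs(model.hairpin_energy(j - i - 1) - target) < _EPS:
            return
        kmax = min(i + MAX_INTERIOR + 1, j - MIN_LOOP - 1)
        for k in range(i + 1, kmax + 1):
            u1 = k - i - 1
            lmin = max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERIOR - u1))
            for l in range(j - 1, lmin - 1, -1):
                if V[k, l] >= INF:
                    continue
                u2 = j - l - 1
                if u1 == 0 and u2 == 0:
                    e = model.stack_dg[p, _PAIR_CODE[seq[k], seq[l]]]
                elif u1 == 0 or u2 == 0:
                    e = model.bulge_energy(u1 + u2)
                else:
                    e = model.internal_energy(u1 + u2)
                if abs(e + V[k, l] - target) < _EPS:
                    trace_v(k, l)
                    return
        for m in range(i + 1, j - 1):
            if abs(model.ml_init + model.ml_branch + WM[i + 1, m] + WM[m + 1, j - 1] - target) < _EPS:
                trace_wm(i + 1, m)
                trace_wm(m + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")

    def trace_wm(i: int, j: int) -> None:
        target = WM[i, j]
        if V[i, j] < INF and abs(V[i, j] + model.ml_branch - target) < _EPS:
            trace_v(i, j)
            return
        if i + 1 <= j and abs(WM[i + 1, j] + model.ml_unpaired - target) < _EPS:
            trace_wm(i + 1, j)
            return
        if i <= j - 1 and abs(WM[i, j - 1] + model.ml_unpaired - target) < _EPS:
            trace_wm(i, j - 1)
            return
        for m in range(i, j):
            if abs(WM[i, m] + WM[m + 1, j] - target) < _EPS:
                trace_wm(i, m)
                trace_wm(m + 1, j)
                return
        raise AssertionError("traceback failed in WM")

    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) < _EPS:
            j -= 1
            continue
        for i in range(0, j):
            if V[i, j] < INF and abs(W[i] + V[i, j] - W[j + 1]) < _EPS:
                trace_v(i, j)
                j = i - 1
                break
        else:
            raise AssertionError("traceback failed in W")
    return sorted(pairs)


def fold_mfe(sequence: str, model: EnergyModel | None = None) -> FoldResult:
    """Predict the minimum free energy and one optimal structure.

    O(n^3) dynamic program over pseudoknot-free structures with hairpin
    loops >= 3; interior loops are capped at 30 unpaired bases (standard,
    and irrelevant for the oracle lengths).  Ties are broken
    deterministically in the traceback (smaller opening index first).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if model is None:
        model = make_model(37.0)
    seq = encode(sequence)
    n = len(seq)
    if n <= MIN_LOOP + 1:
        return FoldResult(0.0, "." * n, model.temperature_c)
    V, WM, W = _fill_matrices(seq, model)
    mfe = float(W[n])
    if mfe >= -1e-12:
        return FoldResult(0.0, "." * n, model.temperature_c)
    pairs = _trace(seq, model, V, WM, W)
    return FoldResult(mfe, pairs_to_structure(pairs, n), model.temperature_c)


def nussinov_max_pairs(sequence: str, min_loop: int = MIN_LOOP) -> int:
    """Maximum number of nested legal pairs (sanity bound, not an energy)."""
    seq = encode(sequence)
    n = len(seq)
    if n == 0:
        return 0
    M = np.zeros((n, n), dtype=np.int64)
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = M[i, j - 1]
            for k in range(i, j - min_loop):
                paired = 1 if _PAIR_CODE[seq[k], seq[j]] else 0
                if paired:
                    left = M[i, k - 1] if k > i else 0
                    inner = M[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            M[i, j] = best
    return int(M[0, n - 1])


def fold_many(
    sequences: list[str], model: EnergyModel | None = None, structures: bool = False
) -> list[FoldResult]:
    """Fold a batch; skips traceback when structures are not requested."""
    if model is None:
        model = make_model(37.0)
    out = []
    for s in sequences:
        if structures:
            out.append(fold_mfe(s, model))
        else:
            seq = encode(s)
            n = len(seq)
            if n <= MIN_LOOP + 1:
                out.append(FoldResult(0.0, "." * n, model.temperature_c))
                continue
            _, _, W = _fill_matrices(seq, model)
            out.append(FoldResult(min(float(W[n]), 0.0), "", model.temperature_c))
    return out
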