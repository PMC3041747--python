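"""Permutation controls preserving mono- or dinucleotide composition.

``shuffle_mono`` is a plain uniform permutation; ``shuffle_dinuc`` is the
Altschul-Erickson shuffle: a random Eulerian path on the dinucleotide
multigraph, which preserves the full 16-count dinucleotide vector together
with the first and last character.  ``order_effect_analysis`` folds native
windows and their shuffles and compares the energies with paired tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .folding import EnergyModel, fold_many, make_model
from .stats import ComparisonResult, signed_rank_test

DEFAULT_GC_GROUPS = ((50, 1), (60, 1), (70, 1), (80, 1))  # (center, half-width)


def mono_counts(sequence: str) -> Counter:
    return Counter(sequence)


def dinuc_counts(sequence: str) -> Counter:
    return Counter(sequence[i : i + 2] for i in range(len(sequence) - 1))


def shuffle_mono(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the characters."""
    if not sequence:
        raise ValueError("empty sequence")
    chars = list(sequence)
    return "".join(rng.permutation(chars))


def shuffle_dinuc(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle via a random Eulerian path.

    Preserves the 16 dinucleotide counts and both endpoints exactly.  The
    last-edge tree is drawn by rejection, the remaining out-edges of every
    vertex are permuted uniformly, and the path is walked from the first
    character (Altschul-Erickson).
    """
    if len(sequence) < 2:
        raise ValueError("need length >= 2 for a dinucleotide shuffle")
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        out_edges.setdefault(a, []).append(b)
    first, last = sequence[0], sequence[-1]
    vertices = sorted(set(sequence))
    if len(vertices) == 1:
        return sequence

    # vertices other than `last` that have out-edges need a last-edge choice
    # forming a tree into `last`
    choosers = [v for v in vertices if v != last and out_edges.get(v)]
    while True:
        last_edge = {v: out_edges[v][rng.integers(len(out_edges[v]))] for v in choosers}
        ok = True
        for v in choosers:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out_edges.get(v, []))
        if v in last_edge:
            edges.remove(last_edge[v])
            edges = [edges[i] for i in rng.permutation(len(edges))] if edges else []
            edges.append(last_edge[v])
        else:
            edges = [edges[i] for i in rng.permutation(len(edges))] if edges else []
        walk_lists[v] = edges

    out = [first]
    cur = first
    pos = {v: 0 for v in vertices}
    for _ in range(len(sequence) - 1):
        nxt = walk_lists[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)
    assert dinuc_counts(shuffled) == dinuc_counts(sequence)
    return shuffled


def check_shuffle(original: str, shuffled: str, order: str) -> bool:
    """Programmatic count-preservation check (mono: 4-vector; dinuc: 16 + ends)."""
    if order == "mono":
        return mono_counts(original) == mono_counts(shuffled)
    if order == "dinuc":
        return (
            dinuc_counts(original) == dinuc_counts(shuffled)
            and original[0] == shuffled[0]
            and original[-1] == shuffled[-1]
        )
    raise ValueError(f"unknown shuffle order {order!r}")


@dataclass
class ShuffleResult:
    """Native vs shuffled MFEs for one window."""

    window_id: str
    native_mfe: float
    shuffled_mfes: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0

    def mean(self, order: str) -> float:
        return float(np.mean(self.shuffled_mfes[order]))


def _window_rng(seed: int, index: int) -> np.random.Generator:
    # per-window substream: deterministic regardless of iteration order
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def order_effect_analysis(
    windows,
    model: EnergyModel | None = None,
    n_reps: int = 10,
    seed: int = 0,
    gc_groups=DEFAULT_GC_GROUPS,
) -> tuple[list[ShuffleResult], dict[str, ComparisonResult]]:
    """Fold native windows and mono/dinuc shuffles; paired comparisons.

    ``windows`` is a list of objects with ``sequence`` and ``gc_number``
    attributes (JunctionWindow works), or plain strings.  Returns per-window
    ShuffleResults plus paired signed-rank comparisons of native vs the
    per-window mean shuffled MFE, overall and per GC-number group.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seqs = [w if isinstance(w, str) else w.sequence for w in windows]
    if not seqs:
        raise ValueError("no windows supplied")
    if model is None:
        model = make_model(37.0)

    native = [r.mfe for r in fold_many(seqs, model)]
    results = []
    for idx, s in enumerate(seqs):
        rng = _window_rng(seed, idx)
        shuffles = {"mono": [], "dinuc": []}
        for order, fn in (("mono", shuffle_mono), ("dinuc", shuffle_dinuc)):
            perms = []
            for _ in range(n_reps):
                p = fn(s, rng)
                assert check_shuffle(s, p, order)
                perms.append(p)
            shuffles[order] = [r.mfe for r in fold_many(perms, model)]
        results.append(ShuffleResult(f"w{idx}", native[idx], shuffles, seed))

    gc_numbers = np.array(
        [s.count("G") + s.count("C") for s in seqs], dtype=np.int64
    )
    comparisons: dict[str, ComparisonResult] = {}
    for order in ("mono", "dinuc"):
        diffs = np.array([r.native_mfe - r.mean(order) for r in results])
        comparisons[f"native_vs_{order}"] = signed_rank_test(
            diffs, label_a="native", label_b=f"{order}_shuffled"
        )
        for center, half in gc_groups:
            mask = np.abs(gc_numbers - center) <= half
            if mask.sum() >= 6:
                comparisons[f"native_vs_{order}_gc{center}"] = signed_rank_test(
                    diffs[mask], label_a="native", label_b=f"{order}_shuffled"
                )
    return results, comparisons
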