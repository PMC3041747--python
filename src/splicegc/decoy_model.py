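"""Splice-site strength scoring and decoy-site selection.

The scorer is a position log-odds (weight-matrix) model over the
conventional windows: donors are scored on a 9-mer (3 exonic + 6 intronic
bases), acceptors on a 23-mer (20 intronic + 3 exonic).  Decoy sites are
GT/AG dinucleotides in the intron flanking a real site, 150-300 nt from the
junction, scoring at least a configurable threshold; among qualifiers the
nearest to the real site wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_assembly import SpliceSiteRecord
from .folding import EnergyModel, fold_many, make_model
from .stats import ComparisonResult, signed_rank_test
from .windows_gc import (
    JunctionWindow,
    extract_window,
    normalized_junction_gc,
    reverse_complement,
)

logger = logging.getLogger(__name__)

# scoring-window geometry, in sense coordinates relative to the junction base
DONOR_EXONIC, DONOR_INTRONIC = 3, 6  # 9-mer
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # 23-mer
DEFAULT_ZONE = (150, 300)
MIN_TRAINING = 50

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def window_length(side: str) -> int:
    return (
        DONOR_EXONIC + DONOR_INTRONIC
        if side == "donor"
        else ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC
    )


@dataclass(frozen=True)
class SiteScoringModel:
    """Per-position log2(foreground/background) weights for one side."""

    side: str
    weights: np.ndarray  # (length, 4)
    background: np.ndarray  # (4,)

    @property
    def length(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DecoyPair:
    """A real splice site matched with its nearest qualifying decoy."""

    real: SpliceSiteRecord
    decoy: SpliceSiteRecord
    distance: int
    real_score: float
    decoy_score: float

    def __post_init__(self):
        if self.distance < 1:
            raise ValueError("decoy distance must be positive")


def site_scoring_sequence(
    genome: Mapping[str, str], site: SpliceSiteRecord
) -> str:
    """Sense-strand scoring window for a junction (9-mer donor / 23-mer acceptor)."""
    seq = genome[site.seq_name]
    p = site.junction_pos
    # sense window spans [p - before, p + after] inclusive; the junction base
    # (first/last intronic base) is part of the intronic segment
    if site.side == "donor":
        before, after = DONOR_EXONIC, DONOR_INTRONIC - 1  # exon(3) | GT...(6)
    else:
        before, after = ACCEPTOR_INTRONIC - 1, ACCEPTOR_EXONIC  # ...AG(20) | exon(3)
    if site.strand == "+":
        lo, hi = p - before, p + after + 1
    else:
        lo, hi = p - after, p + before + 1
    if lo < 0 or hi > len(seq):
        raise ValueError(f"scoring window out of bounds for site {site.key}")
    raw = seq[lo:hi]
    return raw if site.strand == "+" else reverse_complement(raw)


def train_site_model(
    sequences: Sequence[str],
    side: str,
    pseudocount: float = 0.5,
    min_sequences: int = MIN_TRAINING,
) -> SiteScoringModel:
    """Estimate per-position log-odds weights from aligned real-site windows."""
    if side not in ("donor", "acceptor"):
        raise ValueError(f"invalid side {side!r}")
    length = window_length(side)
    if len(sequences) < min_sequences:
        raise ValueError(
            f"need >= {min_sequences} training sequences, got {len(sequences)}"
        )
    counts = np.full((length, 4), pseudocount)
    for s in sequences:
        s = s.upper().replace("U", "T")
        if len(s) != length:
            raise ValueError(f"training sequence length {len(s)} != {length}")
        for i, c in enumerate(s):
            if c in _BASE_IDX:
                counts[i, _BASE_IDX[c]] += 1
    fg = counts / counts.sum(axis=1, keepdims=True)
    bg = counts.sum(axis=0)
    bg = bg / bg.sum()
    weights = np.log2(fg / bg[None, :])
    return SiteScoringModel(side=side, weights=weights, background=bg)


def score_site(model: SiteScoringModel, sequence: str) -> float:
    """Sum of per-position log-odds (bits); additive by construction."""
    s = sequence.upper().replace("U", "T")
    if len(s) != model.length:
        raise ValueError(f"sequence length {len(s)} != model length {model.length}")
    total = 0.0
    for i, c in enumerate(s):
        if c in _BASE_IDX:
            total += model.weights[i, _BASE_IDX[c]]
        # N contributes 0 (background expectation)
    return float(total)


def serialize_model(model: SiteScoringModel, path: str | Path) -> None:
    """Plain-text matrix format: header line, then one row per position."""
    with open(path, "w") as fh:
        fh.write(f"# splice-site log-odds model\tside={model.side}\n")
        fh.write("# background\t" + "\t".join(f"{x:.6f}" for x in model.background) + "\n")
        fh.write("position\t" + "\t".join(_BASES) + "\n")
        for i, row in enumerate(model.weights):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def load_model(path: str | Path) -> SiteScoringModel:
    side = None
    background = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# splice-site"):
                side = line.split("side=")[1]
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line and not line.startswith(("#", "position")):
                rows.append([float(x) for x in line.split("\t")[1:]])
    if side is None or background is None or not rows:
        raise ValueError(f"malformed model file {path}")
    return SiteScoringModel(side=side, weights=np.array(rows), background=background)


def _decoy_record(real: SpliceSiteRecord, junction_pos: int) -> SpliceSiteRecord:
    return replace(real, junction_pos=junction_pos, category="decoy")


def find_decoy(
    genome: Mapping[str, str],
    real: SpliceSiteRecord,
    model: SiteScoringModel,
    zone: tuple[int, int] = DEFAULT_ZONE,
    threshold: float = 0.0,
) -> DecoyPair | None:
    """Nearest qualifying GT/AG candidate in the flanking intron.

    The flanking intron is downstream of a donor and upstream of an
    acceptor (transcription direction).  Candidates must carry the
    consensus dinucleotide in the correct orientation, lie ``zone[0]`` to
    ``zone[1]`` nt from the real junction, and score >= ``threshold`` bits.
    Returns ``None`` when no candidate qualifies.
    """
    lo, hi = zone
    if not 0 < lo < hi:
        raise ValueError(f"invalid zone {zone}")
    seq = genome[real.seq_name]
    p = real.junction_pos
    # genomic direction of "into the flanking intron"
    downstream = (real.side == "donor") == (real.strand == "+")
    step = 1 if downstream else -1
    try:
        real_score = score_site(model, site_scoring_sequence(genome, real))
    except ValueError:
        logger.warning("cannot score real site %s; skipped", real.key)
        return None
    best: DecoyPair | None = None
    for dist in range(lo, hi + 1):
        q = p + step * dist
        cand = _decoy_record(real, q)
        if not _has_consensus_dinucleotide(seq, cand):
            continue
        try:
            s = score_site(model, site_scoring_sequence(genome, cand))
        except ValueError:
            continue
        if s >= threshold:
            best = DecoyPair(real, cand, dist, real_score, s)
            break  # scanning outward => first hit is the nearest
    if best is None:
        logger.debug("no decoy for site %s in zone %s", real.key, zone)
    return best


def _has_consensus_dinucleotide(seq: str, site: SpliceSiteRecord) -> bool:
    """GT just downstream of a donor junction / AG just upstream of an acceptor,
    read on the sense strand."""
    p = site.junction_pos
    if site.side == "donor":
        if site.strand == "+":
            duo = seq[p : p + 2]
        else:
            duo = reverse_complement(seq[p - 1 : p + 1])
        return duo == "GT"
    else:
        if site.strand == "+":
            duo = seq[p - 1 : p + 1]
        else:
            duo = reverse_complement(seq[p : p + 2])
        return duo == "AG"


def paired_decoy_comparison(
    genome: Mapping[str, str],
    pairs: Sequence[DecoyPair],
    flank: int = 70,
    energy_model: EnergyModel | None = None,
) -> dict[str, ComparisonResult]:
    """Paired real-vs-decoy tests on GC, MFE and normalized junction GC."""
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 decoy pairs, got {len(pairs)}")
    if energy_model is None:
        energy_model = make_model(37.0)
    real_w = [extract_window(genome, p.real, flank) for p in pairs]
    decoy_w = [extract_window(genome, p.decoy, flank) for p in pairs]
    gc_diffs = [r.gc_fraction - d.gc_fraction for r, d in zip(real_w, decoy_w)]
    real_mfe = [r.mfe for r in fold_many([w.sequence for w in real_w], energy_model)]
    decoy_mfe = [r.mfe for r in fold_many([w.sequence for w in decoy_w], energy_model)]
    mfe_diffs = [a - b for a, b in zip(real_mfe, decoy_mfe)]
    out = {
        "gc": signed_rank_test(gc_diffs, label_a="real", label_b="decoy"),
        "mfe": signed_rank_test(mfe_diffs, label_a="real", label_b="decoy"),
    }
    norm_diffs = []
    for p in pairs:
        nr = normalized_junction_gc(genome, p.real)
        nd = normalized_junction_gc(genome, p.decoy)
        if nr is not None and nd is not None:
            norm_diffs.append(nr - nd)
    if len(norm_diffs) >= 10:
        out["normalized_gc"] = signed_rank_test(
            norm_diffs, label_a="real", label_b="decoy"
        )
    return out


def write_decoy_table(pairs: Sequence[DecoyPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_name\tstrand\tside\treal_pos_1based\tdecoy_pos_1based\t"
            "distance_nt\treal_score_bits\tdecoy_score_bits\n"
        )
        for p in pairs:
            fh.write(
                f"{p.real.seq_name}\t{p.real.strand}\t{p.real.side}\t"
                f"{p.real.junction_pos + 1}\t{p.decoy.junction_pos + 1}\t"
                f"{p.distance}\t{p.real_score:.4f}\t{p.decoy_score:.4f}\n"
            )


def write_decoy_bed(pairs: Sequence[DecoyPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            d = p.decoy
            fh.write(
                f"{d.seq_name}\t{d.junction_pos}\t{d.junction_pos + 1}\t"
                f"decoy_{d.side}\t{p.decoy_score:.3f}\t{d.strand}\n"
            )
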