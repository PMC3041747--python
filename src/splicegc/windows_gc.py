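"""Junction-window extraction and GC metrics.

Windows are sense-strand sequences of length ``2*flank + 1`` centered on the
junction base (the first intronic base for donors, the last intronic base
for acceptors).  Windows run over raw genomic sequence regardless of
neighboring feature boundaries.  The two flanks are the exonic and intronic
halves; the central junction base belongs to neither half and is counted
separately, so that ``gc_number = GC(exonic) + GC(intronic) + GC(center)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_assembly import SpliceSiteRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_GC_SET = frozenset("GCgc")
_ALPHABET = frozenset("ACGTUNacgtun")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    return sum(1 for c in seq if c in _GC_SET)


def gc_fraction(seq: str) -> float:
    return gc_count(seq) / len(seq) if seq else 0.0


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines fine) -> {name: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class JunctionWindow:
    """Sense-strand window around one splice junction plus its GC metrics."""

    site: SpliceSiteRecord
    sequence: str
    flank: int
    exonic_half: str
    intronic_half: str
    gc_number: int
    gc_fraction: float
    gc_exonic: float
    gc_intronic: float


@dataclass(frozen=True)
class PositionalProfile:
    """Per-offset mean GC indicator across aligned windows.

    Offsets are relative to the junction base; negative offsets lie on the
    exonic side.
    """

    offsets: tuple[int, ...]
    mean_gc: tuple[float, ...]
    n: int


def extract_window(
    genome: Mapping[str, str], site: SpliceSiteRecord, flank: int = 70
) -> JunctionWindow:
    """Extract the sense-strand window around ``site`` and compute GC metrics.

    Raises ``ValueError`` when the window does not fit in the sequence;
    batch callers should use :func:`extract_windows`, which drops such sites
    with a logged warning instead.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = genome.get(site.seq_name)
    if seq is None:
        raise ValueError(f"unknown sequence {site.seq_name!r}")
    p = site.junction_pos
    lo, hi = p - flank, p + flank + 1
    if lo < 0 or hi > len(seq):
        raise ValueError(
            f"window [{lo},{hi}) out of bounds for {site.seq_name} (len {len(seq)})"
        )
    raw = seq[lo:hi]
    window = raw if site.strand == "+" else reverse_complement(raw)
    return gc_metrics(site, window, flank)


def gc_metrics(site: SpliceSiteRecord, window: str, flank: int) -> JunctionWindow:
    """Assemble a :class:`JunctionWindow` with all GC metrics populated."""
    if len(window) != 2 * flank + 1:
        raise ValueError(f"window length {len(window)} != {2 * flank + 1}")
    bad = set(window) - _ALPHABET
    if bad:
        raise ValueError(f"non-alphabet characters in window: {sorted(bad)}")
    # sense orientation: donors read exon -> intron, acceptors intron -> exon
    if site.side == "donor":
        exonic, intronic = window[:flank], window[flank + 1 :]
    else:
        intronic, exonic = window[:flank], window[flank + 1 :]
    return JunctionWindow(
        site=site,
        sequence=window,
        flank=flank,
        exonic_half=exonic,
        intronic_half=intronic,
        gc_number=gc_count(window),
        gc_fraction=gc_fraction(window),
        gc_exonic=gc_fraction(exonic),
        gc_intronic=gc_fraction(intronic),
    )


def extract_windows(
    genome: Mapping[str, str],
    sites: Iterable[SpliceSiteRecord],
    flank: int = 70,
) -> list[JunctionWindow]:
    """Batch extraction; out-of-bounds sites are dropped with a warning."""
    out = []
    dropped = 0
    for site in sites:
        try:
            out.append(extract_window(genome, site, flank))
        except ValueError as exc:
            dropped += 1
            logger.warning("dropping site %s: %s", site.key, exc)
    if dropped:
        logger.warning("dropped %d/%d sites during window extraction",
                       dropped, dropped + len(out))
    return out


def positional_gc_profile(windows: Sequence[JunctionWindow]) -> PositionalProfile:
    """Mean GC indicator per offset (negative offsets = exonic side)."""
    if not windows:
        raise ValueError("no windows supplied")
    flank = windows[0].flank
    side = windows[0].site.side
    for w in windows:
        if w.flank != flank or w.site.side != side:
            raise ValueError("windows must share flank and side")
    mat = np.array(
        [[1.0 if c in _GC_SET else 0.0 for c in w.sequence] for w in windows]
    )
    means = mat.mean(axis=0)
    if side == "donor":
        offsets = tuple(range(-flank, flank + 1))
        ordered = means
    else:  # exonic side is at the end of the sense window; flip to exonic=negative
        offsets = tuple(range(-flank, flank + 1))
        ordered = means[::-1]
    return PositionalProfile(offsets, tuple(float(x) for x in ordered), len(windows))


def pooled_profile(profiles: Sequence[PositionalProfile]) -> PositionalProfile:
    """n-weighted mean of per-set profiles (equals the pooled-window profile)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    offsets = profiles[0].offsets
    total = sum(p.n for p in profiles)
    acc = np.zeros(len(offsets))
    for p in profiles:
        if p.offsets != offsets:
            raise ValueError("profiles must share offsets")
        acc += np.array(p.mean_gc) * p.n
    return PositionalProfile(offsets, tuple(acc / total), total)


def normalized_junction_gc(
    genome: Mapping[str, str],
    site: SpliceSiteRecord,
    near: int = 50,
    far: int = 100,
) -> float | None:
    """GC of the near exonic region divided by GC of the longer exonic region.

    Both regions start at the junction and run in the exonic direction
    (default 50 bp over 100 bp).  Returns ``None`` (with a warning) when a
    region is out of bounds or the denominator is zero.
    """
    seq = genome.get(site.seq_name)
    if seq is None:
        raise ValueError(f"unknown sequence {site.seq_name!r}")
    p = site.junction_pos
    # exonic direction from the junction base
    exon_right = (site.side == "donor") == (site.strand == "-")
    if exon_right:
        near_region = seq[p + 1 : p + 1 + near]
        far_region = seq[p + 1 : p + 1 + far]
        in_bounds = p + 1 + far <= len(seq)
    else:
        near_region = seq[max(p - near, 0) : p]
        far_region = seq[max(p - far, 0) : p]
        in_bounds = p - far >= 0
    if not in_bounds:
        logger.warning("normalized GC: regions out of bounds for site %s", site.key)
        return None
    denom = gc_fraction(far_region)
    if denom == 0.0:
        logger.warning("normalized GC: zero denominator for site %s", site.key)
        return None
    return gc_fraction(near_region) / denom


def write_window_table(windows: Iterable[JunctionWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_name\tstrand\tside\tjunction_pos_1based\tcategory\tsequence\t"
            "gc_number\tgc_fraction\tgc_exonic\tgc_intronic\n"
        )
        for w in windows:
            s = w.site
            fh.write(
                f"{s.seq_name}\t{s.strand}\t{s.side}\t{s.junction_pos + 1}\t"
                f"{s.category}\t{w.sequence}\t{w.gc_number}\t{w.gc_fraction:.6f}\t"
                f"{w.gc_exonic:.6f}\t{w.gc_intronic:.6f}\n"
            )


def write_profile(profile: PositionalProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset_nt\tmean_gc_fraction\tn\n")
        for off, gc in zip(profile.offsets, profile.mean_gc):
            fh.write(f"{off}\t{gc:.6f}\t{profile.n}\n")
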