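"""Synthetic genomes, annotations and tissue tables with planted effects.

Every gene follows a six-exon template realizing all tracked categories:
a first exon (shared TSS; donor constitutive or alternative), an exon with
two competing donors, a cassette exon, an exon with two competing
acceptors, a constitutive exon, and a last exon, over four isoforms.
Junction windows are painted to per-category GC targets (exact GC count,
random arrangement), GT/AG consensus dinucleotides are written at every
real junction, and one decoy site per real site is planted 150-300 nt into
the flanking intron by copying the real site's scoring window; competing
consensus dinucleotides in the decoy zone are scrubbed so that the planted
decoy is the unique qualifier.

All drawing comes from a single seeded generator in a fixed order, so a
fixed seed yields byte-identical FASTA/GTF/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_assembly import (
    ExonInterval,
    SpliceSiteRecord,
    TranscriptModel,
)
from .stats import TissueEvent
from .windows_gc import JunctionWindow, gc_metrics, reverse_complement

DEFAULT_GC_MEANS = {
    "alternative": 0.52,
    "constitutive": 0.48,
    "skipped": 0.47,
    "first_alternative": 0.62,
    "first_constitutive": 0.64,
}
GC_TISSUE_SPECIFIC = 0.56


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; defaults give a small but complete genome."""

    seed: int = 0
    n_genes: int = 30
    gc_means: dict = field(default_factory=lambda: dict(DEFAULT_GC_MEANS))
    gc_sd: float = 0.05
    gc_background: float = 0.44
    gc_tissue_specific: float = GC_TISSUE_SPECIFIC
    exon_len: tuple[int, int] = (150, 190)
    long_exon_len: tuple[int, int] = (220, 280)
    frac_long_constitutive: float = 0.3
    gc_long_boost: float = 0.04  # extra GC planted at long-exon junctions
    intron_len: tuple[int, int] = (700, 900)
    donor_offset: int = 6  # >= 5 bp between competing donors
    acceptor_offset: int = 9  # >= 8 bp between competing acceptors
    frac_first_alternative: float = 0.5
    plant_decoys: bool = True
    decoy_zone: tuple[int, int] = (150, 300)
    flank: int = 70
    paint_tissue_specific: bool = False
    fraction_tissue_specific: float = 0.25
    n_tissues: int = 10
    n_events: int = 200
    seq_name: str = "synth1"

    def __post_init__(self):
        for cat, mu in self.gc_means.items():
            if not 0.0 < mu < 1.0:
                raise ValueError(f"GC mean for {cat} out of (0,1): {mu}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.donor_offset < 5 or self.acceptor_offset < 8:
            raise ValueError("offsets below the minimum-distance filters")
        lo, hi = self.decoy_zone
        if self.intron_len[0] < 2 * hi + 100:
            raise ValueError(
                f"introns of {self.intron_len[0]} nt cannot host two "
                f"{lo}-{hi} nt decoy zones"
            )


@dataclass(frozen=True)
class TruthRecord:
    """One planted splice site with its category and planted parameters."""

    gene_id: str
    seq_name: str
    strand: str
    side: str
    junction_pos: int  # genomic, 0-based
    category: str
    gc_target: float
    decoy_pos: int  # genomic junction position of the planted decoy, or -1
    tissue_specific: bool


def _gc_exact_sequence(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    """Random sequence with exactly round(gc * length) G+C characters."""
    k = int(round(gc * length))
    out = np.empty(length, dtype="<U1")
    strong = rng.integers(0, 2, size=k)
    weak = rng.integers(0, 2, size=length - k)
    idx = rng.permutation(length)
    out[idx[:k]] = np.where(strong == 0, "G", "C")
    out[idx[k:]] = np.where(weak == 0, "A", "T")
    return out.tolist()


@dataclass
class _TxSite:
    side: str
    pos: int  # tx coordinate of the junction base
    category: str
    gc_target: float
    decoy_pos: int
    tissue_specific: bool


def _build_gene(cfg: SyntheticConfig, rng: np.random.Generator, gene_id: str):
    """Assemble one gene in transcription coordinates."""
    exon = lambda: int(rng.integers(*cfg.exon_len))
    intron = lambda: int(rng.integers(*cfg.intron_len))

    first_alt = bool(rng.random() < cfg.frac_first_alternative)
    L1 = exon()
    L1b = L1 + cfg.donor_offset if first_alt else L1
    S2 = L1b + intron()
    d1 = S2 + exon()
    d2 = d1 + cfg.donor_offset
    S3 = d2 + intron()
    E3end = S3 + exon()
    S4 = E3end + intron()
    a2 = S4 + cfg.acceptor_offset
    E4end = a2 + exon()
    S5 = E4end + intron()
    long_cons = rng.random() < cfg.frac_long_constitutive
    L5 = int(rng.integers(*cfg.long_exon_len)) if long_cons else exon()
    E5end = S5 + L5
    S6 = E5end + intron()
    L = S6 + exon()

    e1a, e1b = (0, L1), (0, L1b)
    e2a, e2b = (S2, d1), (S2, d2)
    e3 = (S3, E3end)
    e4a, e4b = (S4, E4end), (a2, E4end)
    e5 = (S5, E5end)
    e6 = (S6, L)
    isoforms = [
        (e1a, e2a, e3, e4a, e5, e6),
        (e1a, e2b, e3, e4b, e5, e6),
        (e1b, e2a, e4a, e5, e6),
        (e1b, e2b, e3, e4b, e5, e6),
    ]

    def target(cat: str) -> float:
        mu = cfg.gc_means[cat]
        return float(np.clip(rng.normal(mu, cfg.gc_sd), 0.25, 0.85))

    ts_donor = cfg.paint_tissue_specific and rng.random() < cfg.fraction_tissue_specific
    ts_accept = cfg.paint_tissue_specific and rng.random() < cfg.fraction_tissue_specific

    def alt_target(ts: bool) -> float:
        mu = cfg.gc_tissue_specific if ts else cfg.gc_means["alternative"]
        return float(np.clip(rng.normal(mu, cfg.gc_sd), 0.25, 0.85))

    first_cat = "first_alternative" if first_alt else "first_constitutive"
    t_first = target(first_cat)
    t_alt_d = alt_target(ts_donor)
    t_alt_a = alt_target(ts_accept)
    t_skip = target("skipped")
    t_cons = target("constitutive") + (cfg.gc_long_boost if long_cons else 0.0)

    dist = lambda: int(rng.integers(160, 291))
    zone_near = 160  # shared decoy distance for variant groups
    sites: list[_TxSite] = []
    if cfg.plant_decoys:
        q_first = L1b + zone_near
        q_alt_d = d2 + zone_near
        q_alt_a = (S4 - 1) - zone_near
        q_skip_d = E3end + dist()
        q_skip_a = (S3 - 1) - dist()
        q_cons_d = E5end + dist()
        q_cons_a = (S5 - 1) - dist()
    else:
        q_first = q_alt_d = q_alt_a = q_skip_d = q_skip_a = q_cons_d = q_cons_a = -1

    sites.append(_TxSite("donor", L1, first_cat, t_first, q_first, False))
    if first_alt:
        sites.append(_TxSite("donor", L1b, first_cat, t_first, q_first, False))
    sites.append(_TxSite("donor", d1, "alternative", t_alt_d, q_alt_d, ts_donor))
    sites.append(_TxSite("donor", d2, "alternative", t_alt_d, q_alt_d, ts_donor))
    sites.append(_TxSite("acceptor", S4 - 1, "alternative", t_alt_a, q_alt_a, ts_accept))
    sites.append(_TxSite("acceptor", a2 - 1, "alternative", t_alt_a, q_alt_a, ts_accept))
    sites.append(_TxSite("donor", E3end, "skipped", t_skip, q_skip_d, False))
    sites.append(_TxSite("acceptor", S3 - 1, "skipped", t_skip, q_skip_a, False))
    sites.append(_TxSite("donor", E5end, "constitutive", t_cons, q_cons_d, False))
    sites.append(_TxSite("acceptor", S5 - 1, "constitutive", t_cons, q_cons_a, False))

    # --- sequence assembly (tx orientation) ---
    seq = _gc_exact_sequence(rng, L, cfg.gc_background)
    f = cfg.flank
    for s in sites:  # paint junction windows to their GC targets
        lo, hi = max(s.pos - f, 0), min(s.pos + f + 1, L)
        seq[lo:hi] = _gc_exact_sequence(rng, hi - lo, s.gc_target)
    for s in sites:  # consensus dinucleotides at real junctions
        if s.side == "donor":
            seq[s.pos], seq[s.pos + 1] = "G", "T"
        else:
            seq[s.pos - 1], seq[s.pos] = "A", "G"

    if cfg.plant_decoys:
        _plant_decoys(cfg, seq, sites)

    return "".join(seq), isoforms, sites


def _plant_decoys(cfg: SyntheticConfig, seq: list[str], sites: list[_TxSite]) -> None:
    from .decoy_model import (
        ACCEPTOR_EXONIC,
        ACCEPTOR_INTRONIC,
        DONOR_EXONIC,
        DONOR_INTRONIC,
    )

    lo, hi = cfg.decoy_zone
    # copy the real scoring window onto the decoy location (first site of a
    # variant group wins; iteration order is fixed for determinism)
    seen: set[tuple[str, int]] = set()
    copies: list[tuple[str, int, int]] = []
    for _s in sites:
        if (_s.side, _s.decoy_pos) not in seen:
            seen.add((_s.side, _s.decoy_pos))
            copies.append((_s.side, _s.decoy_pos, _s.pos))
    for side, q, p in copies:
        if side == "donor":
            a, b = DONOR_EXONIC, DONOR_INTRONIC - 1
        else:
            a, b = ACCEPTOR_INTRONIC - 1, ACCEPTOR_EXONIC
        seq[q - a : q + b + 1] = seq[p - a : p + b + 1]

    planted_donor = {s.decoy_pos for s in sites if s.side == "donor"}
    planted_accept = {s.decoy_pos for s in sites if s.side == "acceptor"}
    for s in sites:  # scrub competing dinucleotides in each zone
        step = 1 if s.side == "donor" else -1
        for d in range(lo, hi + 1):
            r = s.pos + step * d
            if s.side == "donor":
                # T -> A keeps the zone's GC content unchanged
                if r not in planted_donor and seq[r] == "G" and seq[r + 1] == "T":
                    seq[r + 1] = "A"
            else:
                if r not in planted_accept and seq[r - 1] == "A" and seq[r] == "G":
                    seq[r] = "C"


def generate_genome_annotation(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[TranscriptModel], list[TruthRecord]]:
    """Generate (genome, transcript models, truth table) with planted effects."""
    rng = np.random.default_rng(config.seed)
    pad = 200
    chrom_parts: list[str] = []
    models: list[TranscriptModel] = []
    truth: list[TruthRecord] = []
    offset = pad
    chrom_parts.append("".join(_gc_exact_sequence(rng, pad, config.gc_background)))

    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        seq, isoforms, sites = _build_gene(config, rng, gene_id)
        L = len(seq)

        if strand == "+":
            chrom_parts.append(seq)
            tx2gen = lambda p: offset + p
            exon2gen = lambda s, e: (offset + s, offset + e)
        else:
            chrom_parts.append(reverse_complement(seq))
            tx2gen = lambda p: offset + L - 1 - p
            exon2gen = lambda s, e: (offset + L - e, offset + L - s)

        for t, exons in enumerate(isoforms):
            intervals = tuple(
                ExonInterval(config.seq_name, *exon2gen(s, e), strand)
                for s, e in exons
            )
            models.append(
                TranscriptModel(
                    f"{gene_id}.t{t + 1}", gene_id, config.seq_name, strand, intervals
                )
            )
        for s in sites:
            truth.append(
                TruthRecord(
                    gene_id=gene_id,
                    seq_name=config.seq_name,
                    strand=strand,
                    side=s.side,
                    junction_pos=tx2gen(s.pos),
                    category=s.category,
                    gc_target=s.gc_target,
                    decoy_pos=tx2gen(s.decoy_pos) if s.decoy_pos >= 0 else -1,
                    tissue_specific=s.tissue_specific,
                )
            )
        offset += L + pad
        chrom_parts.append("".join(_gc_exact_sequence(rng, pad, config.gc_background)))

    genome = {config.seq_name: "".join(chrom_parts)}
    return genome, models, truth


# ---------------------------------------------------------------------------
# direct window cohorts (bypass genome assembly for fast statistics)


def _dummy_site(category: str, side: str, index: int, seq_name: str = "cohort") -> SpliceSiteRecord:
    exon = ExonInterval(seq_name, index * 1000 + 100, index * 1000 + 250, "+")
    pos = exon.end if side == "donor" else exon.start - 1
    return SpliceSiteRecord(
        seq_name=seq_name, strand="+", side=side, junction_pos=pos,
        category=category, gene_id=f"cohort{index}", source_exon=exon,
    )


def generate_windows_cohort(
    config: SyntheticConfig,
    n_per_category: int = 400,
    categories: Sequence[str] = ("alternative", "constitutive", "skipped"),
    side: str = "donor",
) -> dict[str, list[JunctionWindow]]:
    """Labelled windows sampled straight from the per-category GC targets.

    Each window has exactly round(target * length) G+C characters, with the
    target drawn N(mean, sd) per window (sd = 0 pins the GC count).
    """
    rng = np.random.default_rng(config.seed)
    length = 2 * config.flank + 1
    out: dict[str, list[JunctionWindow]] = {}
    for cat in categories:
        mu = config.gc_means[cat]
        windows = []
        for i in range(n_per_category):
            t = float(np.clip(rng.normal(mu, config.gc_sd), 0.05, 0.95))
            seq = "".join(_gc_exact_sequence(rng, length, t))
            windows.append(gc_metrics(_dummy_site(cat, side, i), seq, config.flank))
        out[cat] = windows
    return out


# ---------------------------------------------------------------------------
# tissue tables


def generate_tissue_table(
    config: SyntheticConfig,
    site_ids: Sequence[str] | None = None,
    specific_flags: Sequence[bool] | None = None,
) -> tuple[list[TissueEvent], dict[str, bool]]:
    """Events whose per-tissue (delta, p) draws sit clear of the rule thresholds.

    Planted tissue-specific events get at least one tissue with
    delta ~ U(0.12, 0.4) and p ~ U(0, 0.25); all other entries fall in the
    non-specific region (delta < 0.04, or strong delta with p > 0.35).
    """
    rng = np.random.default_rng(config.seed + 1)
    tissues = [f"tissue{i:02d}" for i in range(config.n_tissues)]
    if site_ids is None:
        n = config.n_events
        site_ids = [f"site{i:04d}" for i in range(n)]
        specific_flags = list(rng.random(n) < config.fraction_tissue_specific)
    elif specific_flags is None:
        raise ValueError("specific_flags required when site_ids are supplied")

    events: list[TissueEvent] = []
    flags: dict[str, bool] = {}
    for i, (sid, flag) in enumerate(zip(site_ids, specific_flags)):
        rows = []
        for t in tissues:
            if rng.random() < 0.15:  # strong change but unconvincing p-value
                rows.append((t, float(rng.uniform(0.12, 0.4)), float(rng.uniform(0.35, 1.0))))
            else:
                rows.append((t, float(rng.uniform(0.0, 0.04)), float(rng.uniform(0.0, 1.0))))
        if flag:
            k = int(rng.integers(0, config.n_tissues))
            rows[k] = (tissues[k], float(rng.uniform(0.12, 0.4)), float(rng.uniform(0.0, 0.25)))
        events.append(TissueEvent(f"event{i:04d}", sid, tuple(rows)))
        flags[f"event{i:04d}"] = bool(flag)
    return events, flags


# ---------------------------------------------------------------------------
# writers / readers (plain-text artifacts)


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.seq_name}\tsynthetic\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tseq_name\tstrand\tside\tjunction_pos_1based\tcategory\t"
            "gc_target\tdecoy_pos_1based\ttissue_specific\n"
        )
        for r in truth:
            decoy = r.decoy_pos + 1 if r.decoy_pos >= 0 else 0
            fh.write(
                f"{r.gene_id}\t{r.seq_name}\t{r.strand}\t{r.side}\t"
                f"{r.junction_pos + 1}\t{r.category}\t{r.gc_target:.4f}\t"
                f"{decoy}\t{int(r.tissue_specific)}\n"
            )


def write_tissue_table(events: Sequence[TissueEvent], path: str | Path) -> None:
    """Long-format TSV: one row per (event, tissue)."""
    with open(path, "w") as fh:
        fh.write("event_id\tsite_id\ttissue\tdelta_proportion\tp_value\n")
        for ev in events:
            for tissue, delta, p in ev.tissues:
                fh.write(f"{ev.event_id}\t{ev.site_id}\t{tissue}\t{delta:.6f}\t{p:.6f}\n")


def read_tissue_table(path: str | Path) -> list[TissueEvent]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    events = []
    for (eid, sid), grp in df.groupby(["event_id", "site_id"], sort=True):
        rows = tuple(
            (str(r.tissue), float(r.delta_proportion), float(r.p_value))
            for r in grp.itertuples()
        )
        events.append(TissueEvent(str(eid), str(sid), rows))
    return events
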