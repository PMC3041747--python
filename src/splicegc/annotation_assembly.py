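"""Transcript-model parsing and splice-site categorization.

Splice sites of internal exons are classified as alternative (competing
donors/acceptors of the same exon, subject to minimum-distance filters),
constitutive (exon identical in every qualifying isoform of a gene with at
least four isoforms, overlapping no other exon), or skipped (cassette
exons).  First-exon donors are classified separately.  Category lists are
built independently; a site may appear in more than one list.

Coordinates are 0-based half-open internally and 1-based inclusive in
written reports.  For a donor, ``junction_pos`` is the first intronic base;
for an acceptor, the last intronic base (both in genomic coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

LONG_EXON_THRESHOLD = 200
MIN_DONOR_DISTANCE = 5  # between two 5'ss of the same exon
MIN_ACCEPTOR_DISTANCE = 8  # between two 3'ss of the same exon

CATEGORIES = (
    "alternative",
    "constitutive",
    "skipped",
    "first_alternative",
    "first_constitutive",
)


@dataclass(frozen=True, order=True)
class ExonInterval:
    """Genomic exon: 0-based half-open interval on a strand."""

    seq_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"exon end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ExonInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered, non-overlapping exons on one sequence/strand."""

    transcript_id: str
    gene_id: str
    seq_name: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.seq_name != self.seq_name or e.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon on {e.seq_name}{e.strand} "
                    f"does not match transcript {self.seq_name}{self.strand}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} / {b}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def internal_exons(self) -> tuple[ExonInterval, ...]:
        return self.exons[1:-1]

    def first_exon(self) -> ExonInterval:
        # first in transcription order
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end


@dataclass(frozen=True)
class SpliceSiteRecord:
    """One donor/acceptor junction with its category and provenance."""

    seq_name: str
    strand: str
    side: str  # donor | acceptor
    junction_pos: int  # 0-based genomic; see module docstring
    category: str
    gene_id: str
    source_exon: ExonInterval

    def __post_init__(self):
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.category not in CATEGORIES + ("decoy",):
            raise ValueError(f"invalid category {self.category!r}")

    @property
    def exon_length_class(self) -> str:
        return exon_length_class(self.source_exon)

    @property
    def key(self) -> tuple:
        return (self.seq_name, self.strand, self.side, self.junction_pos, self.category)


def exon_length_class(exon: ExonInterval, threshold: int = LONG_EXON_THRESHOLD) -> str:
    """'long' for length > threshold (default 200 bp), else 'short'."""
    return "long" if exon.length > threshold else "short"


def donor_junction(exon: ExonInterval) -> int:
    """Genomic position of the first intronic base downstream of the exon."""
    return exon.end if exon.strand == "+" else exon.start - 1


def acceptor_junction(exon: ExonInterval) -> int:
    """Genomic position of the last intronic base upstream of the exon."""
    return exon.start - 1 if exon.strand == "+" else exon.end


def _site(exon: ExonInterval, side: str, category: str, gene_id: str) -> SpliceSiteRecord:
    pos = donor_junction(exon) if side == "donor" else acceptor_junction(exon)
    return SpliceSiteRecord(
        seq_name=exon.seq_name, strand=exon.strand, side=side,
        junction_pos=pos, category=category, gene_id=gene_id, source_exon=exon,
    )


def dedupe(records: Iterable[SpliceSiteRecord]) -> list[SpliceSiteRecord]:
    seen = set()
    out = []
    for r in records:
        if r.key not in seen:
            seen.add(r.key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# loaders


def load_annotation(path: str | Path, dialect: str = "gtf") -> list[TranscriptModel]:
    """Load transcript models from a GTF or BED12 file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gtf":
        models = _load_gtf(path)
    elif dialect == "bed12":
        models = _load_bed12(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not models:
        logger.warning("no transcripts parsed from %s", path)
    return models


def _load_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "gene_id/transcript_id"
            )
        rec = grouped.setdefault(
            tid, dict(gene_id=gid, seq_name=feat.seqid, strand=feat.strand, exons=[])
        )
        rec["exons"].append(
            ExonInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return [
        TranscriptModel(tid, rec["gene_id"], rec["seq_name"], rec["strand"],
                        tuple(rec["exons"]))
        for tid, rec in grouped.items()
    ]


def _load_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom, start = fields[0], int(fields[1])
                name, strand = fields[3], fields[5]
                count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line: {exc}") from exc
            if len(sizes) != count or len(starts) != count:
                raise ValueError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = tuple(
                ExonInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            )
            gene_id = name.rsplit(".", 1)[0] if "." in name else name
            models.append(TranscriptModel(name, gene_id, chrom, strand, exons))
    return models


def group_by_gene(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    return genes


# ---------------------------------------------------------------------------
# classification


def _check_one_gene(gene: Sequence[TranscriptModel]) -> None:
    ids = {m.gene_id for m in gene}
    if len(ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(ids)}")


def find_constitutive_sites(gene: Sequence[TranscriptModel]) -> list[SpliceSiteRecord]:
    """Donor+acceptor of internal exons identical in every >=3-exon isoform.

    The gene must have at least four qualifying isoforms, and the exon may
    not overlap any other distinct exon of the gene.
    """
    _check_one_gene(gene)
    pool = [m for m in gene if m.n_exons >= 3]
    if len(pool) < 4:
        return []
    gene_id = pool[0].gene_id
    # overlap is checked against every exon of the gene, including isoforms
    # excluded from the identity requirement by the 3-exon rule
    all_exons = {e for m in gene for e in m.exons}
    out = []
    candidates = set(pool[0].internal_exons())
    for exon in sorted(candidates):
        if not all(exon in m.internal_exons() for m in pool):
            continue
        if any(other != exon and other.overlaps(exon) for other in all_exons):
            continue
        out.append(_site(exon, "donor", "constitutive", gene_id))
        out.append(_site(exon, "acceptor", "constitutive", gene_id))
    return dedupe(out)


def find_alternative_sites(
    gene: Sequence[TranscriptModel],
    min_donor_dist: int = MIN_DONOR_DISTANCE,
    min_acceptor_dist: int = MIN_ACCEPTOR_DISTANCE,
) -> list[SpliceSiteRecord]:
    """Competing donors/acceptors of internal exons sharing one boundary.

    A group of exon variants sharing the acceptor-side boundary but
    differing at the donor side yields alternative donor sites (and vice
    versa); all sites of a group are emitted, provided every pairwise
    distance meets the minimum (5 bp donors, 8 bp acceptors) — otherwise
    the whole group is suppressed.
    """
    _check_one_gene(gene)
    gene_id = gene[0].gene_id
    internal = {e for m in gene for e in m.internal_exons()}
    out = []
    for side, min_dist in (("donor", min_donor_dist), ("acceptor", min_acceptor_dist)):
        groups: dict[int, set[int]] = {}
        for exon in internal:
            if side == "donor":
                anchor, var = acceptor_junction(exon), donor_junction(exon)
            else:
                anchor, var = donor_junction(exon), acceptor_junction(exon)
            groups.setdefault(anchor, set()).add(var)
        for anchor, positions in groups.items():
            if len(positions) < 2:
                continue
            pos = sorted(positions)
            if any(b - a < min_dist for a, b in zip(pos, pos[1:])):
                continue
            for exon in internal:
                if side == "donor" and acceptor_junction(exon) == anchor:
                    out.append(_site(exon, "donor", "alternative", gene_id))
                elif side == "acceptor" and donor_junction(exon) == anchor:
                    out.append(_site(exon, "acceptor", "alternative", gene_id))
    return dedupe(out)


def find_skipped_sites(gene: Sequence[TranscriptModel]) -> list[SpliceSiteRecord]:
    """Cassette-exon (skipped) splice sites.

    An internal exon is skipped when some other isoform of the gene retains
    both flanking exons (identical coordinates) but contains no exon
    overlapping the cassette.
    """
    _check_one_gene(gene)
    gene_id = gene[0].gene_id
    out = []
    for m in gene:
        for i, exon in enumerate(m.exons[1:-1], 1):
            prev_e, next_e = m.exons[i - 1], m.exons[i + 1]
            for other in gene:
                if other is m:
                    continue
                if prev_e not in other.exons or next_e not in other.exons:
                    continue
                if any(e.overlaps(exon) for e in other.exons):
                    continue
                out.append(_site(exon, "donor", "skipped", gene_id))
                out.append(_site(exon, "acceptor", "skipped", gene_id))
                break
    return dedupe(out)


def classify_first_donor_sites(gene: Sequence[TranscriptModel]) -> list[SpliceSiteRecord]:
    """First-exon donors for genes whose >=3-exon isoforms share one TSS.

    The donor is ``first_constitutive`` when its position is identical in
    all (>=3) isoforms, otherwise each distinct donor is
    ``first_alternative``.  Genes with differing TSSs are excluded.
    """
    _check_one_gene(gene)
    pool = [m for m in gene if m.n_exons >= 3]
    if len(pool) < 3:
        return []
    gene_id = pool[0].gene_id
    if len({m.tss for m in pool}) != 1:
        return []
    first_exons = [m.first_exon() for m in pool]
    donors = {donor_junction(e) for e in first_exons}
    category = "first_constitutive" if len(donors) == 1 else "first_alternative"
    return dedupe(_site(e, "donor", category, gene_id) for e in first_exons)


def classify_all(
    models: Iterable[TranscriptModel],
    min_donor_dist: int = MIN_DONOR_DISTANCE,
    min_acceptor_dist: int = MIN_ACCEPTOR_DISTANCE,
) -> dict[str, list[SpliceSiteRecord]]:
    """Run every classifier over all genes; one independent list per category."""
    genes = group_by_gene(models)
    lists: dict[str, list[SpliceSiteRecord]] = {c: [] for c in CATEGORIES}
    for gene in genes.values():
        lists["constitutive"].extend(find_constitutive_sites(gene))
        lists["alternative"].extend(
            find_alternative_sites(gene, min_donor_dist, min_acceptor_dist)
        )
        lists["skipped"].extend(find_skipped_sites(gene))
        for rec in classify_first_donor_sites(gene):
            lists[rec.category].append(rec)
    return {c: dedupe(v) for c, v in lists.items()}


def write_site_table(records: Iterable[SpliceSiteRecord], path: str | Path) -> None:
    """TSV writer; junction positions are 1-based in the report."""
    with open(path, "w") as fh:
        fh.write(
            "seq_name\tstrand\tside\tjunction_pos_1based\tcategory\t"
            "gene_id\texon_length\texon_length_class\n"
        )
        for r in records:
            fh.write(
                f"{r.seq_name}\t{r.strand}\t{r.side}\t{r.junction_pos + 1}\t"
                f"{r.category}\t{r.gene_id}\t{r.source_exon.length}\t"
                f"{r.exon_length_class}\n"
            )
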