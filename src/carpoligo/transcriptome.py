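"""Transcriptome ingestion and gene-level collapsing.

Reads a genome (or transcriptome) FASTA together with a GFF3/GTF annotation,
assembles spliced transcript sequences, and collapses multi-isoform genes to a
single representative transcript (the longest isoform) — the unit against
which one 3'-anchored probe per gene is designed.

Paleotetraploid fish genomes carry extensive alternative splicing ("two to at
least fourteen isoforms" per gene is typical), so gene-level collapsing is the
first specificity-preserving step of the design pipeline.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from pyfaidx import Fasta

__all__ = [
    "TranscriptRecord",
    "TranscriptSet",
    "GeneModel",
    "load_transcriptome",
    "collapse_to_genes",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: annotation feature types recognised as transcript-level records
_TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "ncRNA",
    "lnc_RNA",
    "lncRNA",
    "misc_RNA",
    "miscRNA",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
}

_BIOTYPES = {"mRNA", "ncRNA", "miscRNA", "other"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript with its spliced sequence."""

    transcript_id: str
    gene_id: str
    sequence: str
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.biotype not in _BIOTYPES:
            object.__setattr__(self, "biotype", "other")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    """Collection of transcripts indexed by gene."""

    records: dict[str, TranscriptRecord] = field(default_factory=dict)
    gene_index: dict[str, list[str]] = field(default_factory=dict)

    def add(self, rec: TranscriptRecord) -> None:
        if rec.transcript_id in self.records:
            raise ValueError(f"duplicate transcript_id: {rec.transcript_id!r}")
        self.records[rec.transcript_id] = rec
        self.gene_index.setdefault(rec.gene_id, []).append(rec.transcript_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def transcripts_of(self, gene_id: str) -> list[TranscriptRecord]:
        return [self.records[t] for t in self.gene_index[gene_id]]


@dataclass(frozen=True)
class GeneModel:
    """A gene and its representative (longest) transcript."""

    gene_id: str
    representative: TranscriptRecord
    isoform_count: int


def _normalize_biotype(raw: str | None) -> str:
    if raw is None:
        return "mRNA"
    r = raw.strip()
    if r in ("mRNA", "protein_coding"):
        return "mRNA"
    if r in ("ncRNA", "lnc_RNA", "lncRNA", "lincRNA", "non_coding"):
        return "ncRNA"
    if r in ("miscRNA", "misc_RNA"):
        return "miscRNA"
    return "other"


def _attr(feature, *names: str) -> str | None:
    for n in names:
        vals = feature.attributes.get(n)
        if vals:
            return vals[0]
    return None


def load_transcriptome(fasta_path, annotation_path) -> TranscriptSet:
    """Build a :class:`TranscriptSet` from FASTA + GFF3/GTF.

    Spliced sequences are assembled from exon intervals in annotation order
    (GFF 1-based inclusive coordinates) and reverse-complemented for
    minus-strand transcripts. Transcripts lacking a gene parent are kept as
    single-isoform genes with ``gene_id == transcript_id``.

    Raises
    ------
    ValueError
        for a transcript referencing an absent sequence, an exon outside
        sequence bounds, or a duplicate transcript id.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    dialect = _sniff_dialect(annotation_path)
    _check_duplicate_ids(annotation_path, dialect)
    with tempfile.NamedTemporaryFile(suffix=".db") as dbfile:
        db = gffutils.create_db(
            str(annotation_path),
            dbfile.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        return _build_transcripts(fasta, db, dialect)


def _sniff_dialect(annotation_path) -> str:
    for line in Path(annotation_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 9 and "ID=" not in fields[8] and "Parent=" not in fields[8]:
            return "gtf"
        return "gff3"
    return "gff3"


def _check_duplicate_ids(annotation_path, dialect: str) -> None:
    # gffutils uniquifies duplicate IDs, so the contract error is raised here
    seen: set[str] = set()
    for line in Path(annotation_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] not in _TRANSCRIPT_TYPES:
            continue
        attrs = fields[8]
        tx_id = None
        if dialect == "gtf":
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("transcript_id"):
                    tx_id = part.split(None, 1)[1].strip().strip('"')
                    break
        else:
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    tx_id = part[3:]
                    break
        if tx_id is None:
            continue
        if tx_id in seen:
            raise ValueError(f"duplicate transcript_id: {tx_id!r}")
        seen.add(tx_id)


def _build_transcripts(fasta, db, dialect: str) -> TranscriptSet:
    # exons grouped by their parent transcript, preserving file order
    exons_by_tx: dict[str, list] = {}
    for exon in db.features_of_type("exon", order_by=None):
        if dialect == "gtf":
            parent = _attr(exon, "transcript_id")
            parents = [parent] if parent else []
        else:
            parents = list(exon.attributes.get("Parent", []))
        for p in parents:
            exons_by_tx.setdefault(p, []).append(exon)

    ts = TranscriptSet()
    seen: set[str] = set()
    for ftype in sorted(_TRANSCRIPT_TYPES):
        try:
            feats = list(db.features_of_type(ftype, order_by=None))
        except Exception:
            continue
        for tx in feats:
            if dialect == "gtf":
                tx_id = _attr(tx, "transcript_id") or tx.id
                gene_id = _attr(tx, "gene_id") or tx_id
            else:
                tx_id = _attr(tx, "ID") or tx.id
                gene_id = _attr(tx, "Parent") or tx_id
            # gffutils uniquifies duplicate IDs; detect the raw duplication
            raw_id = tx_id
            if raw_id in seen:
                raise ValueError(f"duplicate transcript_id: {raw_id!r}")
            seen.add(raw_id)
            biotype = _normalize_biotype(
                _attr(tx, "biotype", "gene_biotype", "transcript_biotype")
                or (tx.featuretype if tx.featuretype != "transcript" else None)
            )
            exons = exons_by_tx.get(tx_id) or [tx]
            seq = _spliced_sequence(fasta, tx_id, tx.seqid, tx.strand, exons)
            ts.add(TranscriptRecord(tx_id, gene_id, seq, biotype))
    return ts


def _spliced_sequence(fasta, tx_id: str, seqid: str, strand: str, exons) -> str:
    if seqid not in fasta:
        raise ValueError(f"transcript {tx_id!r} references absent sequence {seqid!r}")
    contig = fasta[seqid]
    clen = len(contig)
    parts = []
    for exon in exons:
        start, end = exon.start, exon.end  # 1-based inclusive
        if start < 1 or end > clen or start > end:
            raise ValueError(
                f"exon {start}..{end} of transcript {tx_id!r} outside "
                f"bounds of {seqid!r} (length {clen})"
            )
        parts.append(str(contig[start - 1 : end]))
    seq = "".join(parts)
    if strand == "-":
        seq = reverse_complement(seq)
    return seq


def collapse_to_genes(ts: TranscriptSet) -> list[GeneModel]:
    """One :class:`GeneModel` per gene: the longest isoform is representative.

    Ties on length break toward the lexicographically smallest transcript id,
    making the collapse deterministic and order-independent.
    """
    if len(ts) == 0:
        raise ValueError("empty TranscriptSet")
    models = []
    for gene_id in sorted(ts.gene_index):
        isoforms = ts.transcripts_of(gene_id)
        rep = min(isoforms, key=lambda r: (-r.length, r.transcript_id))
        models.append(GeneModel(gene_id, rep, len(isoforms)))
    return models
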