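"""Genome FASTA / GTF readers and spliced-sequence extraction.

All coordinates are handled in two conventions with a single conversion
point: GTF input is 1-based inclusive; every in-memory coordinate in this
package is 0-based half-open.  :class:`ExonInterval` therefore stores
0-based half-open genomic coordinates, and ``TranscriptModel`` stores
transcript-relative (spliced mRNA) coordinates for the annotated ORF.

Only protein-coding transcripts carrying an annotated ``stop_codon``
feature survive :func:`load_annotation`; transcripts with a non-canonical
stop, a CDS length not divisible by three, or a stop codon split across
an exon junction are dropped with a logged count rather than raised, since
real annotations contain such records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

VALID_NT = set("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")


class AnnotationError(ValueError):
    """Raised for structurally invalid FASTA/GTF input."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: an uppercase nucleotide string over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"empty sequence for chromosome {self.chrom_id!r}")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise AnnotationError(
                f"chromosome {self.chrom_id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return the subsequence [start, end) (0-based half-open)."""
        if start < 0 or end > len(self.sequence) or start >= end:
            raise AnnotationError(
                f"lookup [{start}, {end}) outside chromosome {self.chrom_id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True, order=True)
class ExonInterval:
    """Genomic exon interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"invalid exon interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon/ORF geometry of one protein-coding transcript.

    ``exons`` are ordered 5'->3' in *transcript* orientation (i.e. reversed
    genomic order on the minus strand).  ``orf_start``/``orf_end`` are
    transcript-relative 0-based half-open coordinates of the annotated ORF
    *including* the stop codon, so ``orf_end - orf_start`` is divisible by 3
    and the last three bases are TAA/TAG/TGA.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    orf_start: int
    orf_end: int
    biotype: str = "protein_coding"

    # -- derived geometry ------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.exons)

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    def _cumulative_starts(self) -> list[int]:
        starts = [0]
        for e in self.exons:
            starts.append(starts[-1] + len(e))
        return starts

    def exon_index_of(self, tpos: int) -> int:
        """Exon index (transcript orientation) containing transcript position tpos."""
        if tpos < 0 or tpos >= self.length:
            raise AnnotationError(
                f"transcript position {tpos} outside [0, {self.length}) "
                f"for {self.transcript_id}"
            )
        starts = self._cumulative_starts()
        for i in range(self.n_exons):
            if starts[i] <= tpos < starts[i + 1]:
                return i
        raise AssertionError("unreachable")

    @property
    def stop_codon_exon_index(self) -> int:
        """Index of the exon containing the first base of the annotated stop."""
        return self.exon_index_of(self.orf_end - 3)

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript-relative position to its 0-based genomic position."""
        i = self.exon_index_of(tpos)
        offset = tpos - self._cumulative_starts()[i]
        exon = self.exons[i]
        if self.strand == "+":
            return exon.start + offset
        return exon.end - 1 - offset

    def genomic_to_transcript(self, gpos: int) -> int:
        starts = self._cumulative_starts()
        for i, exon in enumerate(self.exons):
            if exon.start <= gpos < exon.end:
                if self.strand == "+":
                    return starts[i] + (gpos - exon.start)
                return starts[i] + (exon.end - 1 - gpos)
        raise AnnotationError(
            f"genomic position {gpos} not exonic in {self.transcript_id}"
        )

    @property
    def stop_codon_genomic_first(self) -> int:
        """Genomic position of the first base (5' in transcript orientation)."""
        return self.transcript_to_genomic(self.orf_end - 3)

    @property
    def stop_codon_genomic_last(self) -> int:
        return self.transcript_to_genomic(self.orf_end - 1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-record) FASTA into a chrom_id -> GenomeSequence map.

    Sequences are uppercased; duplicate record ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise AnnotationError(f"duplicate chromosome id {record.id!r} in {path}")
        genome[record.id] = GenomeSequence(record.id, str(record.seq).upper())
    if not genome:
        raise AnnotationError(f"no FASTA records found in {path}")
    return genome


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            values = feature.attributes[name]
            if values:
                return values[0]
    return None


def load_annotation(
    path: str | Path,
    genome: Mapping[str, GenomeSequence],
) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into validated transcript models.

    Keeps only protein-coding transcripts with an annotated stop codon and
    a well-formed ORF (length divisible by 3, canonical stop).  Drops are
    counted and logged, not raised; structural errors (unknown chromosome,
    overlapping exons) are raised.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_tx: dict[str, dict[str, list]] = {}
    meta: dict[str, dict[str, str]] = {}
    for ftype in ("exon", "CDS", "stop_codon"):
        for feat in db.features_of_type(ftype):
            tid = _attr(feat, "transcript_id")
            if tid is None:
                raise AnnotationError(f"{ftype} feature without transcript_id in {path}")
            bucket = per_tx.setdefault(tid, {"exon": [], "CDS": [], "stop_codon": []})
            bucket[ftype].append(feat)
            if tid not in meta:
                meta[tid] = {
                    "gene_id": _attr(feat, "gene_id") or tid,
                    "biotype": _attr(feat, "transcript_biotype", "gene_biotype")
                    or "unknown",
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                }

    models: list[TranscriptModel] = []
    n_not_coding = n_no_stop = n_bad_orf = 0
    for tid in sorted(per_tx):
        feats = per_tx[tid]
        info = meta[tid]
        if info["biotype"] != "protein_coding":
            n_not_coding += 1
            continue
        if not feats["stop_codon"]:
            n_no_stop += 1
            continue
        chrom = info["chrom"]
        strand = info["strand"]
        if chrom not in genome:
            raise AnnotationError(
                f"transcript {tid} on chromosome {chrom!r} absent from genome"
            )
        # exons: GTF 1-based inclusive -> 0-based half-open (single conversion point)
        exons_genomic = sorted(
            ExonInterval(chrom, f.start - 1, f.end, strand) for f in feats["exon"]
        )
        for a, b in zip(exons_genomic, exons_genomic[1:]):
            if b.start < a.end:
                raise AnnotationError(f"overlapping exons in transcript {tid}")
        exons = tuple(exons_genomic if strand == "+" else exons_genomic[::-1])

        model = _build_model(tid, info, exons, feats, genome)
        if model is None:
            n_bad_orf += 1
            continue
        models.append(model)

    logger.info(
        "load_annotation: kept %d transcripts (%d non-coding, %d without stop codon, "
        "%d with malformed ORF dropped)",
        len(models),
        n_not_coding,
        n_no_stop,
        n_bad_orf,
    )
    return models


def _build_model(tid, info, exons, feats, genome) -> Optional[TranscriptModel]:
    chrom, strand = info["chrom"], info["strand"]
    draft = TranscriptModel(
        transcript_id=tid,
        gene_id=info["gene_id"],
        chrom=chrom,
        strand=strand,
        exons=exons,
        orf_start=0,
        orf_end=3,
        biotype=info["biotype"],
    )
    # ORF = CDS + stop codon; locate 5'-most CDS base and 3'-most stop base
    # in transcript orientation.
    cds_positions = []
    for f in feats["CDS"] + feats["stop_codon"]:
        cds_positions.extend((f.start - 1, f.end - 1))
    try:
        tpos = [draft.genomic_to_transcript(g) for g in cds_positions]
    except AnnotationError:
        logger.warning("transcript %s: CDS/stop outside annotated exons; dropped", tid)
        return None
    orf_start, orf_end = min(tpos), max(tpos) + 1
    if (orf_end - orf_start) % 3 != 0:
        logger.warning("transcript %s: ORF length not divisible by 3; dropped", tid)
        return None
    draft.orf_start, draft.orf_end = orf_start, orf_end
    mrna = spliced_sequence(draft, genome)
    stop = mrna[orf_end - 3 : orf_end]
    if stop not in STOP_CODONS:
        logger.warning("transcript %s: non-canonical stop %r; dropped", tid, stop)
        return None
    return draft


# ---------------------------------------------------------------------------
# spliced sequence
# ---------------------------------------------------------------------------

def spliced_sequence(
    t: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
    skip_exon_index: Optional[int] = None,
) -> str:
    """Concatenate exon sequences in transcript orientation (mRNA sequence).

    ``skip_exon_index`` omits one exon; skipping the first or last exon is a
    geometry violation and raises.
    """
    if skip_exon_index is not None:
        if skip_exon_index <= 0 or skip_exon_index >= t.n_exons - 1:
            raise AnnotationError(
                f"cannot skip exon {skip_exon_index} of {t.n_exons}-exon transcript "
                f"{t.transcript_id}: only internal exons are skippable"
            )
    chrom_seq = genome[t.chrom]
    parts = []
    for i, exon in enumerate(t.exons):
        if i == skip_exon_index:
            continue
        raw = chrom_seq.fetch(exon.start, exon.end)
        parts.append(raw if t.strand == "+" else reverse_complement(raw))
    return "".join(parts)


def annotated_protein(t: TranscriptModel, genome: Mapping[str, GenomeSequence]) -> str:
    """Translation of the annotated ORF, stop codon excluded."""
    from .discovery import translate_to_stop  # local import to avoid cycle

    mrna = spliced_sequence(t, genome)
    aa, _ = translate_to_stop(mrna[: t.orf_end], t.orf_start)
    return aa


def utr3_sequence(t: TranscriptModel, genome: Mapping[str, GenomeSequence]) -> str:
    """The annotated 3'UTR: everything 3' of the stop codon in the mRNA."""
    return spliced_sequence(t, genome)[t.orf_end :]
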