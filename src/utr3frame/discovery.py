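"""Penultimate-exon skipping: geometry classification, translation of the
alternative C-terminus, gain filters, and cross-isoform deduplication.

The biological logic: skipping the penultimate exon of a protein-coding
transcript either removes the annotated stop codon (stop in the penultimate
exon, class ``Penultimate``) or shifts the reading frame of the last exon
(stop in the last exon, penultimate length not divisible by three, class
``Ultimate``).  In both cases the new stop codon lies in the last exon, so
the transcript escapes nonsense-mediated decay and the ribosome translates
into the region annotated as 3'UTR.  Candidates are retained when the new
C-terminus gains at least ``min_gained`` amino acids of which at least
``min_beyond`` are encoded 3' of the annotated stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .genome_io import (
    AnnotationError,
    GenomeSequence,
    TranscriptModel,
    spliced_sequence,
)

logger = logging.getLogger(__name__)

GEOMETRY_CLASSES = (
    "Ultimate",
    "Penultimate",
    "Internal_fp",
    "Internal_fs",
    "Penulti_fp",
    "Penulti_short",
)

#: classes eligible for the 3'UTR-extension path
CANDIDATE_CLASSES = ("Ultimate", "Penultimate")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class SkipEvent:
    """One potential single-exon skip with its genomic anchor coordinates.

    Genomic coordinates are 0-based; ``upstream_exon_end`` and
    ``downstream_exon_start`` are the boundaries of the flanking exons in
    *genomic* orientation, matching how duplicate events are collapsed.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_index_skipped: int
    upstream_exon_end: int
    exon_start: int
    exon_end: int
    downstream_exon_start: int
    annotated_stop_position: int
    geometry_class: str

    @property
    def exon_length(self) -> int:
        return self.exon_end - self.exon_start

    @property
    def dedup_key(self) -> tuple:
        return (
            self.chrom,
            self.strand,
            self.upstream_exon_end,
            self.exon_start,
            self.exon_end,
            self.downstream_exon_start,
            self.annotated_stop_position,
        )


@dataclass
class FrameshiftCandidate:
    """A translated penultimate-exon skip with its gain metrics.

    ``outcome`` refines the geometric class after translation:
    ``extended`` (new stop 3' of the annotated stop), ``boundary`` (new
    frame terminates at the annotated stop position), ``short`` (new stop
    5' of the annotated stop; reported as Penulti_short), ``non_stop``
    (no stop before the transcript end) or ``nmd`` (new stop upstream of
    the last exon).
    """

    skip_event: SkipEvent
    divergence_point: int
    new_cterm_aa: str
    aa_gained: int
    aa_beyond_stop: int
    new_stop_in_last_exon: bool
    stop_reached: bool
    outcome: str
    has_ambiguous: bool = False

    @property
    def transcript_id(self) -> str:
        return self.skip_event.transcript_id

    @property
    def gene_id(self) -> str:
        return self.skip_event.gene_id

    @property
    def event_id(self) -> str:
        e = self.skip_event
        return f"{e.chrom}:{e.exon_start}-{e.exon_end}:{e.strand}:{e.annotated_stop_position}"


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_to_stop(mrna: str, orf_start: int) -> tuple[str, bool]:
    """Standard-code translation from ``orf_start`` to the first in-frame stop.

    Returns ``(protein, stop_reached)``; the stop itself is not included.
    A truncated final codon is ignored.  Codons containing N translate to
    'X' and never match a stop.
    """
    if orf_start < 0 or orf_start >= len(mrna):
        raise ValueError(f"orf_start {orf_start} outside sequence of length {len(mrna)}")
    aas = []
    for i in range(orf_start, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        if codon in _STOPS:
            return "".join(aas), True
        aas.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aas), False


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def classify_geometry(t: TranscriptModel) -> list[SkipEvent]:
    """One SkipEvent per internal exon of ``t`` (first/last are never skipped).

    2-exon transcripts yield an empty list (logged).  Classes are purely
    geometric here; ``Penulti_short`` is an outcome class assigned after
    translation (see :func:`build_candidate`).
    """
    if t.n_exons < 3:
        logger.debug("transcript %s has %d exons; nothing to skip", t.transcript_id, t.n_exons)
        return []
    stop_idx = t.stop_codon_exon_index
    last = t.n_exons - 1
    events = []
    for i in range(1, last):
        exon = t.exons[i]
        frame_preserving = len(exon) % 3 == 0
        if i == last - 1:  # penultimate
            if stop_idx == i:
                cls = "Penultimate"
            elif stop_idx == last:
                cls = "Ultimate" if not frame_preserving else "Penulti_fp"
            else:
                cls = "Internal_fp" if frame_preserving else "Internal_fs"
        else:
            cls = "Internal_fp" if frame_preserving else "Internal_fs"
        upstream, downstream = t.exons[i - 1], t.exons[i + 1]
        if t.strand == "+":
            up_end, down_start = upstream.end, downstream.start
        else:  # genomic orientation: downstream exon is genomically left
            up_end, down_start = downstream.end, upstream.start
        events.append(
            SkipEvent(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                exon_index_skipped=i,
                upstream_exon_end=up_end,
                exon_start=exon.start,
                exon_end=exon.end,
                downstream_exon_start=down_start,
                annotated_stop_position=t.stop_codon_genomic_first,
                geometry_class=cls,
            )
        )
    return events


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

def _skipped_transcript_to_genomic(
    t: TranscriptModel, skip_index: int, tpos: int
) -> int:
    """Genomic position of a skipped-mRNA transcript coordinate."""
    lengths = [l for i, l in enumerate(t.exon_lengths) if i != skip_index]
    exons = [e for i, e in enumerate(t.exons) if i != skip_index]
    acc = 0
    for exon, length in zip(exons, lengths):
        if tpos < acc + length:
            offset = tpos - acc
            if t.strand == "+":
                return exon.start + offset
            return exon.end - 1 - offset
        acc += length
    raise AnnotationError(f"position {tpos} outside skipped mRNA of {t.transcript_id}")


def _skipped_exon_index_of(t: TranscriptModel, skip_index: int, tpos: int) -> int:
    """Index (in the *skipped* exon list) of the exon containing tpos."""
    lengths = [l for i, l in enumerate(t.exon_lengths) if i != skip_index]
    acc = 0
    for j, length in enumerate(lengths):
        if tpos < acc + length:
            return j
        acc += length
    raise AnnotationError(f"position {tpos} outside skipped mRNA of {t.transcript_id}")


def build_candidate(
    e: SkipEvent,
    t: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
) -> FrameshiftCandidate:
    """Translate the skipped isoform and measure the alternative C-terminus.

    Precondition: ``e.geometry_class`` is Ultimate or Penultimate.  The
    divergence point is found at the protein level (a hybrid junction codon
    can re-encode the same amino acid), and "beyond the annotated stop" is
    decided in genomic coordinates: an amino acid counts when the genomic
    position of its first codon base lies strictly 3' (transcript
    orientation) of the last base of the annotated stop codon.
    """
    if e.geometry_class not in CANDIDATE_CLASSES:
        raise ValueError(
            f"build_candidate requires geometry class in {CANDIDATE_CLASSES}, "
            f"got {e.geometry_class!r}"
        )
    skip = e.exon_index_skipped
    starts = t._cumulative_starts()
    if t.orf_start >= starts[skip]:
        raise AnnotationError(
            f"transcript {t.transcript_id}: ORF starts within or after the "
            f"skipped exon; not a C-terminal event"
        )

    canonical_mrna = spliced_sequence(t, genome)
    skipped_mrna = spliced_sequence(t, genome, skip_exon_index=skip)
    canonical_aa, _ = translate_to_stop(canonical_mrna[: t.orf_end], t.orf_start)
    alt_aa, stop_reached = translate_to_stop(skipped_mrna, t.orf_start)

    divergence = 0
    for a, b in zip(canonical_aa, alt_aa):
        if a != b:
            break
        divergence += 1
    # if one is a prefix of the other, divergence = length of common prefix
    divergence = min(divergence, len(alt_aa), len(canonical_aa))

    new_cterm = alt_aa[divergence:]
    aa_gained = len(new_cterm)

    stop_last_g = t.stop_codon_genomic_last
    aa_beyond = 0
    for k in range(divergence, len(alt_aa)):
        codon_t = t.orf_start + 3 * k
        g = _skipped_transcript_to_genomic(t, skip, codon_t)
        if (t.strand == "+" and g > stop_last_g) or (t.strand == "-" and g < stop_last_g):
            aa_beyond += 1

    skipped_len = len(skipped_mrna)
    new_stop_t = t.orf_start + 3 * len(alt_aa)  # first base of the new stop codon
    n_skipped_exons = t.n_exons - 1
    if stop_reached:
        stop_exon = _skipped_exon_index_of(t, skip, new_stop_t)
        new_stop_in_last = stop_exon == n_skipped_exons - 1
    else:
        new_stop_in_last = False

    if not stop_reached:
        outcome = "non_stop"
    elif not new_stop_in_last:
        outcome = "nmd"
    elif aa_beyond > 0:
        outcome = "extended"
    else:
        new_stop_g = _skipped_transcript_to_genomic(t, skip, new_stop_t)
        outcome = "boundary" if new_stop_g == e.annotated_stop_position else "short"

    return FrameshiftCandidate(
        skip_event=e,
        divergence_point=divergence,
        new_cterm_aa=new_cterm,
        aa_gained=aa_gained,
        aa_beyond_stop=aa_beyond,
        new_stop_in_last_exon=new_stop_in_last,
        stop_reached=stop_reached,
        outcome=outcome,
        has_ambiguous="X" in new_cterm,
    )


def effective_class(c: FrameshiftCandidate) -> str:
    """Post-translation class: frameshifting skips whose new stop is 5' of the
    annotated stop produce a shorter alternative C-terminus (Penulti_short)."""
    if c.outcome == "short":
        return "Penulti_short"
    return c.skip_event.geometry_class


def apply_filters(
    c: FrameshiftCandidate, min_gained: int = 20, min_beyond: int = 10
) -> bool:
    """True iff the candidate passes the gain filters (boundaries inclusive)
    and has a new stop codon in the last exon."""
    return (
        c.stop_reached
        and c.new_stop_in_last_exon
        and c.aa_gained >= min_gained
        and c.aa_beyond_stop >= min_beyond
    )


def deduplicate(cands: Sequence[FrameshiftCandidate]) -> list[FrameshiftCandidate]:
    """One representative per distinct (upstream end, exon start, exon end,
    downstream start, stop position) tuple; the representative is the
    lexicographically smallest transcript_id.  Idempotent."""
    by_key: dict[tuple, FrameshiftCandidate] = {}
    for c in cands:
        key = c.skip_event.dedup_key
        held = by_key.get(key)
        if held is None or c.transcript_id < held.transcript_id:
            by_key[key] = c
    return sorted(by_key.values(), key=lambda c: (c.skip_event.dedup_key, c.transcript_id))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    passing: list[FrameshiftCandidate]
    all_candidates: list[FrameshiftCandidate]
    events_by_class: dict[str, int]
    n_gene_loci: int


def discover(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    min_gained: int = 20,
    min_beyond: int = 10,
    classes: Sequence[str] = CANDIDATE_CLASSES,
) -> DiscoveryResult:
    """Run classification + translation + filters + deduplication."""
    all_cands: list[FrameshiftCandidate] = []
    class_counts: dict[str, int] = {}
    for t in transcripts:
        for e in classify_geometry(t):
            class_counts[e.geometry_class] = class_counts.get(e.geometry_class, 0) + 1
            if e.geometry_class in classes and e.geometry_class in CANDIDATE_CLASSES:
                try:
                    all_cands.append(build_candidate(e, t, genome))
                except AnnotationError as err:
                    logger.warning("skipping event on %s: %s", t.transcript_id, err)
    passing = deduplicate(
        [c for c in all_cands if apply_filters(c, min_gained, min_beyond)]
    )
    for c in all_cands:
        eff = effective_class(c)
        if eff != c.skip_event.geometry_class:
            class_counts[eff] = class_counts.get(eff, 0) + 1
    n_loci = len({c.gene_id for c in passing})
    return DiscoveryResult(passing, all_cands, class_counts, n_loci)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def candidates_to_table(cands: Sequence[FrameshiftCandidate]):
    """Tab-friendly DataFrame: one row per candidate, genomic coordinates
    reported 1-based inclusive (GTF convention)."""
    import pandas as pd

    rows = []
    for c in cands:
        e = c.skip_event
        rows.append(
            {
                "gene_id": c.gene_id,
                "transcript_id": c.transcript_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "upstream_exon_end": e.upstream_exon_end,  # half-open end == 1-based inclusive end
                "exon_start": e.exon_start + 1,
                "exon_end": e.exon_end,
                "downstream_exon_start": e.downstream_exon_start + 1,
                "stop_codon_position": e.annotated_stop_position + 1,
                "geometry_class": e.geometry_class,
                "outcome": c.outcome,
                "aa_gained": c.aa_gained,
                "aa_beyond_stop": c.aa_beyond_stop,
                "new_cterm_aa": c.new_cterm_aa,
            }
        )
    return pd.DataFrame(rows)


def write_cterm_fasta(cands: Sequence[FrameshiftCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in cands:
            fh.write(f">{c.transcript_id}|{c.event_id}\n{c.new_cterm_aa}\n")


def write_skipped_exon_bed(cands: Sequence[FrameshiftCandidate], path) -> None:
    """BED6 (0-based half-open) of the skipped exons."""
    with open(path, "w") as fh:
        for c in cands:
            e = c.skip_event
            fh.write(
                f"{e.chrom}\t{e.exon_start}\t{e.exon_end}\t"
                f"{c.transcript_id}\t{c.aa_gained}\t{e.strand}\n"
            )
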