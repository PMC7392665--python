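"""Ground-truth-bearing toy data: genomes/annotations with planted skip
events, binomial junction counts at planted PSI, and half-life tables with a
planted group effect.

The genome generator works in transcript space first: for each geometry
class it composes exon sequences such that the *canonical* reading frame is
an open, valid ORF and the *skipped-isoform* reading frame of the last exon
encodes an exactly planted number of new amino acids, a planted subset of
which lie 3' of the annotated stop codon.  Because the last exon is read in
two frames at once, stop codons are placed and repaired under both frame
constraints (a TAA placed off-frame can never create a stop in the other
frame, which makes the repair loop safe).  Genes are then laid onto toy
chromosomes on alternating strands with GT..AG introns.

Everything is driven by one integer seed; regenerating with the same seed
reproduces byte-identical FASTA/GTF/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GENERATOR_VERSION = "1"

STOPS = {"TAA", "TAG", "TGA"}
ALL_CODONS = ["".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS]
PROLINE_CODONS = ["CCT", "CCC", "CCA", "CCG"]

#: geometry classes plus fail-filter controls
SIMULATED_CLASSES = (
    "Ultimate",
    "Penultimate",
    "Internal_fp",
    "Internal_fs",
    "Penulti_fp",
    "Penulti_short",
    "fail_gain",
    "fail_beyond",
)
#: classes whose planted candidates pass the 20/10 filter
PASSING_CLASSES = ("Ultimate", "Penultimate")

DEFAULT_TISSUES = ("brain", "liver", "heart", "kidney", "muscle")

#: proline codon sampling weight for frameshift-frame vs canonical codons;
#: plants the proline / PxxP enrichment of the alternative C-termini
FS_PROLINE_WEIGHT = 0.20
FL_PROLINE_WEIGHT = 0.05


def _sense(rng, pro_weight: float = FL_PROLINE_WEIGHT) -> str:
    if rng.random() < pro_weight:
        return PROLINE_CODONS[int(rng.integers(4))]
    return SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]


def _nt(rng, n: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=n))


def _intron(rng, n: int = 80) -> str:
    body = _nt(rng, n - 4)
    return "GT" + body + "AG"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# dual-frame last-exon construction
# ---------------------------------------------------------------------------

def _is_stop(seq: list[str], a: int) -> bool:
    return "".join(seq[a : a + 3]) in STOPS


def _repair_canonical(
    seq: list[str],
    canonical_starts: Sequence[int],
    fixed: set[int],
    rng,
    pro_weight: float,
    protect_codon0: bool = True,
) -> None:
    """Resample frame-0 codons until no canonical-frame codon is a stop.

    Positions in ``fixed`` (planted stop codons) are never touched; frame-0
    codons partially overlapping them are resampled base-by-base, which
    cannot produce a frame-0 stop because the fixed fragment is part of an
    off-frame TAA.
    """
    for _ in range(20000):
        bad = next((a for a in canonical_starts if _is_stop(seq, a)), None)
        if bad is None:
            return
        for k in range(bad // 3, (bad + 2) // 3 + 1):
            if protect_codon0 and k == 0:
                continue
            pos = list(range(3 * k, 3 * k + 3))
            if any(p >= len(seq) for p in pos) or all(p in fixed for p in pos):
                continue
            if any(p in fixed for p in pos):
                for p in pos:
                    if p not in fixed:
                        seq[p] = "ACGT"[int(rng.integers(4))]
            else:
                seq[3 * k : 3 * k + 3] = _sense(rng, pro_weight)
            assert not _is_stop(seq, 3 * k), "repair created a frame-0 stop"
    raise AssertionError("canonical-frame repair did not converge")


def _exon3_extension(G: int, B: int, t: int, rng) -> str:
    """Last-exon core for an extension event.

    Frame 0 (the skipped-isoform frame) reads exactly ``G`` sense codons
    (the first is TGG, guaranteeing protein-level divergence) followed by a
    stop.  The canonical frame (offset ``3-t``, ``t`` = penultimate exon
    length mod 3) reads sense codons up to a TAA placed such that exactly
    ``B`` of the G new amino acids start 3' of the stop's last base.
    Requires ``G >= B + 3``.
    """
    if t not in (1, 2):
        raise ValueError("t must be 1 or 2 for a frameshifting penultimate exon")
    q = G - B - 2
    if q < 1:
        raise ValueError(f"need aa_gained >= aa_beyond + 3, got G={G}, B={B}")
    r = (3 - t) + 3 * q  # canonical stop start within the exon

    codons = ["TGG"] + [_sense(rng, FS_PROLINE_WEIGHT) for _ in range(G - 1)] + ["TAA"]
    seq = list("".join(codons))
    assert r + 3 <= 3 * G, "canonical stop must precede the frame-0 stop"
    seq[r : r + 3] = "TAA"
    fixed = {r, r + 1, r + 2, 3 * G, 3 * G + 1, 3 * G + 2}
    canonical_starts = [(3 - t) + 3 * j for j in range(q)]
    _repair_canonical(seq, canonical_starts, fixed, rng, FS_PROLINE_WEIGHT)
    return "".join(seq)


def _exon3_short(t: int, rng, n_new: int = 4, n_tail_codons: int = 6) -> str:
    """Last-exon core whose frame-0 reading terminates 5' of the canonical
    stop: the skipped isoform gets a *shorter* C-terminus (Penulti_short)."""
    if t not in (1, 2):
        raise ValueError("t must be 1 or 2")
    codons = ["TGG"] + [_sense(rng) for _ in range(n_new - 1)] + ["TAA"]
    seq = list("".join(codons))
    L0 = len(seq)  # frame-0 stop occupies [L0-3, L0)
    fixed = set(range(L0 - 3, L0))
    a0 = 3 - t
    starts = [a for a in range(a0, L0 - 5, 3)]  # fully free canonical codons
    _repair_canonical(seq, starts, fixed, rng, FL_PROLINE_WEIGHT)
    # complete the canonical codon straddling the end (starts inside the TAA,
    # so it can never be a stop), then add sense tail codons and the stop
    while (len(seq) - a0) % 3 != 0:
        seq.append("ACGT"[int(rng.integers(4))])
    for _ in range(n_tail_codons):
        seq.extend(_sense(rng))
    seq.extend("TAA")
    return "".join(seq)


# ---------------------------------------------------------------------------
# per-class gene builders (transcript space)
# ---------------------------------------------------------------------------

@dataclass
class ToyGene:
    gene_id: str
    class_name: str
    strand: str
    exon_seqs: list[str]        # transcript orientation
    orf_start: int              # mRNA coordinate of the A of ATG
    aa_gained: Optional[int] = None
    aa_beyond: Optional[int] = None
    duplicate_isoform: bool = False
    psi_by_tissue: dict[str, float] = field(default_factory=dict)


def _exon1(rng) -> str:
    """5'UTR (6 nt) + ATG + five sense codons: 18 nt of codon-aligned CDS."""
    return _nt(rng, 6) + "ATG" + "".join(_sense(rng) for _ in range(5))


def _build_ultimate_like(gene_id, strand, rng, G, B, class_name) -> ToyGene:
    t = int(rng.integers(1, 3))
    m2 = int(rng.integers(8, 25))
    e1 = _exon1(rng)
    e2 = "GGA" + "".join(_sense(rng) for _ in range(m2 - 1)) + "C" * t
    core = _exon3_extension(G, B, t, rng)
    e3 = core + _nt(rng, 30)
    return ToyGene(gene_id, class_name, strand, [e1, e2, e3], 6, G, B)


def _build_penultimate(gene_id, strand, rng, G) -> ToyGene:
    m2 = int(rng.integers(8, 25))
    e1 = _exon1(rng)
    e2 = "GGA" + "".join(_sense(rng) for _ in range(m2 - 1)) + "TAA" + _nt(rng, int(rng.integers(4, 10)))
    e3 = "TGG" + "".join(_sense(rng, FS_PROLINE_WEIGHT) for _ in range(G - 1)) + "TAA" + _nt(rng, 30)
    return ToyGene(gene_id, "Penultimate", strand, [e1, e2, e3], 6, G, G)


def _build_penulti_short(gene_id, strand, rng) -> ToyGene:
    t = int(rng.integers(1, 3))
    m2 = int(rng.integers(8, 25))
    e1 = _exon1(rng)
    e2 = "GGA" + "".join(_sense(rng) for _ in range(m2 - 1)) + "C" * t
    e3 = _exon3_short(t, rng) + _nt(rng, 30)
    return ToyGene(gene_id, "Penulti_short", strand, [e1, e2, e3], 6, 4, 0)


def _build_codon_aligned(gene_id, strand, rng, class_name) -> ToyGene:
    """Internal_fp / Internal_fs / Penulti_fp control genes.

    The full CDS is one open codon string cut into exons; boundary offsets
    choose the class.  Penultimate exons of the 4-exon genes are kept
    frame-preserving so they classify as Penulti_fp (ineligible)."""
    e1 = _exon1(rng)
    n_codons = int(rng.integers(18, 28))
    S = "".join(_sense(rng) for _ in range(n_codons))
    tail = "TAA" + _nt(rng, 30)
    if class_name == "Penulti_fp":
        cut = 3 * int(rng.integers(5, 8))
        exons = [e1, S[:cut], S[cut:] + tail]
    elif class_name == "Internal_fp":
        c1 = 3 * int(rng.integers(4, 7))
        c2 = c1 + 3 * int(rng.integers(5, 8))
        exons = [e1, S[:c1], S[c1:c2], S[c2:] + tail]
    elif class_name == "Internal_fs":
        c1 = 3 * int(rng.integers(4, 7)) + int(rng.integers(1, 3))
        c2 = c1 + 3 * int(rng.integers(5, 8))
        exons = [e1, S[:c1], S[c1:c2], S[c2:] + tail]
    else:
        raise ValueError(class_name)
    return ToyGene(gene_id, class_name, strand, exons, 6)


def _build_gene(class_name, gene_id, strand, rng) -> ToyGene:
    if class_name == "Ultimate":
        G = int(rng.integers(25, 60))
        B = int(rng.integers(12, G - 6))
        g = _build_ultimate_like(gene_id, strand, rng, G, B, "Ultimate")
        g.duplicate_isoform = True
        return g
    if class_name == "Penultimate":
        return _build_penultimate(gene_id, strand, rng, int(rng.integers(22, 50)))
    if class_name == "fail_gain":
        return _build_ultimate_like(gene_id, strand, rng, 19, 10, "fail_gain")
    if class_name == "fail_beyond":
        return _build_ultimate_like(gene_id, strand, rng, 25, 9, "fail_beyond")
    if class_name == "Penulti_short":
        return _build_penulti_short(gene_id, strand, rng)
    return _build_codon_aligned(gene_id, strand, rng, class_name)


# ---------------------------------------------------------------------------
# genome assembly + GTF
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    seed: int
    genes: list[ToyGene]

    @property
    def passing_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.class_name in PASSING_CLASSES]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "class": g.class_name,
                    "strand": g.strand,
                    "aa_gained": g.aa_gained,
                    "aa_beyond_stop": g.aa_beyond,
                    "duplicate_isoform": g.duplicate_isoform,
                    **{f"psi_{t}": v for t, v in sorted(g.psi_by_tissue.items())},
                }
                for g in self.genes
            ]
        )


@dataclass
class SyntheticBundle:
    seed: int
    fasta_text: str
    gtf_text: str
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gtf": out / "annotation.gtf",
            "truth": out / "truth.tsv",
        }
        paths["genome"].write_text(self.fasta_text)
        paths["gtf"].write_text(self.gtf_text)
        header = f"# seed={self.seed} generator_version={GENERATOR_VERSION}\n"
        paths["truth"].write_text(
            header + self.truth.to_frame().to_csv(sep="\t", index=False)
        )
        return paths


def _orf_end(mrna: str, orf_start: int) -> int:
    from .discovery import translate_to_stop

    aa, stopped = translate_to_stop(mrna, orf_start)
    if not stopped:
        raise AssertionError("generated canonical ORF has no stop codon")
    return orf_start + 3 * len(aa) + 3


def _gtf_line(chrom, ftype, start0, end0, strand, frame, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\tutr3frame_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t{frame}\t{attr_str}\n"


def _emit_transcript(
    lines, chrom, region_offset, region_len, strand, gene, tid, exon_spans, orf_start
):
    """Write exon/CDS/stop_codon GTF lines for one transcript.

    ``exon_spans`` are (start, end) within the gene region, transcript
    orientation; minus-strand regions are laid down reverse-complemented.
    """
    def to_genomic(a, b):
        if strand == "+":
            return region_offset + a, region_offset + b
        return region_offset + region_len - b, region_offset + region_len - a

    tstarts = [0]
    for a, b in exon_spans:
        tstarts.append(tstarts[-1] + (b - a))
    orf_end = gene._orf_end_by_tid[tid]

    attrs_base = [
        ("gene_id", gene.gene_id),
        ("transcript_id", tid),
        ("gene_biotype", "protein_coding"),
        ("transcript_biotype", "protein_coding"),
    ]
    phase_acc = 0
    for i, (a, b) in enumerate(exon_spans):
        ga, gb = to_genomic(a, b)
        lines.append(
            _gtf_line(chrom, "exon", ga, gb, strand, ".", attrs_base + [("exon_number", i + 1)])
        )
        # CDS segment (stop excluded) within this exon, transcript coords
        t_lo, t_hi = tstarts[i], tstarts[i + 1]
        seg_lo, seg_hi = max(t_lo, orf_start), min(t_hi, orf_end - 3)
        if seg_lo < seg_hi:
            off_lo, off_hi = seg_lo - t_lo, seg_hi - t_lo
            cds_g = to_genomic(a + off_lo, a + off_hi)
            frame = (3 - phase_acc % 3) % 3
            lines.append(
                _gtf_line(chrom, "CDS", cds_g[0], cds_g[1], strand, frame,
                          attrs_base + [("exon_number", i + 1)])
            )
            phase_acc += seg_hi - seg_lo
        # stop codon segment
        s_lo, s_hi = max(t_lo, orf_end - 3), min(t_hi, orf_end)
        if s_lo < s_hi:
            off_lo, off_hi = s_lo - t_lo, s_hi - t_lo
            sg = to_genomic(a + off_lo, a + off_hi)
            lines.append(
                _gtf_line(chrom, "stop_codon", sg[0], sg[1], strand, "0",
                          attrs_base + [("exon_number", i + 1)])
            )


def generate_toy_genome(
    n_per_class: int = 5,
    seed: int = 0,
    classes: Sequence[str] = SIMULATED_CLASSES,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    genes_per_chrom: int = 100,
) -> SyntheticBundle:
    """Toy genome + GTF with ``n_per_class`` genes per geometry class.

    Strands alternate gene by gene; every Ultimate gene additionally carries
    a second isoform differing only in its 5'UTR start, which collapses with
    the first in event deduplication.  Per-tissue PSI values are planted for
    every gene: a constitutive baseline (91-99) with zero to three
    alternative tissues (PSI 30-85).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[ToyGene] = []
    idx = 0
    for c in range(n_per_class):
        for class_name in classes:
            strand = "+" if idx % 2 == 0 else "-"
            g = _build_gene(class_name, f"g{idx:04d}", strand, rng)
            for tis in tissues:
                g.psi_by_tissue[tis] = round(float(rng.uniform(91, 99)), 2)
            n_alt = int(rng.integers(0, 4))
            alt_tissues = rng.choice(len(tissues), size=n_alt, replace=False)
            for ti in alt_tissues:
                g.psi_by_tissue[tissues[int(ti)]] = round(float(rng.uniform(30, 85)), 2)
            genes.append(g)
            idx += 1

    fasta_chunks = []
    gtf_lines = [
        f"#!utr3frame synthetic genome seed={seed} version={GENERATOR_VERSION}\n"
    ]
    chrom_seq: list[str] = []
    chrom_pos = 0
    chrom_idx = 1

    def flush_chrom():
        nonlocal chrom_seq, chrom_pos, chrom_idx
        if chrom_pos:
            seq = "".join(chrom_seq)
            wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
            fasta_chunks.append(f">chrT{chrom_idx}\n{wrapped}\n")
            chrom_idx += 1
            chrom_seq, chrom_pos = [], 0

    for gi, g in enumerate(genes):
        if gi and gi % genes_per_chrom == 0:
            flush_chrom()
        chrom = f"chrT{chrom_idx}"
        flank = 20
        parts = [_nt(rng, flank)]
        spans = []
        pos = flank
        for i, ex in enumerate(g.exon_seqs):
            if i:
                intr = _intron(rng)
                parts.append(intr)
                pos += len(intr)
            parts.append(ex)
            spans.append((pos, pos + len(ex)))
            pos += len(ex)
        parts.append(_nt(rng, flank))
        region = "".join(parts)
        region_len = len(region)

        mrna = "".join(g.exon_seqs)
        g._orf_end_by_tid = {}
        tid1 = f"{g.gene_id}.t1"
        g._orf_end_by_tid[tid1] = _orf_end(mrna, g.orf_start)
        transcripts = [(tid1, spans, g.orf_start)]
        if g.duplicate_isoform:
            # same exons except a 9 nt longer 5'UTR: identical dedup 5-tuple
            tid2 = f"{g.gene_id}.t2"
            spans2 = [(spans[0][0] - 9, spans[0][1])] + spans[1:]
            g._orf_end_by_tid[tid2] = _orf_end(region[spans2[0][0]:spans2[0][1]] + "".join(g.exon_seqs[1:]), g.orf_start + 9)
            transcripts.append((tid2, spans2, g.orf_start + 9))

        region_offset = chrom_pos
        chrom_seq.append(region if g.strand == "+" else _revcomp(region))
        chrom_pos += region_len
        gap = _nt(rng, 50)
        chrom_seq.append(gap)
        chrom_pos += 50

        for tid, tspans, orf_start in transcripts:
            _emit_transcript(
                gtf_lines, chrom, region_offset, region_len, g.strand, g, tid, tspans, orf_start
            )
    flush_chrom()

    return SyntheticBundle(
        seed=seed,
        fasta_text="".join(fasta_chunks),
        gtf_text="".join(gtf_lines),
        truth=SyntheticTruth(seed=seed, genes=genes),
    )


def generate_extension_genes(
    specs: Sequence[tuple[int, int]], seed: int = 0
) -> SyntheticBundle:
    """One Ultimate-geometry gene per (aa_gained, aa_beyond_stop) pair, for
    boundary experiments on the gain filters."""
    rng = np.random.default_rng(seed)
    genes = []
    for i, (G, B) in enumerate(specs):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_build_ultimate_like(f"g{i:04d}", strand, rng, G, B, "Ultimate"))
    return _assemble(genes, seed, rng)


def _assemble(genes: list[ToyGene], seed: int, rng) -> SyntheticBundle:
    """Assembly used by generate_extension_genes (single chromosome)."""
    fasta_chunks = []
    gtf_lines = [
        f"#!utr3frame synthetic genome seed={seed} version={GENERATOR_VERSION}\n"
    ]
    chrom_seq: list[str] = []
    chrom_pos = 0
    chrom = "chrT1"
    for g in genes:
        flank = 20
        parts = [_nt(rng, flank)]
        spans = []
        pos = flank
        for i, ex in enumerate(g.exon_seqs):
            if i:
                intr = _intron(rng)
                parts.append(intr)
                pos += len(intr)
            parts.append(ex)
            spans.append((pos, pos + len(ex)))
            pos += len(ex)
        parts.append(_nt(rng, flank))
        region = "".join(parts)
        g._orf_end_by_tid = {f"{g.gene_id}.t1": _orf_end("".join(g.exon_seqs), g.orf_start)}
        region_offset = chrom_pos
        chrom_seq.append(region if g.strand == "+" else _revcomp(region))
        chrom_pos += len(region)
        chrom_seq.append(_nt(rng, 50))
        chrom_pos += 50
        _emit_transcript(
            gtf_lines, chrom, region_offset, len(region), g.strand, g,
            f"{g.gene_id}.t1", spans, g.orf_start,
        )
    seq = "".join(chrom_seq)
    wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
    fasta_chunks.append(f">{chrom}\n{wrapped}\n")
    return SyntheticBundle(
        seed=seed,
        fasta_text="".join(fasta_chunks),
        gtf_text="".join(gtf_lines),
        truth=SyntheticTruth(seed=seed, genes=genes),
    )


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def simulate_event_counts(psi: float, depth: int, rng) -> tuple[int, int, int]:
    """Junction reads for one event/sample: each of ``depth`` molecules is
    excluded with probability 1 - psi/100 (one exclusion-junction read) or
    included (one read on *each* inclusion junction), which makes the
    half-inclusion PSI estimator calibrated."""
    if not 0 <= psi <= 100:
        raise ValueError("planted PSI must be in [0, 100]")
    exc = int(rng.binomial(depth, 1 - psi / 100.0))
    n_inc = depth - exc
    return n_inc, n_inc, exc


def simulate_junction_counts(
    truth: SyntheticTruth,
    depth: int = 50,
    samples_per_tissue: int = 3,
    seed: int = 0,
    tissues: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomially sampled junction counts at the planted per-tissue PSI.

    Returns (counts, sample metadata); event ids are gene ids.
    """
    rng = np.random.default_rng(seed)
    if tissues is None:
        tissues = sorted({t for g in truth.genes for t in g.psi_by_tissue})
    meta_rows = [
        {"sample_id": f"{tis}_s{i + 1}", "tissue": tis}
        for tis in tissues
        for i in range(samples_per_tissue)
    ]
    rows = []
    for g in truth.genes:
        for tis in tissues:
            psi = g.psi_by_tissue.get(tis)
            if psi is None:
                continue
            for i in range(samples_per_tissue):
                iu, idn, exc = simulate_event_counts(psi, depth, rng)
                rows.append(
                    {
                        "event_id": g.gene_id,
                        "sample_id": f"{tis}_s{i + 1}",
                        "inc_up": iu,
                        "inc_down": idn,
                        "exc": exc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# half-life tables
# ---------------------------------------------------------------------------

def simulate_halflife(
    seed: int = 0,
    n_all: int = 3573,
    n_decreased: int = 36,
    n_unchanged: int = 76,
    n_rich: int = 80,
    n_unskipped: int = 20,
    base_halflife_h: float = 20.0,
    sigma_log: float = 0.5,
    effect_rich: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal half-life table with a planted effect confined to P-rich.

    Returns ``(halflife, candidates)``: half-lives for all ``n_all`` genes,
    and a candidate table (gene_id, psi, P_fl, P_fs) in which the first
    ``n_decreased + n_unchanged + n_rich`` genes are skipped (PSI < 90) and
    split into the three proline-delta groups, plus ``n_unskipped``
    candidates with PSI >= 90 that the join must exclude.  Default group
    sizes mirror a 3T3 pulse-SILAC setting.
    """
    if effect_rich <= 0:
        raise ValueError("effect_rich must be > 0")
    n_skipped = n_decreased + n_unchanged + n_rich
    if n_skipped + n_unskipped > n_all:
        raise ValueError("group sizes exceed n_all")
    rng = np.random.default_rng(seed)
    gene_ids = [f"hl{i:05d}" for i in range(n_all)]
    half_life = base_halflife_h * np.exp(rng.normal(0.0, sigma_log, size=n_all))
    half_life[n_decreased + n_unchanged : n_skipped] *= effect_rich  # P-rich block
    halflife_df = pd.DataFrame({"gene_id": gene_ids, "half_life_h": half_life})

    cand_rows = []
    for i in range(n_skipped + n_unskipped):
        skipped = i < n_skipped
        psi = float(rng.uniform(20, 85)) if skipped else float(rng.uniform(92, 99))
        p_fl = float(rng.uniform(6, 14))
        if i < n_decreased:
            p_fs = p_fl - float(rng.uniform(4, 8))
        elif i < n_decreased + n_unchanged:
            p_fs = p_fl + float(rng.uniform(-2.5, 2.5))
        elif i < n_skipped:
            p_fs = p_fl + float(rng.uniform(4, 12))
        else:
            p_fs = p_fl + float(rng.uniform(-8, 8))
        cand_rows.append(
            {
                "gene_id": gene_ids[i],
                "psi": round(psi, 2),
                "P_fl": round(p_fl, 3),
                "P_fs": round(max(p_fs, 0.0), 3),
            }
        )
    return halflife_df, pd.DataFrame(cand_rows)
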