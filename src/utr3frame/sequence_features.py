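"""Amino-acid composition, SH3-binding proline-rich motif scores,
proline-delta stability groups, and coil-fraction disorder summaries.

Motif frequency scores follow the observed/expected convention: the chance
probability of a motif is the product over pattern positions of the summed
background frequencies of each position's residue class (wildcards count
1); the expected count in a sequence of length L is that probability times
the number of start offsets (L - m + 1).  A sequence with no match scores
0; observed == expected scores 1; above 1 is overrepresentation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: hydrophobic residue class used in class I/II SH3 ligand motifs; follows
#: common SH3-ligand conventions and is configurable via builtin_motifs()
DEFAULT_PHI = frozenset("AVILMFWYP")

#: average amino-acid frequencies of the UniProtKB/Swiss-Prot database
#: (release statistics, percent), used as the default motif background
SWISSPROT_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.64, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}


def default_background() -> dict[str, float]:
    total = sum(SWISSPROT_FREQUENCIES.values())
    return {aa: v / total for aa, v in SWISSPROT_FREQUENCIES.items()}


def background_from_fasta(path) -> dict[str, float]:
    """Per-AA frequencies of a proteome FASTA (non-standard symbols dropped)."""
    from Bio import SeqIO

    counts: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        counts.update(aa for aa in str(rec.seq).upper() if aa in STANDARD_AAS)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no standard amino acids found in {path}")
    return {aa: counts.get(aa, 0) / total for aa in STANDARD_AAS}


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionProfile:
    """Per-AA fractions over the 20 standard amino acids.

    Stop symbols ('*') and ambiguous residues ('X') are excluded from both
    numerator and denominator, so fractions always sum to 1.
    """

    fractions: Mapping[str, float]
    length: int
    context: Optional[str] = None

    def __getitem__(self, aa: str) -> float:
        return self.fractions.get(aa, 0.0)

    def proline_percent(self) -> float:
        return 100.0 * self["P"]

    def as_vector(self) -> np.ndarray:
        return np.array([self[aa] for aa in STANDARD_AAS])


def aa_composition(seq: str, context: Optional[str] = None) -> CompositionProfile:
    if not seq:
        raise ValueError("empty sequence")
    counted = [aa for aa in seq.upper() if aa in STANDARD_AAS]
    if not counted:
        raise ValueError("sequence contains no countable amino acids")
    counts = Counter(counted)
    n = len(counted)
    return CompositionProfile(
        fractions={aa: counts.get(aa, 0) / n for aa in STANDARD_AAS},
        length=n,
        context=context,
    )


def _translate_through_stops(nt: str, max_aa: int) -> str:
    """Translate ignoring stops (stops appear as '*'), up to max_aa codons."""
    from Bio.Data.CodonTable import standard_dna_table

    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    out = []
    for i in range(0, len(nt) - 2, 3):
        if len(out) >= max_aa:
            break
        codon = nt[i : i + 3]
        out.append("*" if codon in stops else table.get(codon, "X"))
    return "".join(out)


def utr_composition(t, genome, n_aa: int = 100) -> tuple[CompositionProfile, CompositionProfile]:
    """(CDS, 3'UTR) composition pair for one transcript.

    CDS side: the last ``n_aa`` amino acids of the annotated protein.
    UTR side: the first ``n_aa`` codons of each of the three frames starting
    right after the stop codon, translated *through* internal stops, with
    the per-AA content averaged over the three frames (unweighted).
    """
    from .genome_io import annotated_protein, utr3_sequence

    utr = utr3_sequence(t, genome)
    if len(utr) < 3:
        raise ValueError(
            f"3'UTR of {t.transcript_id} is shorter than one codon ({len(utr)} nt)"
        )
    protein = annotated_protein(t, genome)
    cds_profile = aa_composition(protein[-n_aa:], context="cds_last100")

    frame_profiles = []
    for f in range(3):
        aa = _translate_through_stops(utr[f:], n_aa)
        frame_profiles.append(aa)
    countable = [p for p in frame_profiles if any(c in STANDARD_AAS for c in p)]
    if len(countable) < 3:
        raise ValueError(
            f"3'UTR of {t.transcript_id} yields a frame with no countable amino acids"
        )
    vectors = [aa_composition(p).as_vector() for p in frame_profiles]
    mean_vec = np.mean(vectors, axis=0)
    utr_profile = CompositionProfile(
        fractions=dict(zip(STANDARD_AAS, mean_vec.tolist())),
        length=sum(len(p) for p in frame_profiles),
        context="utr_first100_3frame_avg",
    )
    return cds_profile, utr_profile


# ---------------------------------------------------------------------------
# proline-rich motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDefinition:
    """Ordered residue classes; ``None`` is a wildcard position."""

    name: str
    pattern: tuple[Optional[frozenset], ...]

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern length must be >= 2")
        for cls in self.pattern:
            if cls is not None and not cls:
                raise ValueError("empty residue class")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifScore:
    motif: str
    observed: int
    expected: float
    score: float


def _cls(spec: str) -> Optional[frozenset]:
    return None if spec == "x" else frozenset(spec)


def builtin_motifs(phi: Iterable[str] = DEFAULT_PHI) -> list[MotifDefinition]:
    """The SH3-domain-binding proline-rich motif set.

    PxxP, the most frequent ligands PxxPxR and RxxPxxP, and the class I
    ([RK]xPhiPxPhiP) and class II (PhiPxPhiPx[RK]) consensus motifs, with a
    configurable hydrophobic class Phi.
    """
    phi = frozenset(phi)
    rk = frozenset("RK")
    p = frozenset("P")
    r = frozenset("R")

    def make(name, classes):
        return MotifDefinition(name, tuple(classes))

    return [
        make("PxxP", [p, None, None, p]),
        make("PxxPxR", [p, None, None, p, None, r]),
        make("RxxPxxP", [r, None, None, p, None, None, p]),
        make("classI_[RK]xPhiPxPhiP", [rk, None, phi, p, None, phi, p]),
        make("classII_PhiPxPhiPx[RK]", [phi, p, None, phi, p, None, rk]),
    ]


def scan_motif(seq: str, m: MotifDefinition) -> int:
    """Count motif matches at all start offsets (overlaps allowed)."""
    seq = seq.upper()
    n, k = len(seq), len(m)
    count = 0
    for i in range(n - k + 1):
        if all(cls is None or seq[i + j] in cls for j, cls in enumerate(m.pattern)):
            count += 1
    return count


def motif_probability(m: MotifDefinition, background: Mapping[str, float]) -> float:
    p = 1.0
    for cls in m.pattern:
        if cls is None:
            continue
        p *= sum(background.get(aa, 0.0) for aa in cls)
    return p


def motif_frequency_score(
    seq: str,
    m: MotifDefinition,
    background: Optional[Mapping[str, float]] = None,
) -> MotifScore:
    """Observed/expected frequency score of one motif in one sequence."""
    if background is None:
        background = default_background()
    total = sum(background.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"background frequencies sum to {total}, expected 1")
    observed = scan_motif(seq, m)
    p = motif_probability(m, background)
    expected = p * max(0, len(seq) - len(m) + 1)
    if observed == 0:
        score = 0.0
    elif expected == 0:
        raise ValueError(
            f"motif {m.name} observed {observed} times but expected 0 under the "
            f"background; inconsistent background table"
        )
    else:
        score = observed / expected
    return MotifScore(m.name, observed, expected, score)


def score_sequences(
    seqs: Mapping[str, str],
    motifs: Optional[Sequence[MotifDefinition]] = None,
    background: Optional[Mapping[str, float]] = None,
):
    """Motif score table (one row per sequence x motif) as a DataFrame."""
    import pandas as pd

    if motifs is None:
        motifs = builtin_motifs()
    rows = []
    for sid, seq in seqs.items():
        for m in motifs:
            s = motif_frequency_score(seq, m, background)
            rows.append(
                {"sequence_id": sid, "motif": m.name, "observed": s.observed,
                 "expected": s.expected, "score": s.score}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proline-delta groups and disorder
# ---------------------------------------------------------------------------

PROLINE_GROUPS = ("P-decreased", "P-unchanged", "P-rich")
PROLINE_DELTA_CUTOFF = 3.0


def proline_group(p_fl: float, p_fs: float) -> str:
    """Group by canonical-minus-frameshift proline percent difference:
    > +3 P-decreased, < -3 P-rich, otherwise (boundaries included)
    P-unchanged."""
    for v in (p_fl, p_fs):
        if not 0 <= v <= 100:
            raise ValueError(f"proline percent {v} outside [0, 100]")
    delta = p_fl - p_fs
    if delta > PROLINE_DELTA_CUTOFF:
        return "P-decreased"
    if delta < -PROLINE_DELTA_CUTOFF:
        return "P-rich"
    return "P-unchanged"


@dataclass(frozen=True)
class CoilRecord:
    sequence_id: str
    ss_string: str
    coil_fraction: float


def coil_fraction(ss_string: str, sequence_id: str = "") -> CoilRecord:
    """Fraction of residues predicted as coil ('C') in a {C,H,E} string —
    the disorder proxy for a C-terminal sequence."""
    if not ss_string:
        raise ValueError("empty secondary-structure string")
    bad = set(ss_string) - set("CHE")
    if bad:
        raise ValueError(f"invalid secondary-structure labels: {sorted(bad)}")
    frac = ss_string.count("C") / len(ss_string)
    return CoilRecord(sequence_id, ss_string, frac)


@dataclass(frozen=True)
class CtermPair:
    """Canonical and frameshift C-termini of one candidate, with up to 10
    upstream residues of shared sequence context when available."""

    candidate_id: str
    fl_cterm: str
    fs_cterm: str
    upstream: str = ""


def select_top_proline_delta(
    pairs: Sequence[CtermPair], n: int = 200
) -> list[tuple[str, str, str]]:
    """The ``n`` candidates gaining the most proline in the frameshift
    C-terminus, emitted as (id, fl_seq, fs_seq) with upstream context
    prepended.  Ties break on candidate id; if fewer than ``n`` are
    available all are returned."""
    scored = []
    for pair in pairs:
        delta = (
            aa_composition(pair.fs_cterm).proline_percent()
            - aa_composition(pair.fl_cterm).proline_percent()
        )
        scored.append((delta, pair))
    scored.sort(key=lambda item: (-item[0], item[1].candidate_id))
    out = []
    for _, pair in scored[:n]:
        up = pair.upstream[-10:]
        out.append((pair.candidate_id, up + pair.fl_cterm, up + pair.fs_cterm))
    return out
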