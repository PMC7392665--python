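"""Frameshift-augmented protein search databases, in-silico tryptic
digestion, proteotypic cross-referencing, and IP-MS enrichment calls.

Digestion follows the trypsin rule used by standard search engines: cleave
C-terminal to K or R except when the next residue is P, allowing up to a
configurable number of missed cleavage sites.  Digestion is implemented
here (rather than delegated) because downstream bookkeeping needs the
missed-cleavage count and position of every peptide; the result is
cross-checked against pyteomics' cleavage in the test suite, and pyteomics
provides peptide masses for inclusion lists.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    origin: str = "canonical"  # canonical | annotated_isoform | predicted_frameshift
    source_event: Optional[str] = None
    #: index where the novel C-terminal segment begins (frameshift records)
    divergence: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence or not re.fullmatch(r"[A-Z]+", self.sequence):
            raise ValueError(f"invalid protein sequence for {self.accession}")
        if self.origin == "predicted_frameshift" and self.divergence is None:
            raise ValueError("frameshift records must carry a divergence index")


@dataclass
class PeptideRecord:
    sequence: str
    start: int  # 0-based position in the parent protein
    missed_cleavages: int
    parent_accessions: set[str] = field(default_factory=set)
    maps_to_fs_cterm: bool = False
    proteotypic: bool = False


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

def build_fs_database(
    canonical: Mapping[str, str] | Sequence[ProteinRecord],
    candidates: Sequence,
) -> list[ProteinRecord]:
    """Canonical entries plus one predicted-frameshift record per
    deduplicated candidate: canonical prefix up to the divergence point,
    then the novel C-terminus.  Accessions are suffixed deterministically
    with the skipped-exon coordinates; identical fs sequences arising from
    different isoform annotations collapse (logged)."""
    if isinstance(canonical, Mapping):
        records = [ProteinRecord(acc, seq) for acc, seq in sorted(canonical.items())]
    else:
        records = list(canonical)
    by_acc = {r.accession: r for r in records}
    out = list(records)
    seen_seqs = {r.sequence for r in records}
    n_collapsed = 0
    for c in candidates:
        parent = by_acc.get(c.transcript_id)
        if parent is None:
            raise KeyError(
                f"candidate {c.event_id} references unknown canonical accession "
                f"{c.transcript_id!r}"
            )
        fs_seq = parent.sequence[: c.divergence_point] + c.new_cterm_aa
        if fs_seq in seen_seqs:
            n_collapsed += 1
            continue
        seen_seqs.add(fs_seq)
        e = c.skip_event
        out.append(
            ProteinRecord(
                accession=f"{parent.accession}_fs_{e.exon_start}_{e.exon_end}",
                sequence=fs_seq,
                origin="predicted_frameshift",
                source_event=c.event_id,
                divergence=c.divergence_point,
            )
        )
    if n_collapsed:
        logger.info("build_fs_database: %d duplicate fs sequences collapsed", n_collapsed)
    return out


def write_database_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.accession} origin={r.origin}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# tryptic digestion
# ---------------------------------------------------------------------------

def cleavage_sites(sequence: str) -> list[int]:
    """Positions *after* which trypsin cleaves (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    p: ProteinRecord | str,
    max_missed: int = 2,
    min_len: int = 6,
) -> list[PeptideRecord]:
    """All tryptic peptides with 0..max_missed internal missed cleavages and
    length >= min_len."""
    seq = p.sequence if isinstance(p, ProteinRecord) else p
    if not seq:
        raise ValueError("empty sequence")
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for missed in range(0, max_missed + 1):
            j = i + missed + 1
            if j >= len(bounds):
                break
            pep = seq[bounds[i] : bounds[j]]
            if len(pep) >= min_len:
                peptides.append(
                    PeptideRecord(sequence=pep, start=bounds[i], missed_cleavages=missed)
                )
    return peptides


def peptide_mz(sequence: str, charge: int, carbamidomethyl_c: bool = False) -> float:
    """Monoisotopic m/z (optionally with fixed carbamidomethyl-C)."""
    from pyteomics import mass

    m = mass.fast_mass(sequence, charge=0)
    if carbamidomethyl_c:
        m += 57.02146 * sequence.count("C")
    proton = 1.00727646688
    return (m + charge * proton) / charge


# ---------------------------------------------------------------------------
# proteotypic cross-referencing
# ---------------------------------------------------------------------------

def flag_proteotypic(
    peptides: Iterable[PeptideRecord | str],
    database: Sequence[ProteinRecord],
) -> tuple[list[PeptideRecord], dict[str, int]]:
    """Assign parents (all database records containing the peptide as a
    substring), flag proteotypic peptides (exactly one parent), and flag
    peptides overlapping a novel frameshift C-terminal segment.

    Returns the annotated peptides and summary counts: total fs-mapping
    peptides, proteotypic fs peptides, and distinct fs isoforms that are
    unambiguously identified.
    """
    out: list[PeptideRecord] = []
    for pep in peptides:
        rec = (
            pep
            if isinstance(pep, PeptideRecord)
            else PeptideRecord(sequence=pep, start=-1, missed_cleavages=0)
        )
        parents = set()
        maps_fs = False
        for prot in database:
            idx = prot.sequence.find(rec.sequence)
            if idx < 0:
                continue
            parents.add(prot.accession)
            if prot.origin == "predicted_frameshift":
                # overlap the novel segment: at least one residue at or past
                # the divergence point, at any occurrence
                while idx >= 0:
                    if idx + len(rec.sequence) > prot.divergence:
                        maps_fs = True
                        break
                    idx = prot.sequence.find(rec.sequence, idx + 1)
        rec.parent_accessions = parents
        rec.proteotypic = len(parents) == 1
        rec.maps_to_fs_cterm = maps_fs
        out.append(rec)

    fs_peps = [r for r in out if r.maps_to_fs_cterm]
    proteo_fs = [r for r in fs_peps if r.proteotypic]
    fs_isoforms = {next(iter(r.parent_accessions)) for r in proteo_fs}
    summary = {
        "total_peptides": len(out),
        "fs_mapping_peptides": len(fs_peps),
        "proteotypic_fs_peptides": len(proteo_fs),
        "fs_isoforms_identified": len(fs_isoforms),
    }
    return out, summary


def peptide_table(peptides: Sequence[PeptideRecord], charges=(2, 3)) -> pd.DataFrame:
    rows = []
    for p in peptides:
        row = {
            "peptide": p.sequence,
            "missed_cleavages": p.missed_cleavages,
            "parents": ";".join(sorted(p.parent_accessions)),
            "proteotypic": p.proteotypic,
            "maps_to_fs_cterm": p.maps_to_fs_cterm,
        }
        for z in charges:
            row[f"mz_z{z}"] = round(peptide_mz(p.sequence, z), 4)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IP-MS enrichment
# ---------------------------------------------------------------------------

DEFAULT_EXCLUSION_PATTERNS = (r"(?i)tub", r"(?i)hsp")


@dataclass(frozen=True)
class EnrichmentRecord:
    protein_id: str
    normalized_ratios: tuple
    quantified: bool
    enriched: bool
    reason: str = ""


def call_ip_enrichment(
    ratios: pd.DataFrame,
    threshold: float = 1.5,
    exclusions: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
) -> list[EnrichmentRecord]:
    """Enrichment calls from a protein x replicate heavy/light ratio table.

    Each replicate column is first normalized by its median, so the bulk of
    (non-interacting) proteins centres at 1.  A protein is enriched when
    its normalized ratio exceeds ``threshold`` in *every* replicate, with
    at least two replicates quantified.  Proteins matching an exclusion
    pattern (tubulins, heat-shock proteins by default — habitual false
    positives) are never called enriched.
    """
    if ratios.shape[1] < 2:
        raise ValueError("need at least two replicate columns")
    norm = ratios / ratios.median(axis=0, skipna=True)
    compiled = [re.compile(p) for p in exclusions]
    out = []
    for protein_id, row in norm.iterrows():
        values = tuple(row.tolist())
        n_quant = row.notna().sum()
        if n_quant < 2:
            out.append(
                EnrichmentRecord(protein_id, values, False, False, "not quantified")
            )
            continue
        passes = bool((row.dropna() > threshold).all())
        if passes and any(rx.search(str(protein_id)) for rx in compiled):
            out.append(
                EnrichmentRecord(protein_id, values, True, False, "excluded family")
            )
            continue
        out.append(EnrichmentRecord(protein_id, values, True, passes))
    return out
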