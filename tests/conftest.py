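"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's code paths: translation
uses a hard-coded codon dictionary, splicing is naive per-exon substring
plus join, and motif/digestion checks are plain brute force.
"""

from __future__ import annotations

import pytest

from utr3frame import genome_io, discovery, synthetic

# --------------------------------------------------------------------------
# independent standard genetic code (spelled out, not imported)
# --------------------------------------------------------------------------

_BASES = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
ORACLE_CODON_TABLE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
ORACLE_STOPS = {codon for codon, aa in ORACLE_CODON_TABLE.items() if aa == "*"}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_translate(nt: str, start: int = 0) -> tuple[str, bool]:
    """Translate until the first stop; returns (protein, stop_reached)."""
    out = []
    for i in range(start, len(nt) - 2, 3):
        aa = ORACLE_CODON_TABLE.get(nt[i : i + 3], "X")
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def oracle_spliced(chrom_seq: str, exons, strand: str, skip_index=None) -> str:
    """Naive per-exon substring + join; exons are (start, end) 0-based
    half-open in transcript orientation."""
    parts = []
    for i, (s, e) in enumerate(exons):
        if i == skip_index:
            continue
        sub = chrom_seq[s:e]
        parts.append(sub if strand == "+" else oracle_revcomp(sub))
    return "".join(parts)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy")
    bundle = synthetic.generate_toy_genome(n_per_class=2, seed=7)
    paths = bundle.write(out)
    return {"bundle": bundle, **paths}


@pytest.fixture(scope="session")
def toy_genome(toy_dir):
    return genome_io.load_genome(toy_dir["genome"])


@pytest.fixture(scope="session")
def toy_models(toy_dir, toy_genome):
    return genome_io.load_annotation(toy_dir["gtf"], toy_genome)


@pytest.fixture(scope="session")
def toy_discovery(toy_models, toy_genome):
    return discovery.discover(toy_models, toy_genome)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path
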