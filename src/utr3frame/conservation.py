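"""Cross-species frame analysis: three-frame ORF scanning of last exons and
hypergeometric overlap testing of candidate sets linked by 1:1 orthologues.

The frame scan answers: how far can a ribosome read the last exon of a gene
in each forward frame before hitting a stop?  Frames are labelled relative
to the annotated reading frame (frame 0); no ATG is required because the
scanned frames continue an upstream coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .discovery import translate_to_stop


@dataclass(frozen=True)
class FrameScanResult:
    sequence_id: str
    #: longest-ORF length in AA keyed by relative frame (-1, 0, +1)
    orf_lengths: Mapping[int, int]
    #: frames whose ORF exceeds the highlight threshold (strictly more)
    highlighted: frozenset


def scan_last_exon(
    exon_seq: str,
    annotated_offset: int,
    min_len: int = 50,
    sequence_id: str = "",
) -> FrameScanResult:
    """Translate a last exon in all three forward frames.

    ``annotated_offset`` (0/1/2) is the frame of the annotated C-terminus,
    relabelled as frame 0; the other two frames become +1/-1 by offset
    difference.  ORF length counts amino acids from the frame's first codon
    to the first stop (stop excluded, sequence end otherwise); a frame is
    highlighted when its ORF is strictly longer than ``min_len``.
    """
    if annotated_offset not in (0, 1, 2):
        raise ValueError("annotated_offset must be 0, 1 or 2")
    if len(exon_seq) < 3:
        raise ValueError("exon shorter than one codon")
    lengths: dict[int, int] = {}
    for offset in range(3):
        aa, _ = translate_to_stop(exon_seq, offset)
        diff = (offset - annotated_offset) % 3
        rel = {0: 0, 1: +1, 2: -1}[diff]
        lengths[rel] = len(aa)
    highlighted = frozenset(f for f, L in lengths.items() if L > min_len)
    return FrameScanResult(sequence_id, lengths, highlighted)


@dataclass(frozen=True)
class OverlapTestResult:
    universe: int
    k_first: int
    n_second: int
    overlap: int
    p_value: float


def ortholog_overlap_test(N: int, K: int, n: int, k: int) -> OverlapTestResult:
    """Upper-tail hypergeometric probability of observing an overlap of at
    least ``k`` between a set of ``K`` and a set of ``n`` drawn from a
    universe of ``N`` genes."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"infeasible counts N={N}, K={K}, n={n}, k={k}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(N, K, n, k, min(p, 1.0))


def candidate_overlap(
    set_a: Sequence[str],
    set_b: Sequence[str],
    ortholog_map: Mapping[str, str],
    universe: int | None = None,
) -> OverlapTestResult:
    """Overlap test between candidate gene sets of two species.

    ``ortholog_map`` maps species-A gene ids to their 1:1 orthologue in
    species B; only candidates with a 1:1 orthologue are retained.  The
    universe defaults to the number of 1:1 pairs in the map (configurable,
    since different universes are defensible).
    """
    forward = dict(ortholog_map)
    # enforce 1:1 both ways
    seen: dict[str, str] = {}
    one_to_one = {}
    for a, b in forward.items():
        if b in seen:
            one_to_one.pop(seen[b], None)
            continue
        seen[b] = a
        one_to_one[a] = b
    a_mapped = {g for g in set_a if g in one_to_one}
    b_values = set(set_b)
    valid_b = set(one_to_one.values())
    k = sum(1 for g in a_mapped if one_to_one[g] in b_values)
    n_b = len(b_values & valid_b)
    N = universe if universe is not None else len(one_to_one)
    return ortholog_overlap_test(N, len(a_mapped), n_b, k)
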