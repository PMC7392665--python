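"""Composition, proline-rich motif scoring, proline groups, disorder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utr3frame import sequence_features as sf
from utr3frame.sequence_features import (
    CtermPair,
    aa_composition,
    builtin_motifs,
    coil_fraction,
    default_background,
    motif_frequency_score,
    proline_group,
    scan_motif,
    select_top_proline_delta,
    utr_composition,
)

MOTIFS = {m.name: m for m in builtin_motifs()}


def brute_force_scan(seq: str, pattern) -> int:
    """Independent offset-by-offset matcher."""
    n = 0
    for i in range(len(seq)):
        if i + len(pattern) > len(seq):
            break
        ok = True
        for j, cls in enumerate(pattern):
            if cls is not None and seq[i + j] not in cls:
                ok = False
                break
        if ok:
            n += 1
    return n


class TestComposition:
    def test_homopolymer(self):
        assert aa_composition("PPPP")["P"] == pytest.approx(1.0)

    def test_even_split(self):
        prof = aa_composition("PA")
        assert prof["P"] == pytest.approx(0.5)
        assert prof["A"] == pytest.approx(0.5)

    def test_stops_and_x_excluded(self):
        prof = aa_composition("MPPE*P")
        assert prof["P"] == pytest.approx(3 / 5)
        assert prof.length == 5

    def test_only_stops_errors(self):
        with pytest.raises(ValueError, match="countable"):
            aa_composition("***XX")

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        aas = sf.STANDARD_AAS + "*X"
        for _ in range(50):
            seq = "".join(rng.choice(list(aas), size=30))
            try:
                prof = aa_composition(seq)
            except ValueError:
                continue
            assert sum(prof.fractions.values()) == pytest.approx(1.0)


class TestUtrComposition:
    def test_polyA_utr_is_pure_lysine(self, toy_models, toy_genome):
        # graft a poly-A UTR onto a toy transcript via a custom toy genome
        from utr3frame.genome_io import ExonInterval, GenomeSequence, TranscriptModel

        chrom = "ATG" + "AAA" * 4 + "TAA" + "A" * 320
        t = TranscriptModel(
            transcript_id="t", gene_id="g", chrom="c", strand="+",
            exons=(ExonInterval("c", 0, len(chrom), "+"),),
            orf_start=0, orf_end=18,
        )
        genome = {"c": GenomeSequence("c", chrom)}
        cds, utr = utr_composition(t, genome)
        assert utr["K"] == pytest.approx(1.0)

    def test_all_stop_utr_errors(self):
        from utr3frame.genome_io import ExonInterval, GenomeSequence, TranscriptModel

        # a 3 nt UTR consisting of one stop codon: frame 0 yields only '*',
        # frames 1/2 yield no codon at all -> no countable amino acids
        chrom = "ATGAAA" + "TAA" + "TAA"
        t = TranscriptModel(
            transcript_id="t", gene_id="g", chrom="c", strand="+",
            exons=(ExonInterval("c", 0, len(chrom), "+"),),
            orf_start=0, orf_end=9,
        )
        with pytest.raises(ValueError):
            utr_composition(t, {"c": GenomeSequence("c", chrom)})

    def test_average_of_three_frames_matches_oracle(self, toy_models, toy_genome):
        from conftest import ORACLE_CODON_TABLE

        from utr3frame.genome_io import utr3_sequence

        checked = 0
        for t in toy_models:
            utr = utr3_sequence(t, toy_genome)
            if len(utr) < 9:
                continue
            try:
                _, utr_prof = utr_composition(t, toy_genome)
            except ValueError:
                continue
            # oracle: per-frame composition with stops dropped, then mean
            vecs = []
            for f in range(3):
                aas = [
                    ORACLE_CODON_TABLE.get(utr[i : i + 3], "X")
                    for i in range(f, len(utr) - 2, 3)
                ][:100]
                counted = [a for a in aas if a in sf.STANDARD_AAS]
                vecs.append(
                    np.array([counted.count(a) / len(counted) for a in sf.STANDARD_AAS])
                )
            expected = np.mean(vecs, axis=0)
            assert np.allclose(utr_prof.as_vector(), expected)
            checked += 1
        assert checked >= 5


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq,name,expected",
        [
            ("PAAP", "PxxP", 1),
            ("PAAPAAP", "PxxP", 2),  # overlapping starts 0 and 3
            ("AAAA", "PxxP", 0),
            ("PAAPAR", "PxxPxR", 1),
            ("RAAPAAP", "RxxPxxP", 1),
            ("KAVPAVP", "classI_[RK]xPhiPxPhiP", 1),
            ("VPAVPAR", "classII_PhiPxPhiPx[RK]", 1),
        ],
    )
    def test_examples(self, seq, name, expected):
        assert scan_motif(seq, MOTIFS[name]) == expected

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.text(alphabet=sf.STANDARD_AAS, min_size=0, max_size=60))
    def test_matches_bruteforce(self, seq):
        for m in MOTIFS.values():
            assert scan_motif(seq, m) == brute_force_scan(seq, m.pattern)


class TestMotifScore:
    def test_worked_uniform_background_example(self):
        bg = {aa: 0.05 for aa in sf.STANDARD_AAS}
        seq = "PAAP" + "G" * 39  # length 43, exactly one PxxP match
        s = motif_frequency_score(seq, MOTIFS["PxxP"], bg)
        assert s.observed == 1
        assert s.expected == pytest.approx(0.1)
        assert s.score == pytest.approx(10.0)

    def test_no_match_scores_zero(self):
        s = motif_frequency_score("GGGGGG", MOTIFS["PxxP"])
        assert s.observed == 0 and s.score == 0.0

    def test_observed_equals_expected_scores_one(self):
        bg = {aa: 0.05 for aa in sf.STANDARD_AAS}
        # expected = 0.0025 * (L - 3); choose L = 403 -> expected exactly 1
        seq = "PAAP" + "G" * 399
        s = motif_frequency_score(seq, MOTIFS["PxxP"], bg)
        assert s.observed == 1 and s.expected == pytest.approx(1.0)
        assert s.score == pytest.approx(1.0)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            motif_frequency_score("PAAP", MOTIFS["PxxP"], {"P": 0.5})

    def test_mean_score_near_one_under_background_sampling(self):
        """Sequences drawn i.i.d. from the background distribution should
        score ~1 on average (conditioned on >= 1 match, plus the zero mass)."""
        rng = np.random.default_rng(11)
        bg = default_background()
        aas = list(bg)
        probs = np.array([bg[a] for a in aas])
        m = MOTIFS["PxxP"]
        L = 200
        n = 3000
        scores = []
        for _ in range(n):
            seq = "".join(rng.choice(aas, size=L, p=probs))
            scores.append(motif_frequency_score(seq, m, bg).score)
        # E[score] = E[observed]/expected = 1 exactly; check within 3 SE
        scores = np.array(scores)
        se = scores.std(ddof=1) / np.sqrt(n)
        assert abs(scores.mean() - 1.0) < 3 * se + 0.05


class TestProlineGroups:
    @pytest.mark.parametrize(
        "p_fl,p_fs,label",
        [
            (10, 5, "P-decreased"),
            (10, 10, "P-unchanged"),
            (5, 15, "P-rich"),
            (13, 10, "P-unchanged"),  # boundary delta = +3
            (10, 13, "P-unchanged"),  # boundary delta = -3
        ],
    )
    def test_grouping(self, p_fl, p_fs, label):
        assert proline_group(p_fl, p_fs) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            proline_group(101, 5)


class TestCoil:
    @pytest.mark.parametrize("ss,frac", [("CCCC", 1.0), ("HHEE", 0.0), ("CHCE", 0.5)])
    def test_fraction(self, ss, frac):
        assert coil_fraction(ss).coil_fraction == pytest.approx(frac)

    def test_empty_or_invalid_rejected(self):
        with pytest.raises(ValueError):
            coil_fraction("")
        with pytest.raises(ValueError):
            coil_fraction("CHQ")


class TestTopProlineDelta:
    PAIRS = [
        CtermPair("c1", "AAAAA", "PPPPA", upstream="MKLV"),  # delta +80
        CtermPair("c2", "AAAAA", "PAAAA"),  # delta +20
        CtermPair("c3", "PPPPP", "AAAAA"),  # delta -100
    ]

    def test_top_selection_and_upstream_prepend(self):
        out = select_top_proline_delta(self.PAIRS, n=1)
        assert [o[0] for o in out] == ["c1"]
        assert out[0][1] == "MKLVAAAAA"  # 4 available upstream residues kept
        assert out[0][2] == "MKLVPPPPA"

    def test_n_larger_than_available_returns_all(self):
        assert len(select_top_proline_delta(self.PAIRS, n=10)) == 3

    def test_tie_breaks_on_id(self):
        pairs = [CtermPair("b", "A", "P"), CtermPair("a", "A", "P")]
        out = select_top_proline_delta(pairs, n=2)
        assert [o[0] for o in out] == ["a", "b"]


def test_planted_proline_and_pxxp_enrichment(toy_models, toy_discovery, toy_genome):
    """The generator plants proline-enriched frameshift C-termini; the
    composition and motif machinery must recover the direction (higher
    proline and PxxP density in fs vs fl tails)."""
    from utr3frame.genome_io import annotated_protein

    tx = {m.transcript_id: m for m in toy_models}
    pxxp = MOTIFS["PxxP"]
    fl_p, fs_p, fl_scores, fs_scores = [], [], [], []
    for c in toy_discovery.passing:
        t = tx[c.transcript_id]
        canon = annotated_protein(t, toy_genome)
        fl_tail = canon[c.divergence_point :]
        fs_tail = c.new_cterm_aa
        fl_p.append(aa_composition(fl_tail).proline_percent())
        fs_p.append(aa_composition(fs_tail).proline_percent())
        fl_scores.append(scan_motif(fl_tail, pxxp) / max(1, len(fl_tail)))
        fs_scores.append(scan_motif(fs_tail, pxxp) / max(1, len(fs_tail)))
    assert np.mean(fs_p) > np.mean(fl_p)
    assert np.mean(fs_scores) >= np.mean(fl_scores)
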