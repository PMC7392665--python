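"""Geometry classification, alternative C-terminus translation, gain
filters and event deduplication."""

import pathlib

import pytest

from utr3frame import discovery, genome_io, synthetic
from utr3frame.discovery import (
    apply_filters,
    build_candidate,
    classify_geometry,
    deduplicate,
    translate_to_stop,
)

from conftest import oracle_spliced, oracle_translate


class TestTranslateToStop:
    @pytest.mark.parametrize(
        "mrna,start,expected,stopped",
        [
            ("ATGTAA", 0, "M", True),
            ("ATGCCACCG", 0, "MPP", False),
            ("ATGCCTGAATAG", 0, "MPE", True),
            ("ATGNNNTAA", 0, "MX", True),  # N-codon -> X, never a stop
            ("ATGCC", 0, "M", False),  # truncated final codon ignored
        ],
    )
    def test_examples(self, mrna, start, expected, stopped):
        assert translate_to_stop(mrna, start) == (expected, stopped)

    def test_matches_oracle_on_toy_mrnas(self, toy_models, toy_genome):
        for m in toy_models:
            mrna = genome_io.spliced_sequence(m, toy_genome)
            assert translate_to_stop(mrna, m.orf_start) == oracle_translate(
                mrna, m.orf_start
            )


class TestClassifyGeometry:
    def test_planted_classes_recovered(self, toy_dir, toy_models):
        truth = {g.gene_id: g.class_name for g in toy_dir["bundle"].truth.genes}
        geometric = {  # Penulti_short and fail controls share Ultimate geometry
            "Penulti_short": "Ultimate",
            "fail_gain": "Ultimate",
            "fail_beyond": "Ultimate",
        }
        for m in toy_models:
            events = classify_geometry(m)
            internal = m.n_exons - 2
            assert len(events) == internal
            penult = [e for e in events if e.exon_index_skipped == m.n_exons - 2]
            (pe,) = penult
            expected = truth[m.gene_id]
            assert pe.geometry_class == geometric.get(expected, expected) or (
                expected in ("Internal_fp", "Internal_fs")
                and pe.geometry_class == "Penulti_fp"
            )

    def test_frame_law(self, toy_models):
        """Ultimate events always have a non-frame-preserving skipped exon."""
        for m in toy_models:
            for e in classify_geometry(m):
                if e.geometry_class == "Ultimate":
                    assert e.exon_length % 3 != 0
                if e.geometry_class in ("Penulti_fp", "Internal_fp"):
                    assert e.exon_length % 3 == 0

    def test_two_exon_transcript_yields_nothing(self, toy_models, toy_genome):
        m = toy_models[0]
        short = genome_io.TranscriptModel(
            transcript_id="t2x", gene_id="g2x", chrom=m.chrom, strand=m.strand,
            exons=m.exons[:2], orf_start=0, orf_end=3,
        )
        assert classify_geometry(short) == []


class TestBuildCandidate:
    def test_planted_gain_values(self, toy_dir, toy_models, toy_genome):
        truth = {g.gene_id: g for g in toy_dir["bundle"].truth.genes}
        checked = 0
        for m in toy_models:
            g = truth[m.gene_id]
            if g.class_name not in ("Ultimate", "Penultimate"):
                continue
            for e in classify_geometry(m):
                if e.geometry_class not in discovery.CANDIDATE_CLASSES:
                    continue
                c = build_candidate(e, m, toy_genome)
                assert (c.aa_gained, c.aa_beyond_stop) == (g.aa_gained, g.aa_beyond)
                assert c.outcome == "extended"
                assert c.new_stop_in_last_exon
                checked += 1
        assert checked >= 4

    def test_ineligible_class_rejected(self, toy_models, toy_genome):
        for m in toy_models:
            for e in classify_geometry(m):
                if e.geometry_class == "Penulti_fp":
                    with pytest.raises(ValueError, match="geometry class"):
                        build_candidate(e, m, toy_genome)
                    return
        pytest.fail("no Penulti_fp event found in toy annotation")

    def test_early_stop_yields_short_outcome(self, toy_dir, toy_models, toy_genome):
        truth = {g.gene_id: g.class_name for g in toy_dir["bundle"].truth.genes}
        seen = 0
        for m in toy_models:
            if truth[m.gene_id] != "Penulti_short":
                continue
            for e in classify_geometry(m):
                if e.geometry_class in discovery.CANDIDATE_CLASSES:
                    c = build_candidate(e, m, toy_genome)
                    assert c.outcome == "short"
                    assert c.aa_beyond_stop == 0
                    assert not apply_filters(c)
                    seen += 1
        assert seen >= 1

    def test_new_cterm_matches_bruteforce_oracle(self, toy_models, toy_genome):
        """The reported C-terminus equals the suffix of an independent naive
        translation of the skipped mRNA."""
        for m in toy_models:
            for e in classify_geometry(m):
                if e.geometry_class not in discovery.CANDIDATE_CLASSES:
                    continue
                c = build_candidate(e, m, toy_genome)
                chrom = toy_genome[m.chrom].sequence
                skipped = oracle_spliced(
                    chrom, [(x.start, x.end) for x in m.exons], m.strand,
                    skip_index=e.exon_index_skipped,
                )
                alt, _ = oracle_translate(skipped, m.orf_start)
                assert alt[c.divergence_point :] == c.new_cterm_aa


class TestFilters:
    @pytest.mark.parametrize(
        "gained,beyond,expected",
        [(20, 10, True), (19, 10, False), (20, 9, False), (35, 12, True)],
    )
    def test_boundaries_via_planted_genes(self, tmp_path, gained, beyond, expected):
        bundle = synthetic.generate_extension_genes([(gained, beyond)], seed=5)
        paths = bundle.write(tmp_path / f"g{gained}_{beyond}")
        genome = genome_io.load_genome(paths["genome"])
        models = genome_io.load_annotation(paths["gtf"], genome)
        result = discovery.discover(models, genome)
        (c,) = result.all_candidates
        assert (c.aa_gained, c.aa_beyond_stop) == (gained, beyond)
        assert apply_filters(c) is expected
        assert len(result.passing) == (1 if expected else 0)

    def test_monotone_in_thresholds(self, toy_discovery):
        cands = toy_discovery.all_candidates
        base = sum(apply_filters(c, 20, 10) for c in cands)
        assert sum(apply_filters(c, 25, 10) for c in cands) <= base
        assert sum(apply_filters(c, 20, 15) for c in cands) <= base


class TestDeduplicate:
    def test_isoform_duplicates_collapse(self, toy_dir, toy_discovery):
        dup_genes = {
            g.gene_id for g in toy_dir["bundle"].truth.genes if g.duplicate_isoform
        }
        passing = toy_discovery.passing
        for gene in dup_genes:
            reps = [c for c in passing if c.gene_id == gene]
            assert len(reps) == 1
            # representative = lexicographically smallest transcript id
            assert reps[0].transcript_id.endswith(".t1")

    def test_distinct_stop_positions_stay_separate(self, toy_discovery):
        c = toy_discovery.passing[0]
        clone = discovery.FrameshiftCandidate(
            skip_event=discovery.SkipEvent(
                **{
                    **c.skip_event.__dict__,
                    "transcript_id": "zzz",
                    "annotated_stop_position": c.skip_event.annotated_stop_position + 3,
                }
            ),
            divergence_point=c.divergence_point,
            new_cterm_aa=c.new_cterm_aa,
            aa_gained=c.aa_gained,
            aa_beyond_stop=c.aa_beyond_stop,
            new_stop_in_last_exon=True,
            stop_reached=True,
            outcome="extended",
        )
        out = deduplicate([c, clone])
        assert len(out) == 2

    def test_idempotent(self, toy_discovery):
        once = deduplicate(toy_discovery.all_candidates)
        assert deduplicate(once) == once
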