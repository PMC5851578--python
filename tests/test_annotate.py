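import numpy as np
import pytest

from carp.align import GenomeHit
from carp.annotate import (
    AnnotationHit,
    FilterParams,
    annotate_genome,
    classify_consensus,
    consensus_te_class,
    detect_ssr,
    filter_consensus_set,
    is_unclassified,
    parse_te_class,
    resolve_overlaps,
    search_protein,
    summarize_repeat_content,
    translate,
)
from carp.consensus import ConsensusRecord
from carp.seqio import GenomeInterval, SequenceRecord
from carp.simulate import _random_protein, reverse_translate
from conftest import random_seq


class TestDetectSsr:
    def test_pure_dinucleotide_tract(self):
        assert detect_ssr("ACACACACACAC") == 1.0

    def test_random_sequence_low_fraction(self, rng):
        for _ in range(5):
            assert detect_ssr(random_seq(rng, 1000)) < 0.1

    def test_embedded_tract_fraction(self, rng):
        flank = random_seq(rng, 500)
        tract = "AGT" * 4  # unit 3, 4 copies, 12 bp
        seq = flank + tract + flank
        frac = detect_ssr(seq)
        assert frac == pytest.approx(12 / len(seq), abs=0.01)

    def test_three_copies_not_enough(self):
        # unit 6, 3 copies: 18 bp but below the 4-copy floor
        seq = "ATCGGA" * 3 + "TTTACGCATGCA" * 4
        covered = detect_ssr("GACTGACGTACGATCA" + "ATCGGA" * 3 + "CAGTTACGGTAC")
        assert covered == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detect_ssr("")


class TestTranslateAndSearchProtein:
    def test_translation_standard_code(self):
        assert translate("ATGGCTTAA") == "MA*"

    def test_exact_protein_recovered(self, rng):
        protein = _random_protein(rng, 300)
        flanks = random_seq(rng, 200), random_seq(rng, 200)
        consensus = SequenceRecord(
            "c1", flanks[0] + reverse_translate(protein) + flanks[1]
        )
        hits = search_protein(consensus, [SequenceRecord("ref", protein)])
        assert hits
        assert hits[0].evalue < 1e-50
        assert hits[0].query_start == pytest.approx(200, abs=3)

    def test_reverse_strand_hit(self, rng):
        from carp.seqio import reverse_complement

        protein = _random_protein(rng, 200)
        consensus = SequenceRecord(
            "c1",
            random_seq(rng, 150)
            + reverse_complement(reverse_translate(protein))
            + random_seq(rng, 150),
        )
        hits = search_protein(consensus, [SequenceRecord("ref", protein)])
        assert hits and hits[0].evalue < 1e-50

    def test_random_sequence_no_hits(self, rng):
        protein = _random_protein(rng, 300)
        for _ in range(3):
            consensus = SequenceRecord("c", random_seq(rng, 1000))
            assert (
                search_protein(consensus, [SequenceRecord("ref", protein)])
                == []
            )

    def test_empty_db(self, rng):
        assert search_protein(SequenceRecord("c", random_seq(rng, 500)), []) == []


class TestFilterConsensusSet:
    def _consensus(self, name, sequence):
        return ConsensusRecord(name, sequence, [])

    def test_host_gene_removed(self, rng):
        protein = _random_protein(rng, 300)
        cons = self._consensus(
            "family000001",
            random_seq(rng, 100) + reverse_translate(protein) + random_seq(rng, 100),
        )
        host_db = [SequenceRecord("hostP", protein)]
        kept, removed = filter_consensus_set([cons], host_db, [])
        assert kept == []
        assert removed[0].reason == "host_protein"

    def test_rt_positive_consensus_retained(self, rng):
        protein = _random_protein(rng, 300)
        cons = self._consensus(
            "family000001",
            random_seq(rng, 100) + reverse_translate(protein) + random_seq(rng, 100),
        )
        host_db = [SequenceRecord("hostP", protein)]
        rt_db = [SequenceRecord("rtP", protein)]
        kept, removed = filter_consensus_set([cons], host_db, rt_db)
        assert len(kept) == 1 and removed == []

    def test_plain_consensus_kept(self, rng):
        cons = self._consensus("family000001", random_seq(rng, 800))
        protein = _random_protein(rng, 300)
        kept, removed = filter_consensus_set(
            [cons], [SequenceRecord("hostP", protein)], []
        )
        assert len(kept) == 1 and removed == []

    def test_ssr_consensus_removed(self):
        cons = self._consensus("family000001", "TA" * 300)
        kept, removed = filter_consensus_set([cons], [], [])
        assert kept == [] and removed[0].reason == "ssr"


class TestClassifyConsensus:
    def test_header_parsing(self):
        assert parse_te_class("L2-1_Mono#LINE/L2") == ("L2-1_Mono", "LINE")
        assert parse_te_class("plain") == ("plain", "Other")

    def _with_library(self, rng, cover_frac):
        ref = random_seq(rng, 2000)
        flank_len = int(2000 * (1 - cover_frac) / cover_frac / 2) if cover_frac < 1 else 0
        covered = int(2000)
        consensus_seq = (
            random_seq(rng, flank_len) + ref[:covered] + random_seq(rng, flank_len)
        )
        cons = ConsensusRecord("family000001", consensus_seq, [])
        library = [SequenceRecord("anc#LINE/L2", ref)]
        classify_consensus([cons], library)
        return cons

    def test_full_coverage_well_annotated(self, rng):
        cons = self._with_library(rng, 0.95)
        assert cons.annotation_class == "well_annotated"
        assert consensus_te_class(cons) == "LINE"
        assert not is_unclassified(cons)

    def test_small_hit_partially_annotated(self, rng):
        ref = random_seq(rng, 2000)
        cons = ConsensusRecord(
            "family000001",
            random_seq(rng, 600) + ref[:120] + random_seq(rng, 600),
            [],
        )
        classify_consensus([cons], [SequenceRecord("anc#LINE", ref)])
        assert cons.annotation_class == "partially_annotated"
        assert is_unclassified(cons)

    def test_no_hits_unannotated(self, rng):
        cons = ConsensusRecord("family000001", random_seq(rng, 1000), [])
        classify_consensus([cons], [SequenceRecord("anc#LINE", random_seq(rng, 1000))])
        assert cons.annotation_class == "unannotated"

    def test_empty_library_all_unannotated(self, rng):
        cons = ConsensusRecord("family000001", random_seq(rng, 1000), [])
        classify_consensus([cons], [])
        assert cons.annotation_class == "unannotated"

    def test_monotone_in_library(self, rng):
        """Adding references can only improve annotation status."""
        ref = random_seq(rng, 1000)
        rank = {
            "unannotated": 0, "partially_annotated": 1, "well_annotated": 2
        }
        cons = ConsensusRecord("family000001", ref, [])
        classify_consensus([cons], [SequenceRecord("x#DNA", random_seq(rng, 800))])
        before = rank[cons.annotation_class]
        classify_consensus(
            [cons],
            [
                SequenceRecord("x#DNA", random_seq(rng, 800)),
                SequenceRecord("y#LINE", ref),
            ],
        )
        assert rank[cons.annotation_class] >= before


class TestOverlapResolution:
    def _hit(self, qid, start, end, score, q_len=None):
        q_len = q_len or (end - start)
        return GenomeHit(
            qid, 0, q_len, GenomeInterval("c", start, end), 0.9, score
        )

    def test_best_hit_wins_overlap(self):
        hits = [
            self._hit("consX", 1000, 1500, 500),
            self._hit("refY", 1200, 1700, 300),
        ]
        resolved = resolve_overlaps(hits, {"consX": "LINE", "refY": "SINE"})
        by_lib = {r.library_id: r for r in resolved}
        assert by_lib["consX"].interval == GenomeInterval("c", 1000, 1500)
        # loser trimmed to its non-overlapping remainder
        assert by_lib["refY"].interval == GenomeInterval("c", 1500, 1700)

    def test_loser_discarded_when_trimmed_below_floor(self):
        hits = [
            self._hit("a", 1000, 1500, 500),
            self._hit("b", 1010, 1520, 300),
        ]
        resolved = resolve_overlaps(hits, {}, min_keep_bp=30)
        # remainder of b is [1500,1520) = 20 bp < 30 -> discarded
        assert [r.library_id for r in resolved] == ["a"]

    def test_resolved_hits_never_overlap(self, rng):
        hits = [
            self._hit(f"q{i}", int(s), int(s) + int(l), int(sc))
            for i, (s, l, sc) in enumerate(
                zip(
                    rng.integers(0, 5000, 40),
                    rng.integers(40, 400, 40),
                    rng.integers(10, 1000, 40),
                )
            )
        ]
        resolved = resolve_overlaps(hits, {})
        spans = sorted((r.interval.start, r.interval.end) for r in resolved)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestAnnotateGenome:
    def test_diverged_copy_annotated_below_self_alignment_gate(self, rng):
        """A planted copy at ~85% identity to a library entry is invisible
        to the 94% self-alignment but annotated by the relaxed library
        search."""
        from carp.align import align_all

        ancestor = random_seq(rng, 600)
        copy = list(ancestor)
        for site in rng.choice(600, size=90, replace=False):
            copy[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[site]]
        copy = "".join(copy)
        genome = [
            SequenceRecord(
                "chr1", random_seq(rng, 3000) + copy + random_seq(rng, 3000)
            )
        ]
        assert align_all(genome) == []
        resolved = annotate_genome(
            genome, [SequenceRecord("anc#LINE", ancestor)], {"anc#LINE": "LINE"}
        )
        assert len(resolved) == 1
        hit = resolved[0]
        assert hit.interval.overlap_length(GenomeInterval("chr1", 3000, 3600)) >= 500
        assert hit.te_class == "LINE"

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            annotate_genome(
                [SequenceRecord("c", random_seq(rng, 1000))], [], {}
            )

    def test_unrelated_genome_unannotated(self, rng):
        resolved = annotate_genome(
            [SequenceRecord("c", random_seq(rng, 5000))],
            [SequenceRecord("anc#LINE", random_seq(rng, 500))],
            {"anc#LINE": "LINE"},
        )
        assert resolved == []


class TestSummary:
    def _resolved(self, cls, start, end):
        from carp.annotate import ResolvedHit

        return ResolvedHit(
            "lib", cls, GenomeInterval("c", start, end), 0, end - start, 0.9, 100
        )

    def test_single_hit_percentage(self):
        summary = summarize_repeat_content(
            [self._resolved("LINE", 0, 1000)], 100_000
        )
        assert summary["LINE"] == pytest.approx(1.0)
        assert summary["Total"] == pytest.approx(1.0)

    def test_classes_partition_coverage(self):
        hits = [
            self._resolved("LINE", 0, 1000),
            self._resolved("SINE", 2000, 2500),
            self._resolved("Unclassified", 5000, 9000),
        ]
        summary = summarize_repeat_content(hits, 10_000)
        assert summary["IR"] == pytest.approx(15.0)
        assert summary["SD"] == pytest.approx(40.0)
        assert summary["Total"] == pytest.approx(55.0)

    def test_empty_annotation_all_zero(self):
        summary = summarize_repeat_content([], 1000)
        assert all(v == 0 for v in summary.values())
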