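import numpy as np
import pytest

from carp.align import LocalAlignment
from carp.families import (
    alignment_images,
    build_piles,
    export_family_members,
    link_families,
    member_record_id,
    parse_member_record_id,
)
from carp.seqio import GenomeInterval, SequenceRecord
from conftest import random_seq
from oracles import union_find_components


def _aln(a, b, orientation="same", identity=0.99, score=500):
    return LocalAlignment(
        GenomeInterval(*a), GenomeInterval(*b), identity, score, orientation
    )


class TestBuildPiles:
    def test_overlapping_images_merge(self):
        images = [
            (0, GenomeInterval("c", 100, 400)),
            (1, GenomeInterval("c", 150, 450)),
        ]
        instances = build_piles(images, pile_min_overlap=0.5)
        assert len(instances) == 1
        inst = instances[0]
        assert (inst.interval.start, inst.interval.end) == (100, 450)
        assert inst.image_ids == [0, 1]

    def test_insufficient_overlap_stays_separate(self):
        # overlap 50 bp / shorter 300 bp = 0.17 < 0.5
        images = [
            (0, GenomeInterval("c", 100, 400)),
            (1, GenomeInterval("c", 350, 650)),
        ]
        assert len(build_piles(images, 0.5)) == 2

    def test_disjoint_images_two_instances(self):
        images = [
            (0, GenomeInterval("c", 0, 300)),
            (1, GenomeInterval("c", 1000, 1300)),
        ]
        assert len(build_piles(images)) == 2

    def test_empty(self):
        assert build_piles([]) == []

    def test_transitive_merge(self):
        images = [
            (0, GenomeInterval("c", 0, 300)),
            (1, GenomeInterval("c", 200, 500)),
            (2, GenomeInterval("c", 400, 700)),
        ]
        instances = build_piles(images, 0.3)
        assert len(instances) == 1
        assert instances[0].interval.end - instances[0].interval.start == 700

    def test_exhaustive_pairwise_oracle(self, rng):
        """Pile membership equals the transitive closure of the pairwise
        overlap criterion computed by brute force."""
        for trial in range(20):
            n = 12
            ivs = []
            for i in range(n):
                start = int(rng.integers(0, 2000))
                length = int(rng.integers(50, 400))
                ivs.append(GenomeInterval("c", start, start + length))
            images = list(enumerate(ivs))
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    ov = ivs[i].overlap_length(ivs[j])
                    if ov >= 0.5 * min(ivs[i].length, ivs[j].length):
                        edges.append((i, j))
            expected = {
                frozenset(c)
                for c in union_find_components(n, edges)
            }
            got = {
                frozenset(inst.image_ids)
                for inst in build_piles(images, 0.5)
            }
            assert got == expected


class TestLinkFamilies:
    def _instances_and_alignments(self):
        alignments = [
            _aln(("c", 100, 400), ("c", 1000, 1300)),
            _aln(("c", 1000, 1300), ("c", 2000, 2300)),
        ]
        instances = build_piles(alignment_images(alignments))
        return instances, alignments

    def test_transitive_linkage_single_family(self):
        instances, alignments = self._instances_and_alignments()
        families = link_families(instances, alignments)
        assert len(families) == 1
        assert families[0].size == 3

    def test_no_alignments_no_families(self):
        assert link_families([], []) == []

    def test_two_separate_families(self):
        alignments = [
            _aln(("c", 100, 400), ("c", 1000, 1300)),
            _aln(("c", 5000, 5400), ("c", 7000, 7400)),
        ]
        instances = build_piles(alignment_images(alignments))
        families = link_families(instances, alignments)
        assert [f.size for f in families] == [2, 2]

    def test_families_partition_instances(self):
        instances, alignments = self._instances_and_alignments()
        families = link_families(instances, alignments)
        seen = [m.id for f in families for m in f.members]
        assert len(seen) == len(set(seen))

    def test_edge_list_retained(self):
        instances, alignments = self._instances_and_alignments()
        family = link_families(instances, alignments)[0]
        assert len(family.edges) == 2
        assert {e[2] for e in family.edges} == {0, 1}

    def test_dangling_image_raises(self):
        alignments = [_aln(("c", 100, 400), ("c", 1000, 1300))]
        with pytest.raises(ValueError, match="no instance"):
            link_families([], alignments)

    def test_union_find_oracle_on_random_graphs(self, rng):
        """Connected components agree with brute-force union-find over
        randomly generated alignment edge sets."""
        for trial in range(10):
            n_loci = 20
            loci = [(int(s), int(s) + 300) for s in rng.integers(0, 10**6, n_loci) * 2]
            loci = sorted(set(loci))
            pairs = set()
            while len(pairs) < 12:
                i, j = sorted(rng.choice(len(loci), 2, replace=False))
                if i != j:
                    pairs.add((int(i), int(j)))
            pairs = sorted(pairs)
            alignments = [
                _aln(("c", *loci[i]), ("c", *loci[j])) for i, j in pairs
            ]
            instances = build_piles(alignment_images(alignments))
            families = link_families(instances, alignments)
            # brute force on locus indices
            expected = [
                c
                for c in union_find_components(len(loci), pairs)
                if len(c) > 1
            ]
            got = [
                {loci.index((m.interval.start, m.interval.end)) for m in f.members}
                for f in families
            ]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestExportMembers:
    def _family(self, rng, strands=("+", "+", "+")):
        copy = random_seq(rng, 300)
        from carp.seqio import reverse_complement

        parts = []
        pos = 0
        spans = []
        for s in strands:
            pad = random_seq(rng, 500)
            parts.append(pad)
            pos += 500
            parts.append(copy if s == "+" else reverse_complement(copy))
            spans.append((pos, pos + 300))
            pos += 300
        genome = [SequenceRecord("c", "".join(parts))]
        alignments = [
            _aln(
                ("c", *spans[0]),
                ("c", *spans[i]),
                orientation="same" if strands[i] == strands[0] else "opposite",
            )
            for i in range(1, len(strands))
        ]
        instances = build_piles(alignment_images(alignments))
        families = link_families(instances, alignments)
        assert len(families) == 1
        return genome, families[0], copy

    def test_record_ids_round_trip(self, rng):
        genome, family, _ = self._family(rng)
        records = export_family_members(family, genome)
        assert len(records) == 3
        for member, record in zip(family.members, records):
            fam_id, inst_id, iv = parse_member_record_id(record.id)
            assert fam_id == family.id
            assert inst_id == member.id
            assert (iv.start, iv.end) == (
                member.interval.start,
                member.interval.end,
            )

    def test_minority_orientation_member_emitted_reverse_complemented(
        self, rng
    ):
        genome, family, copy = self._family(rng, strands=("+", "+", "-"))
        records = export_family_members(family, genome)
        # all exported sequences should now be on the majority strand:
        # mutually near-identical
        from oracles import needleman_wunsch_identity

        for rec in records[1:]:
            assert (
                needleman_wunsch_identity(records[0].sequence, rec.sequence)
                > 0.95
            )
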