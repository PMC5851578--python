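"""Repeat family construction.

Alignment images are merged into element instances ("piles": maximal sets
of mutually overlapping images), and instances linked by at least one
alignment are single-linkage clustered into repeat families.  The edge list
of supporting alignments is preserved per family, so every consensus can be
traced back to its member instances and from there to genome intervals —
the audit trail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .align import LocalAlignment
from .seqio import (
    GenomeInterval,
    SequenceRecord,
    as_dict,
    extract_subsequence,
)


@dataclass
class ElementInstance:
    """A genomic element occurrence: the union span of overlapping
    alignment images, with the supporting image ids."""

    id: str
    interval: GenomeInterval
    image_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class RepeatFamily:
    """A single-linkage cluster of element instances.

    ``edges`` holds (instance_id, instance_id, alignment_index) triples —
    the alignments that link the members.  ``orientations`` maps each member
    to '+'/'-' relative to the family's majority orientation.
    """

    id: str
    members: list[ElementInstance]
    edges: list[tuple[str, str, int]]
    orientations: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def alignment_images(
    alignments: Sequence[LocalAlignment],
) -> list[tuple[int, GenomeInterval]]:
    """Flatten alignments into (image_id, interval) pairs.

    Image ids are ``2*i`` and ``2*i + 1`` for alignment ``i``'s two images.
    """
    images = []
    for i, aln in enumerate(alignments):
        images.append((2 * i, aln.image_a))
        images.append((2 * i + 1, aln.image_b))
    return images


def build_piles(
    images: Sequence[tuple[int, GenomeInterval]],
    pile_min_overlap: float = 0.5,
) -> list[ElementInstance]:
    """Merge overlapping images into element instances.

    Two images belong to the same instance iff (transitively) they overlap
    by at least ``pile_min_overlap`` of the shorter image.  The instance
    interval is the union span of its member images.
    """
    by_seq: dict[str, list[tuple[int, GenomeInterval]]] = {}
    for img_id, iv in images:
        by_seq.setdefault(iv.seq_id, []).append((img_id, iv))

    instances: list[ElementInstance] = []
    counter = 0
    for seq_id in sorted(by_seq):
        items = sorted(by_seq[seq_id], key=lambda x: (x[1].start, x[1].end))
        # active piles: (union_start, union_end, member list of (id, iv))
        active: list[list] = []
        for img_id, iv in items:
            # retire piles that end before this image starts: later images
            # (sorted by start) can never reach them
            still: list[list] = []
            for pile in active:
                if pile[1] <= iv.start:
                    counter += 1
                    instances.append(_close_pile(seq_id, counter, pile))
                else:
                    still.append(pile)
            active = still

            merged_into = []
            for pile in active:
                for _, other in pile[2]:
                    ov = iv.overlap_length(other)
                    if ov >= pile_min_overlap * min(iv.length, other.length):
                        merged_into.append(pile)
                        break
            if merged_into:
                target = merged_into[0]
                for other_pile in merged_into[1:]:
                    target[0] = min(target[0], other_pile[0])
                    target[1] = max(target[1], other_pile[1])
                    target[2].extend(other_pile[2])
                    active.remove(other_pile)
                target[0] = min(target[0], iv.start)
                target[1] = max(target[1], iv.end)
                target[2].append((img_id, iv))
            else:
                active.append([iv.start, iv.end, [(img_id, iv)]])
        for pile in active:
            counter += 1
            instances.append(_close_pile(seq_id, counter, pile))
    instances.sort(key=lambda inst: inst.interval)
    return instances


def _close_pile(seq_id: str, counter: int, pile: list) -> ElementInstance:
    iv = GenomeInterval(seq_id, pile[0], pile[1])
    return ElementInstance(
        id=f"inst{counter:06d}",
        interval=iv,
        image_ids=sorted(i for i, _ in pile[2]),
    )


def link_families(
    instances: Sequence[ElementInstance],
    alignments: Sequence[LocalAlignment],
) -> list[RepeatFamily]:
    """Single-linkage clustering: families are the connected components of
    the instance graph whose edges are alignments linking two distinct
    instances.  Components of size 1 are discarded; the edge list is kept.
    """
    image_to_instance: dict[int, str] = {}
    inst_by_id = {inst.id: inst for inst in instances}
    for inst in instances:
        for img_id in inst.image_ids:
            image_to_instance[img_id] = inst.id

    graph = nx.Graph()
    graph.add_nodes_from(inst_by_id)
    edge_records: list[tuple[str, str, int, str]] = []
    for i, aln in enumerate(alignments):
        try:
            a = image_to_instance[2 * i]
            b = image_to_instance[2 * i + 1]
        except KeyError:
            raise ValueError(
                f"alignment {i} has an image that belongs to no instance"
            ) from None
        if a != b:
            graph.add_edge(a, b)
            edge_records.append((a, b, i, aln.orientation))

    families: list[RepeatFamily] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: inst_by_id[c[0]].interval,
    )
    n = 0
    for comp in components:
        if len(comp) < 2:
            continue
        n += 1
        comp_set = set(comp)
        edges = [
            (a, b, i) for a, b, i, _ in edge_records
            if a in comp_set and b in comp_set
        ]
        fam = RepeatFamily(
            id=f"family{n:06d}",
            members=sorted(
                (inst_by_id[c] for c in comp), key=lambda x: x.interval
            ),
            edges=edges,
        )
        fam.orientations = _resolve_orientations(fam, edge_records)
        families.append(fam)
    return families


def _resolve_orientations(
    family: RepeatFamily,
    edge_records: list[tuple[str, str, int, str]],
) -> dict[str, str]:
    """Propagate relative strand over the alignment graph (opposite-
    orientation edges flip sign), then flip the family so '+' is the
    majority; ties resolve to '+'."""
    members = {m.id for m in family.members}
    adj: dict[str, list[tuple[str, bool]]] = {m: [] for m in members}
    for a, b, _, orient in edge_records:
        if a in members and b in members:
            flip = orient == "opposite"
            adj[a].append((b, flip))
            adj[b].append((a, flip))
    sign: dict[str, int] = {}
    for start in sorted(members):
        if start in sign:
            continue
        sign[start] = 1
        stack = [start]
        while stack:
            node = stack.pop()
            for nb, flip in adj[node]:
                if nb not in sign:
                    sign[nb] = -sign[node] if flip else sign[node]
                    stack.append(nb)
    plus = sum(1 for s in sign.values() if s > 0)
    if plus * 2 < len(sign):
        sign = {k: -v for k, v in sign.items()}
    return {k: "+" if v > 0 else "-" for k, v in sign.items()}


_MEMBER_ID_RE = re.compile(
    r"^(?P<family>[^:]+):(?P<inst>[^:]+):(?P<seq>.+):"
    r"(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$"
)


def member_record_id(family: RepeatFamily, member: ElementInstance) -> str:
    strand = family.orientations.get(member.id, "+")
    iv = member.interval
    return f"{family.id}:{member.id}:{iv.seq_id}:{iv.start}-{iv.end}({strand})"


def parse_member_record_id(record_id: str) -> tuple[str, str, GenomeInterval]:
    """Inverse of :func:`member_record_id`: (family_id, instance_id,
    interval with the emitted strand)."""
    m = _MEMBER_ID_RE.match(record_id)
    if not m:
        raise ValueError(f"unparseable member record id {record_id!r}")
    return (
        m["family"],
        m["inst"],
        GenomeInterval(m["seq"], int(m["start"]), int(m["end"]), m["strand"]),
    )


def export_family_members(
    family: RepeatFamily,
    genome: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
) -> list[SequenceRecord]:
    """Member sequences oriented to the family majority strand, with ids
    that encode the family, instance and genome interval."""
    if not isinstance(genome, Mapping):
        genome = as_dict(genome)
    records = []
    for member in family.members:
        strand = family.orientations.get(member.id, "+")
        iv = GenomeInterval(
            member.interval.seq_id,
            member.interval.start,
            member.interval.end,
            strand,
        )
        records.append(
            SequenceRecord(
                member_record_id(family, member),
                extract_subsequence(genome, iv),
            )
        )
    return records
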