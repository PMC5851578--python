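"""Per-family consensus construction.

Members within a length fraction of the longest member are sampled (at most
``max_sample``, longest always included), multiple-aligned, and the
consensus is called by per-column majority vote.  Columns where the gap is
the strict majority are dropped, which prevents indel-driven consensus
expansion.

The built-in MSA is a center-star progressive alignment with the longest
sequence as the center.  Family members pass the self-alignment identity
gate (≥ ~94% pairwise), so star alignment is adequate; an external MSA
program can be substituted behind the same contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .families import ElementInstance, RepeatFamily


@dataclass
class ConsensusRecord:
    """A family's consensus sequence plus (later) its annotation."""

    family_id: str
    sequence: str
    sampled_member_ids: list[str]
    annotation_class: str = "unannotated"
    annotation_hits: list = field(default_factory=list)


def select_members(
    family: RepeatFamily,
    length_fraction: float = 0.95,
    max_sample: int = 100,
    rng_seed: int = 0,
) -> list[ElementInstance]:
    """Members within ``length_fraction`` of the longest member length,
    down-sampled to ``max_sample`` uniformly without replacement.  The
    longest member is always part of the sample."""
    if family.size < 2:
        raise ValueError(f"family {family.id} has fewer than 2 members")
    longest = max(family.members, key=lambda m: (m.length, m.id))
    threshold = length_fraction * longest.length
    eligible = [m for m in family.members if m.length >= threshold]
    if len(eligible) <= max_sample:
        return eligible
    rng = np.random.default_rng(rng_seed)
    others = [m for m in eligible if m.id != longest.id]
    picked = rng.choice(len(others), size=max_sample - 1, replace=False)
    sample = [longest] + [others[i] for i in sorted(picked)]
    sample.sort(key=lambda m: m.interval)
    return sample


def _pairwise_to_center(center: str, other: str) -> list[tuple[int, int]]:
    """Global alignment of ``other`` to ``center`` via edlib; returns the
    per-column (center_advance, other_advance) steps."""
    res = edlib.align(other, center, mode="NW", task="path")
    steps = []
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        count = int(count)
        if op in ("=", "X", "M"):
            steps.append((count, count))
        elif op == "I":  # insertion in `other` relative to center
            steps.append((0, count))
        else:  # deletion: center advances alone
            steps.append((count, 0))
    return steps


def align_members(sequences: Sequence[str]) -> list[str]:
    """Center-star multiple alignment over {A,C,G,T,N,-}.

    The longest sequence is the center; every other sequence is globally
    aligned to it and gaps are merged column-wise ("once a gap, always a
    gap").  Removing gaps from row i reproduces input i.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return [sequences[0]]
    center_idx = max(range(len(sequences)), key=lambda i: len(sequences[i]))
    center = sequences[center_idx]

    # per-member insert counts before each center position (and at the end)
    n = len(center)
    inserts = np.zeros(n + 1, dtype=np.int64)
    member_steps = []
    for i, seq in enumerate(sequences):
        if i == center_idx:
            member_steps.append(None)
            continue
        steps = _pairwise_to_center(center, seq)
        member_steps.append(steps)
        cpos = 0
        for c_adv, o_adv in steps:
            if c_adv == 0:
                inserts[cpos] = max(inserts[cpos], o_adv)
            else:
                cpos += c_adv
    # column layout: inserts[j] insert columns before center position j
    col_of_center = np.zeros(n, dtype=np.int64)
    col = 0
    for j in range(n):
        col += inserts[j]
        col_of_center[j] = col
        col += 1
    total_cols = col + int(inserts[n])

    rows = []
    for i, seq in enumerate(sequences):
        row = ["-"] * total_cols
        if i == center_idx:
            for j, base in enumerate(center):
                row[col_of_center[j]] = base
        else:
            cpos = 0
            opos = 0
            for c_adv, o_adv in member_steps[i]:
                if c_adv == 0:
                    # place the insert right before center position cpos,
                    # right-aligned within the reserved insert columns
                    if cpos < n:
                        first_col = col_of_center[cpos] - int(inserts[cpos])
                        offset = int(inserts[cpos]) - o_adv
                    else:
                        first_col = total_cols - int(inserts[n])
                        offset = int(inserts[n]) - o_adv
                    for t in range(o_adv):
                        row[first_col + offset + t] = seq[opos + t]
                    opos += o_adv
                elif o_adv == 0:
                    cpos += c_adv
                else:
                    for t in range(c_adv):
                        row[col_of_center[cpos + t]] = seq[opos + t]
                    cpos += c_adv
                    opos += o_adv
        rows.append("".join(row))
    return rows


_BASE_ORDER = "ACGT"


def call_consensus(msa: Sequence[str]) -> str:
    """Majority-vote consensus of an MSA.

    Per column the most frequent base wins; ties break in the fixed order
    A < C < G < T.  Columns where the gap is the strict majority are
    dropped.  N is emitted only when every row is N.
    """
    if not msa:
        raise ValueError("empty alignment")
    ncols = len(msa[0])
    if any(len(row) != ncols for row in msa):
        raise ValueError("ragged alignment")
    arr = np.frombuffer("".join(msa).encode("ascii"), dtype=np.uint8).reshape(
        len(msa), ncols
    )
    out = []
    nrows = len(msa)
    for j in range(ncols):
        col = arr[:, j]
        gaps = int(np.count_nonzero(col == ord("-")))
        if 2 * gaps > nrows:
            continue
        counts = [
            (int(np.count_nonzero(col == ord(b))), b) for b in _BASE_ORDER
        ]
        best_count, best_base = max(counts, key=lambda x: (x[0], -_BASE_ORDER.index(x[1])))
        if best_count == 0:
            if np.all((col == ord("N")) | (col == ord("-"))):
                out.append("N")
            continue
        out.append(best_base)
    return "".join(out)


def build_consensus(
    family: RepeatFamily,
    member_sequences: dict[str, str],
    length_fraction: float = 0.95,
    max_sample: int = 100,
    rng_seed: int = 0,
    max_expansion: float = 1.05,
) -> ConsensusRecord:
    """Sample members, align, and call the family consensus.

    ``member_sequences`` maps instance id -> already-oriented sequence.
    The consensus is guarded against gap-driven expansion: its length never
    exceeds ``max_expansion`` times the longest sampled member.
    """
    sample = select_members(family, length_fraction, max_sample, rng_seed)
    seqs = [member_sequences[m.id] for m in sample]
    msa = align_members(seqs)
    consensus = call_consensus(msa)
    limit = int(max_expansion * max(len(s) for s in seqs))
    if len(consensus) > limit:
        consensus = consensus[:limit]
    return ConsensusRecord(
        family_id=family.id,
        sequence=consensus,
        sampled_member_ids=[m.id for m in sample],
    )
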