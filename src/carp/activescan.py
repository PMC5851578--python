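"""Potentially-active autonomous element scan.

A LINE-type element is called potentially active when it carries an intact
long open reading frame (the ORF2 criterion: ATG to stop, no internal
stops, at least ``min_orf_nt`` nucleotides) whose protein contains a
reverse-transcriptase domain, detected by local protein alignment against a
user-supplied RT reference set with a minimum envelope length in amino
acids.  The state of ORF1 is deliberately ignored: an intact ORF2 suffices
for autonomous retrotransposition or SINE mobilisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .annotate import KA_K, KA_LAMBDA, _protein_seq, translate
from .seqio import SequenceRecord, reverse_complement

_STOPS = ("TAA", "TAG", "TGA")
_PROTEIN_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG-to-stop open reading frame.

    ``start``/``end`` are on the input's forward strand (0-based half-open,
    stop codon included); ``protein`` excludes the stop.
    """

    source_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RtEnvelope:
    """Span of the best RT-reference alignment on an ORF protein."""

    ref_id: str
    protein_start: int
    protein_end: int
    score: int
    evalue: float

    @property
    def aa_length(self) -> int:
        return self.protein_end - self.protein_start


def find_orfs(
    sequence: str,
    min_orf_nt: int = 1500,
    source_id: str = "",
) -> list[OrfCandidate]:
    """All maximal ATG->stop ORFs of at least ``min_orf_nt`` nt, all three
    frames, both strands, standard genetic code.

    For each stop codon the ORF starts at the first ATG after the previous
    in-frame stop, so reported ORFs are maximal and internally stop-free.
    """
    seq = sequence.upper()
    n = len(seq)
    orfs: list[OrfCandidate] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            first_atg = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon in _STOPS:
                    if first_atg is not None:
                        length = i + 3 - first_atg
                        if length >= min_orf_nt:
                            if strand == "+":
                                start, end = first_atg, i + 3
                            else:
                                start, end = n - (i + 3), n - first_atg
                            orfs.append(
                                OrfCandidate(
                                    source_id=source_id,
                                    start=start,
                                    end=end,
                                    strand=strand,
                                    frame=frame,
                                    protein=translate(s[first_atg:i]),
                                )
                            )
                    first_atg = None
                elif codon == "ATG" and first_atg is None:
                    first_atg = i
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def detect_rt_domain(
    protein: str,
    rt_references: Sequence[SequenceRecord],
    min_rt_aa: int = 200,
    evalue_max: float = 1e-5,
    gap_penalty: tuple[int, int] = (-11, -1),
) -> RtEnvelope | None:
    """Best local BLOSUM62 alignment of the protein against the RT
    references; returns the envelope iff it spans at least ``min_rt_aa``
    amino acids at E <= ``evalue_max``."""
    if not rt_references:
        raise ValueError("empty RT reference set")
    db_total = sum(len(r.sequence) for r in rt_references)
    query = _protein_seq(protein)
    best: RtEnvelope | None = None
    for ref in rt_references:
        alns = balign.align_optimal(
            query,
            _protein_seq(ref.sequence),
            _PROTEIN_MATRIX,
            gap_penalty=gap_penalty,
            local=True,
            max_number=1,
        )
        if not alns:
            continue
        aln = alns[0]
        score = int(aln.score)
        evalue = KA_K * len(protein) * db_total * math.exp(-KA_LAMBDA * score)
        trace = aln.trace[:, 0]
        span = trace[trace >= 0]
        if len(span) == 0:
            continue
        env = RtEnvelope(
            ref.id, int(span[0]), int(span[-1]) + 1, score, evalue
        )
        if best is None or env.score > best.score:
            best = env
    if best is None:
        return None
    if best.aa_length < min_rt_aa or best.evalue > evalue_max:
        return None
    return best


@dataclass
class ActivityCall:
    element_id: str
    active: bool
    orf: OrfCandidate | None = None
    envelope: RtEnvelope | None = None


def flag_potentially_active(
    elements: Sequence[SequenceRecord],
    rt_references: Sequence[SequenceRecord],
    min_orf_nt: int = 1500,
    min_rt_aa: int = 200,
    evalue_max: float = 1e-5,
) -> list[ActivityCall]:
    """Per-element activity call: active iff at least one qualifying ORF
    carries an RT envelope."""
    calls = []
    for element in elements:
        call = ActivityCall(element.id, False)
        for orf in find_orfs(element.sequence, min_orf_nt, element.id):
            env = detect_rt_domain(
                orf.protein, rt_references, min_rt_aa, evalue_max
            )
            if env is not None:
                if call.envelope is None or env.score > call.envelope.score:
                    call = ActivityCall(element.id, True, orf, env)
        calls.append(call)
    return calls
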