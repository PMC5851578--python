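"""Consensus cleaning, classification and genome annotation.

Consensus sequences are screened for simple sequence repeats and for host
protein-coding genes (by six-frame translated alignment against a host
protein set, retaining anything that also hits the retroviral/RT protein
set).  Surviving consensuses are classified against a nucleotide TE
reference library into well annotated / partially annotated / unannotated;
partial and unannotated together form the *unclassified* set.  Finally the
combined library (kept consensuses plus the TE references) is aligned back
to the genome at a relaxed identity floor and overlapping hits are resolved
best-hit-first, which recovers copies more diverged than the self-alignment
identity gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from intervaltree import IntervalTree

from .align import AlignerParams, GenomeHit, GenomeIndex, search_genome
from .consensus import ConsensusRecord
from .seqio import GenomeInterval, SequenceRecord, reverse_complement

# Ungapped Karlin-Altschul constants for BLOSUM62
KA_LAMBDA = 0.318
KA_K = 0.13

_PROTEIN_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()

_CODON_TABLE = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def translate(seq: str) -> str:
    """Standard-code translation; codons with N translate to X."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


@dataclass(frozen=True)
class AnnotationHit:
    """One alignment of a query (consensus) against a reference."""

    query_id: str
    query_start: int  # nucleotide span on the query
    query_end: int
    ref_id: str
    ref_class: str
    identity: float
    score: int
    evalue: float | None = None  # protein searches only


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for consensus cleaning and classification."""

    protein_evalue_max: float = 1e-5
    ssr_cov_max: float = 0.8
    well_annotated_cov_min: float = 0.8
    partial_hit_min_bp: int = 50
    classify_min_identity: float = 0.80
    annotate_min_identity: float = 0.80
    annotate_min_bp: int = 30

    def __post_init__(self) -> None:
        for name in ("ssr_cov_max", "well_annotated_cov_min",
                     "classify_min_identity", "annotate_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def parse_te_class(header: str) -> tuple[str, str]:
    """Split a Repbase/RepeatMasker-style ``name#class/subclass`` header
    into (name, class); headers without '#' classify as 'Other'."""
    if "#" in header:
        name, _, cls = header.partition("#")
        return name, cls.split("/")[0] or "Other"
    return header, "Other"


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------


def detect_ssr(
    sequence: str,
    max_unit: int = 6,
    min_copies: int = 4,
    min_run: int = 12,
) -> float:
    """Fraction of the sequence inside maximal tandem runs.

    A run qualifies when its repeat unit is at most ``max_unit`` bp, it
    spans at least ``min_run`` bp and contains at least ``min_copies`` unit
    copies.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    covered = np.zeros(n, dtype=bool)
    for unit in range(1, max_unit + 1):
        if n < unit * min_copies:
            continue
        eq = arr[: n - unit] == arr[unit:]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(changes[::2], changes[1::2]):
            run_len = (e - s) + unit  # tandem span including first unit
            if run_len >= min_run and run_len // unit >= min_copies:
                covered[s : s + run_len] = True
    return float(covered.sum()) / n


# ---------------------------------------------------------------------------
# translated protein search
# ---------------------------------------------------------------------------


def _protein_seq(p: str) -> bseq.ProteinSequence:
    return bseq.ProteinSequence(p.replace("*", "X"))


def search_protein(
    consensus: SequenceRecord,
    protein_db: Sequence[SequenceRecord],
    evalue_max: float = 1e-5,
    gap_penalty: tuple[int, int] = (-11, -1),
) -> list[AnnotationHit]:
    """Six-frame translated local alignment (BLOSUM62) of a nucleotide
    consensus against a protein reference set.

    E-values use the ungapped Karlin-Altschul approximation with
    search space = frame length x total database length.  Hits with
    E <= ``evalue_max`` are returned with nucleotide query coordinates.
    """
    if not protein_db:
        return []
    db_total = sum(len(p.sequence) for p in protein_db)
    nt = consensus.sequence
    frames: list[tuple[str, int, str]] = []  # (protein, frame_offset, strand)
    for off in range(3):
        frames.append((translate(nt[off:]), off, "+"))
    rc = reverse_complement(nt)
    for off in range(3):
        frames.append((translate(rc[off:]), off, "-"))

    hits: list[AnnotationHit] = []
    for prot, off, strand in frames:
        if len(prot) < 10:
            continue
        query = _protein_seq(prot)
        for ref in protein_db:
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
            evalue = KA_K * len(prot) * db_total * math.exp(-KA_LAMBDA * score)
            if evalue > evalue_max:
                continue
            trace = aln.trace[:, 0]
            aa_s = int(trace[trace >= 0][0])
            aa_e = int(trace[trace >= 0][-1]) + 1
            if strand == "+":
                q_s = off + 3 * aa_s
                q_e = off + 3 * aa_e
            else:
                q_e = len(nt) - off - 3 * aa_s
                q_s = len(nt) - off - 3 * aa_e
            hits.append(
                AnnotationHit(
                    query_id=consensus.id,
                    query_start=max(0, q_s),
                    query_end=min(len(nt), q_e),
                    ref_id=ref.id,
                    ref_class="protein",
                    identity=float(
                        balign.get_sequence_identity(aln, mode="all")
                    ),
                    score=score,
                    evalue=evalue,
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.ref_id))
    return hits


# ---------------------------------------------------------------------------
# consensus filtering
# ---------------------------------------------------------------------------


@dataclass
class RemovalRecord:
    consensus_id: str
    reason: str  # 'ssr' or 'host_protein'
    detail: str = ""


def filter_consensus_set(
    consensuses: Sequence[ConsensusRecord],
    host_protein_db: Sequence[SequenceRecord],
    rt_protein_db: Sequence[SequenceRecord],
    params: FilterParams | None = None,
) -> tuple[list[ConsensusRecord], list[RemovalRecord]]:
    """Remove SSR consensuses and host-gene consensuses.

    A consensus is removed iff its SSR-covered fraction reaches
    ``ssr_cov_max``, or it hits the host protein set at the E-value gate
    without any hit to the retroviral/RT protein set (a host hit that also
    annotates as RT is retained).
    """
    params = params or FilterParams()
    kept: list[ConsensusRecord] = []
    removed: list[RemovalRecord] = []
    for cons in consensuses:
        rec = SequenceRecord(cons.family_id, cons.sequence)
        ssr_frac = detect_ssr(cons.sequence)
        if ssr_frac >= params.ssr_cov_max:
            removed.append(
                RemovalRecord(cons.family_id, "ssr", f"ssr_fraction={ssr_frac:.3f}")
            )
            continue
        host_hits = search_protein(
            rec, host_protein_db, params.protein_evalue_max
        )
        if host_hits:
            rt_hits = search_protein(
                rec, rt_protein_db, params.protein_evalue_max
            )
            if not rt_hits:
                removed.append(
                    RemovalRecord(
                        cons.family_id,
                        "host_protein",
                        f"best_hit={host_hits[0].ref_id}"
                        f" evalue={host_hits[0].evalue:.2e}",
                    )
                )
                continue
        kept.append(cons)
    return kept, removed


# ---------------------------------------------------------------------------
# classification against the TE reference library
# ---------------------------------------------------------------------------


def classify_consensus(
    consensuses: Sequence[ConsensusRecord],
    te_library: Sequence[SequenceRecord],
    params: FilterParams | None = None,
    class_map: Mapping[str, str] | None = None,
    aligner_params: AlignerParams | None = None,
) -> None:
    """Classify each consensus in place against the TE reference library.

    well_annotated: hits to a single reference jointly cover at least
    ``well_annotated_cov_min`` of the consensus; partially_annotated: some
    hit of at least ``partial_hit_min_bp``; otherwise unannotated.  The
    partial and unannotated classes together form the unclassified set.
    """
    params = params or FilterParams()
    for cons in consensuses:
        cons.annotation_class = "unannotated"
        cons.annotation_hits = []
    if not te_library or not consensuses:
        return
    lib_index = GenomeIndex(
        te_library, (aligner_params or AlignerParams()).seed_k
    )
    queries = [
        SequenceRecord(c.family_id, c.sequence) for c in consensuses
    ]
    hits = search_genome(
        queries,
        lib_index,
        min_identity=params.classify_min_identity,
        min_length=params.annotate_min_bp,
        params=aligner_params,
    )
    by_query: dict[str, list[GenomeHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for cons in consensuses:
        qhits = by_query.get(cons.family_id, [])
        ann_hits = []
        cover_by_ref: dict[str, np.ndarray] = {}
        for h in qhits:
            name, cls = _ref_class(h.interval.seq_id, class_map)
            ann_hits.append(
                AnnotationHit(
                    query_id=cons.family_id,
                    query_start=h.query_start,
                    query_end=h.query_end,
                    ref_id=h.interval.seq_id,
                    ref_class=cls,
                    identity=h.identity,
                    score=h.score,
                )
            )
            cov = cover_by_ref.setdefault(
                h.interval.seq_id, np.zeros(len(cons.sequence), dtype=bool)
            )
            cov[h.query_start : h.query_end] = True
        cons.annotation_hits = sorted(
            ann_hits, key=lambda h: (-h.score, h.ref_id)
        )
        best_cov = max(
            (cov.mean() for cov in cover_by_ref.values()), default=0.0
        )
        if best_cov >= params.well_annotated_cov_min:
            cons.annotation_class = "well_annotated"
        elif any(
            h.query_end - h.query_start >= params.partial_hit_min_bp
            for h in ann_hits
        ):
            cons.annotation_class = "partially_annotated"
        else:
            cons.annotation_class = "unannotated"


def _ref_class(
    ref_id: str, class_map: Mapping[str, str] | None
) -> tuple[str, str]:
    if class_map and ref_id in class_map:
        return ref_id, class_map[ref_id].split("/")[0]
    return parse_te_class(ref_id)


def consensus_te_class(cons: ConsensusRecord) -> str:
    """TE class a consensus inherits from its best-covering reference;
    'Unclassified' for the partial/unannotated (unclassified) set."""
    if cons.annotation_class != "well_annotated" or not cons.annotation_hits:
        return "Unclassified"
    cover: dict[str, int] = {}
    cls_of: dict[str, str] = {}
    for h in cons.annotation_hits:
        cover[h.ref_id] = cover.get(h.ref_id, 0) + (h.query_end - h.query_start)
        cls_of[h.ref_id] = h.ref_class
    best = max(cover, key=lambda r: (cover[r], r))
    return cls_of[best]


def is_unclassified(cons: ConsensusRecord) -> bool:
    return cons.annotation_class in ("partially_annotated", "unannotated")


# ---------------------------------------------------------------------------
# genome annotation with the combined library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResolvedHit:
    """A genome annotation hit surviving best-hit overlap resolution."""

    library_id: str
    te_class: str
    interval: GenomeInterval
    query_start: int
    query_end: int
    identity: float
    score: int


def resolve_overlaps(
    hits: Sequence[GenomeHit],
    class_of: Mapping[str, str],
    min_keep_bp: int = 30,
) -> list[ResolvedHit]:
    """Best-hit-first overlap resolution.

    Hits are taken in decreasing score order; a lower-scoring hit is
    trimmed to its longest genome stretch not already annotated and is
    discarded if that stretch falls below ``min_keep_bp``.  Query
    coordinates of trimmed hits are rescaled proportionally.
    """
    trees: dict[str, IntervalTree] = {}
    resolved: list[ResolvedHit] = []
    for h in sorted(
        hits, key=lambda x: (-x.score, x.interval, x.query_id)
    ):
        iv = h.interval
        tree = trees.setdefault(iv.seq_id, IntervalTree())
        taken = sorted(
            (max(o.begin, iv.start), min(o.end, iv.end))
            for o in tree[iv.start : iv.end]
        )
        # longest uncovered stretch within the hit
        best_s, best_e = iv.start, iv.start
        cur = iv.start
        for s, e in taken:
            if s - cur > best_e - best_s:
                best_s, best_e = cur, s
            cur = max(cur, e)
        if iv.end - cur > best_e - best_s:
            best_s, best_e = cur, iv.end
        if best_e - best_s < min_keep_bp:
            continue
        frac_s = (best_s - iv.start) / iv.length
        frac_e = (best_e - iv.start) / iv.length
        q_len = h.query_end - h.query_start
        q_s = h.query_start + int(round(frac_s * q_len))
        q_e = h.query_start + int(round(frac_e * q_len))
        tree[best_s:best_e] = True
        resolved.append(
            ResolvedHit(
                library_id=h.query_id,
                te_class=class_of.get(h.query_id, "Other"),
                interval=GenomeInterval(iv.seq_id, best_s, best_e, iv.strand),
                query_start=q_s,
                query_end=max(q_e, q_s + 1),
                identity=h.identity,
                score=h.score,
            )
        )
    resolved.sort(key=lambda r: (r.interval, r.library_id))
    return resolved


def annotate_genome(
    genome: Sequence[SequenceRecord] | GenomeIndex,
    combined_library: Sequence[SequenceRecord],
    class_of: Mapping[str, str],
    params: FilterParams | None = None,
    aligner_params: AlignerParams | None = None,
) -> list[ResolvedHit]:
    """Annotate every repeat interval in the genome with the combined
    library (kept consensuses plus TE references), best hit first."""
    params = params or FilterParams()
    if not combined_library:
        raise ValueError("empty annotation library")
    if isinstance(genome, GenomeIndex):
        index = genome
    else:
        index = GenomeIndex(
            genome, (aligner_params or AlignerParams()).seed_k
        )
    hits = search_genome(
        combined_library,
        index,
        min_identity=params.annotate_min_identity,
        min_length=params.annotate_min_bp,
        params=aligner_params,
    )
    return resolve_overlaps(hits, class_of, params.annotate_min_bp)


SUMMARY_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Other", "Unclassified")


def summarize_repeat_content(
    resolved: Sequence[ResolvedHit], genome_length: int
) -> dict[str, float]:
    """Per-class genome coverage percentages.

    Resolved hits are non-overlapping, so no genome position contributes
    to two classes.  'IR' sums the interspersed classes, 'SD' mirrors the
    unclassified (segmental-duplication candidate) coverage, and 'Total'
    is their sum.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    bp: dict[str, int] = {c: 0 for c in SUMMARY_CLASSES}
    for hit in resolved:
        cls = hit.te_class if hit.te_class in bp else "Other"
        bp[cls] += hit.interval.length
    pct = {c: 100.0 * bp[c] / genome_length for c in SUMMARY_CLASSES}
    ir = sum(pct[c] for c in SUMMARY_CLASSES if c != "Unclassified")
    pct["IR"] = ir
    pct["SD"] = pct["Unclassified"]
    pct["Total"] = ir + pct["Unclassified"]
    return pct
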