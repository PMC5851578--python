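"""All-vs-all local self-alignment of a genome assembly.

The aligner follows the classic seed-and-extend design used by PALS-family
whole-genome repeat aligners: exact k-mer seeds are collected for both
orientations (via canonical k-mers), grouped by diagonal, chained greedily,
and each chain is extended by banded affine-gap dynamic programming.  Only
alignments passing the identity (``min_identity``, the -dpid gate) and
length (``min_length``, the -dplen gate) thresholds are reported.

Identity is defined as matches divided by alignment columns, counting gap
columns in the denominator, which makes the identity gate conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from intervaltree import IntervalTree

from .seqio import GenomeInterval, SequenceRecord, reverse_complement

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i

_ALPHABET = bseq.LetterAlphabet("ACGTN")
_NT_MATRIX_CACHE: dict[tuple[int, int], balign.SubstitutionMatrix] = {}


def _nt_matrix(match: int, mismatch: int) -> balign.SubstitutionMatrix:
    key = (match, mismatch)
    if key not in _NT_MATRIX_CACHE:
        scores = np.full((5, 5), mismatch, dtype=np.int32)
        np.fill_diagonal(scores, match)
        scores[4, :] = mismatch  # N never rewards a match
        scores[:, 4] = mismatch
        _NT_MATRIX_CACHE[key] = balign.SubstitutionMatrix(
            _ALPHABET, _ALPHABET, scores
        )
    return _NT_MATRIX_CACHE[key]


@dataclass(frozen=True)
class AlignerParams:
    """Thresholds and scoring for the self-alignment stage.

    ``min_identity``/``min_length`` mirror the -dpid/-dplen gates of the
    alignment stage (defaults 0.94 and 250 bp).  The seeding and chaining
    parameters are implementation knobs: seeds within ``band_width``
    diagonals and at most ``chain_gap`` apart are chained before banded DP.
    K-mer occurrence lists larger than ``occ_all_pairs_max`` are linked only
    to their ``occ_neighbor_links`` nearest neighbours in genome order,
    which keeps very high copy number families tractable while preserving
    the connectivity single-linkage clustering needs.
    """

    min_identity: float = 0.94
    min_length: int = 250
    seed_k: int = 12
    band_width: int = 32
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    chain_gap: int = 200
    extend_margin: int = 200
    min_chain_seeds: int = 3
    occ_all_pairs_max: int = 30
    occ_neighbor_links: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < self.seed_k:
            raise ValueError("min_length must be >= seed_k")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")


@dataclass(frozen=True)
class LocalAlignment:
    """One pairwise local alignment between two genome intervals.

    ``image_a``/``image_b`` are stored in canonical order (lexicographic by
    seq_id, then start).  ``orientation`` is ``same`` or ``opposite``.
    """

    image_a: GenomeInterval
    image_b: GenomeInterval
    identity: float
    score: int
    orientation: str

    @property
    def min_image_length(self) -> int:
        return min(self.image_a.length, self.image_b.length)


class GenomeIndex:
    """Concatenated, 2-bit-encoded view of an assembly with a sorted
    canonical k-mer index.

    Records are joined with runs of N so that no k-mer spans a boundary;
    k-mers containing N are excluded from seeding.
    """

    SPACER = 20

    def __init__(self, records: Sequence[SequenceRecord], seed_k: int = 12):
        if seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        self.records = list(records)
        self.seed_k = seed_k
        self.ids = [r.id for r in self.records]
        spacer = "N" * self.SPACER
        self.offsets = np.zeros(len(self.records) + 1, dtype=np.int64)
        parts = []
        pos = 0
        for i, rec in enumerate(self.records):
            self.offsets[i] = pos
            parts.append(rec.sequence)
            pos += len(rec.sequence)
            if i < len(self.records) - 1:
                parts.append(spacer)
                pos += self.SPACER
        self.offsets[-1] = pos
        self.concat = "".join(parts)
        self.codes = _BASE_CODES[
            np.frombuffer(self.concat.encode("ascii"), dtype=np.uint8)
        ]
        self._starts = self.offsets[:-1]
        self._ends = self._starts + np.array(
            [len(r.sequence) for r in self.records], dtype=np.int64
        )
        self._build_kmer_index()

    def _build_kmer_index(self) -> None:
        k = self.seed_k
        codes = self.codes.astype(np.int64)
        n = len(codes)
        if n < k:
            self.kmer_pos = np.empty(0, dtype=np.int64)
            self.kmer_canon = np.empty(0, dtype=np.int64)
            self.kmer_fwd = np.empty(0, dtype=bool)
            return
        m = n - k + 1
        fwd = np.zeros(m, dtype=np.int64)
        rev = np.zeros(m, dtype=np.int64)
        for j in range(k):
            fwd = (fwd << 2) | codes[j : m + j]
        for j in range(k - 1, -1, -1):
            rev = (rev << 2) | (3 - codes[j : m + j])
        has_n = np.convolve(
            (self.codes == 4).astype(np.int32), np.ones(k, dtype=np.int32), "valid"
        )
        valid = has_n == 0
        pos = np.flatnonzero(valid).astype(np.int64)
        fwd = fwd[valid]
        rev = rev[valid]
        canon = np.minimum(fwd, rev)
        is_fwd = fwd <= rev
        order = np.lexsort((pos, canon))
        self.kmer_pos = pos[order]
        self.kmer_canon = canon[order]
        self.kmer_fwd = is_fwd[order]

    # -- coordinate mapping -------------------------------------------------

    def record_index_of(self, gpos: np.ndarray | int):
        return np.searchsorted(self.offsets[1:], gpos, side="right")

    def to_local(self, gpos: int) -> tuple[str, int]:
        i = int(self.record_index_of(gpos))
        return self.ids[i], int(gpos - self._starts[i])

    def record_bounds(self, gpos: int) -> tuple[int, int]:
        """Global [start, end) of the record containing ``gpos``."""
        i = int(self.record_index_of(gpos))
        return int(self._starts[i]), int(self._ends[i])

    def kmer_values(self, sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, canonical values, forward-is-canonical) for a query."""
        k = self.seed_k
        codes = _BASE_CODES[
            np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
        ].astype(np.int64)
        n = len(codes)
        if n < k:
            e = np.empty(0, dtype=np.int64)
            return e, e, np.empty(0, dtype=bool)
        m = n - k + 1
        fwd = np.zeros(m, dtype=np.int64)
        rev = np.zeros(m, dtype=np.int64)
        for j in range(k):
            fwd = (fwd << 2) | codes[j : m + j]
        for j in range(k - 1, -1, -1):
            rev = (rev << 2) | (3 - codes[j : m + j])
        has_n = np.convolve(
            (codes == 4).astype(np.int32), np.ones(k, dtype=np.int32), "valid"
        )
        valid = has_n == 0
        pos = np.flatnonzero(valid).astype(np.int64)
        return pos, np.minimum(fwd, rev)[valid], (fwd <= rev)[valid]


@dataclass
class SeedHits:
    """Seed matches grouped by (orientation, diagonal).

    ``pos_a``/``pos_b`` are global concatenated coordinates of the k-mer
    starts with ``pos_a < pos_b``; ``opposite`` marks reverse-orientation
    hits; ``diag`` is ``pos_b - pos_a`` for same orientation and
    ``pos_a + pos_b`` (the anti-diagonal) for opposite orientation.
    """

    pos_a: np.ndarray
    pos_b: np.ndarray
    opposite: np.ndarray
    diag: np.ndarray

    def __len__(self) -> int:
        return len(self.pos_a)


def find_seed_matches(index: GenomeIndex, params: AlignerParams) -> SeedHits:
    """All exact k-mer matches between distinct genome positions, both
    orientations, excluding the self-diagonal and N-containing k-mers.

    Occurrence lists longer than ``occ_all_pairs_max`` are linked only to
    nearby occurrences (see :class:`AlignerParams`).
    """
    canon = index.kmer_canon
    pos = index.kmer_pos
    fwd = index.kmer_fwd
    if len(canon) == 0:
        e = np.empty(0, dtype=np.int64)
        return SeedHits(e, e.copy(), np.empty(0, dtype=bool), e.copy())

    # run-length encode the sorted canonical values
    boundary = np.empty(len(canon), dtype=bool)
    boundary[0] = True
    np.not_equal(canon[1:], canon[:-1], out=boundary[1:])
    run_id = np.cumsum(boundary) - 1
    run_sizes = np.bincount(run_id)
    size_here = run_sizes[run_id]
    offset_in_run = np.arange(len(canon)) - np.flatnonzero(boundary)[run_id]

    cap_small = params.occ_all_pairs_max
    cap_links = params.occ_neighbor_links
    max_j = int(min(size_here.max() - 1, cap_small)) if len(size_here) else 0

    pa_parts, pb_parts, opp_parts = [], [], []
    for j in range(1, max_j + 1):
        if j > cap_links:
            allowed = size_here[: len(canon) - j] <= cap_small
        else:
            allowed = np.ones(len(canon) - j, dtype=bool)
        same_run = run_id[: len(canon) - j] == run_id[j:]
        take = np.flatnonzero(same_run & allowed)
        if len(take) == 0:
            continue
        a = pos[take]
        b = pos[take + j]
        opp = fwd[take] != fwd[take + j]
        keep = a != b
        pa_parts.append(a[keep])
        pb_parts.append(b[keep])
        opp_parts.append(opp[keep])

    if not pa_parts:
        e = np.empty(0, dtype=np.int64)
        return SeedHits(e, e.copy(), np.empty(0, dtype=bool), e.copy())

    pa = np.concatenate(pa_parts)
    pb = np.concatenate(pb_parts)
    opp = np.concatenate(opp_parts)
    swap = pa > pb
    pa2 = np.where(swap, pb, pa)
    pb2 = np.where(swap, pa, pb)
    diag = np.where(opp, pa2 + pb2, pb2 - pa2)
    return SeedHits(pa2, pb2, opp, diag)


def _chain_groups(hits: SeedHits, params: AlignerParams):
    """Greedy chaining: hits sorted by (orientation, diagonal, position)
    are split into chains at diagonal jumps > ``band_width`` or position
    jumps > ``chain_gap``.  Indel-driven diagonal drift within one locus
    pair stays chained; distinct locus pairs that happen to share nearby
    diagonals split on the position jump (any resulting duplicate
    alignments collapse during dedup).  Yields index arrays into ``hits``.
    """
    if len(hits) == 0:
        return
    order = np.lexsort((hits.pos_a, hits.diag, hits.opposite.astype(np.int8)))
    opp = hits.opposite[order]
    diag = hits.diag[order]
    pos_a = hits.pos_a[order]

    new_chain = np.empty(len(order), dtype=bool)
    new_chain[0] = True
    new_chain[1:] = (
        (opp[1:] != opp[:-1])
        | (np.abs(diag[1:] - diag[:-1]) > params.band_width)
        | (np.abs(pos_a[1:] - pos_a[:-1]) > params.chain_gap)
    )
    starts = np.flatnonzero(new_chain)
    ends = np.append(starts[1:], len(order))
    for s, e in zip(starts, ends):
        yield order[s:e]


def _banded_align(
    seq_a: str,
    seq_b: str,
    band: tuple[int, int],
    params: AlignerParams,
) -> tuple[int, int, int, int, float, int] | None:
    """Best local banded alignment of two region strings.

    Returns (a_start, a_end, b_start, b_end, identity, score) in region
    coordinates (half-open), or None if no positive-scoring alignment.
    """
    sa = bseq.GeneralSequence(_ALPHABET, seq_a)
    sb = bseq.GeneralSequence(_ALPHABET, seq_b)
    lo = max(band[0], -(len(seq_a) - 1))
    hi = min(band[1], len(seq_b) - 1)
    if lo > hi:
        lo = hi = 0
    alns = balign.align_banded(
        sa,
        sb,
        _nt_matrix(params.match, params.mismatch),
        band=(lo, hi),
        gap_penalty=(params.gap_open, params.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return None
    aln = alns[0]
    trace = aln.trace
    a_cols = trace[:, 0]
    b_cols = trace[:, 1]
    a_idx = a_cols[a_cols >= 0]
    b_idx = b_cols[b_cols >= 0]
    if len(a_idx) == 0 or len(b_idx) == 0:
        return None
    # identity = matches / alignment columns (gap columns in denominator)
    both = (a_cols >= 0) & (b_cols >= 0)
    code_a = aln.sequences[0].code[a_cols[both]]
    code_b = aln.sequences[1].code[b_cols[both]]
    n_code = _ALPHABET.encode("N")
    matches = int(
        np.count_nonzero(
            (code_a == code_b) & (code_a != n_code)
        )
    )
    identity = matches / len(trace)
    return (
        int(a_idx[0]),
        int(a_idx[-1]) + 1,
        int(b_idx[0]),
        int(b_idx[-1]) + 1,
        float(identity),
        int(aln.score),
    )


def _dedupe(alignments: list[LocalAlignment]) -> list[LocalAlignment]:
    """Collapse overlapping/duplicate alignments for the same locus pair to
    the highest-scoring one."""
    kept: list[LocalAlignment] = []
    trees: dict[tuple, IntervalTree] = {}
    for aln in sorted(alignments, key=lambda x: -x.score):
        key = (aln.image_a.seq_id, aln.image_b.seq_id, aln.orientation)
        tree = trees.setdefault(key, IntervalTree())
        duplicate = False
        for hit in tree[aln.image_a.start : aln.image_a.end]:
            other = kept[hit.data]
            if aln.image_b.overlaps(other.image_b):
                duplicate = True
                break
        if duplicate:
            continue
        tree[aln.image_a.start : aln.image_a.end] = len(kept)
        kept.append(aln)
    kept.sort(key=lambda x: (x.image_a, x.image_b))
    return kept


def extend_and_filter(
    index: GenomeIndex, hits: SeedHits, params: AlignerParams
) -> list[LocalAlignment]:
    """Extend chained seed groups by banded DP and apply the -dpid/-dplen
    gates.  Self-overlapping (tandem) image pairs are discarded; duplicate
    alignments of the same locus pair collapse to the best-scoring one."""
    k = params.seed_k
    results: list[LocalAlignment] = []
    for idx in _chain_groups(hits, params):
        if len(idx) < params.min_chain_seeds:
            continue  # spurious isolated seed matches
        pa = hits.pos_a[idx]
        pb = hits.pos_b[idx]
        opposite = bool(hits.opposite[idx[0]])
        d = hits.diag[idx]

        a_lo, a_hi = int(pa.min()), int(pa.max()) + k
        b_lo, b_hi = int(pb.min()), int(pb.max()) + k
        ra_lo, ra_hi = index.record_bounds(a_lo)
        rb_lo, rb_hi = index.record_bounds(b_lo)
        m = params.extend_margin
        a_lo = max(a_lo - m, ra_lo)
        a_hi = min(a_hi + m, ra_hi)
        b_lo = max(b_lo - m, rb_lo)
        b_hi = min(b_hi + m, rb_hi)
        if a_hi - a_lo < k or b_hi - b_lo < k:
            continue
        seq_a = index.concat[a_lo:a_hi]
        seq_b = index.concat[b_lo:b_hi]
        if opposite:
            seq_b = reverse_complement(seq_b)
            # antidiagonal s = pos_a + pos_b maps to region diagonal C - s
            c = b_hi - k + a_lo
            d_lo, d_hi = int(c - d.max()), int(c - d.min())
        else:
            off = b_lo - a_lo
            d_lo, d_hi = int(d.min() - off), int(d.max() - off)
        band = (d_lo - params.band_width, d_hi + params.band_width)
        res = _banded_align(seq_a, seq_b, band, params)
        if res is None:
            continue
        a_s, a_e, b_s, b_e, identity, score = res
        if identity < params.min_identity:
            continue
        ga = (a_lo + a_s, a_lo + a_e)
        if opposite:
            gb = (b_hi - b_e, b_hi - b_s)
        else:
            gb = (b_lo + b_s, b_lo + b_e)
        if (ga[1] - ga[0]) < params.min_length or (gb[1] - gb[0]) < params.min_length:
            continue
        if ga[1] > gb[0] and gb[1] > ga[0]:
            continue  # self-overlapping pair on the same sequence
        id_a, loc_a = index.to_local(ga[0])
        id_b, loc_b = index.to_local(gb[0])
        iv_a = GenomeInterval(id_a, loc_a, loc_a + (ga[1] - ga[0]))
        iv_b = GenomeInterval(id_b, loc_b, loc_b + (gb[1] - gb[0]))
        if (iv_b.seq_id, iv_b.start) < (iv_a.seq_id, iv_a.start):
            iv_a, iv_b = iv_b, iv_a
        results.append(
            LocalAlignment(
                iv_a,
                iv_b,
                identity,
                score,
                "opposite" if opposite else "same",
            )
        )
    return _dedupe(results)


def align_all(
    genome: Sequence[SequenceRecord], params: AlignerParams | None = None
) -> list[LocalAlignment]:
    """All-vs-all local self-alignment of an assembly.

    Deterministic given the input and parameters.  Returns alignments in
    canonical order, each passing both the identity and length gates.
    """
    params = params or AlignerParams()
    index = GenomeIndex(genome, params.seed_k)
    hits = find_seed_matches(index, params)
    return extend_and_filter(index, hits, params)


# ---------------------------------------------------------------------------
# library-vs-genome search (used by the genome annotation stage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeHit:
    """A local alignment of a library sequence against the genome."""

    query_id: str
    query_start: int
    query_end: int
    interval: GenomeInterval  # genome location; strand is hit orientation
    identity: float
    score: int


def search_genome(
    queries: Iterable[SequenceRecord],
    index: GenomeIndex,
    min_identity: float = 0.80,
    min_length: int = 30,
    params: AlignerParams | None = None,
) -> list[GenomeHit]:
    """Seed-and-extend search of query sequences against an indexed genome.

    The same chaining/banded-extension engine as the self-aligner, at a
    relaxed identity floor so that copies more diverged than the self
    alignment gate are still annotated.
    """
    params = params or AlignerParams()
    params = replace(params, min_identity=min_identity, min_length=min_length)
    k = index.seed_k
    hits_out: list[GenomeHit] = []
    for query in queries:
        qpos, qcanon, qfwd = index.kmer_values(query.sequence)
        if len(qpos) == 0:
            continue
        lo = np.searchsorted(index.kmer_canon, qcanon, side="left")
        hi = np.searchsorted(index.kmer_canon, qcanon, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        q_rep = np.repeat(np.arange(len(qpos)), counts)
        g_idx = np.concatenate(
            [np.arange(l, h) for l, h in zip(lo, hi) if h > l]
        )
        qp = qpos[q_rep]
        qf = qfwd[q_rep]
        gp = index.kmer_pos[g_idx]
        gf = index.kmer_fwd[g_idx]
        opp = qf != gf
        diag = np.where(opp, qp + gp, gp - qp)
        seed = SeedHits(qp, gp, opp, diag)
        for idx in _chain_groups(seed, params):
            if len(idx) < params.min_chain_seeds:
                continue
            qa = seed.pos_a[idx]
            gb = seed.pos_b[idx]
            opposite = bool(seed.opposite[idx[0]])
            d = seed.diag[idx]
            q_lo, q_hi = int(qa.min()), int(qa.max()) + k
            g_lo, g_hi = int(gb.min()), int(gb.max()) + k
            rg_lo, rg_hi = index.record_bounds(g_lo)
            m = params.extend_margin
            q_lo = max(q_lo - m, 0)
            q_hi = min(q_hi + m, len(query.sequence))
            g_lo = max(g_lo - m, rg_lo)
            g_hi = min(g_hi + m, rg_hi)
            seq_q = query.sequence[q_lo:q_hi]
            seq_g = index.concat[g_lo:g_hi]
            if opposite:
                seq_g = reverse_complement(seq_g)
                c = g_hi - k + q_lo
                d_lo, d_hi = int(c - d.max()), int(c - d.min())
            else:
                off = g_lo - q_lo
                d_lo, d_hi = int(d.min() - off), int(d.max() - off)
            band = (d_lo - params.band_width, d_hi + params.band_width)
            res = _banded_align(seq_q, seq_g, band, params)
            if res is None:
                continue
            q_s, q_e, g_s, g_e, identity, score = res
            if identity < min_identity:
                continue
            if (q_e - q_s) < min_length or (g_e - g_s) < min_length:
                continue
            if opposite:
                g_span = (g_hi - g_e, g_hi - g_s)
            else:
                g_span = (g_lo + g_s, g_lo + g_e)
            seq_id, local = index.to_local(g_span[0])
            hits_out.append(
                GenomeHit(
                    query.id,
                    q_lo + q_s,
                    q_lo + q_e,
                    GenomeInterval(
                        seq_id,
                        local,
                        local + (g_span[1] - g_span[0]),
                        "-" if opposite else "+",
                    ),
                    identity,
                    score,
                )
            )
    # collapse duplicate hits of the same query on the same genome locus
    deduped: list[GenomeHit] = []
    trees: dict[tuple, IntervalTree] = {}
    for h in sorted(hits_out, key=lambda x: -x.score):
        key = (h.query_id, h.interval.seq_id, h.interval.strand)
        tree = trees.setdefault(key, IntervalTree())
        dup = False
        for o in tree[h.interval.start : h.interval.end]:
            other = deduped[o.data]
            if h.query_start < other.query_end and other.query_start < h.query_end:
                dup = True
                break
        if dup:
            continue
        tree[h.interval.start : h.interval.end] = len(deduped)
        deduped.append(h)
    deduped.sort(key=lambda x: (x.interval, x.query_id))
    return deduped
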