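"""Synthetic genomes with planted repeat structure.

The generator emulates the repeat landscape the pipeline is designed for:
dispersed low-divergence TE families (optionally 5'-truncated, as LINE
insertions typically are), low-copy long segmental duplications, host gene
families with several paralogs, SSR tracts, and optionally an
autonomous-element family whose ancestor carries an intact long ORF
embedding a reverse-transcriptase protein.  Every planted copy is recorded
in a machine-readable truth table so each pipeline stage can be tested
without external data.

Background sequence is i.i.d. at a configurable GC content.  Copies are
the ancestor mutated by substitutions then short indels, placed uniformly
at random on random strands without overlap.  All output is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid for reverse translation (no stops)
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class FamilySpec:
    """One planted dispersed repeat family."""

    name: str
    ancestor_length: int
    copies: int
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    truncation_mean_frac: float = 0.0  # mean 5' truncated fraction; 0 = none
    te_class: str = "LINE"
    has_intact_orf2: bool = False
    rt_protein_length: int = 250

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")
        if self.copies < 2:
            raise ValueError("families need copies >= 2")


@dataclass(frozen=True)
class SdSpec:
    """One planted segmental duplication."""

    name: str
    length: int
    copies: int = 2
    identity: float = 0.97

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("segmental duplications need copies >= 2")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")


@dataclass(frozen=True)
class HostParalogSpec:
    """A host gene family: a protein-coding sequence planted in several
    paralogous copies, with its protein emitted to the host protein set."""

    name: str
    protein_length: int = 300
    copies: int = 3
    substitution_rate: float = 0.005


@dataclass(frozen=True)
class SsrSpec:
    name: str
    unit: str = "AC"
    copies: int = 200


@dataclass(frozen=True)
class PlantSpec:
    background_length: int = 100_000
    gc: float = 0.42
    families: tuple[FamilySpec, ...] = ()
    sds: tuple[SdSpec, ...] = ()
    host_paralogs: tuple[HostParalogSpec, ...] = ()
    ssr_tracts: tuple[SsrSpec, ...] = ()
    seq_id: str = "chr1"
    min_spacing: int = 150  # background bp guaranteed between insertions

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        names += [s.name for s in self.sds]
        names += [h.name for h in self.host_paralogs]
        names += [s.name for s in self.ssr_tracts]
        if len(set(names)) != len(names):
            raise ValueError("planted element names must be unique")


@dataclass
class TruthTable:
    """Planted truth: one row per copy, plus per-family metadata."""

    copies: pd.DataFrame
    # columns: name, kind, seq_id, start, end, strand, identity,
    #          truncation_fraction
    ancestors: dict[str, str]
    classes: dict[str, str]
    orf2_status: dict[str, bool]
    host_proteins: dict[str, str] = field(default_factory=dict)
    rt_proteins: dict[str, str] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = rng.choice(len(_AA20), size=length)
    prot = "".join(_AA20[i] for i in aa)
    return "M" + prot[1:]


def reverse_translate(protein: str) -> str:
    return "".join(_CODON_OF[aa] for aa in protein)


def mutate(
    sequence: str,
    rng: np.random.Generator,
    substitution_rate: float,
    indel_rate: float = 0.0,
    max_indel: int = 3,
) -> tuple[str, float]:
    """Substitutions then short indels; returns (mutant, fraction of
    ancestor positions left unchanged by substitution)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    n_sub = rng.binomial(n, substitution_rate)
    if n_sub:
        sites = rng.choice(n, size=n_sub, replace=False)
        for s in sites:
            choices = [b for b in b"ACGT" if b != arr[s]]
            arr[s] = choices[rng.integers(3)]
    seq = arr.tobytes().decode("ascii")
    identity = 1.0 - n_sub / n
    if indel_rate > 0:
        n_indel = rng.binomial(n, indel_rate)
        for _ in range(n_indel):
            pos = int(rng.integers(len(seq)))
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + size :]
            else:
                ins = "".join(_BASES[rng.integers(4, size=size)])
                seq = seq[:pos] + ins + seq[pos:]
    return seq, identity


def _orf_ancestor(
    rng: np.random.Generator,
    total_length: int,
    rt_protein: str,
    gc: float,
) -> str:
    """Ancestor with an intact ORF (ATG ... stop, no internal stops) that
    embeds the codons of ``rt_protein``, padded by UTR-like sequence."""
    rt_nt = reverse_translate(rt_protein)
    # flanking coding sequence inside the ORF
    orf_nt_target = max(1503, len(rt_nt) + 303)
    extra_aa = (orf_nt_target - len(rt_nt) - 6) // 3
    pre_aa = extra_aa // 2
    post_aa = extra_aa - pre_aa
    pre = reverse_translate(_random_protein(rng, pre_aa)) if pre_aa else ""
    post = reverse_translate(_random_protein(rng, post_aa)) if post_aa else ""
    orf = "ATG" + pre + rt_nt + post + "TAA"
    utr = total_length - len(orf)
    if utr < 0:
        raise ValueError("ancestor_length too small for an intact ORF")
    utr5 = _random_sequence(rng, utr // 2, gc)
    utr3 = _random_sequence(rng, utr - utr // 2, gc)
    return utr5 + orf + utr3


def generate_genome(
    spec: PlantSpec, rng_seed: int = 0
) -> tuple[list[SequenceRecord], TruthTable]:
    """Build the synthetic assembly and its truth table.

    Copies are inserted at uniformly random background positions (so planted
    intervals never overlap); strands are random.  Raises if the planted
    material cannot fit (background shorter than ~2x the planted total).
    """
    rng = np.random.default_rng(rng_seed)
    background = _random_sequence(rng, spec.background_length, spec.gc)

    ancestors: dict[str, str] = {}
    classes: dict[str, str] = {}
    orf2: dict[str, bool] = {}
    host_proteins: dict[str, str] = {}
    rt_proteins: dict[str, str] = {}
    inserts: list[tuple[str, str, str, str, float, float]] = []
    # (name, kind, sequence, strand, identity, truncation_fraction)

    for fam in spec.families:
        if fam.has_intact_orf2:
            rt_prot = _random_protein(rng, fam.rt_protein_length)
            rt_proteins[fam.name] = rt_prot
            ancestor = _orf_ancestor(
                rng, fam.ancestor_length, rt_prot, spec.gc
            )
        else:
            ancestor = _random_sequence(rng, fam.ancestor_length, spec.gc)
        ancestors[fam.name] = ancestor
        classes[fam.name] = fam.te_class
        orf2[fam.name] = fam.has_intact_orf2
        for _ in range(fam.copies):
            trunc_frac = 0.0
            copy_seq = ancestor
            if fam.truncation_mean_frac > 0:
                trunc_frac = min(
                    float(rng.exponential(fam.truncation_mean_frac)), 0.9
                )
                cut = int(trunc_frac * len(ancestor))
                copy_seq = ancestor[cut:]
                trunc_frac = cut / len(ancestor)
            mutant, identity = mutate(
                copy_seq, rng, fam.substitution_rate, fam.indel_rate
            )
            strand = "+" if rng.random() < 0.5 else "-"
            inserts.append(
                (fam.name, "family", mutant, strand, identity, trunc_frac)
            )

    for sd in spec.sds:
        ancestor = _random_sequence(rng, sd.length, spec.gc)
        ancestors[sd.name] = ancestor
        classes[sd.name] = "SD"
        orf2[sd.name] = False
        rate = 1.0 - np.sqrt(sd.identity)  # pairwise identity ~ requested
        for _ in range(sd.copies):
            mutant, identity = mutate(ancestor, rng, rate)
            strand = "+" if rng.random() < 0.5 else "-"
            inserts.append((sd.name, "sd", mutant, strand, identity, 0.0))

    for host in spec.host_paralogs:
        protein = _random_protein(rng, host.protein_length)
        host_proteins[host.name] = protein
        cds = reverse_translate(protein)
        ancestors[host.name] = cds
        classes[host.name] = "host_gene"
        orf2[host.name] = False
        for _ in range(host.copies):
            mutant, identity = mutate(cds, rng, host.substitution_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            inserts.append(
                (host.name, "host_paralog", mutant, strand, identity, 0.0)
            )

    for ssr in spec.ssr_tracts:
        tract = ssr.unit * ssr.copies
        ancestors[ssr.name] = tract
        classes[ssr.name] = "SSR"
        orf2[ssr.name] = False
        inserts.append((ssr.name, "ssr", tract, "+", 1.0, 0.0))

    order = rng.permutation(len(inserts))
    # stars-and-bars placement with a guaranteed background gap between
    # consecutive insertion points, so planted copies never abut: adjacent
    # insertions would create chimeric junction alignments
    n_ins = len(inserts)
    gap = spec.min_spacing
    reduced = spec.background_length - (n_ins - 1) * gap
    if reduced < n_ins:
        raise ValueError(
            "background too small for the requested insertions and spacing"
        )
    base = np.sort(rng.choice(reduced, size=n_ins, replace=False))
    positions = base + gap * np.arange(n_ins)
    rows = []
    parts = []
    cursor = 0
    offset = 0
    for pos, idx in zip(positions, order):
        name, kind, seq, strand, identity, trunc = inserts[idx]
        parts.append(background[cursor:pos])
        offset += pos - cursor
        placed = seq if strand == "+" else reverse_complement(seq)
        parts.append(placed)
        rows.append(
            {
                "name": name,
                "kind": kind,
                "seq_id": spec.seq_id,
                "start": offset,
                "end": offset + len(placed),
                "strand": strand,
                "identity": identity,
                "truncation_fraction": trunc,
            }
        )
        offset += len(placed)
        cursor = pos
    parts.append(background[cursor:])
    genome = "".join(parts)

    truth = TruthTable(
        copies=pd.DataFrame(
            rows,
            columns=[
                "name", "kind", "seq_id", "start", "end", "strand",
                "identity", "truncation_fraction",
            ],
        ).sort_values(["seq_id", "start"], ignore_index=True),
        ancestors=ancestors,
        classes=classes,
        orf2_status=orf2,
        host_proteins=host_proteins,
        rt_proteins=rt_proteins,
    )
    return [SequenceRecord(spec.seq_id, genome)], truth


def make_reference_fixtures(
    truth: TruthTable,
    te_library_names: Sequence[str] = (),
    include_rt_in_host: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """Build the reference inputs the annotation stages consume:
    (TE nucleotide library, host protein set, RT protein set).

    The TE library holds the chosen ancestors under Repbase-style
    ``name#class`` headers.  Host paralog proteins go to the host set; RT
    proteins go to the RT set and, by default, also to the host set —
    reverse transcriptases are ordinary entries in curated protein
    databases, and the filter must retain consensuses hitting both.
    """
    te_library = []
    for name in te_library_names:
        if name not in truth.ancestors:
            raise KeyError(f"unknown planted element {name!r}")
        cls = truth.classes.get(name, "Other")
        te_library.append(
            SequenceRecord(f"{name}#{cls}", truth.ancestors[name])
        )
    host_db = [
        SequenceRecord(f"{name}_protein", prot)
        for name, prot in sorted(truth.host_proteins.items())
    ]
    rt_db = [
        SequenceRecord(f"{name}_rt", prot)
        for name, prot in sorted(truth.rt_proteins.items())
    ]
    if include_rt_in_host:
        host_db += [
            SequenceRecord(f"{rec.id}_sp", rec.sequence) for rec in rt_db
        ]
    return te_library, host_db, rt_db
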