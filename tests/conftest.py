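from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from carp.seqio import SequenceRecord
from carp.simulate import (
    FamilySpec,
    HostParalogSpec,
    PlantSpec,
    SdSpec,
    generate_genome,
    make_reference_fixtures,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(4, size=length)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)


@pytest.fixture(scope="session")
def small_planted():
    """A 120 kb genome with three families, one SD and a host paralog
    family — the shared mid-size fixture for pipeline-level tests."""
    spec = PlantSpec(
        background_length=120_000,
        families=(
            FamilySpec("famA", 1200, 15, 0.01, 0.001, te_class="LINE"),
            FamilySpec("famB", 700, 25, 0.005, 0.0, te_class="SINE"),
            FamilySpec("famC", 2000, 8, 0.0075, 0.0, te_class="LTR"),
        ),
        sds=(SdSpec("sd1", 6000, 2, 0.97),),
        host_paralogs=(HostParalogSpec("hostA", 250, 4),),
    )
    genome, truth = generate_genome(spec, 42)
    te_lib, host_db, rt_db = make_reference_fixtures(truth, ["famA", "famB"])
    return spec, genome, truth, te_lib, host_db, rt_db


def planted_pair_genome(
    rng: np.random.Generator,
    copy_length: int = 300,
    n_copies: int = 2,
    background: int = 10_000,
    divergence: float = 0.0,
    strands: tuple[str, ...] | None = None,
) -> tuple[list[SequenceRecord], list[tuple[int, int]], str]:
    """Hand-rolled planted-duplicate genome for aligner unit tests:
    returns (records, planted [start, end) spans, ancestor).

    The first copy is the unmutated ancestor, so the pairwise divergence
    between copy 0 and copy i is exactly ``divergence``.
    """
    from carp.seqio import reverse_complement

    ancestor = random_seq(rng, copy_length)
    gap = background // (n_copies + 1)
    parts = []
    spans = []
    pos = 0
    for i in range(n_copies):
        pad = random_seq(rng, gap)
        parts.append(pad)
        pos += len(pad)
        copy = list(ancestor)
        n_mut = round(divergence * copy_length) if i > 0 else 0
        if n_mut:
            sites = rng.choice(copy_length, size=n_mut, replace=False)
            for s in sites:
                copy[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[s]]
        copy = "".join(copy)
        if strands and strands[i] == "-":
            copy = reverse_complement(copy)
        parts.append(copy)
        spans.append((pos, pos + copy_length))
        pos += copy_length
    parts.append(random_seq(rng, gap))
    genome = "".join(parts)
    return [SequenceRecord("chr1", genome)], spans, ancestor
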