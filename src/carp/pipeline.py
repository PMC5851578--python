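"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — self-alignment, pile building,
single-linkage clustering, consensus construction, protein/SSR filtering,
TE-library classification, genome annotation with the combined library,
copy-number analysis and SD triage — and writes every intermediate as a
plain-text artifact (TSV / FASTA / GFF3) plus a manifest linking each
consensus to its sampled members and their genome intervals: the audit
trail.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import annotate as ann
from . import families as fam
from . import sd as sdmod
from .align import AlignerParams, GenomeIndex, LocalAlignment, align_all
from .consensus import ConsensusRecord, build_consensus
from .seqio import (
    GenomeInterval,
    GffFeature,
    SequenceRecord,
    as_dict,
    write_fasta,
    write_gff,
)

logger = logging.getLogger("carp")


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter in one serialisable record."""

    aligner: AlignerParams = field(default_factory=AlignerParams)
    filters: ann.FilterParams = field(default_factory=ann.FilterParams)
    pile_min_overlap: float = 0.5
    consensus_length_fraction: float = 0.95
    consensus_max_sample: int = 100
    high_copy_threshold: int = 2000
    peak_frac: float = 0.5
    min_peak_bp: int = 30
    rng_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    out_dir: Path
    alignments: list[LocalAlignment]
    families: list[fam.RepeatFamily]
    consensuses: list[ConsensusRecord]
    removed: list[ann.RemovalRecord]
    resolved_hits: list[ann.ResolvedHit]
    copy_numbers: list[sdmod.CopyNumberRecord]
    triage: sdmod.TriageResult | None
    regression: sdmod.RegressionResult | None
    summary: dict[str, float]


def _alignments_frame(alignments: Sequence[LocalAlignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_a": a.image_a.seq_id,
                "start_a": a.image_a.start,
                "end_a": a.image_a.end,
                "seq_b": a.image_b.seq_id,
                "start_b": a.image_b.start,
                "end_b": a.image_b.end,
                "orientation": a.orientation,
                "identity": round(a.identity, 6),
                "score": a.score,
            }
            for a in alignments
        ],
        columns=[
            "seq_a", "start_a", "end_a", "seq_b", "start_b", "end_b",
            "orientation", "identity", "score",
        ],
    )


def write_alignments_tsv(
    alignments: Sequence[LocalAlignment], path: Path
) -> None:
    _alignments_frame(alignments).to_csv(path, sep="\t", index=False)


def run_pipeline(
    genome: Sequence[SequenceRecord],
    te_library: Sequence[SequenceRecord],
    host_db: Sequence[SequenceRecord],
    rt_db: Sequence[SequenceRecord],
    config: PipelineConfig,
    out_dir: str | Path,
) -> PipelineResult:
    """Run every stage and write the run directory.

    Reference inputs may be empty: with an empty TE library every surviving
    consensus is unannotated (hence unclassified), and empty protein sets
    disable the corresponding filter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json() + "\n")
    genome_map = as_dict(genome)
    genome_length = sum(len(r.sequence) for r in genome)
    t0 = time.perf_counter()

    def tick(stage: str, detail: str) -> None:
        logger.info("%s: %s (%.1fs)", stage, detail, time.perf_counter() - t0)

    # 1. self-alignment
    alignments = align_all(genome, config.aligner)
    write_alignments_tsv(alignments, out / "alignments.tsv")
    tick("align", f"{len(alignments)} alignments")

    # 2. piles and single-linkage families
    instances = fam.build_piles(
        fam.alignment_images(alignments), config.pile_min_overlap
    )
    families = fam.link_families(instances, alignments)
    tick("cluster", f"{len(instances)} instances, {len(families)} families")

    gff_features = []
    edge_rows = []
    member_seqs_dir = out / "families"
    member_seqs_dir.mkdir(exist_ok=True)
    family_members: dict[str, dict[str, str]] = {}
    for family in families:
        records = fam.export_family_members(family, genome_map)
        family_members[family.id] = {
            m.id: rec.sequence
            for m, rec in zip(family.members, records)
        }
        write_fasta(records, member_seqs_dir / f"{family.id}.fasta")
        for member in family.members:
            gff_features.append(
                GffFeature(
                    interval=GenomeInterval(
                        member.interval.seq_id,
                        member.interval.start,
                        member.interval.end,
                        family.orientations.get(member.id, "+"),
                    ),
                    type="repeat_instance",
                    attributes={
                        "ID": member.id,
                        "Family": family.id,
                    },
                )
            )
        for a, b, aln_id in family.edges:
            edge_rows.append(
                {"family": family.id, "member_a": a, "member_b": b,
                 "alignment": aln_id}
            )
    write_gff(gff_features, out / "families.gff3")
    pd.DataFrame(
        edge_rows, columns=["family", "member_a", "member_b", "alignment"]
    ).to_csv(out / "family_edges.tsv", sep="\t", index=False)

    # 3. consensus per family
    consensuses = []
    for family in families:
        consensuses.append(
            build_consensus(
                family,
                family_members[family.id],
                config.consensus_length_fraction,
                config.consensus_max_sample,
                config.rng_seed,
            )
        )
    consensuses = [c for c in consensuses if c.sequence]
    tick("consensus", f"{len(consensuses)} consensus sequences")

    # 4. SSR / host-protein filtering
    kept, removed = ann.filter_consensus_set(
        consensuses, host_db, rt_db, config.filters
    )
    pd.DataFrame(
        [
            {"consensus": r.consensus_id, "reason": r.reason,
             "detail": r.detail}
            for r in removed
        ],
        columns=["consensus", "reason", "detail"],
    ).to_csv(out / "removed_consensus.tsv", sep="\t", index=False)
    tick("filter", f"{len(kept)} kept, {len(removed)} removed")

    # 5. classification against the TE library
    class_map = {r.id: ann.parse_te_class(r.id)[1] for r in te_library}
    ann.classify_consensus(kept, te_library, config.filters,
                           aligner_params=config.aligner)
    write_fasta(
        {c.family_id: c.sequence for c in kept}, out / "consensus.fasta"
    )
    pd.DataFrame(
        [
            {
                "consensus": c.family_id,
                "length": len(c.sequence),
                "class": c.annotation_class,
                "te_class": ann.consensus_te_class(c),
                "n_members_sampled": len(c.sampled_member_ids),
                "best_ref": c.annotation_hits[0].ref_id
                if c.annotation_hits else "",
            }
            for c in kept
        ],
        columns=["consensus", "length", "class", "te_class",
                 "n_members_sampled", "best_ref"],
    ).to_csv(out / "classification.tsv", sep="\t", index=False)
    tick("classify", "done")

    # 6. genome annotation with the combined library
    resolved: list[ann.ResolvedHit] = []
    summary: dict[str, float] = {}
    if kept or te_library:
        combined = [
            SequenceRecord(c.family_id, c.sequence) for c in kept
        ] + list(te_library)
        class_of = {c.family_id: ann.consensus_te_class(c) for c in kept}
        class_of.update(class_map)
        index = GenomeIndex(genome, config.aligner.seed_k)
        resolved = ann.annotate_genome(
            index, combined, class_of, config.filters, config.aligner
        )
        summary = ann.summarize_repeat_content(resolved, genome_length)
    write_gff(
        [
            GffFeature(
                interval=h.interval,
                type="repeat_hit",
                score=float(h.score),
                attributes={
                    "ID": f"hit{i:07d}",
                    "Library": h.library_id,
                    "Class": h.te_class,
                    "Identity": f"{h.identity:.4f}",
                },
            )
            for i, h in enumerate(resolved)
        ],
        out / "genome_annotation.gff3",
    )
    pd.DataFrame(
        [{"class": k, "percent_of_genome": round(v, 4)}
         for k, v in summary.items()],
        columns=["class", "percent_of_genome"],
    ).to_csv(out / "repeat_summary.tsv", sep="\t", index=False)
    tick("annotate", f"{len(resolved)} resolved hits")

    # 7. copy number, regression, triage of the unclassified set
    unclassified = [c for c in kept if ann.is_unclassified(c)]
    copy_numbers = sdmod.copy_number_table(resolved, unclassified)
    pd.DataFrame(
        [
            {"consensus": r.consensus_id, "length": r.length,
             "copies": r.copies}
            for r in copy_numbers
        ],
        columns=["consensus", "length", "copies"],
    ).to_csv(out / "copy_number.tsv", sep="\t", index=False)

    regression = None
    usable = [r for r in copy_numbers if r.copies >= 1]
    if len(usable) >= 3 and len({r.length for r in usable}) >= 2:
        regression = sdmod.loglog_regression(copy_numbers)
        pd.DataFrame(
            [
                {"term": "intercept", "estimate": regression.intercept,
                 "std_error": regression.intercept_se},
                {"term": "log10_length", "estimate": regression.slope,
                 "std_error": regression.slope_se,
                 "t_value": regression.t_slope,
                 "p_value": regression.p_slope},
            ]
        ).to_csv(out / "regression.tsv", sep="\t", index=False)
        sdmod.plot_loglog_scatter(
            copy_numbers, regression, out / "copy_number_scatter.png"
        )

    triage = None
    if unclassified:
        triage = sdmod.triage_unclassified(
            copy_numbers,
            resolved,
            {c.family_id: c for c in unclassified},
            config.high_copy_threshold,
            config.peak_frac,
            config.min_peak_bp,
        )
        pd.DataFrame(
            [
                {"consensus": r.consensus_id, "length": r.length,
                 "copies": r.copies, "bin": "sd_candidate"}
                for r in triage.sd_candidates
            ]
            + [
                {"consensus": r.consensus_id, "length": r.length,
                 "copies": r.copies, "bin": "high_copy_review"}
                for r in triage.high_copy_review
            ],
            columns=["consensus", "length", "copies", "bin"],
        ).to_csv(out / "sd_triage.tsv", sep="\t", index=False)
        cov_dir = out / "coverage"
        cov_dir.mkdir(exist_ok=True)
        for cid, profile in triage.profiles.items():
            pd.DataFrame(
                {"position": range(len(profile.depth)),
                 "depth": profile.depth}
            ).to_csv(cov_dir / f"{cid}.tsv", sep="\t", index=False)
            sdmod.plot_coverage(profile, cov_dir / f"{cid}.png")
    tick("sd", f"{len(copy_numbers)} unclassified consensus records")

    # 8. manifest: consensus -> sampled members -> genome intervals
    manifest = {
        "config": dataclasses.asdict(config),
        "consensus": {
            c.family_id: {
                "class": c.annotation_class,
                "sampled_members": {
                    mid: _member_interval(families, c.family_id, mid)
                    for mid in c.sampled_member_ids
                },
            }
            for c in kept
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )

    return PipelineResult(
        out_dir=out,
        alignments=alignments,
        families=families,
        consensuses=kept,
        removed=removed,
        resolved_hits=resolved,
        copy_numbers=copy_numbers,
        triage=triage,
        regression=regression,
        summary=summary,
    )


def _member_interval(
    families: Sequence[fam.RepeatFamily], family_id: str, member_id: str
) -> dict:
    for family in families:
        if family.id == family_id:
            for member in family.members:
                if member.id == member_id:
                    iv = member.interval
                    return {
                        "seq_id": iv.seq_id,
                        "start": iv.start,
                        "end": iv.end,
                        "strand": family.orientations.get(member_id, "+"),
                    }
    raise KeyError(f"{family_id}/{member_id} not found")
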