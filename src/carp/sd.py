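"""Segmental-duplication vs novel-TE triage of unclassified consensuses.

Segmental duplications are long, low-copy, high-identity duplicates, so
unclassified consensus sequences present at low genome hit copy number are
strong SD candidates.  The module builds the per-consensus (length, copy
number) table, fits the log10-log10 copy-number-vs-length regression, and
computes coverage profiles so that the small high-copy tail can be reviewed
for novel or partial TEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotate import ResolvedHit
from .consensus import ConsensusRecord


@dataclass(frozen=True)
class CopyNumberRecord:
    consensus_id: str
    length: int
    copies: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int
    t_slope: float = float("nan")
    p_slope: float = float("nan")


@dataclass
class CoverageProfile:
    """Per-position genome-hit depth along a consensus, with its peaks."""

    consensus_id: str
    depth: np.ndarray
    peaks: list[tuple[int, int, int]] = field(default_factory=list)
    # peaks: (start, end, max_depth) on the consensus


def copy_number_table(
    resolved: Sequence[ResolvedHit],
    unclassified: Sequence[ConsensusRecord],
) -> list[CopyNumberRecord]:
    """One record per unclassified consensus; copies counts resolved
    (post overlap-trimming) genome hits labelled with it."""
    counts: dict[str, int] = {}
    for hit in resolved:
        counts[hit.library_id] = counts.get(hit.library_id, 0) + 1
    return [
        CopyNumberRecord(
            c.family_id, len(c.sequence), counts.get(c.family_id, 0)
        )
        for c in unclassified
    ]


def loglog_regression(records: Sequence[CopyNumberRecord]) -> RegressionResult:
    """OLS of log10(copies) on log10(length) via the closed-form normal
    equations.  Zero-copy records are excluded (log undefined); at least 3
    usable records are required for the standard errors."""
    usable = [r for r in records if r.copies >= 1]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 records with copies >= 1, got {len(usable)}"
        )
    x = np.log10([r.length for r in usable])
    y = np.log10([r.copies for r in usable])
    n = len(usable)
    sx = x.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    sy = y.sum()
    det = n * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate fit: all lengths identical")
    slope = (n * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    slope_se = float(np.sqrt(s2 * n / det))
    intercept_se = float(np.sqrt(s2 * sxx / det))
    if slope_se > 0:
        t = slope / slope_se
        p = 2 * stats.t.sf(abs(t), dof)
    else:
        t, p = float("inf"), 0.0
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=slope_se,
        intercept_se=intercept_se,
        n=n,
        t_slope=float(t),
        p_slope=float(p),
    )


def coverage_profile(
    consensus: ConsensusRecord,
    hits: Sequence[ResolvedHit],
    peak_frac: float = 0.5,
    min_peak_bp: int = 30,
) -> CoverageProfile:
    """Depth[i] = number of genome hits covering consensus position i.

    Peaks are maximal runs with depth >= ``peak_frac`` x max depth, each at
    least ``min_peak_bp`` wide.
    """
    n = len(consensus.sequence)
    depth = np.zeros(n, dtype=np.int64)
    for h in hits:
        if h.library_id != consensus.family_id:
            continue
        depth[max(0, h.query_start) : min(n, h.query_end)] += 1
    peaks: list[tuple[int, int, int]] = []
    maxd = int(depth.max()) if n else 0
    if maxd > 0:
        thresh = peak_frac * maxd
        above = depth >= thresh
        padded = np.concatenate(([False], above, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(changes[::2], changes[1::2]):
            if e - s >= min_peak_bp:
                peaks.append((int(s), int(e), int(depth[s:e].max())))
    return CoverageProfile(consensus.family_id, depth, peaks)


def plot_loglog_scatter(
    records: Sequence[CopyNumberRecord],
    regression: RegressionResult | None,
    path,
) -> None:
    """log10 copy number vs log10 length scatter with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = [r for r in records if r.copies >= 1]
    x = np.log10([r.length for r in usable])
    y = np.log10([r.copies for r in usable])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    if regression is not None and len(x):
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, regression.intercept + regression.slope * xs, "r-")
    ax.set_xlabel("log10 consensus length (bp)")
    ax.set_ylabel("log10 genome hit copy number")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage(profile: CoverageProfile, path) -> None:
    """Per-position hit depth along a consensus."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.fill_between(
        np.arange(len(profile.depth)), profile.depth, step="mid", alpha=0.7
    )
    ax.set_xlabel(f"position on {profile.consensus_id} (bp)")
    ax.set_ylabel("hit depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class TriageResult:
    sd_candidates: list[CopyNumberRecord]
    high_copy_review: list[CopyNumberRecord]
    profiles: dict[str, CoverageProfile] = field(default_factory=dict)


def triage_unclassified(
    records: Sequence[CopyNumberRecord],
    resolved: Sequence[ResolvedHit] | None = None,
    unclassified: Mapping[str, ConsensusRecord] | None = None,
    high_copy_threshold: int = 2000,
    peak_frac: float = 0.5,
    min_peak_bp: int = 30,
) -> TriageResult:
    """Copy-number triage of the unclassified set.

    copies > ``high_copy_threshold`` (strict) lands in high_copy_review —
    novel/partial TE candidates, with coverage profiles attached when hits
    are provided; everything else is an SD candidate.
    """
    sd, high = [], []
    for rec in records:
        (high if rec.copies > high_copy_threshold else sd).append(rec)
    result = TriageResult(sd_candidates=sd, high_copy_review=high)
    if resolved is not None and unclassified is not None:
        for rec in high:
            cons = unclassified.get(rec.consensus_id)
            if cons is not None:
                result.profiles[rec.consensus_id] = coverage_profile(
                    cons, resolved, peak_frac, min_peak_bp
                )
    return result
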