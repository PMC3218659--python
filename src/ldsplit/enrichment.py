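"""Genomic-feature enrichment around candidate split SNPs.

Candidate SNPs (q ≤ 0.01) and controls (q > 0.5) are de-duplicated into
LD blocks, controls are matched to candidates by hotspot distance, tag
SNPs are extended to fixed-width windows (0-based half-open BED
coordinates), windows are intersected with feature tracks, and candidate
enrichment is assessed by a one-sided (greater) Fisher exact test.  The
derived-allele temperature tabulation cross-classifies hotspot–SNP pairs
by q-value and distance to check that allele-age artifacts do not drive
small q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import SplitTest, pair_distances  # noqa: F401  (re-export)
from .hotspots import Hotspot
from .panel import HaplotypePanel, SnpRecord, select_ld_blocks

__all__ = [
    "GenomicInterval",
    "ContingencyTable",
    "select_candidates_controls",
    "extend_windows",
    "count_overlaps",
    "fisher_greater",
    "pair_distances",
    "derived_temperature_table",
    "read_bed",
    "write_bed",
]

Q_CANDIDATE = 0.01
Q_CONTROL = 0.5


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class ContingencyTable:
    candidate_hits: int
    candidate_misses: int
    control_hits: int
    control_misses: int

    def __post_init__(self) -> None:
        if min(
            self.candidate_hits,
            self.candidate_misses,
            self.control_hits,
            self.control_misses,
        ) < 0:
            raise ValueError("counts must be non-negative")


def select_candidates_controls(
    tests: list[SplitTest],
    panel: HaplotypePanel,
    r2_threshold: float = 0.8,
    q_candidate: float = Q_CANDIDATE,
    q_control: float = Q_CONTROL,
    controls_per_candidate: int = 2,
) -> tuple[list[int], list[int]]:
    """Distance-matched candidate and control tag SNPs.

    Candidates are split SNPs with q ≤ ``q_candidate``, controls have
    q > ``q_control``; each pool is clustered into LD blocks separately.
    For every candidate block of a hotspot, up to
    ``controls_per_candidate`` control blocks of the same hotspot are
    chosen whose block-center distance to the hotspot center is closest
    to the candidate's.  The smallest-q member of each chosen block is
    its tag.  Hotspots with no available control are kept and noted.
    """
    best_q: dict[int, float] = {}
    for t in tests:
        best_q[t.snp] = min(best_q.get(t.snp, np.inf), t.q_value)

    by_hotspot: dict[tuple, list[SplitTest]] = {}
    for t in tests:
        by_hotspot.setdefault(t.hotspot.interval, []).append(t)

    cand_tags: list[int] = []
    ctrl_tags: list[int] = []
    pos = panel.positions

    for _, group in sorted(by_hotspot.items()):
        hs: Hotspot = group[0].hotspot
        cands = sorted({t.snp for t in group if t.q_value <= q_candidate})
        ctrls = sorted({t.snp for t in group if t.q_value > q_control})
        if not cands:
            continue
        cand_blocks = select_ld_blocks(panel, cands, r2_threshold)
        ctrl_blocks = select_ld_blocks(panel, ctrls, r2_threshold) if ctrls else []

        def center_dist(block) -> float:
            c = float(np.mean([pos[s] for s in block.member_snps]))
            return abs(c - hs.peak_center)

        available = list(ctrl_blocks)
        for cb in cand_blocks:
            tag = min(cb.member_snps, key=lambda s: (best_q.get(s, np.inf), s))
            cand_tags.append(tag)
            d_cand = center_dist(cb)
            available.sort(key=lambda b: (abs(center_dist(b) - d_cand),
                                          b.member_snps[0]))
            chosen = available[:controls_per_candidate]
            available = available[controls_per_candidate:]
            for blk in chosen:
                ctrl_tags.append(
                    min(blk.member_snps, key=lambda s: (best_q.get(s, np.inf), s))
                )
    return cand_tags, ctrl_tags


def extend_windows(
    snps: list[SnpRecord], width: int, chrom: str = "chr1"
) -> list[GenomicInterval]:
    """Fixed-width windows around SNPs, 0-based half-open.

    A SNP at 1-based position p gets [p−1−⌊w/2⌋, p−1+⌈w/2⌉); for even
    widths the SNP sits one base right of center.  Windows running past
    the contig start are clipped.
    """
    if width < 2:
        raise ValueError("window width must be at least 2")
    out = []
    for s in snps:
        base = s.position - 1
        start = base - width // 2
        end = base + (width + 1) // 2
        start = max(0, start)
        out.append(GenomicInterval(chrom, start, end, label=s.snp_id))
    return out


def count_overlaps(
    windows: list[GenomicInterval], features: list[GenomicInterval]
) -> tuple[int, int]:
    """(hits, misses): a window is a hit if it shares ≥ 1 bp with any
    feature on the same chromosome (half-open abutment is a miss)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    arrs = {
        c: (
            np.array([f.start for f in fs]),
            np.array([f.end for f in fs]),
        )
        for c, fs in by_chrom.items()
    }
    hits = 0
    for w in windows:
        if w.chrom in arrs:
            fs, fe = arrs[w.chrom]
            if bool(np.any((fs < w.end) & (fe > w.start))):
                hits += 1
    return hits, len(windows) - hits


def fisher_greater(table: ContingencyTable) -> float:
    """One-sided Fisher exact p for candidate over-representation."""
    return float(
        sps.fisher_exact(
            [
                [table.candidate_hits, table.candidate_misses],
                [table.control_hits, table.control_misses],
            ],
            alternative="greater",
        ).pvalue
    )


_Q_BINS = ((0.0, 0.01), (0.01, 0.05), (0.05, 0.5), (0.5, 1.0001))
_Q_LABELS = ("q<0.01", "0.01<=q<0.05", "0.05<=q<0.5", "q>=0.5")
_D_LABELS = ("inside", "D<=50kb", "50kb<D<=100kb", "D>100kb")


def _distance_label(t: SplitTest) -> str:
    if t.dist_bp == 0:
        return _D_LABELS[0]
    d = abs(t.dist_bp)
    if d <= 50_000:
        return _D_LABELS[1]
    if d <= 100_000:
        return _D_LABELS[2]
    return _D_LABELS[3]


def derived_temperature_table(
    tests: list[SplitTest], panel: HaplotypePanel
) -> pd.DataFrame:
    """Derived-cold vs derived-hot pair counts per q-value × distance bin.

    The derived allele is 'cold' when its subpopulation has the strictly
    smaller hotspot strength.  SNPs with unknown ancestral state are
    skipped and tallied in the ``skipped`` column.  Cells are formatted
    as cold/hot counts with their ratio.
    """
    cold = {(q, d): 0 for q in _Q_LABELS for d in _D_LABELS}
    hot = {(q, d): 0 for q in _Q_LABELS for d in _D_LABELS}
    skipped = {q: 0 for q in _Q_LABELS}
    for t in tests:
        qlab = None
        for (lo, hi), lab in zip(_Q_BINS, _Q_LABELS):
            if lo <= t.q_value < hi:
                qlab = lab
                break
        if qlab is None:
            continue
        code = panel.snps[t.snp].derived_allele_code
        if code is None:
            skipped[qlab] += 1
            continue
        derived_strength = t.rho1 if code == 1 else t.rho0
        other = t.rho0 if code == 1 else t.rho1
        dlab = _distance_label(t)
        if derived_strength < other:
            cold[(qlab, dlab)] += 1
        else:
            hot[(qlab, dlab)] += 1
    rows = []
    for q in _Q_LABELS:
        row: dict = {"q_bin": q}
        for d in _D_LABELS:
            c, h = cold[(q, d)], hot[(q, d)]
            ratio = c / h if h else np.inf if c else np.nan
            row[f"{d}_cold"] = c
            row[f"{d}_hot"] = h
            row[f"{d}_ratio"] = ratio
        row["skipped"] = skipped[q]
        rows.append(row)
    return pd.DataFrame(rows).set_index("q_bin")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split()
            label = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
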