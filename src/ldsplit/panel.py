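"""Phased haplotype panels: the universal input container.

A :class:`HaplotypePanel` holds a complete, phased, biallelic 0/1 matrix
(rows = chromosomes, columns = SNPs) together with per-SNP metadata.  All
downstream machinery — rate estimation, allele splits, permutation tests —
operates on this container.  Missing genotypes are rejected at load time:
the method assumes complete phased panels, and silent imputation would bias
the allele-split contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "HaplotypePanel",
    "LdBlock",
    "minor_allele_freq",
    "r_squared",
    "select_ld_blocks",
]


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP locus.

    Parameters
    ----------
    snp_id : str
        Identifier (e.g. an rs number).
    position : int
        1-based physical position in base pairs; must be positive.
    allele0, allele1 : str
        The two alleles (nucleotides or symbolic "0"/"1"); must differ.
    ancestral_state : str or None
        ``allele0``, ``allele1`` or ``None`` (unknown).  Used only by the
        derived-allele temperature tabulation.
    """

    snp_id: str
    position: int
    allele0: str = "0"
    allele1: str = "1"
    ancestral_state: str | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")
        if self.allele0 == self.allele1:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")
        if self.ancestral_state is not None and self.ancestral_state not in (
            self.allele0,
            self.allele1,
        ):
            raise ValueError(
                f"SNP {self.snp_id}: ancestral state {self.ancestral_state!r} "
                "is neither allele"
            )

    @property
    def derived_allele_code(self) -> int | None:
        """0/1 code of the derived allele, or None if ancestral state unknown."""
        if self.ancestral_state is None:
            return None
        return 1 if self.ancestral_state == self.allele0 else 0


@dataclass
class HaplotypePanel:
    """A phased binary haplotype matrix with SNP metadata.

    ``haplotypes`` is an (n_chromosomes, n_snps) uint8 array of 0/1.  Two
    consecutive rows belonging to one diploid individual carry the same
    individual label in ``chromosome_ids`` (suffixed _A/_B on export).
    SNP positions must be strictly increasing and the matrix complete.
    """

    haplotypes: np.ndarray
    snps: list[SnpRecord]
    chromosome_ids: list[str] = field(default_factory=list)
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        n, m = self.haplotypes.shape
        if n < 1:
            # loaded panels must have >= 2 rows (checked at load); allele
            # splits may produce single-chromosome subpanels
            raise ValueError("panel needs at least 1 chromosome")
        if m != len(self.snps):
            raise ValueError("column count does not match SNP metadata")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1 (no missing)")
        pos = self.positions
        if m > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("SNP positions must be strictly increasing")
        if not self.chromosome_ids:
            self.chromosome_ids = [f"hap{i}" for i in range(n)]
        if len(self.chromosome_ids) != n:
            raise ValueError("chromosome_ids length does not match row count")

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    def allele_freq(self, snp: int) -> float:
        """Frequency of allele 1 at column ``snp``."""
        return float(self.haplotypes[:, snp].mean())

    def is_monomorphic(self, snp: int) -> bool:
        col = self.haplotypes[:, snp]
        return bool((col == col[0]).all())

    def monomorphic_mask(self) -> np.ndarray:
        """Boolean mask of columns fixed in this panel (kept but flagged)."""
        h = self.haplotypes
        return (h == h[0]).all(axis=0)

    def take_rows(self, rows: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        rows = np.asarray(rows, dtype=np.intp)
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows],
            snps=list(self.snps),
            chromosome_ids=[self.chromosome_ids[i] for i in rows],
            chrom_name=self.chrom_name,
        )

    def take_snps(self, cols: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        cols = np.asarray(cols, dtype=np.intp)
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, cols],
            snps=[self.snps[i] for i in cols],
            chromosome_ids=list(self.chromosome_ids),
            chrom_name=self.chrom_name,
        )

    def with_ancestral_states(self, states: dict[str, str]) -> "HaplotypePanel":
        """Return a copy annotated with ancestral alleles (by snp_id)."""
        snps = [
            replace(s, ancestral_state=states.get(s.snp_id, s.ancestral_state))
            for s in self.snps
        ]
        return HaplotypePanel(
            self.haplotypes.copy(), snps, list(self.chromosome_ids), self.chrom_name
        )


@dataclass(frozen=True)
class LdBlock:
    """A greedy LD bin: member SNP indices represented by one tag SNP."""

    member_snps: tuple[int, ...]
    tag_snp: int

    def __post_init__(self) -> None:
        if self.tag_snp not in self.member_snps:
            raise ValueError("tag SNP must be a block member")


def minor_allele_freq(panel: HaplotypePanel, snp: int) -> float:
    """Minor allele frequency at ``snp``: min(f, 1 - f) with f the allele-1 mean."""
    f = panel.allele_freq(snp)
    return min(f, 1.0 - f)


def r_squared(panel: HaplotypePanel, a: int, b: int) -> float:
    """Pairwise LD r² between SNP columns ``a`` and ``b``.

    r² = D² / (p_a (1-p_a) p_b (1-p_b)) with D the haplotype-frequency
    covariance.  Undefined (raises) on monomorphic columns.
    """
    xa = panel.haplotypes[:, a].astype(np.float64)
    xb = panel.haplotypes[:, b].astype(np.float64)
    pa, pb = xa.mean(), xb.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        raise ValueError(f"r² undefined: monomorphic column ({a if va == 0 else b})")
    d = (xa * xb).mean() - pa * pb
    return float(d * d / (va * vb))


def _r2_matrix(panel: HaplotypePanel, idx: np.ndarray) -> np.ndarray:
    h = panel.haplotypes[:, idx].astype(np.float64)
    p = h.mean(axis=0)
    v = p * (1 - p)
    c = h.T @ h / h.shape[0] - np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = c * c / np.outer(v, v)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def select_ld_blocks(
    panel: HaplotypePanel,
    snp_set: Sequence[int],
    r2_threshold: float = 0.8,
) -> list[LdBlock]:
    """Greedy maximal-bin LD clustering (ldSelect semantics).

    Repeatedly pick as tag the SNP that covers the most yet-unassigned SNPs
    at r² ≥ threshold; assign that bin; repeat until every SNP of
    ``snp_set`` is in exactly one block.  Ties broken by smallest SNP index.
    Monomorphic columns in ``snp_set`` are rejected.
    """
    if len(snp_set) == 0:
        raise ValueError("snp_set must be non-empty")
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    idx = np.asarray(sorted(set(int(i) for i in snp_set)), dtype=np.intp)
    for i in idx:
        if panel.is_monomorphic(int(i)):
            raise ValueError(f"monomorphic SNP {i} cannot be LD-clustered")
    r2 = _r2_matrix(panel, idx)
    linked = r2 >= r2_threshold
    unassigned = np.ones(len(idx), dtype=bool)
    blocks: list[LdBlock] = []
    while unassigned.any():
        cover = (linked & unassigned).sum(axis=1)
        cover[~unassigned] = -1
        tag = int(np.argmax(cover))  # argmax takes smallest index on ties
        members = np.flatnonzero(linked[tag] & unassigned)
        unassigned[members] = False
        blocks.append(
            LdBlock(tuple(int(idx[m]) for m in members), tag_snp=int(idx[tag]))
        )
    blocks.sort(key=lambda b: b.member_snps[0])
    return blocks
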