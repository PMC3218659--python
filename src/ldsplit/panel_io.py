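"""Readers and writers for phased haplotype panels.

Three dialects are supported:

``hapmap_phased``
    Space-separated text; header row ``rsID position <chrom_id> ...``,
    then one row per SNP (``snp_id position allele allele ...``).  The
    matrix is transposed on load to rows = chromosomes.
``vcf``
    Phased biallelic VCF (uncompressed or bgzipped), read with cyvcf2.
    Any unphased or missing genotype aborts the load, naming the site.
``matrix_tsv``
    Plain 0/1 TSV, rows = chromosomes; header columns ``chrom_id`` then
    ``snp_id:position`` tokens.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

from .panel import HaplotypePanel, SnpRecord

__all__ = ["load_panel", "write_panel", "load_ancestral_states"]

FORMATS = ("hapmap_phased", "vcf", "matrix_tsv")


def load_panel(path: str | os.PathLike, format: str) -> HaplotypePanel:
    """Load a phased, biallelic, complete haplotype panel.

    Raises ``ValueError`` naming the offending site on unphased genotypes,
    missing data, more than two alleles, or non-monotone positions.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "matrix_tsv":
        panel = _load_matrix_tsv(path)
    elif format == "hapmap_phased":
        panel = _load_hapmap(path)
    else:
        panel = _load_vcf(path)
    if panel.n_chromosomes < 2:
        raise ValueError(f"{path}: a panel needs at least 2 chromosomes")
    return panel


def write_panel(panel: HaplotypePanel, path: str | os.PathLike, format: str) -> None:
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "matrix_tsv":
        _write_matrix_tsv(panel, path)
    elif format == "hapmap_phased":
        _write_hapmap(panel, path)
    else:
        _write_vcf(panel, path)


# -- matrix TSV -------------------------------------------------------------


def _load_matrix_tsv(path) -> HaplotypePanel:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "chrom_id":
            raise ValueError(f"{path}: matrix_tsv header must start with 'chrom_id'")
        snps = []
        for tok in header[1:]:
            sid, _, pos = tok.rpartition(":")
            if not sid:
                raise ValueError(f"{path}: bad SNP token {tok!r} (want id:position)")
            snps.append(SnpRecord(sid, int(pos)))
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            try:
                rows.append([int(x) for x in parts[1:]])
            except ValueError as e:
                raise ValueError(f"{path}: non-binary entry in row {parts[0]}") from e
    return HaplotypePanel(np.array(rows, dtype=np.uint8), snps, ids)


def _write_matrix_tsv(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        toks = [f"{s.snp_id}:{s.position}" for s in panel.snps]
        fh.write("\t".join(["chrom_id"] + toks) + "\n")
        for cid, row in zip(panel.chromosome_ids, panel.haplotypes):
            fh.write(cid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


# -- HapMap phased text -----------------------------------------------------


def _load_hapmap(path) -> HaplotypePanel:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[0] != "rsID":
            raise ValueError(f"{path}: expected header 'rsID position <ids...>'")
        ids = header[2:]
        snps, cols = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sid, pos, alleles = parts[0], int(parts[1]), parts[2:]
            if len(alleles) != len(ids):
                raise ValueError(f"{path}: SNP {sid}: wrong allele count")
            uniq = sorted(set(alleles))
            if len(uniq) > 2:
                raise ValueError(f"{path}: SNP {sid} is not biallelic: {uniq}")
            a0 = uniq[0]
            a1 = uniq[1] if len(uniq) == 2 else ("A" if a0 != "A" else "T")
            snps.append(SnpRecord(sid, pos, a0, a1))
            cols.append([0 if a == a0 else 1 for a in alleles])
    return HaplotypePanel(np.array(cols, dtype=np.uint8).T, snps, ids)


def _write_hapmap(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(["rsID", "position"] + list(panel.chromosome_ids)) + "\n")
        for j, s in enumerate(panel.snps):
            col = panel.haplotypes[:, j]
            alleles = [s.allele0 if x == 0 else s.allele1 for x in col]
            fh.write(" ".join([s.snp_id, str(s.position)] + alleles) + "\n")


# -- VCF --------------------------------------------------------------------


def _load_vcf(path) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids = [f"{s}_{h}" for s in samples for h in ("A", "B")]
    snps, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{var.CHROM}:{var.POS} ({var.ID}): not biallelic (ALT={var.ALT})"
            )
        gts = var.genotype.array()  # (n_samples, 3): a, b, phased flag
        if (gts[:, :2] < 0).any():
            raise ValueError(f"{var.CHROM}:{var.POS} ({var.ID}): missing genotype")
        het = gts[:, 0] != gts[:, 1]
        if ((gts[:, 2] == 0) & het).any():
            bad = samples[int(np.flatnonzero((gts[:, 2] == 0) & het)[0])]
            raise ValueError(
                f"{var.CHROM}:{var.POS} ({var.ID}): unphased genotype for {bad}"
            )
        snps.append(SnpRecord(var.ID or f"{var.CHROM}:{var.POS}", var.POS,
                              var.REF, var.ALT[0]))
        cols.append(gts[:, :2].reshape(-1))
    if not snps:
        raise ValueError(f"{path}: no variant records")
    panel = HaplotypePanel(np.array(cols, dtype=np.uint8).T, snps, ids)
    panel.chrom_name = "chr?"
    return panel


def _write_vcf(panel: HaplotypePanel, path) -> None:
    n = panel.n_chromosomes
    if n % 2 != 0:
        raise ValueError("VCF export needs an even number of chromosomes")
    samples = [panel.chromosome_ids[i].removesuffix("_A") for i in range(0, n, 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom_name}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, s in enumerate(panel.snps):
            col = panel.haplotypes[:, j]
            ref = s.allele0 if s.allele0 in "ACGT" else "A"
            alt = s.allele1 if s.allele1 in "ACGT" else "C"
            gts = "\t".join(f"{col[i]}|{col[i + 1]}" for i in range(0, n, 2))
            fh.write(
                f"{panel.chrom_name}\t{s.position}\t{s.snp_id}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# -- ancestral-state annotations -------------------------------------------


def load_ancestral_states(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV ``snp_id<TAB>ancestral_allele``.

    Unknown states may be written as ``.`` or ``?`` and are skipped.
    """
    states: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2 or parts[0].startswith("#"):
                continue
            if parts[1] in (".", "?", "NA"):
                continue
            states[parts[0]] = parts[1]
    return states
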