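"""Forward-time diploid simulator of a hotspot under allelic control.

A constant-size population of diploids evolves on a 200-kb region.  A
causal SNP controls the recombination hotspot at the region center: with
two cold alleles there is no hotspot and the (at most one) crossover per
meiosis falls uniformly; a heterozygote raises the crossover probability
ten-fold and a hot homozygote twenty-fold, with the breakpoint drawn from
a normal distribution around the hotspot center.  Biased gene conversion
(BGC) repairs the double-strand break initiated on the hot-allele
haplotype by copying from its homolog, so a heterozygous causal SNP
covered by the conversion tract is transmitted cold — recombinant gametes
from heterozygous parents carry the cold allele in a fraction
0.5 + 0.5·p_BGC·P(tract covers the SNP).

Neutral sites follow the infinite-site model (Poisson mutation influx,
fixed or lost sites dropped); the hot-allele frequency is forced along a
linear trajectory between configured endpoints by reject-sampling whole
offspring generations.  The simulator doubles as the package's synthetic
benchmark generator: :func:`sample_panels` exports haplotype panels with
the causal SNP annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import HaplotypePanel, SnpRecord

__all__ = [
    "SimConfig",
    "Population",
    "EventCounts",
    "SamplePanel",
    "initial_population",
    "mutate",
    "crossover_probability",
    "sample_breakpoint",
    "meiosis",
    "enforce_trajectory",
    "evolve",
    "sample_panels",
    "transmission_distortion",
]


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation parameters.

    Rates follow the study conditions of the benchmark: one crossover at
    most per meiosis, background probability 0.001 in the 200-kb region,
    ten-/twenty-fold increases for het / hot-homozygous causal genotypes,
    BGC probability 0.5 conditional on a crossover, mean tract 500 bp.
    ``mutation_rate`` is the expected number of new neutral sites per
    haplotype per generation across the region; together with
    ``init_sites`` (standing variation at start) it is calibrated to give
    a few hundred usable sites in sampled panels.
    """

    pop_size: int = 5000
    generations: int = 3000
    region_length: int = 200_000
    background_crossover_prob: float = 0.001
    het_multiplier: float = 10.0
    hom_hot_multiplier: float = 20.0
    causal_position: int = 100_000
    hotspot_center: float = 100_000.0
    breakpoint_sigma: float = 1000.0
    bgc_prob: float = 0.5
    tract_mean: float = 500.0
    tract_sigma: float | None = None  # defaults to tract_mean / 5
    mutation_rate: float = 0.03
    init_sites: int = 300
    start_hot_freq: float = 1.0
    end_hot_freq: float = 0.5
    recurrent_causal_mutation: bool = False
    trajectory_tol: float = 0.02
    rejection_budget: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for f_ in (self.start_hot_freq, self.end_hot_freq, self.bgc_prob):
            if not 0.0 <= f_ <= 1.0:
                raise ValueError("frequencies/probabilities must be in [0, 1]")
        if self.het_multiplier < 1 or self.hom_hot_multiplier < 1:
            raise ValueError("hotspot multipliers must be >= 1")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")

    @property
    def tract_sd(self) -> float:
        return self.tract_mean / 5.0 if self.tract_sigma is None else self.tract_sigma


@dataclass
class Population:
    """Evolving diploid population.

    ``haplotypes`` is a (2·pop_size, n_sites) 0/1 matrix of derived-allele
    indicators at the segregating neutral sites ``positions`` (sorted,
    causal site excluded); haplotypes 2i and 2i+1 belong to individual i.
    ``causal`` carries the causal-SNP allele per haplotype (1 = hot).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    causal: np.ndarray
    sex: np.ndarray  # per individual, 0/1
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.sex)

    @property
    def hot_freq(self) -> float:
        return float(self.causal.mean())

    def drop_fixed_sites(self) -> "Population":
        freq = self.haplotypes.mean(axis=0)
        keep = (freq > 0) & (freq < 1)
        if keep.all():
            return self
        return replace(
            self,
            haplotypes=np.ascontiguousarray(self.haplotypes[:, keep]),
            positions=self.positions[keep],
        )


@dataclass
class EventCounts:
    generation: int
    meioses: int = 0
    crossovers: int = 0
    bgc_events: int = 0
    het_recombinants: int = 0
    het_recombinant_cold: int = 0
    hot_freq: float = float("nan")  # after trajectory enforcement


@dataclass
class SamplePanel:
    """A sampled benchmark panel with simulation truth attached."""

    panel: HaplotypePanel
    causal_snp: int  # column index of the causal SNP
    hot_allele: int  # 0/1 code of the hot allele in that column
    causal_maf: float
    flagged: bool  # causal MAF < 0.3 → to be discarded from evaluation


# --------------------------------------------------------------------------


def initial_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Found the population with standing neutral variation.

    Site minor-allele frequencies are drawn from the neutral 1/f spectrum
    and alleles assigned independently (linkage builds up during the
    run); the causal SNP starts at ``start_hot_freq`` rounded to copies.
    """
    n2 = 2 * config.pop_size
    k = config.init_sites
    pos = _fresh_positions(rng, k, config, existing=np.empty(0))
    fmin = 1.0 / n2
    u = rng.random(k)
    freqs = fmin * (0.5 / fmin) ** u  # log-uniform ~ 1/f density on [fmin, 0.5]
    H = (rng.random((n2, k)) < freqs).astype(np.uint8)
    order = np.argsort(pos)
    causal = np.zeros(n2, dtype=np.uint8)
    n_hot = int(round(config.start_hot_freq * n2))
    causal[rng.choice(n2, size=n_hot, replace=False)] = 1
    sex = _draw_sexes(config.pop_size, rng)
    pop = Population(
        haplotypes=np.ascontiguousarray(H[:, order]),
        positions=pos[order],
        causal=causal,
        sex=sex,
    )
    return pop.drop_fixed_sites()


def _fresh_positions(rng, k, config, existing) -> np.ndarray:
    """Distinct integer positions, avoiding existing sites and the causal site."""
    taken = set(existing.tolist())
    taken.add(int(config.causal_position))
    out = []
    while len(out) < k:
        cand = rng.integers(1, config.region_length + 1, size=2 * (k - len(out)))
        for c in cand:
            c = int(c)
            if c not in taken:
                taken.add(c)
                out.append(c)
                if len(out) == k:
                    break
    return np.array(out, dtype=np.int64)


def _draw_sexes(n: int, rng) -> np.ndarray:
    while True:
        sex = (rng.random(n) < 0.5).astype(np.uint8)
        if 0 < sex.sum() < n:
            return sex


def mutate(pop: Population, config: SimConfig, rng: np.random.Generator) -> Population:
    """Poisson neutral mutation influx; fixed or lost sites removed.

    Each haplotype gains Poisson(``mutation_rate``) new sites at fresh
    positions (infinite-site model).  With recurrent causal mutation
    enabled, each haplotype's causal allele flips hot↔cold at ten times
    the per-site background rate.
    """
    n2 = pop.haplotypes.shape[0]
    n_new = int(rng.poisson(config.mutation_rate * n2))
    if n_new > 0:
        newpos = _fresh_positions(rng, n_new, config, pop.positions)
        carriers = rng.integers(0, n2, size=n_new)
        cols = np.zeros((n2, n_new), dtype=np.uint8)
        cols[carriers, np.arange(n_new)] = 1
        pos = np.concatenate([pop.positions, newpos])
        H = np.concatenate([pop.haplotypes, cols], axis=1)
        order = np.argsort(pos)
        pop = replace(
            pop,
            haplotypes=np.ascontiguousarray(H[:, order]),
            positions=pos[order],
        )
    if config.recurrent_causal_mutation:
        per_site = config.mutation_rate / config.region_length
        flips = rng.random(n2) < 10.0 * per_site
        if flips.any():
            causal = pop.causal.copy()
            causal[flips] ^= 1
            pop = replace(pop, causal=causal)
    return pop.drop_fixed_sites()


def crossover_probability(genotype_at_causal: int, config: SimConfig) -> float:
    """Per-meiosis crossover probability for causal genotype 0/1/2 hot alleles."""
    base = config.background_crossover_prob
    if genotype_at_causal == 0:
        return base
    if genotype_at_causal == 1:
        return base * config.het_multiplier
    if genotype_at_causal == 2:
        return base * config.hom_hot_multiplier
    raise ValueError("genotype must be 0, 1 or 2 hot alleles")


def sample_breakpoint(
    is_hot_meiosis: bool, config: SimConfig, rng: np.random.Generator
) -> float:
    """Crossover position: uniform, or normal around the hotspot center."""
    L = config.region_length
    if not is_hot_meiosis:
        return float(rng.uniform(0, L))
    while True:
        b = rng.normal(config.hotspot_center, config.breakpoint_sigma)
        if 0 <= b < L:
            return float(b)


def _gametes(
    pop: Population,
    parents: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    events: EventCounts | None = None,
):
    """Vectorized meiosis for an array of parent individuals.

    Returns (gamete haplotypes, gamete causal alleles).
    """
    M = len(parents)
    H, pos, causal = pop.haplotypes, pop.positions, pop.causal
    iA = 2 * parents
    iB = iA + 1
    geno = causal[iA].astype(np.int64) + causal[iB]
    prob = np.where(
        geno == 0,
        config.background_crossover_prob,
        np.where(
            geno == 1,
            config.background_crossover_prob * config.het_multiplier,
            config.background_crossover_prob * config.hom_hot_multiplier,
        ),
    )
    crossed = rng.random(M) < prob
    # orientation: which haplotype contributes the left flank / the whole
    # gamete when there is no crossover
    left_is_A = rng.random(M) < 0.5
    left = np.where(left_is_A, iA, iB)
    right = np.where(left_is_A, iB, iA)

    # breakpoints: uniform for background meioses, truncated normal for hot
    hot_meiosis = crossed & (geno > 0)
    b = np.full(M, np.inf)
    n_bg = int((crossed & ~hot_meiosis).sum())
    if n_bg:
        b[crossed & ~hot_meiosis] = rng.uniform(0, config.region_length, size=n_bg)
    idx_hot = np.flatnonzero(hot_meiosis)
    if len(idx_hot):
        draws = rng.normal(
            config.hotspot_center, config.breakpoint_sigma, size=len(idx_hot)
        )
        bad = (draws < 0) | (draws >= config.region_length)
        while bad.any():
            draws[bad] = rng.normal(
                config.hotspot_center, config.breakpoint_sigma, size=int(bad.sum())
            )
            bad = (draws < 0) | (draws >= config.region_length)
        b[idx_hot] = draws

    left_mask = pos[None, :] < b[:, None]  # (M, S)
    G = np.where(left_mask, H[left], H[right]).astype(np.uint8)
    g_causal = np.where(
        config.causal_position < b, causal[left], causal[right]
    ).astype(np.uint8)

    # biased gene conversion: the transmitted tract is overwritten with the
    # non-initiating haplotype (the homolog of the hot, DSB-initiating one)
    bgc = crossed & (rng.random(M) < config.bgc_prob)
    tract_len = np.maximum(
        rng.normal(config.tract_mean, config.tract_sd, size=M), 1.0
    )
    # initiating haplotype: the hot one for heterozygotes, random for homs
    A_is_hot = causal[iA] == 1
    B_is_hot = causal[iB] == 1
    rand_init = rng.random(M) < 0.5
    init_is_A = np.where(
        A_is_hot & ~B_is_hot, True, np.where(B_is_hot & ~A_is_hot, False, rand_init)
    )
    donor = np.where(init_is_A, iB, iA)  # homolog of the initiating haplotype
    idx_bgc = np.flatnonzero(bgc)
    for i in idx_bgc:
        lo = b[i] - tract_len[i] / 2.0
        hi = b[i] + tract_len[i] / 2.0
        tm = (pos >= lo) & (pos < hi)
        if tm.any():
            G[i, tm] = H[donor[i], tm]
        if lo <= config.causal_position < hi:
            g_causal[i] = causal[donor[i]]

    if events is not None:
        events.meioses += M
        events.crossovers += int(crossed.sum())
        events.bgc_events += len(idx_bgc)
        het_rec = crossed & (geno == 1)
        events.het_recombinants += int(het_rec.sum())
        events.het_recombinant_cold += int((het_rec & (g_causal == 0)).sum())
    return G, g_causal, crossed


def meiosis(
    pop: Population,
    parent: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, dict]:
    """One meiosis of ``parent``: gamete haplotype, causal allele, event record."""
    ev = EventCounts(generation=pop.generation)
    G, gc, crossed = _gametes(pop, np.array([parent]), config, rng, ev)
    record = {
        "recombinant": bool(crossed[0]),
        "causal_allele": int(gc[0]),
        "bgc": ev.bgc_events > 0,
    }
    return G[0], int(gc[0]), record


def _reproduce(
    pop: Population, config: SimConfig, rng: np.random.Generator,
    events: EventCounts | None = None,
) -> Population:
    """One generation of random mating between opposite-sex parents."""
    n = pop.n_individuals
    males = np.flatnonzero(pop.sex == 1)
    females = np.flatnonzero(pop.sex == 0)
    fathers = males[rng.integers(0, len(males), size=n)]
    mothers = females[rng.integers(0, len(females), size=n)]
    Gp, cp, _ = _gametes(pop, fathers, config, rng, events)
    Gm, cm, _ = _gametes(pop, mothers, config, rng, events)
    H = np.empty((2 * n, pop.haplotypes.shape[1]), dtype=np.uint8)
    H[0::2] = Gp
    H[1::2] = Gm
    causal = np.empty(2 * n, dtype=np.uint8)
    causal[0::2] = cp
    causal[1::2] = cm
    return Population(
        haplotypes=H,
        positions=pop.positions,
        causal=causal,
        sex=_draw_sexes(n, rng),
        generation=pop.generation + 1,
    )


def _target_freq(generation: int, config: SimConfig) -> float:
    t = generation / config.generations
    return config.start_hot_freq + (config.end_hot_freq - config.start_hot_freq) * t


def enforce_trajectory(
    pop: Population,
    generation: int,
    config: SimConfig,
    rng: np.random.Generator,
    events: EventCounts | None = None,
) -> Population:
    """Produce the next generation with the hot-allele frequency held on
    the linear trajectory by reject-sampling offspring generations."""
    target = _target_freq(generation, config)
    tol = config.trajectory_tol
    n2 = 2 * pop.n_individuals
    # (re-)introduce the derived allele by a mutation event when required
    if target < 1.0 - tol and pop.causal.min() == 1:
        causal = pop.causal.copy()
        causal[rng.integers(0, n2)] = 0
        pop = replace(pop, causal=causal)
    if target > tol and pop.causal.max() == 0:
        causal = pop.causal.copy()
        causal[rng.integers(0, n2)] = 1
        pop = replace(pop, causal=causal)
    # a frequency step of at most `tol` per generation is always reachable:
    # targets move by |end-start|/generations per generation
    grid = 1.0 / n2
    for _ in range(config.rejection_budget):
        off = _reproduce(pop, config, rng, events)
        if abs(off.hot_freq - target) <= tol + grid:
            return off
    raise RuntimeError(
        f"trajectory rejection budget exhausted at generation {generation}: "
        f"target hot frequency {target:.4f}, parental {pop.hot_freq:.4f}, "
        f"tolerance {tol}"
    )


def evolve(config: SimConfig) -> tuple[Population, list[EventCounts]]:
    """Run the full forward simulation; deterministic per ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pop = initial_population(config, rng)
    log: list[EventCounts] = []
    for g in range(1, config.generations + 1):
        pop = mutate(pop, config, rng)
        ev = EventCounts(generation=g)
        pop = enforce_trajectory(pop, g, config, rng, ev)
        pop = pop.drop_fixed_sites()
        ev.hot_freq = pop.hot_freq
        log.append(ev)
    return pop, log


def sample_panels(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    n_subsets: int = 10,
    subset_size: int = 90,
    site_maf_min: float = 0.05,
) -> list[SamplePanel]:
    """Randomly sample benchmark panels of ``subset_size`` individuals.

    The causal SNP is inserted as an annotated column; panels where its
    sample MAF falls below 0.3 are flagged for exclusion from evaluation.
    Sites below ``site_maf_min`` in the sample are not exported (rare
    alleles carry essentially no pairwise-LD information and only slow
    the rate estimator); the causal SNP is always kept.
    """
    rng = np.random.default_rng(rng)
    n = pop.n_individuals
    if subset_size > n:
        raise ValueError("subset_size exceeds population size")
    out = []
    for _ in range(n_subsets):
        ind = np.sort(rng.choice(n, size=subset_size, replace=False))
        rows = np.empty(2 * subset_size, dtype=np.intp)
        rows[0::2] = 2 * ind
        rows[1::2] = 2 * ind + 1
        H = pop.haplotypes[rows]
        causal_col = pop.causal[rows]
        if site_maf_min > 0:
            f = H.mean(axis=0)
            keep = np.minimum(f, 1 - f) >= site_maf_min
            H = np.ascontiguousarray(H[:, keep])
            site_pos = pop.positions[keep]
        else:
            site_pos = pop.positions
        insert_at = int(np.searchsorted(site_pos, config.causal_position))
        Hfull = np.concatenate(
            [H[:, :insert_at], causal_col[:, None], H[:, insert_at:]], axis=1
        )
        positions = np.concatenate(
            [
                site_pos[:insert_at],
                [config.causal_position],
                site_pos[insert_at:],
            ]
        )
        snps = [
            SnpRecord(
                "causal" if p == config.causal_position else f"s{p}",
                int(p),
                "0",
                "1",
            )
            for p in positions
        ]
        ids = [f"ind{i}_{h}" for i in ind for h in ("A", "B")]
        panel = HaplotypePanel(Hfull, snps, ids, chrom_name="sim")
        f_hot = float(causal_col.mean())
        maf = min(f_hot, 1 - f_hot)
        out.append(
            SamplePanel(
                panel=panel,
                causal_snp=insert_at,
                hot_allele=1,
                causal_maf=maf,
                flagged=maf < 0.3,
            )
        )
    return out


def transmission_distortion(
    config: SimConfig,
    n_recombinants: int = 10_000,
    rng: np.random.Generator | int | None = None,
    batch: int = 100_000,
) -> tuple[float, int]:
    """Cold-allele fraction among recombinant gametes of het parents.

    Repeatedly runs the meiosis operator on heterozygous parents until
    ``n_recombinants`` recombinant gametes are collected; returns the
    fraction carrying the cold allele and the count used.
    """
    rng = np.random.default_rng(rng)
    # a minimal heterozygous population: hapA hot, hapB cold, a few sites
    pos = np.array(
        [config.causal_position - 50_000, config.causal_position + 50_000],
        dtype=np.int64,
    )
    n_ind = 500
    H = np.zeros((2 * n_ind, len(pos)), dtype=np.uint8)
    H[0::2] = 1
    causal = np.zeros(2 * n_ind, dtype=np.uint8)
    causal[0::2] = 1  # every individual heterozygous hot/cold
    pop = Population(H, pos, causal, sex=_draw_sexes(n_ind, rng))
    cold = 0
    total = 0
    while total < n_recombinants:
        parents = rng.integers(0, n_ind, size=batch)
        _, gc, crossed = _gametes(pop, parents, config, rng)
        rec = crossed
        total += int(rec.sum())
        cold += int((rec & (gc == 0)).sum())
    return cold / total, total
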