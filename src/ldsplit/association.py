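"""The allele-split association engine.

For a candidate SNP near a hotspot, the panel is divided into the two
allele-defined subpopulations, the recombination-rate profile is estimated
for each side with the identical estimator, and the hotspot strengths ρ0
and ρ1 (on boundaries fixed from the combined panel) are contrasted as

    Δρ = (ρ0 − ρ1) / (ρ0 + ρ1).

Significance comes from random splits of the same sample: the observed,
MAF-standardized Δρ is compared against the standardized Δρ of random
splits honoring a 30% minimum subpopulation size.  Hotspots whose random
Δρ distribution fails Shapiro normality are gated out; side scores and
Grubbs' test locate the outlier chromosomes that typically cause the
failure.  q-values (Storey) summarize the scan-wide FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .hotspots import Hotspot
from .panel import HaplotypePanel, minor_allele_freq
from .rates import EstimatorConfig, estimate_rates, hotspot_strength

__all__ = [
    "SplitTest",
    "PermutationNull",
    "MafBinStats",
    "SideScoreTable",
    "ScanConfig",
    "split_by_allele",
    "delta_rho",
    "candidate_snps",
    "random_split",
    "permutation_null",
    "normality_gate",
    "maf_bin_stats",
    "standardize",
    "association_p",
    "side_scores",
    "grubbs_outliers",
    "retest_without_outliers",
    "qvalues",
    "scan",
    "null_scan",
    "pair_distances",
    "write_tests_tsv",
]


# --------------------------------------------------------------------------
# data types


@dataclass
class SplitTest:
    """One hotspot–SNP association test."""

    hotspot: Hotspot
    snp: int
    snp_id: str
    rho0: float
    rho1: float
    delta_rho: float
    delta_rho_freq_oriented: float
    n0: int
    n1: int
    maf: float
    dist_bp: float
    dist_snps: int
    z: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    shapiro_p: float = np.nan


@dataclass
class PermutationNull:
    """Random-split Δρ distribution for one hotspot.

    ``membership[i, c]`` is the side (0/1) of chromosome ``c`` in the
    *i*-th random split; ``deltas[i]`` is (ρ_side0 − ρ_side1)/(sum).
    """

    hotspot: Hotspot
    deltas: np.ndarray
    membership: np.ndarray
    sizes: np.ndarray  # (n_perm, 2)
    shapiro_p: float

    @property
    def n_perm(self) -> int:
        return len(self.deltas)

    def oriented_deltas(self) -> np.ndarray:
        """Δρ of the larger side minus the smaller side (ties keep side 0)."""
        flip = self.sizes[:, 0] < self.sizes[:, 1]
        out = self.deltas.copy()
        out[flip] = -out[flip]
        return out


class MafBinStats:
    """Per-MAF-bin mean and SD of the frequency-oriented Δρ.

    MAF is binned at the sample's natural resolution (minor-allele count
    out of n chromosomes); bins with fewer than two entries are merged
    with the nearest populated bin.
    """

    def __init__(self, n_chromosomes: int):
        self.n_chromosomes = n_chromosomes
        self._stats: dict[int, tuple[float, float, int]] = {}
        self._bin_of: dict[int, int] = {}
        self.merged_bins: list[tuple[int, int]] = []

    def bin_index(self, maf: float) -> int:
        return int(round(maf * self.n_chromosomes))

    def fit(self, mafs, deltas) -> "MafBinStats":
        raw: dict[int, list[float]] = {}
        for m, d in zip(mafs, deltas):
            raw.setdefault(self.bin_index(m), []).append(float(d))
        bins = sorted(raw)
        merged: dict[int, list[float]] = {b: list(v) for b, v in raw.items()}
        changed = True
        while changed and len(merged) > 1:
            changed = False
            for b in sorted(merged):
                if len(merged[b]) < 2:
                    others = [o for o in merged if o != b]
                    near = min(others, key=lambda o: (abs(o - b), o))
                    merged[near].extend(merged.pop(b))
                    self.merged_bins.append((b, near))
                    changed = True
                    break
        for b in bins:
            home = b
            seen = set()
            while home not in merged and home not in seen:
                seen.add(home)
                for src, dst in self.merged_bins:
                    if src == home:
                        home = dst
                        break
            self._bin_of[b] = home
        for b, vals in merged.items():
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            self._stats[b] = (float(arr.mean()), sd, len(arr))
        return self

    def lookup(self, maf: float) -> tuple[float, float]:
        b = self.bin_index(maf)
        if b not in self._bin_of:
            if not self._stats:
                raise KeyError("no MAF bins fitted")
            b2 = min(self._stats, key=lambda o: (abs(o - b), o))
        else:
            b2 = self._bin_of[b]
        mean, sd, _ = self._stats[b2]
        return mean, sd

    def items(self):
        return sorted(self._stats.items())


@dataclass
class SideScoreTable:
    """Per-chromosome side scores S = Σ_i ±|Δρ_i| over permutations."""

    scores: dict[str, float]
    grubbs_p: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScanConfig:
    """Scan-level settings (permutations, windows, gating, modes)."""

    n_perm: int = 200
    maf_min: float = 0.3
    span_snps: int = 200
    window_segments: int = 500
    trim_segments: int = 50
    shapiro_alpha: float = 0.05
    min_fraction: float = 0.3
    split_mode: str = "matched"  # or "half" (the 50/50 archive mode)
    keep_pairs: bool = False
    compare: str = "standardized"  # or "raw"
    pseudo_count: bool = False  # (k+1)/(n+1) p-value correction
    grubbs_p_threshold: float = 0.1
    # strengths inside splits/permutations use an unpenalized per-segment
    # fit: the changepoint penalty is a detection device and makes small-
    # subpanel strengths bimodal (peak kept or flattened), wrecking the
    # normality of random Δρ
    split_block_penalty: float = 0.0


# --------------------------------------------------------------------------
# elementary operations


def split_by_allele(
    panel: HaplotypePanel, snp: int
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Divide the panel rows by the allele carried at ``snp``."""
    col = panel.haplotypes[:, snp]
    if (col == col[0]).all():
        raise ValueError(f"SNP {snp} is monomorphic; cannot split")
    rows0 = np.flatnonzero(col == 0)
    rows1 = np.flatnonzero(col == 1)
    return panel.take_rows(rows0), panel.take_rows(rows1)


def delta_rho(rho0: float, rho1: float) -> float:
    """Normalized strength difference (ρ0 − ρ1)/(ρ0 + ρ1); 0 when both 0."""
    if rho0 < 0 or rho1 < 0:
        raise ValueError("hotspot strengths must be non-negative")
    tot = rho0 + rho1
    if tot == 0:
        return 0.0
    return (rho0 - rho1) / tot


def candidate_snps(
    panel: HaplotypePanel,
    hotspot: Hotspot,
    maf_min: float = 0.3,
    span_snps: int = 200,
) -> list[int]:
    """SNPs inside the hotspot plus ≤ ``span_snps`` beyond each boundary,
    keeping only polymorphic sites with MAF ≥ ``maf_min``."""
    pos = panel.positions
    lo, hi = panel.positions[0], panel.positions[-1]
    if hotspot.start < lo or hotspot.end > hi:
        raise ValueError("hotspot outside the panel span")
    first_in = int(np.searchsorted(pos, hotspot.start, side="left"))
    first_out = int(np.searchsorted(pos, hotspot.end, side="left"))
    a = max(0, first_in - span_snps)
    b = min(panel.n_snps, first_out + span_snps)
    out = []
    for i in range(a, b):
        if panel.is_monomorphic(i):
            continue
        if minor_allele_freq(panel, i) >= maf_min - 1e-12:
            out.append(i)
    return out


def random_split(
    panel: HaplotypePanel,
    min_fraction: float = 0.3,
    rng: np.random.Generator | int | None = None,
    sizes: tuple[int, int] | None = None,
    keep_pairs: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Random balanced split of the panel rows; returns two index arrays.

    The smaller side holds at least ``min_fraction`` of the chromosomes.
    When ``sizes`` is given, the split sizes are fixed to it; otherwise
    the size of side 0 is drawn uniformly over the feasible range.  With
    ``keep_pairs`` the two rows of one individual move together.
    """
    rng = np.random.default_rng(rng)
    n = panel.n_chromosomes
    if n < 4:
        raise ValueError("need at least 4 chromosomes to split")
    lo = int(np.ceil(min_fraction * n - 1e-9))
    hi = n - lo
    if lo > hi:
        raise ValueError(f"min_fraction={min_fraction} infeasible for n={n}")
    if sizes is not None:
        n0, n1 = sizes
        if n0 + n1 != n or min(n0, n1) < lo:
            raise ValueError(f"requested sizes {sizes} violate the {min_fraction:.0%} minimum")
    else:
        n0 = int(rng.integers(lo, hi + 1))
    if keep_pairs:
        if n % 2 or n0 % 2:
            raise ValueError("keep_pairs needs even panel and side sizes")
        pairs = rng.permutation(n // 2)
        rows = np.concatenate([[2 * p, 2 * p + 1] for p in pairs])
    else:
        rows = rng.permutation(n)
    return np.sort(rows[:n0]), np.sort(rows[n0:])


def _strength_for_rows(
    panel: HaplotypePanel,
    rows: np.ndarray,
    interval: tuple[float, float],
    config: EstimatorConfig,
) -> float:
    profile = estimate_rates(panel.take_rows(rows), config)
    return hotspot_strength(profile, interval)


def permutation_null(
    panel: HaplotypePanel,
    hotspot: Hotspot,
    estimator: EstimatorConfig,
    n_perm: int = 200,
    rng: np.random.Generator | int | None = None,
    sizes: tuple[int, int] | None = None,
    min_fraction: float = 0.3,
    keep_pairs: bool = False,
) -> PermutationNull:
    """Δρ distribution over ``n_perm`` random splits, boundaries fixed."""
    rng = np.random.default_rng(rng)
    n = panel.n_chromosomes
    deltas = np.empty(n_perm)
    membership = np.empty((n_perm, n), dtype=np.uint8)
    size_arr = np.empty((n_perm, 2), dtype=np.int64)
    interval = hotspot.interval
    for i in range(n_perm):
        r0, r1 = random_split(
            panel, min_fraction, rng, sizes=sizes, keep_pairs=keep_pairs
        )
        s0 = _strength_for_rows(panel, r0, interval, estimator)
        s1 = _strength_for_rows(panel, r1, interval, estimator)
        deltas[i] = delta_rho(s0, s1)
        membership[i] = 1
        membership[i, r0] = 0
        size_arr[i] = (len(r0), len(r1))
    if n_perm >= 3 and np.ptp(deltas) > 0:
        shapiro_p = float(sps.shapiro(deltas).pvalue)
    else:
        shapiro_p = 1.0
    return PermutationNull(hotspot, deltas, membership, size_arr, shapiro_p)


def normality_gate(null: PermutationNull, alpha: float = 0.05) -> bool:
    """True when the random-Δρ distribution is consistent with normality."""
    if null.n_perm < 3:
        raise ValueError("need at least 3 permutation deltas")
    return null.shapiro_p >= alpha


def maf_bin_stats(tests: list[SplitTest], n_chromosomes: int) -> MafBinStats:
    """Empirical E(Δρ) and SD(Δρ) per MAF bin from the scan's tests."""
    stats = MafBinStats(n_chromosomes)
    return stats.fit(
        [t.maf for t in tests], [t.delta_rho_freq_oriented for t in tests]
    )


def standardize(delta_freq_oriented: float, maf: float, stats: MafBinStats) -> float:
    """(Δρ − E(Δρ)) / SD(Δρ) within the SNP's MAF bin."""
    mean, sd = stats.lookup(maf)
    if sd == 0:
        raise ValueError(f"degenerate MAF bin at maf={maf}: SD is 0")
    return (delta_freq_oriented - mean) / sd


def association_p(
    observed: float, null_values: np.ndarray, pseudo_count: bool = False
) -> float:
    """Proportion of random |values| exceeding the observed |value|."""
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) == 0:
        raise ValueError("empty permutation null")
    k = int(np.sum(np.abs(null_values) > abs(observed)))
    if pseudo_count:
        return (k + 1) / (len(null_values) + 1)
    return k / len(null_values)


# --------------------------------------------------------------------------
# outlier chromosomes


def side_scores(null: PermutationNull, chromosome_ids: list[str]) -> SideScoreTable:
    """Sum of ±|Δρ_i|: + when the chromosome sat on the hotter side."""
    n = null.membership.shape[1]
    if len(chromosome_ids) != n:
        raise ValueError("chromosome_ids length mismatch")
    s = np.zeros(n)
    for d, side in zip(null.deltas, null.membership):
        if d == 0:
            continue
        hot_side = 0 if d > 0 else 1
        s += np.where(side == hot_side, abs(d), -abs(d))
    return SideScoreTable({cid: float(v) for cid, v in zip(chromosome_ids, s)})


def _grubbs_p(values: np.ndarray) -> tuple[int, float, float]:
    """Index, G statistic and two-sided p of the most extreme value."""
    n = len(values)
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        return 0, 0.0, 1.0
    dev = np.abs(values - mean)
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        return i, G, 0.0
    t = np.sqrt(n * (n - 2) * G * G / denom)
    p = min(1.0, 2 * n * float(sps.t.sf(t, n - 2)))
    return i, G, p


def grubbs_outliers(
    table: SideScoreTable, p_threshold: float = 0.1
) -> list[tuple[str, float]]:
    """Iterative one-at-a-time Grubbs outlier detection on side scores."""
    ids = list(table.scores)
    values = np.array([table.scores[c] for c in ids], dtype=float)
    if len(values) < 7:
        raise ValueError("Grubbs outlier detection needs at least 7 chromosomes")
    out: list[tuple[str, float]] = []
    while len(values) >= 7:
        i, _, p = _grubbs_p(values)
        if p >= p_threshold:
            break
        out.append((ids[i], p))
        table.grubbs_p[ids[i]] = p
        ids.pop(i)
        values = np.delete(values, i)
    return out


# --------------------------------------------------------------------------
# FDR


def qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with π0 estimated at one λ.

    π0 = #{p > λ} / ((1 − λ) m), clipped to (0, 1]; q for the i-th ranked
    p is min over j ≥ i of π0·m·p_(j)/j, so q is monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = np.sum(p > lambda_) / ((1.0 - lambda_) * m)
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# --------------------------------------------------------------------------
# distances


def pair_distances(
    panel: HaplotypePanel, hotspot: Hotspot, snp: int
) -> tuple[float, int]:
    """(signed bp to hotspot center, SNP count to the proximal boundary).

    Both are 0 when the SNP lies inside the hotspot; the bp distance is
    negative for SNPs left of the hotspot.
    """
    pos = panel.positions
    p = pos[snp]
    center = hotspot.peak_center
    if hotspot.start <= p < hotspot.end:
        return 0.0, 0
    if p < hotspot.start:
        between = int(np.sum((pos > p) & (pos < hotspot.start)))
        return float(p - center), between
    between = int(np.sum((pos > hotspot.end) & (pos < p)))
    return float(p - center), between


# --------------------------------------------------------------------------
# windowing and the scan


def _window_cols(
    panel: HaplotypePanel, center_snp: int, config: ScanConfig
) -> tuple[np.ndarray, tuple[float, float]]:
    """Sliding-window columns around a SNP, plus the trusted (trimmed) span.

    Windows span ``window_segments`` segments; when a window edge is
    interior to the panel, ``trim_segments`` segments at that edge are
    discarded from the trusted span (their rates depend on SNPs outside
    the window).
    """
    n_seg = panel.n_snps - 1
    w = config.window_segments
    if w >= n_seg:
        cols = np.arange(panel.n_snps)
        pos = panel.positions
        return cols, (float(pos[0]), float(pos[-1]))
    half = w // 2
    a = max(0, center_snp - half)
    b = min(n_seg, a + w)
    a = max(0, b - w)
    cols = np.arange(a, b + 1)
    pos = panel.positions
    lo_idx = a + (config.trim_segments if a > 0 else 0)
    hi_idx = b - (config.trim_segments if b < n_seg else 0)
    return cols, (float(pos[lo_idx]), float(pos[hi_idx]))


def _nearest_snp(panel: HaplotypePanel, bp: float) -> int:
    pos = panel.positions
    i = int(np.clip(np.searchsorted(pos, bp), 0, panel.n_snps - 1))
    if i > 0 and abs(pos[i - 1] - bp) < abs(pos[i] - bp):
        i -= 1
    return i


def _null_for(
    panel, hotspot, estimator, config, sizes, seed
) -> PermutationNull:
    center = _nearest_snp(panel, hotspot.peak_center)
    cols, core = _window_cols(panel, center, config)
    sub = panel.take_snps(cols)
    return permutation_null(
        sub,
        hotspot,
        replace(estimator, block_penalty=config.split_block_penalty),
        n_perm=config.n_perm,
        rng=seed,
        sizes=None if config.split_mode == "half" else sizes,
        min_fraction=config.min_fraction,
        keep_pairs=config.keep_pairs,
    )


def scan(
    panel: HaplotypePanel,
    hotspots: list[Hotspot],
    estimator: EstimatorConfig,
    config: ScanConfig = ScanConfig(),
    rng: np.random.Generator | int | None = None,
    snp_subset: list[int] | None = None,
) -> list[SplitTest]:
    """Run the full association scan.

    For every hotspot passing the normality gate and every candidate SNP
    (MAF ≥ 0.3 within 200 SNPs of the boundaries), computes the allele
    split Δρ in a sliding estimation window centered at the SNP, the
    MAF-standardized statistic, the permutation p-value against the
    hotspot's random-split null, and one global Storey q-value over all
    pairs.  Reproducible bit-for-bit given (panel, configs, seed).
    """
    seed_seq = np.random.SeedSequence(
        rng if isinstance(rng, (int, np.integer)) or rng is None else rng.integers(2**31)
    )
    master = np.random.default_rng(seed_seq)

    raw: list[SplitTest] = []
    nulls: dict[int, dict[tuple[int, int], PermutationNull]] = {}
    gate_null: dict[int, PermutationNull] = {}

    for hi_, hs in enumerate(hotspots):
        cands = candidate_snps(panel, hs, config.maf_min, config.span_snps)
        if snp_subset is not None:
            cands = [c for c in cands if c in set(snp_subset)]
        if not cands:
            continue
        # canonical (sorted) split sizes per candidate SNP
        sizes = {}
        for s in cands:
            n1 = int(panel.haplotypes[:, s].sum())
            sizes[s] = (panel.n_chromosomes - n1, n1)
        # gate on the null of the most common size
        size_counts: dict[tuple[int, int], int] = {}
        for sz in sizes.values():
            key = (min(sz), max(sz))
            size_counts[key] = size_counts.get(key, 0) + 1
        modal = sorted(size_counts, key=lambda k: (-size_counts[k], k))[0]
        hseed = int(master.integers(2**31))
        nulls[hi_] = {}
        null0 = _null_for(panel, hs, estimator, config, modal, hseed)
        nulls[hi_][modal] = null0
        gate_null[hi_] = null0
        if not normality_gate(null0, config.shapiro_alpha):
            continue

        for s in cands:
            key = (min(sizes[s]), max(sizes[s]))
            if key not in nulls[hi_]:
                nulls[hi_][key] = _null_for(
                    panel, hs, estimator, config, key, int(master.integers(2**31))
                )
            cols, core = _window_cols(panel, s, config)
            if hs.start < core[0] or hs.end > core[1]:
                continue  # hotspot outside the trusted part of this window
            sub = panel.take_snps(cols)
            est_s = replace(estimator, block_penalty=config.split_block_penalty)
            p0, p1 = split_by_allele(sub, int(np.searchsorted(cols, s)))
            s0 = hotspot_strength(estimate_rates(p0, est_s), hs.interval)
            s1 = hotspot_strength(estimate_rates(p1, est_s), hs.interval)
            d = delta_rho(s0, s1)
            n0, n1 = p0.n_chromosomes, p1.n_chromosomes
            d_freq = d if n0 >= n1 else -d
            dist_bp, dist_snps = pair_distances(panel, hs, s)
            raw.append(
                SplitTest(
                    hotspot=hs,
                    snp=s,
                    snp_id=panel.snps[s].snp_id,
                    rho0=s0,
                    rho1=s1,
                    delta_rho=d,
                    delta_rho_freq_oriented=d_freq,
                    n0=n0,
                    n1=n1,
                    maf=minor_allele_freq(panel, s),
                    dist_bp=dist_bp,
                    dist_snps=dist_snps,
                    shapiro_p=null0.shapiro_p,
                )
            )
            raw[-1]._null = nulls[hi_][key]  # type: ignore[attr-defined]

    if not raw:
        return raw

    stats = maf_bin_stats(raw, panel.n_chromosomes)
    for t in raw:
        null: PermutationNull = t._null  # type: ignore[attr-defined]
        use_z = config.compare == "standardized"
        if use_z:
            # the observed Δρ is standardized within its MAF bin (allele
            # splits of equal MAF); the permutation Δρ receive the same
            # treatment with respect to their own empirical distribution,
            # so both statistics are pivotal under the null
            nd = null.oriented_deltas()
            n_sd = nd.std(ddof=1)
            try:
                t.z = standardize(t.delta_rho_freq_oriented, t.maf, stats)
                if n_sd == 0:
                    raise ValueError("degenerate permutation null")
                null_z = (nd - nd.mean()) / n_sd
            except (ValueError, KeyError):
                use_z = False
        if use_z:
            t.p_value = association_p(t.z, null_z, config.pseudo_count)
        else:
            t.p_value = association_p(
                t.delta_rho, null.deltas, config.pseudo_count
            )
    qs = qvalues([t.p_value for t in raw])
    for t, q in zip(raw, qs):
        t.q_value = float(q)
    return raw


def null_scan(
    panel: HaplotypePanel,
    tests: list[SplitTest],
    estimator: EstimatorConfig,
    config: ScanConfig = ScanConfig(),
    rng: np.random.Generator | int | None = None,
) -> list[SplitTest]:
    """Size-matched random pseudo-split per real test (the null model scan)."""
    master = np.random.default_rng(rng)
    out: list[SplitTest] = []
    for t in tests:
        cols, core = _window_cols(panel, t.snp, config)
        sub = panel.take_snps(cols)
        r0, r1 = random_split(
            sub, config.min_fraction, master, sizes=(t.n0, t.n1)
        )
        est_s = replace(estimator, block_penalty=config.split_block_penalty)
        s0 = _strength_for_rows(sub, r0, t.hotspot.interval, est_s)
        s1 = _strength_for_rows(sub, r1, t.hotspot.interval, est_s)
        d = delta_rho(s0, s1)
        d_freq = d if t.n0 >= t.n1 else -d
        pt = replace(
            t,
            rho0=s0,
            rho1=s1,
            delta_rho=d,
            delta_rho_freq_oriented=d_freq,
            z=np.nan,
            p_value=np.nan,
            q_value=np.nan,
        )
        null: PermutationNull = t._null  # type: ignore[attr-defined]
        nd = null.oriented_deltas()
        n_sd = nd.std(ddof=1)
        try:
            # pseudo-splits are random splits: standardize against the
            # permutation distribution itself
            if n_sd == 0:
                raise ValueError("degenerate permutation null")
            pt.z = (d_freq - nd.mean()) / n_sd
            null_z = (nd - nd.mean()) / n_sd
            pt.p_value = association_p(pt.z, null_z, config.pseudo_count)
        except (ValueError, KeyError):
            pt.p_value = association_p(d, null.deltas, config.pseudo_count)
        out.append(pt)
    if out:
        qs = qvalues([t.p_value for t in out])
        for t, q in zip(out, qs):
            t.q_value = float(q)
    return out


def retest_without_outliers(
    panel: HaplotypePanel,
    hotspot: Hotspot,
    snp: int,
    outliers: list[str],
    estimator: EstimatorConfig,
    config: ScanConfig = ScanConfig(),
    rng: np.random.Generator | int | None = None,
) -> SplitTest:
    """Re-run one hotspot–SNP test after dropping outlier chromosomes."""
    missing = set(outliers) - set(panel.chromosome_ids)
    if missing:
        raise ValueError(f"outliers not in panel: {sorted(missing)}")
    keep = [i for i, cid in enumerate(panel.chromosome_ids) if cid not in set(outliers)]
    reduced = panel.take_rows(keep)
    col = reduced.haplotypes[:, snp]
    n1 = int(col.sum())
    n0 = len(col) - n1
    if min(n0, n1) < np.ceil(config.min_fraction * len(col) - 1e-9):
        raise ValueError(
            "outlier removal leaves a subpopulation below the "
            f"{config.min_fraction:.0%} minimum"
        )
    tests = scan(
        reduced, [hotspot], estimator, config, rng=rng, snp_subset=[snp]
    )
    if not tests:
        raise ValueError("retest produced no test (gate failure or no candidate)")
    return tests[0]


def write_tests_tsv(tests: list[SplitTest], path) -> None:
    """One row per hotspot–SNP pair with all test fields."""
    cols = [
        "hotspot_start", "hotspot_end", "hotspot_center", "snp_index", "snp_id",
        "maf", "n0", "n1", "rho0", "rho1", "delta_rho",
        "delta_rho_freq_oriented", "z", "p_value", "q_value", "shapiro_p",
        "dist_bp", "dist_snps",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in tests:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        t.hotspot.start, t.hotspot.end, t.hotspot.peak_center,
                        t.snp, t.snp_id, t.maf, t.n0, t.n1, t.rho0, t.rho1,
                        t.delta_rho, t.delta_rho_freq_oriented, t.z,
                        t.p_value, t.q_value, t.shapiro_p, t.dist_bp,
                        t.dist_snps,
                    ]
                )
                + "\n"
            )
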