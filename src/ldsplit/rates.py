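"""Population recombination-rate profiles from phased haplotype panels.

The estimator fills the role a composite-likelihood rate mapper (such as
LDhat's ``interval``) plays on real data: a per-segment population rate
ρ = 4·Ne·r between every pair of adjacent SNPs.  The allele-split contrast
downstream is a *normalized within-run* difference, so what matters is
that the identical estimator is applied to both subpopulations and to all
permutation splits — not absolute-scale agreement with any particular
external mapper.  Externally produced profiles can be supplied through the
TSV interface instead.

The built-in estimator models each haplotype as a mosaic of previously
seen haplotypes (the product-of-approximate-conditionals, or PAC,
likelihood).  Copying switches between templates at a per-segment
exponential rate proportional to ρ; expectation-maximization alternates a
forward-backward E-step (expected switch events per segment) with an
M-step that refits a piecewise-constant rate under a per-changepoint
penalty (``block_penalty``), solved exactly by dynamic programming.  All
stochasticity (the haplotype orderings averaged in the composite
likelihood) derives from one seed, and rows are canonicalized first, so a
profile is reproducible bit-for-bit and invariant to row order.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from ._pac import accumulate_expectations, segment_dp
from .panel import HaplotypePanel

__all__ = [
    "EstimatorConfig",
    "RateProfile",
    "estimate_rates",
    "hotspot_strength",
    "rho_to_cm_per_mb",
    "write_rate_profile",
    "read_rate_profile",
    "MIN_CHROMOSOMES",
]

MIN_CHROMOSOMES = 10


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings of the PAC rate estimator.

    n_orderings : haplotype orderings averaged in the composite likelihood.
    block_penalty : per-changepoint cost on the piecewise-constant rate;
        larger values give flatter maps.
    n_iterations : EM iterations.
    effective_pop_size : Ne used only to convert ρ to cM/Mb.
    rho_floor, rho_ceil : clamp on per-kb rates (the estimator's boundary).
    """

    n_orderings: int = 2
    block_penalty: float = 5.0
    n_iterations: int = 30
    effective_pop_size: int = 10_000
    seed: int = 0
    rho_floor: float = 1e-3
    rho_ceil: float = 500.0

    def __post_init__(self) -> None:
        if self.n_orderings < 1 or self.n_iterations < 1:
            raise ValueError("n_orderings and n_iterations must be >= 1")
        if self.block_penalty < 0:
            raise ValueError("block_penalty must be non-negative")


@dataclass
class RateProfile:
    """Piecewise-constant rate map: one segment per adjacent SNP pair."""

    segment_starts: np.ndarray  # bp, one per segment
    segment_ends: np.ndarray  # bp, half-open
    rho_per_kb: np.ndarray  # population rate per kb of each segment
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segment_starts = np.asarray(self.segment_starts, dtype=np.float64)
        self.segment_ends = np.asarray(self.segment_ends, dtype=np.float64)
        self.rho_per_kb = np.asarray(self.rho_per_kb, dtype=np.float64)
        ns = len(self.segment_starts)
        if not (len(self.segment_ends) == len(self.rho_per_kb) == ns):
            raise ValueError("segment arrays must have equal length")
        if (self.rho_per_kb < 0).any():
            raise ValueError("rates must be non-negative")
        if ns > 1 and not np.allclose(self.segment_starts[1:], self.segment_ends[:-1]):
            raise ValueError("segments must tile the SNP span without gaps")

    @property
    def n_segments(self) -> int:
        return len(self.rho_per_kb)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.segment_starts[0]), float(self.segment_ends[-1])

    @property
    def lengths_kb(self) -> np.ndarray:
        return (self.segment_ends - self.segment_starts) / 1000.0

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.segment_starts + self.segment_ends)


def _panel_hash(h: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(h).tobytes()).hexdigest()[:12]


def estimate_rates(panel: HaplotypePanel, config: EstimatorConfig) -> RateProfile:
    """Fit a per-segment rate profile to a phased panel.

    Deterministic given (panel, config) and invariant to haplotype row
    order: rows are put in canonical (lexicographic) order before the
    seeded orderings are applied.
    """
    if panel.n_chromosomes < MIN_CHROMOSOMES:
        raise ValueError(
            f"panel has {panel.n_chromosomes} chromosomes; rate estimation on "
            f"fewer than {MIN_CHROMOSOMES} is unreliable — enlarge the "
            "subpopulation or relax the candidate-SNP MAF bound"
        )
    if panel.n_snps < 3:
        raise ValueError("need at least 3 SNPs to estimate a rate profile")

    H0 = panel.haplotypes
    # canonical row order -> row-order invariance
    order = np.lexsort(H0.T[::-1])
    H0 = np.ascontiguousarray(H0[order])
    pos = panel.positions.astype(np.float64)
    d_kb = np.diff(pos) / 1000.0
    d_kb = np.maximum(d_kb, 1e-6)

    rng = np.random.default_rng(config.seed)
    orderings = [rng.permutation(H0.shape[0]) for _ in range(config.n_orderings)]

    rho = np.full(panel.n_snps - 1, 1.0)
    loglik = -np.inf
    for _ in range(config.n_iterations):
        counts = np.zeros_like(rho)
        expo = np.zeros_like(rho)
        ll = 0.0
        for perm in orderings:
            H = np.ascontiguousarray(H0[perm])
            ll += accumulate_expectations(H, d_kb, rho, counts, expo)
        rho = segment_dp(
            counts, expo, config.block_penalty, config.rho_floor, config.rho_ceil
        )
        if abs(ll - loglik) < 1e-6 * max(1.0, abs(ll)):
            loglik = ll
            break
        loglik = ll

    return RateProfile(
        segment_starts=pos[:-1],
        segment_ends=pos[1:],
        rho_per_kb=rho,
        meta={
            "estimator": "pac-em-dp",
            "seed": config.seed,
            "panel_hash": _panel_hash(panel.haplotypes),
            "loglik": float(loglik),
            "n_orderings": config.n_orderings,
            "block_penalty": config.block_penalty,
        },
    )


def hotspot_strength(profile: RateProfile, interval: tuple[float, float]) -> float:
    """Recombination activity of an interval: Σ ρ_per_kb × overlap (kb).

    Partial segment overlaps are pro-rated; a zero-length interval has
    strength 0.  The interval must lie within the profile span.
    """
    start, end = interval
    if end < start:
        raise ValueError(f"inverted interval [{start}, {end})")
    lo, hi = profile.span
    if start < lo - 1e-9 or end > hi + 1e-9:
        raise ValueError(f"interval [{start}, {end}) outside profile span [{lo}, {hi})")
    ov = np.minimum(profile.segment_ends, end) - np.maximum(
        profile.segment_starts, start
    )
    ov = np.maximum(ov, 0.0) / 1000.0
    return float(np.sum(profile.rho_per_kb * ov))


def rho_to_cm_per_mb(rho_per_kb: float, Ne: int) -> float:
    """Convert a per-kb population rate ρ = 4·Ne·r to cM/Mb."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    r_per_bp = rho_per_kb / (4.0 * Ne * 1000.0)
    return r_per_bp * 1e8


def write_rate_profile(profile: RateProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for k, v in profile.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("start\tend\trho_per_kb\n")
        for s, e, r in zip(
            profile.segment_starts, profile.segment_ends, profile.rho_per_kb
        ):
            fh.write(f"{s:.0f}\t{e:.0f}\t{r:.8g}\n")


def read_rate_profile(path: str | os.PathLike) -> RateProfile:
    """Read a rate-profile TSV (also the entry point for external maps)."""
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
                continue
            parts = line.split()
            if not parts or parts[0] == "start":
                continue
            rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
    if not rows:
        raise ValueError(f"{path}: empty rate profile")
    arr = np.array(rows)
    return RateProfile(arr[:, 0], arr[:, 1], arr[:, 2], meta)
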