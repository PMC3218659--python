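"""Scoring scan output against simulation truth.

Two views of performance: how often the allele split orders the causal
SNP's hot and cold alleles correctly (direction accuracy), and a tag-SNP
confusion matrix in which LD blocks (r² ≥ 0.8) de-duplicate linked
signals — the causal SNP is the only "true" tag, a tag is "positive" when
its permutation p-value is below α.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import SplitTest
from .panel import LdBlock

__all__ = [
    "ConfusionCounts",
    "direction_accuracy",
    "classify_tests",
    "metrics",
    "causal_split_strengths",
    "simulated_direction_benchmark",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


def causal_split_strengths(
    sample,
    estimator,
    Ne: int,
    hotspot_center: float,
    match_within_bp: float = 25_000.0,
) -> tuple[float, float] | None:
    """(hot-allele strength, cold-allele strength) at the causal SNP.

    Runs the benchmark protocol on one simulated sample: estimate the
    combined-panel rate profile, call hotspots, match the call nearest
    the true hotspot center (within ``match_within_bp``), split the
    panel at the causal SNP and measure each side's strength on the
    fixed call boundaries.  Calling uses the (penalized) ``estimator``
    as given; the per-side strengths use its unpenalized variant, as in
    the association scan.  Returns None for flagged samples (causal
    MAF < 0.3) and samples without a matching hotspot call.
    """
    from dataclasses import replace

    from .association import split_by_allele
    from .hotspots import call_hotspots
    from .rates import estimate_rates, hotspot_strength

    if sample.flagged:
        return None
    panel = sample.panel
    profile = estimate_rates(panel, estimator)
    calls = call_hotspots(profile, Ne=Ne)
    calls = [
        h
        for h in calls
        if h.start <= hotspot_center < h.end
        or abs(h.peak_center - hotspot_center) <= match_within_bp
    ]
    if not calls:
        return None
    hs = min(calls, key=lambda h: abs(h.peak_center - hotspot_center))
    est_s = replace(estimator, block_penalty=0.0)
    p0, p1 = split_by_allele(panel, sample.causal_snp)
    s0 = hotspot_strength(estimate_rates(p0, est_s), hs.interval)
    s1 = hotspot_strength(estimate_rates(p1, est_s), hs.interval)
    if sample.hot_allele == 1:
        return s1, s0
    return s0, s1


def simulated_direction_benchmark(
    seed: int,
    n_populations: int = 10,
    n_samples: int = 5,
    pop_size: int = 1000,
    generations: int = 500,
    subset_size: int = 90,
    end_hot_freq: float = 0.5,
    estimator=None,
) -> dict:
    """Direction accuracy of the allele split on the forward benchmark.

    Simulates ``n_populations`` populations under the normal condition
    (single causal mutation, cooling model, BGC probability 0.5, 500-bp
    mean tract) at the given scale, draws ``n_samples`` panels of
    ``subset_size`` individuals from each, and scores a sample correct
    when the hot-allele subpopulation's estimated hotspot strength
    exceeds the cold-allele one.  Returns per-population percentages and
    their mean; samples with causal MAF < 0.3 or no matching hotspot
    call are not evaluated.
    """
    import numpy as np

    from .rates import EstimatorConfig
    from .simulate import SimConfig, evolve, sample_panels

    if estimator is None:
        estimator = EstimatorConfig(seed=0)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_populations) % (2**31)
    per_pop = []
    n_correct = n_eval = 0
    for i in range(n_populations):
        cfg = SimConfig(
            pop_size=pop_size,
            generations=generations,
            start_hot_freq=1.0,
            end_hot_freq=end_hot_freq,
            seed=int(seeds[2 * i]),
        )
        pop, _ = evolve(cfg)
        samples = sample_panels(
            pop,
            cfg,
            rng=int(seeds[2 * i + 1]),
            n_subsets=n_samples,
            subset_size=subset_size,
        )
        correct = evaluated = 0
        for s in samples:
            r = causal_split_strengths(
                s, estimator, Ne=pop_size, hotspot_center=cfg.hotspot_center
            )
            if r is None:
                continue
            evaluated += 1
            if r[0] > r[1]:
                correct += 1
        if evaluated:
            per_pop.append(100.0 * correct / evaluated)
            n_correct += correct
            n_eval += evaluated
    return {
        "per_population_pct": per_pop,
        "mean_pct": float(np.mean(per_pop)) if per_pop else float("nan"),
        "n_correct": n_correct,
        "n_evaluated": n_eval,
    }


def hot_cold_strengths(test: SplitTest, hot_allele: int) -> tuple[float, float]:
    """(hot-allele strength, cold-allele strength) for a causal-SNP test."""
    if hot_allele == 1:
        return test.rho1, test.rho0
    return test.rho0, test.rho1


def direction_accuracy(tests: list[SplitTest], hot_allele: int = 1) -> float:
    """Fraction of samples whose hot-allele side shows the larger strength.

    Each element of ``tests`` is the causal-SNP test of one evaluated
    sample (samples with causal MAF < 0.3 are excluded upstream).  Ties
    count as incorrect (strict inequality).
    """
    if not tests:
        raise ValueError("no evaluated samples")
    correct = 0
    for t in tests:
        hot, cold = hot_cold_strengths(t, hot_allele)
        if hot > cold:
            correct += 1
    return correct / len(tests)


def classify_tests(
    tests: list[SplitTest],
    causal_snp: int,
    blocks: list[LdBlock],
    alpha: float = 0.05,
) -> ConfusionCounts:
    """Tag-SNP confusion counts over the LD blocks of one sample.

    Per block the tag is the causal SNP if it is a member, otherwise the
    member with the smallest p-value (ties → smallest SNP index).  A tag
    is true iff it is the causal SNP and positive iff p < ``alpha``.
    """
    by_snp = {t.snp: t for t in tests}
    counts = ConfusionCounts()
    for block in blocks:
        members = [s for s in block.member_snps if s in by_snp]
        if not members:
            continue
        if causal_snp in members:
            tag = causal_snp
        else:
            tag = min(members, key=lambda s: (by_snp[s].p_value, s))
        positive = by_snp[tag].p_value < alpha
        true = tag == causal_snp
        if true and positive:
            counts.TP += 1
        elif true:
            counts.FN += 1
        elif positive:
            counts.FP += 1
        else:
            counts.TN += 1
    return counts


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP).

    A ratio with zero denominator is reported as None, not 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(counts.TP, counts.TP + counts.FN),
        "specificity": ratio(counts.TN, counts.TN + counts.FP),
        "ppv": ratio(counts.TP, counts.TP + counts.FP),
    }
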