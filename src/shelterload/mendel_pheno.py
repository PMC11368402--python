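"""Permutation tests for segregation distortion and homozygote phenotype contrasts.

Tests the proportion of S-locus homozygotes among offspring reaching the
reproductive stage against the Mendelian expectation (25% for two
heterozygous parents sharing one allele, 50% when one parent is
homozygous) with Monte-Carlo segregation replicates, contrasts phenotype
means between S-locus homozygotes and their heterozygous full sibs with
label permutations, and screens binary covariates whose group contrast
exceeds the permutation 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "SegregationTestResult",
    "expected_hom_fraction",
    "segregation_test",
    "carrier_test",
    "phenotype_contrast",
    "covariate_screen",
]

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class SegregationTestResult:
    n_offspring: int
    n_homozygotes: int
    expected_proportion: float
    observed_proportion: float
    ratio: float  # observed / expected proportion
    p_value: float  # Monte-Carlo one-sided lower tail
    p_exact: float  # exact binomial lower tail (cross-check)
    p_randomized: float | None
    n_permutations: int
    seed: int


def expected_hom_fraction(parent1_s, parent2_s, focal_allele) -> float:
    """Mendelian probability of a focal-allele homozygote offspring.

    Equals P(parent1 transmits focal) * P(parent2 transmits focal); the
    focal allele must be present in both parents (0.25 for het x het,
    0.5 for hom x het, 1.0 for hom x hom).
    """
    p1, p2 = tuple(parent1_s), tuple(parent2_s)
    for label, parent in (("parent1", p1), ("parent2", p2)):
        if focal_allele not in parent:
            raise ValueError(f"focal allele {focal_allele!r} absent from {label} {parent}")
    return (p1.count(focal_allele) / 2.0) * (p2.count(focal_allele) / 2.0)


def segregation_test(
    n_offspring: int,
    n_homozygotes: int,
    expected_p: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    randomized: bool = False,
) -> SegregationTestResult:
    """One-sided lower-tail Monte-Carlo test of a homozygote deficit.

    Simulates ``n_perm`` Mendelian segregation replicates
    Binomial(n_offspring, expected_p); the p-value is the fraction of
    replicates with a homozygote count <= observed. The exact binomial
    lower tail is returned alongside as a cross-check. With
    ``randomized=True`` a continuity-randomised p-value
    P(X < obs) + U * P(X = obs), which is exactly Uniform(0,1) under the
    null, is additionally reported (used for calibration checks).
    """
    if not (0 <= n_homozygotes <= n_offspring):
        raise ValueError("need 0 <= n_homozygotes <= n_offspring")
    if not (0.0 < expected_p < 1.0):
        raise ValueError("expected_p must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_offspring, expected_p, size=n_perm)
    p_mc = float(np.mean(draws <= n_homozygotes))
    p_exact = float(binom.cdf(n_homozygotes, n_offspring, expected_p))
    p_rand = None
    if randomized:
        below = float(binom.cdf(n_homozygotes - 1, n_offspring, expected_p))
        pmf = float(binom.pmf(n_homozygotes, n_offspring, expected_p))
        p_rand = below + float(rng.random()) * pmf
    observed = n_homozygotes / n_offspring
    return SegregationTestResult(
        n_offspring=n_offspring,
        n_homozygotes=n_homozygotes,
        expected_proportion=expected_p,
        observed_proportion=observed,
        ratio=observed / expected_p,
        p_value=p_mc,
        p_exact=p_exact,
        p_randomized=p_rand,
        n_permutations=n_perm,
        seed=seed,
    )


def carrier_test(
    n_with_focal: int,
    n_heterozygotes: int,
    expected: float = 2.0 / 3.0,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Two-sided Monte-Carlo test of the focal-carrier fraction among heterozygotes.

    Under Mendelian segregation the focal S-allele is carried by 2/3 of
    the heterozygous offspring of a het x het cross sharing that allele.
    The p-value is the fraction of Binomial(n, expected) draws deviating
    from the expectation by at least the observed absolute deviation.
    """
    if n_heterozygotes <= 0:
        raise ValueError("no heterozygotes to test")
    if not (0 <= n_with_focal <= n_heterozygotes):
        raise ValueError("inconsistent counts")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_heterozygotes, expected, size=n_perm)
    obs_dev = abs(n_with_focal - expected * n_heterozygotes)
    p = float(np.mean(np.abs(draws - expected * n_heterozygotes) >= obs_dev - 1e-12))
    return {
        "observed_fraction": n_with_focal / n_heterozygotes,
        "expected": expected,
        "p_value": p,
        "n_permutations": n_perm,
        "seed": seed,
    }


def phenotype_contrast(
    values,
    labels,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Homozygote vs heterozygote phenotype contrast by label permutation.

    ``labels`` are "hom"/"het" per value. The statistic reported is the
    homozygote mean normalised by the heterozygote mean (and the raw
    difference); the two-sided p-value is the fraction of label
    permutations whose |mean difference| is at least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    hom = values[labels == "hom"]
    het = values[labels == "het"]
    if len(hom) < 2 or len(het) < 2:
        raise ValueError("need >= 2 values per group")
    obs_diff = hom.mean() - het.mean()
    ratio = float(hom.mean() / het.mean()) if het.mean() != 0 else float("nan")
    rng = np.random.default_rng(seed)
    n_hom = len(hom)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        d = perm[:n_hom].mean() - perm[n_hom:].mean()
        if abs(d) >= abs(obs_diff) - 1e-12:
            count += 1
    return {
        "normalized": ratio,
        "difference": float(obs_diff),
        "ratio_defined": het.mean() != 0,
        "p_value": (count + 1) / (n_perm + 1),
        "n_permutations": n_perm,
        "seed": seed,
    }


def covariate_screen(
    values,
    covariate,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Flag a binary covariate whose group contrast beats the permutation 95th pct.

    The observed |difference in trait means| between the two covariate
    levels is compared to the distribution of the same statistic under
    random redistribution of the trait values into groups of the observed
    sizes; the covariate is flagged (to be used as an adjustment term
    downstream) when the observed difference exceeds the 95th percentile.
    """
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covariate)
    levels = np.unique(cov)
    if len(levels) != 2:
        raise ValueError("covariate must have exactly two observed levels")
    g1 = values[cov == levels[0]]
    g2 = values[cov == levels[1]]
    obs = abs(g1.mean() - g2.mean())
    rng = np.random.default_rng(seed)
    n1 = len(g1)
    perm_stats = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(values)
        perm_stats[k] = abs(perm[:n1].mean() - perm[n1:].mean())
    threshold = float(np.percentile(perm_stats, 95))
    p = float((np.sum(perm_stats >= obs - 1e-12) + 1) / (n_perm + 1))
    return {
        "flagged": bool(obs > threshold),
        "observed_difference": float(obs),
        "threshold_95": threshold,
        "p_value": p,
        "n_permutations": n_perm,
        "seed": seed,
    }
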