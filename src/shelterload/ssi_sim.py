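"""Forward-time simulator of sporophytic self-incompatibility with linked load.

A panmictic diploid population of constant census size evolves with
non-overlapping generations. Each individual carries two fully linked
haplotypes, each consisting of an S-allele (self-incompatibility
specificity) and a vector of L biallelic positions where fully recessive
deleterious mutations accumulate (the "D-locus"). Pollen expression of
S-alleles follows a linear dominance hierarchy between classes
(I < II < III < IV) with codominance within classes; the pistil side is
codominant by default. Zygotes survive with probability (1 - s)^n where
n is the number of positions homozygous for the deleterious allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SAlleleDef",
    "DominanceHierarchy",
    "SimParams",
    "PopulationState",
    "EquilibriumResult",
    "LineageLoadSummary",
    "default_hierarchy",
    "pollen_phenotype",
    "pistil_phenotype",
    "is_compatible",
    "zygote_survival_prob",
    "deterministic_equilibrium",
    "initial_population",
    "step_generation",
    "run_replicates",
    "summarize_load",
]

#: Default roster: 8 alleles of class IV, 3 of class III, 2 of class II, 1 of class I.
DEFAULT_CLASS_COUNTS = {4: 8, 3: 3, 2: 2, 1: 1}


class UnknownAlleleError(KeyError):
    """An S-allele label is absent from the dominance hierarchy."""


class MatingImpossibleError(RuntimeError):
    """No compatible father could be found after bounded rejection attempts."""


@dataclass(frozen=True)
class SAlleleDef:
    """One self-incompatibility specificity and its dominance class (1..4)."""

    id: str
    dominance_class: int

    def __post_init__(self) -> None:
        if self.dominance_class not in (1, 2, 3, 4):
            raise ValueError(
                f"dominance_class must be in 1..4, got {self.dominance_class}"
            )


@dataclass(frozen=True)
class DominanceHierarchy:
    """Roster of S-alleles ordered by dominance class.

    Between classes the pollen dominance relation is a strict linear order
    (class 1 most recessive, class 4 most dominant); within a class alleles
    are codominant.
    """

    alleles: tuple[SAlleleDef, ...]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.alleles]
        if len(set(ids)) != len(ids):
            raise ValueError("S-allele ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.alleles]

    def dominance_class(self, allele_id: str) -> int:
        for a in self.alleles:
            if a.id == allele_id:
                return a.dominance_class
        raise UnknownAlleleError(f"unknown S-allele label: {allele_id!r}")

    def index(self, allele_id: str) -> int:
        for i, a in enumerate(self.alleles):
            if a.id == allele_id:
                return i
        raise UnknownAlleleError(f"unknown S-allele label: {allele_id!r}")

    def class_array(self) -> np.ndarray:
        return np.array([a.dominance_class for a in self.alleles], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.alleles)


def default_hierarchy(class_counts: dict[int, int] | None = None) -> DominanceHierarchy:
    """Build the default 14-allele roster (8 class IV, 3 III, 2 II, 1 I).

    Allele ids are ``S<class>_<k>``, e.g. ``S4_1 .. S4_8``.
    """
    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    alleles = []
    for cls in sorted(counts):
        for k in range(counts[cls]):
            alleles.append(SAlleleDef(id=f"S{cls}_{k + 1}", dominance_class=cls))
    return DominanceHierarchy(alleles=tuple(alleles))


@dataclass(frozen=True)
class SimParams:
    """Configuration of one simulation experiment."""

    N: int = 10_000
    L: int = 100
    mu_forward: float = 1e-4
    mu_back: float = 1e-5
    s: float = 0.01
    h: float = 0.0
    n_generations: int = 100_000
    burn_in: int = 0
    record_every: int = 1000
    n_replicates: int = 100
    seed: int = 0
    hierarchy: DominanceHierarchy = field(default_factory=default_hierarchy)
    eq_tolerance: float = 1e-3
    pistil_dominance: bool = False
    max_mating_attempts: int = 10_000
    summary_max_copies: int | None = None  # equal-subsample load summaries

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.mu_back <= self.mu_forward < 1.0):
            raise ValueError("require 0 <= mu_back <= mu_forward < 1")
        if not (0.0 < self.s < 1.0):
            raise ValueError("require 0 < s < 1")
        if self.h != 0.0:
            raise ValueError("only fully recessive deleterious mutations (h=0) are modelled")
        if self.eq_tolerance <= 0:
            raise ValueError("eq_tolerance must be positive")


@dataclass
class PopulationState:
    """Population at one generation.

    ``s_geno`` has shape (N, 2) holding hierarchy indices of the S-alleles;
    ``d_geno`` has shape (N, 2, L) holding 0/1 deleterious states. Haplotype
    k of individual i is the pair (s_geno[i, k], d_geno[i, k, :]).
    """

    generation: int
    s_geno: np.ndarray
    d_geno: np.ndarray

    @property
    def N(self) -> int:
        return self.s_geno.shape[0]

    @property
    def L(self) -> int:
        return self.d_geno.shape[2]


@dataclass(frozen=True)
class EquilibriumResult:
    allele_freqs: dict[str, float]
    genotype_freqs: np.ndarray  # over unordered genotypes, see genotype_list
    genotype_list: tuple[tuple[int, int], ...]
    iterations: int
    converged: bool


@dataclass(frozen=True)
class LineageLoadSummary:
    """Fixed / segregating / total deleterious counts among copies of one S-allele."""

    s_allele: str
    dominance_class: int
    n_copies: int
    n_fixed: int | None  # None when undefined (fewer than 2 copies)
    n_segregating: int | None
    n_total: int


# ---------------------------------------------------------------------------
# phenotypes and compatibility


def _genotype_classes(genotype, hierarchy: DominanceHierarchy):
    a, b = genotype
    return hierarchy.dominance_class(a), hierarchy.dominance_class(b)


def pollen_phenotype(genotype, hierarchy: DominanceHierarchy) -> frozenset[str]:
    """S-alleles expressed by pollen of an individual with this genotype.

    Alleles of the higher dominance class mask those of lower classes;
    alleles of equal class are codominant (both expressed).
    """
    a, b = genotype
    ca, cb = _genotype_classes(genotype, hierarchy)
    if ca > cb:
        return frozenset([a])
    if cb > ca:
        return frozenset([b])
    return frozenset([a, b])


def pistil_phenotype(
    genotype, hierarchy: DominanceHierarchy, pistil_dominance: bool = False
) -> frozenset[str]:
    """S-alleles expressed by the pistil: codominant unless ``pistil_dominance``."""
    if pistil_dominance:
        return pollen_phenotype(genotype, hierarchy)
    a, b = genotype
    _genotype_classes(genotype, hierarchy)  # label validation
    return frozenset([a, b])


def is_compatible(
    pistil_genotype,
    pollen_parent_genotype,
    hierarchy: DominanceHierarchy,
    pistil_dominance: bool = False,
) -> bool:
    """True iff pollen from the pollen parent can fertilise the pistil.

    Fertilisation happens when no S-allele expressed by the pollen is also
    expressed by the pistil.
    """
    pol = pollen_phenotype(pollen_parent_genotype, hierarchy)
    pis = pistil_phenotype(pistil_genotype, hierarchy, pistil_dominance)
    return len(pol & pis) == 0


def zygote_survival_prob(d_hap1: np.ndarray, d_hap2: np.ndarray, s: float) -> float:
    """(1 - s)^n with n the number of positions homozygous deleterious."""
    if not (0.0 < s < 1.0):
        raise ValueError("require 0 < s < 1")
    n = int(np.sum(np.asarray(d_hap1, bool) & np.asarray(d_hap2, bool)))
    return (1.0 - s) ** n


# ---------------------------------------------------------------------------
# deterministic S-allele equilibrium


def _unordered_genotypes(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def _compat_matrix(hierarchy: DominanceHierarchy, pistil_dominance: bool) -> np.ndarray:
    """compat[m, f]=1 iff pollen of genotype f is accepted by pistil of genotype m."""
    ids = hierarchy.ids
    genos = _unordered_genotypes(len(ids))
    out = np.zeros((len(genos), len(genos)), dtype=bool)
    for mi, (m1, m2) in enumerate(genos):
        for fi, (f1, f2) in enumerate(genos):
            out[mi, fi] = is_compatible(
                (ids[m1], ids[m2]), (ids[f1], ids[f2]), hierarchy, pistil_dominance
            )
    return out


def deterministic_equilibrium(
    hierarchy: DominanceHierarchy,
    eq_tolerance: float = 1e-3,
    max_iter: int = 100_000,
    pistil_dominance: bool = False,
) -> EquilibriumResult:
    """Iterate the deterministic SSI genotype-frequency recursion to equilibrium.

    Mothers contribute equally; each mother's ovules are fertilised by
    compatible fathers in proportion to their genotype frequency; both
    parents transmit each of their two alleles with probability 1/2.
    Convergence: max per-allele frequency change < ``eq_tolerance``.
    """
    k = len(hierarchy)
    if k < 2:
        raise ValueError("need at least 2 S-alleles")
    genos = _unordered_genotypes(k)
    n_g = len(genos)
    compat = _compat_matrix(hierarchy, pistil_dominance)
    geno_index = {g: gi for gi, g in enumerate(genos)}

    # trans[f, g_off] for a (mother, father) pair is built on the fly from
    # allele transmission; precompute per-genotype transmitted-allele dists.
    trans_allele = np.zeros((n_g, k))
    for gi, (i, j) in enumerate(genos):
        trans_allele[gi, i] += 0.5
        trans_allele[gi, j] += 0.5

    # start from uniform genotype frequencies over heterozygotes
    freqs = np.array([0.0 if i == j else 1.0 for (i, j) in genos])
    freqs /= freqs.sum()

    def allele_freqs(gf: np.ndarray) -> np.ndarray:
        af = np.zeros(k)
        for gi, (i, j) in enumerate(genos):
            af[i] += 0.5 * gf[gi]
            af[j] += 0.5 * gf[gi]
        return af

    pair_to_geno = np.empty((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(k):
            pair_to_geno[i, j] = geno_index[(min(i, j), max(i, j))]

    prev_af = allele_freqs(freqs)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new = np.zeros(n_g)
        for mi in range(n_g):
            if freqs[mi] == 0.0:
                continue
            w = freqs * compat[mi]
            tot = w.sum()
            if tot == 0.0:
                continue  # mother cannot be fertilised; contributes no seed
            father_dist = w / tot
            # transmitted allele distribution of the father pool
            pat = father_dist @ trans_allele
            mat = trans_allele[mi]
            contrib = freqs[mi] * np.outer(mat, pat)
            np.add.at(new, pair_to_geno.ravel(), contrib.ravel())
        total = new.sum()
        if total == 0.0:
            # no compatible mating exists (e.g. two codominant alleles only):
            # frequencies cannot change, so the fixed point is the current state
            converged = True
            break
        new /= total
        af = allele_freqs(new)
        delta = np.max(np.abs(af - prev_af))
        freqs, prev_af = new, af
        if delta < eq_tolerance:
            converged = True
            break

    return EquilibriumResult(
        allele_freqs={hierarchy.ids[i]: float(prev_af[i]) for i in range(k)},
        genotype_freqs=freqs,
        genotype_list=tuple(genos),
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# stochastic machinery


def initial_population(
    params: SimParams, rng: np.random.Generator, equilibrium: EquilibriumResult | None = None
) -> PopulationState:
    """Sample N S-genotypes from the deterministic equilibrium; D-locus all zero."""
    if equilibrium is None:
        equilibrium = deterministic_equilibrium(
            params.hierarchy, params.eq_tolerance, pistil_dominance=params.pistil_dominance
        )
    genos = equilibrium.genotype_list
    draws = rng.choice(len(genos), size=params.N, p=equilibrium.genotype_freqs)
    s_geno = np.array([genos[d] for d in draws], dtype=np.int64)
    # randomise haplotype order so hap slots are exchangeable
    flip = rng.random(params.N) < 0.5
    s_geno[flip] = s_geno[flip][:, ::-1]
    d_geno = np.zeros((params.N, 2, params.L), dtype=bool)
    return PopulationState(generation=0, s_geno=s_geno, d_geno=d_geno)


def _pollen_expressed(s_geno: np.ndarray, classes: np.ndarray):
    """Expressed pollen alleles for each genotype row; returns (e1, e2).

    When classes differ both entries equal the dominant allele, so membership
    tests against {e1, e2} implement the expressed set.
    """
    a1, a2 = s_geno[:, 0], s_geno[:, 1]
    c1, c2 = classes[a1], classes[a2]
    e1 = np.where(c1 >= c2, a1, a2)
    e2 = np.where(c2 >= c1, a2, a1)
    return e1, e2


def _mutate_gametes(g: np.ndarray, mu_f: float, mu_b: float, rng: np.random.Generator):
    if mu_f == 0.0 and mu_b == 0.0:
        return g
    r = rng.random(g.shape)
    gained = (~g) & (r < mu_f)
    lost = g & (r < mu_b)
    return (g | gained) & ~lost


def step_generation(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """Produce the next generation of exactly N surviving offspring.

    For each offspring slot: a mother is sampled uniformly; fathers are
    sampled uniformly with rejection until pollen-pistil compatible; each
    parent transmits one haplotype uniformly at random; per-position
    mutation is applied to the transmitted gametes; the zygote survives
    with probability (1 - s)^n, otherwise the whole mating is redrawn.
    """
    N, L = state.N, state.L
    classes = params.hierarchy.class_array()
    s_geno, d_geno = state.s_geno, state.d_geno
    if params.pistil_dominance:
        pis1, pis2 = _pollen_expressed(s_geno, classes)
    else:
        pis1, pis2 = s_geno[:, 0], s_geno[:, 1]
    pol1, pol2 = _pollen_expressed(s_geno, classes)

    out_s = np.empty((N, 2), dtype=np.int64)
    out_d = np.empty((N, 2, L), dtype=bool)
    pending = np.arange(N)
    mothers = rng.integers(0, N, size=N)
    one_minus_s = 1.0 - params.s

    for _attempt in range(params.max_mating_attempts):
        if pending.size == 0:
            break
        m = mothers[pending]
        f = rng.integers(0, N, size=pending.size)
        # pollen expressed set of father disjoint from pistil expressed set of mother
        fp1, fp2 = pol1[f], pol2[f]
        mp1, mp2 = pis1[m], pis2[m]
        ok = (fp1 != mp1) & (fp1 != mp2) & (fp2 != mp1) & (fp2 != mp2)
        if not ok.any():
            continue
        idx = pending[ok]
        mo, fa = m[ok], f[ok]
        hm = rng.integers(0, 2, size=idx.size)
        hf = rng.integers(0, 2, size=idx.size)
        gm = _mutate_gametes(d_geno[mo, hm], params.mu_forward, params.mu_back, rng)
        gf = _mutate_gametes(d_geno[fa, hf], params.mu_forward, params.mu_back, rng)
        n_hom = (gm & gf).sum(axis=1)
        survive = rng.random(idx.size) < one_minus_s**n_hom
        keep = idx[survive]
        out_s[keep, 0] = s_geno[mo[survive], hm[survive]]
        out_s[keep, 1] = s_geno[fa[survive], hf[survive]]
        out_d[keep, 0] = gm[survive]
        out_d[keep, 1] = gf[survive]
        # dead zygotes: redraw the whole mating (new mother); incompatible
        # matings keep their mother and redraw the father only
        dead = idx[~survive]
        mothers[dead] = rng.integers(0, N, size=dead.size)
        still = np.ones(pending.size, dtype=bool)
        still[np.flatnonzero(ok)[survive]] = False
        pending = pending[still]
    if pending.size:
        raise MatingImpossibleError(
            f"could not complete generation {state.generation + 1}: "
            f"{pending.size} offspring slots unfilled after "
            f"{params.max_mating_attempts} rejection rounds"
        )

    return PopulationState(generation=state.generation + 1, s_geno=out_s, d_geno=out_d)


def summarize_load(
    state: PopulationState,
    hierarchy: DominanceHierarchy,
    max_copies: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[LineageLoadSummary]:
    """Per-S-allele fixed/segregating/total deleterious mutation counts.

    A position is *fixed* within a lineage when every haplotype copy linked
    to that S-allele carries the deleterious allele (defined only when the
    lineage has >= 2 copies) and *segregating* when the within-lineage
    frequency is strictly between 0 and 1. Single-copy lineages report
    n_total as the number of deleterious alleles on the single copy.

    ``max_copies`` subsamples each lineage to at most that many copies
    (uniformly, using ``rng``) before tabulating, mimicking the
    equal-sized haplotype samples of an empirical study and removing the
    dependence of the segregating-site count on lineage copy number.
    """
    if max_copies is not None and rng is None:
        raise ValueError("subsampling requires an rng")
    s_flat = state.s_geno.reshape(-1)
    d_flat = state.d_geno.reshape(-1, state.L)
    out: list[LineageLoadSummary] = []
    for ai, allele in enumerate(hierarchy.alleles):
        mask = s_flat == ai
        n_copies = int(mask.sum())
        if n_copies == 0:
            continue
        block = d_flat[mask]
        if max_copies is not None and n_copies > max_copies:
            keep = rng.choice(n_copies, size=max_copies, replace=False)
            block = block[keep]
            n_copies = max_copies
        counts = block.sum(axis=0)
        if n_copies >= 2:
            n_fixed = int(np.sum(counts == n_copies))
            n_seg = int(np.sum((counts > 0) & (counts < n_copies)))
            n_total = n_fixed + n_seg
        else:
            n_fixed = None
            n_seg = None
            n_total = int(np.sum(counts > 0))
        out.append(
            LineageLoadSummary(
                s_allele=allele.id,
                dominance_class=allele.dominance_class,
                n_copies=n_copies,
                n_fixed=n_fixed,
                n_segregating=n_seg,
                n_total=n_total,
            )
        )
    return out


@dataclass
class ReplicateResult:
    replicate: int
    frequency_series: pd.DataFrame  # columns: generation, position, frequency
    load_summaries: list[LineageLoadSummary]
    lost_alleles: list[tuple[int, str]]  # (generation, allele id)


def run_single_replicate(
    params: SimParams, replicate: int, equilibrium: EquilibriumResult | None = None
) -> ReplicateResult:
    """Run one replicate; rng is seeded deterministically from (seed, replicate)."""
    rng = np.random.default_rng((params.seed, replicate))
    if equilibrium is None:
        equilibrium = deterministic_equilibrium(
            params.hierarchy, params.eq_tolerance, pistil_dominance=params.pistil_dominance
        )
    state = initial_population(params, rng, equilibrium)
    k = len(params.hierarchy)
    present = np.ones(k, dtype=bool)
    lost: list[tuple[int, str]] = []
    records: list[pd.DataFrame] = []

    def record(st: PopulationState) -> None:
        freq = st.d_geno.reshape(-1, st.L).mean(axis=0)
        records.append(
            pd.DataFrame(
                {
                    "generation": st.generation,
                    "position": np.arange(st.L),
                    "frequency": freq,
                }
            )
        )

    record(state)
    for gen in range(params.n_generations):
        try:
            state = step_generation(state, params, rng)
        except MatingImpossibleError as exc:
            raise MatingImpossibleError(
                f"replicate {replicate}, generation {gen + 1}: {exc}"
            ) from exc
        if (gen + 1) % params.record_every == 0:
            record(state)
        now = np.isin(np.arange(k), state.s_geno)
        for ai in np.flatnonzero(present & ~now):
            lost.append((state.generation, params.hierarchy.ids[ai]))
        present = now

    return ReplicateResult(
        replicate=replicate,
        frequency_series=pd.concat(records, ignore_index=True),
        load_summaries=summarize_load(
            state, params.hierarchy, max_copies=params.summary_max_copies, rng=rng
        ),
        lost_alleles=lost,
    )


def run_replicates(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates; returns (frequency time series, final load summaries).

    The equilibrium initialisation is computed once and shared. Replicate r
    uses an rng seeded from (params.seed, r), so runs are reproducible and
    independent of execution order.
    """
    equilibrium = deterministic_equilibrium(
        params.hierarchy, params.eq_tolerance, pistil_dominance=params.pistil_dominance
    )
    series = []
    summaries = []
    for r in range(params.n_replicates):
        res = run_single_replicate(params, r, equilibrium)
        ts = res.frequency_series.copy()
        ts.insert(0, "replicate", r)
        series.append(ts)
        for summ in res.load_summaries:
            summaries.append(
                {
                    "replicate": r,
                    "s_allele": summ.s_allele,
                    "dominance_class": summ.dominance_class,
                    "n_copies": summ.n_copies,
                    "n_fixed": summ.n_fixed,
                    "n_segregating": summ.n_segregating,
                    "n_total": summ.n_total,
                }
            )
    return pd.concat(series, ignore_index=True), pd.DataFrame(summaries)
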