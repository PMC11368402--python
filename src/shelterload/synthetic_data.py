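"""Generators for synthetic inputs with known truth.

These emulate the statistical structure the downstream analyses assume:
haplotypes whose lineage identity determines alleles close to the S-locus
(within ``d0``) with population structure taking over farther away;
parent-offspring trios with known phase; control regions carrying
population structure only; and family phenotype tables with configurable
homozygote penalties. No coalescent realism is attempted — structure is
injected directly, which is sufficient to exercise every contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SynthConfig",
    "RegionTruth",
    "HaplotypeSet",
    "generate_region",
    "generate_haplotypes",
    "generate_control_haplotypes",
    "generate_trios",
    "generate_phenotypes",
    "PRESETS",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all generators; presets tune load intensities."""

    seed: int = 0
    populations: tuple[str, ...] = ("popA", "popB")
    class_counts: dict[int, int] = field(default_factory=lambda: {1: 2, 2: 2, 3: 2, 4: 2})
    haps_per_lineage_per_pop: int = 3
    flank_bp: int = 50_000
    s_locus_bp: int = 5_000
    d0: int = 10_000
    n_snps: int = 300
    divergence: float = 0.25  # Balding-Nichols F between populations
    background_maf: tuple[float, float] = (0.1, 0.9)
    # per-class probabilities that a near-S zerofold site is lineage-fixed /
    # lineage-segregating derived; keyed by dominance class 1..4
    fixed_load_per_class: dict[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.02, 3: 0.02, 4: 0.02}
    )
    seg_load_per_class: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.05, 3: 0.05, 4: 0.05}
    )
    zerofold_fraction: float = 0.5
    founder_derived_p: float = 0.5  # per near fourfold site, lineage marker prob
    n_trios: int = 10
    genotype_error_rate: float = 0.0
    n_families: int = 6
    offspring_per_family: int = 40
    hom_penalty: float = 0.0
    trait_hom_shift: float = 0.0
    covariate_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.d0 > self.flank_bp:
            raise ValueError("d0 must not exceed the flank length")
        for d in (self.fixed_load_per_class, self.seg_load_per_class):
            if any(v < 0 for v in d.values()):
                raise ValueError("load intensities must be >= 0")

    @property
    def s_locus(self) -> tuple[int, int]:
        return (self.flank_bp + 1, self.flank_bp + self.s_locus_bp)

    @property
    def region_bp(self) -> int:
        return 2 * self.flank_bp + self.s_locus_bp

    def lineages(self) -> list[tuple[str, int]]:
        out = []
        for cls in sorted(self.class_counts):
            for k in range(self.class_counts[cls]):
                out.append((f"S{cls}_{k + 1}", cls))
        return out


PRESETS: dict[str, dict] = {
    # strong, class-graded load architecture (more fixed on dominant,
    # more segregating on recessive lineages)
    "fig45": dict(
        fixed_load_per_class={1: 0.02, 2: 0.06, 3: 0.10, 4: 0.14},
        seg_load_per_class={1: 0.20, 2: 0.15, 3: 0.10, 4: 0.05},
    ),
    # no load at all; population structure everywhere (null calibration)
    "null": dict(
        fixed_load_per_class={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        seg_load_per_class={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        d0=0,
    ),
    # crisp topology switch at d0 for the scan
    "topo": dict(d0=10_000, divergence=0.5, n_snps=400),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SynthConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# reference region with CDS of known degeneracy


@dataclass
class RegionTruth:
    sequences: dict[str, str]
    cds_features: pd.DataFrame  # seqid, start, end, strand, phase, gene
    degeneracy_truth: pd.DataFrame  # seqid, pos, degeneracy


def _truth_site_class(codon: str, offset: int) -> str:
    """Independent degeneracy call by direct enumeration of the 3 variants."""
    fwd = standard_dna_table.forward_table

    def aa(c: str) -> str:
        return fwd.get(c, "*")

    ref_aa = aa(codon)
    n_change = sum(
        1
        for alt in _BASES
        if alt != codon[offset] and aa(codon[:offset] + alt + codon[offset + 1 :]) != ref_aa
    )
    return {3: "zerofold", 0: "fourfold"}.get(n_change, "other")


def generate_region(
    length: int = 3000,
    n_genes: int = 4,
    gene_len_codons: tuple[int, int] = (20, 60),
    seqid: str = "chrS",
    seed: int = 0,
) -> RegionTruth:
    """Random reference with non-overlapping CDS genes on both strands.

    Returns the sequence, a CDS feature table, and the per-site degeneracy
    truth computed by direct enumeration of the nine single-base variants
    of each codon.
    """
    if length < 300:
        raise ValueError("region length must be >= 300")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=length)
    feats = []
    truth_rows = []
    cursor = 10
    for gi in range(n_genes):
        n_codons = int(rng.integers(gene_len_codons[0], gene_len_codons[1] + 1))
        glen = 3 * n_codons
        if cursor + glen + 10 > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor + 1, cursor + glen  # 1-based inclusive
        gene = f"gene{gi + 1}"
        feats.append(
            {"seqid": seqid, "start": start, "end": end, "strand": strand,
             "phase": 0, "gene": gene}
        )
        coords = list(range(start, end + 1))
        if strand == "-":
            coords = coords[::-1]
        for ci in range(0, glen, 3):
            trip = coords[ci : ci + 3]
            bases = [seq[p - 1] for p in trip]
            if strand == "-":
                bases = [_COMPLEMENT[b] for b in bases]
            codon = "".join(bases)
            # avoid stop codons inside genes: rewrite the wobble base
            if codon in standard_dna_table.stop_codons:
                new_third = "C"
                codon = codon[:2] + new_third
                p3 = trip[2]
                seq[p3 - 1] = new_third if strand == "+" else _COMPLEMENT[new_third]
            for off, pos in enumerate(trip):
                truth_rows.append(
                    {"seqid": seqid, "pos": pos,
                     "degeneracy": _truth_site_class(codon, off)}
                )
        cursor = end + int(rng.integers(10, 50))
    return RegionTruth(
        sequences={seqid: "".join(seq)},
        cds_features=pd.DataFrame(feats),
        degeneracy_truth=pd.DataFrame(truth_rows).sort_values("pos").reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# labeled haplotypes with lineage structure near the S-locus


@dataclass
class HaplotypeSet:
    """Binary haplotype matrix plus labels, bases, and generation truth."""

    names: list[str]
    populations: list[str]
    s_alleles: list[str]
    dominance: dict[str, int]
    positions: np.ndarray  # 1-based
    ref: np.ndarray  # reference base per site
    alt: np.ndarray  # alternative base per site
    matrix: np.ndarray  # (n_hap, n_sites) 0/1 derived-allele indicator
    site_category: np.ndarray  # degeneracy truth per site
    truth: pd.DataFrame  # per (lineage, pos): fixed / segregating flags

    def base_matrix(self) -> np.ndarray:
        """(n_hap, n_sites) int8 base codes for the topology scan."""
        base_to_int = {b: i for i, b in enumerate(_BASES)}
        refs = np.array([base_to_int[b] for b in self.ref], dtype=np.int8)
        alts = np.array([base_to_int[b] for b in self.alt], dtype=np.int8)
        return np.where(self.matrix == 1, alts[None, :], refs[None, :]).astype(np.int8)

    def degeneracy_map(self, seqid: str = ""):
        """Site-category truth as a DegeneracyMap usable by the counting code."""
        from .load_stats import DegeneracyMap

        dmap = DegeneracyMap()
        for pos, cat in zip(self.positions, self.site_category):
            dmap.site_class[(seqid, int(pos))] = cat
        return dmap

    def long_table(self) -> pd.DataFrame:
        """Long format for count_lineage_mutations."""
        n, m = self.matrix.shape
        return pd.DataFrame(
            {
                "haplotype_id": np.repeat(self.names, m),
                "population": np.repeat(self.populations, m),
                "s_allele": np.repeat(self.s_alleles, m),
                "pos": np.tile(self.positions, n),
                "allele": self.matrix.ravel(),
            }
        )


def _snp_positions(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.s_locus
    candidates = np.concatenate(
        [np.arange(1, lo), np.arange(hi + 1, cfg.region_bp + 1)]
    )
    pos = rng.choice(candidates, size=min(cfg.n_snps, candidates.size), replace=False)
    return np.sort(pos)


def generate_haplotypes(cfg: SynthConfig) -> HaplotypeSet:
    """Labeled haplotypes: lineage-determined within d0, population pools beyond.

    Within ``d0`` of an S-locus boundary each haplotype copies its lineage
    founder, plus lineage-fixed derived alleles (probability increasing
    with dominance class under the fig45 preset) at zerofold-truth sites
    and lineage-segregating derived alleles on a random proper subset of
    copies. Beyond ``d0``, alleles are drawn from population-level
    frequencies with Balding-Nichols divergence between populations.
    """
    lineages = cfg.lineages()
    if len(lineages) < 2:
        raise ValueError("need at least 2 lineages")
    rng = np.random.default_rng(cfg.seed)
    positions = _snp_positions(cfg, rng)
    m = positions.size
    lo, hi = cfg.s_locus
    dist = np.where(positions < lo, lo - positions, positions - hi)
    near = dist <= cfg.d0

    ref = rng.choice(list(_BASES), size=m)
    alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])
    site_cat = np.where(
        rng.random(m) < cfg.zerofold_fraction, "zerofold", "fourfold"
    ).astype(object)

    names, pops, sals = [], [], []
    dominance = {}
    hap_rows = []
    truth_rows = []

    # founders: lineage-marker alleles at near fourfold sites only, so the
    # class-graded load (injected at zerofold sites) stays identifiable
    fourfold = site_cat == "fourfold"
    founders = {
        sal: (rng.random(m) < cfg.founder_derived_p) & near & fourfold
        for sal, _cls in lineages
    }
    # ancestral/population frequencies for far sites
    p_anc = rng.uniform(*cfg.background_maf, size=m)
    f = cfg.divergence
    pop_freqs = {}
    for pop in cfg.populations:
        if f > 0:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs[pop] = rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3))
        else:
            pop_freqs[pop] = p_anc

    for sal, cls in lineages:
        dominance[sal] = cls
        founder = founders[sal]
        fixed_p = cfg.fixed_load_per_class.get(cls, 0.0)
        seg_p = cfg.seg_load_per_class.get(cls, 0.0)
        zf = site_cat == "zerofold"
        lineage_fixed = near & zf & ~founder & (rng.random(m) < fixed_p)
        lineage_seg_site = near & zf & ~founder & ~lineage_fixed & (rng.random(m) < seg_p)
        n_copies_total = len(cfg.populations) * cfg.haps_per_lineage_per_pop
        # carriers of each segregating site: a nonempty proper subset of copies
        carrier_counts = rng.integers(1, max(2, n_copies_total), size=m)
        carrier_matrix = np.zeros((n_copies_total, m), dtype=bool)
        for j in np.flatnonzero(lineage_seg_site):
            carriers = rng.choice(n_copies_total, size=carrier_counts[j], replace=False)
            carrier_matrix[carriers, j] = True

        copy_idx = 0
        for pop in cfg.populations:
            for k in range(cfg.haps_per_lineage_per_pop):
                hap = np.where(near, founder, rng.random(m) < pop_freqs[pop])
                hap = hap | lineage_fixed | carrier_matrix[copy_idx]
                names.append(f"{pop}_{sal}_h{k + 1}")
                pops.append(pop)
                sals.append(sal)
                hap_rows.append(hap)
                copy_idx += 1
        for j in np.flatnonzero(lineage_fixed | (founder & near)):
            truth_rows.append(
                {"s_allele": sal, "pos": int(positions[j]), "status": "fixed"}
            )
        for j in np.flatnonzero(lineage_seg_site):
            if 0 < carrier_matrix[:, j].sum() < n_copies_total:
                truth_rows.append(
                    {"s_allele": sal, "pos": int(positions[j]), "status": "segregating"}
                )

    return HaplotypeSet(
        names=names,
        populations=pops,
        s_alleles=sals,
        dominance=dominance,
        positions=positions,
        ref=ref,
        alt=alt,
        matrix=np.array(hap_rows, dtype=np.int8),
        site_category=np.asarray(site_cat),
        truth=pd.DataFrame(truth_rows, columns=["s_allele", "pos", "status"]),
    )


def generate_control_haplotypes(
    cfg: SynthConfig, n_regions: int = 3, snps_per_region: int = 150, seed_offset: int = 1000
) -> list[HaplotypeSet]:
    """Control regions: population structure only (d0 = 0, no load)."""
    out = []
    for k in range(n_regions):
        ctrl = replace(
            cfg,
            seed=cfg.seed + seed_offset + k,
            d0=0,
            n_snps=snps_per_region,
            fixed_load_per_class={c: 0.0 for c in cfg.class_counts},
            seg_load_per_class={c: 0.0 for c in cfg.class_counts},
        )
        out.append(generate_haplotypes(ctrl))
    return out


# ---------------------------------------------------------------------------
# trios


@dataclass
class TrioSet:
    genotypes: pd.DataFrame  # long: individual, pos, gt (0/1/2)
    manifest: pd.DataFrame  # offspring, parent1, parent2
    s_genotypes: pd.DataFrame  # individual, allele1, allele2, class1, class2
    truth_phase: pd.DataFrame  # individual, s_allele, pos, allele, transmitted
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    n_errors_injected: int


def generate_trios(cfg: SynthConfig, haps: HaplotypeSet | None = None) -> TrioSet:
    """Parent-offspring trios built from generated haplotypes, with truth phase.

    Parents pair two haplotypes with distinct S-alleles from one
    population; each parent transmits one haplotype without recombination.
    Genotyping errors are injected at ``cfg.genotype_error_rate`` per
    offspring genotype (flipping to a random other dosage), producing
    Mendelian inconsistencies at a known rate.
    """
    if cfg.n_trios < 1:
        raise ValueError("need at least one trio")
    rng = np.random.default_rng(cfg.seed + 77)
    if haps is None:
        haps = generate_haplotypes(cfg)
    m = haps.positions.size
    by_pop: dict[str, list[int]] = {}
    for i, pop in enumerate(haps.populations):
        by_pop.setdefault(pop, []).append(i)

    geno_rows = []
    manifest = []
    s_rows = []
    phase_rows = []
    n_err = 0

    def pick_parent(pop_haps):
        while True:
            i, j = rng.choice(pop_haps, size=2, replace=False)
            if haps.s_alleles[i] != haps.s_alleles[j]:
                return i, j

    seen_individuals = set()

    def emit_individual(ind, hap_pair, transmitted_idx=None):
        if ind in seen_individuals:
            return
        seen_individuals.add(ind)
        i, j = hap_pair
        gt = haps.matrix[i] + haps.matrix[j]
        for pos, g in zip(haps.positions, gt):
            geno_rows.append({"individual": ind, "pos": int(pos), "gt": int(g)})
        s_rows.append(
            {
                "individual": ind,
                "allele1": haps.s_alleles[i],
                "allele2": haps.s_alleles[j],
                "class1": haps.dominance[haps.s_alleles[i]],
                "class2": haps.dominance[haps.s_alleles[j]],
            }
        )
        for hap_idx, slot in ((i, 0), (j, 1)):
            for pos, a in zip(haps.positions, haps.matrix[hap_idx]):
                phase_rows.append(
                    {
                        "individual": ind,
                        "s_allele": haps.s_alleles[hap_idx],
                        "pos": int(pos),
                        "allele": int(a),
                        "transmitted": transmitted_idx == slot,
                    }
                )

    for t in range(cfg.n_trios):
        pop = cfg.populations[t % len(cfg.populations)]
        p1 = pick_parent(by_pop[pop])
        p2 = pick_parent(by_pop[pop])
        p1_id, p2_id, off_id = f"P{2 * t + 1}", f"P{2 * t + 2}", f"O{t + 1}"
        t1 = int(rng.integers(0, 2))
        t2 = int(rng.integers(0, 2))
        emit_individual(p1_id, p1, t1)
        emit_individual(p2_id, p2, t2)
        off_h1 = haps.matrix[p1[t1]]
        off_h2 = haps.matrix[p2[t2]]
        off_gt = (off_h1 + off_h2).astype(np.int64)
        if cfg.genotype_error_rate > 0:
            flips = rng.random(m) < cfg.genotype_error_rate
            for j in np.flatnonzero(flips):
                choices = [g for g in (0, 1, 2) if g != off_gt[j]]
                off_gt[j] = rng.choice(choices)
            n_err += int(flips.sum())
        for pos, g in zip(haps.positions, off_gt):
            geno_rows.append({"individual": off_id, "pos": int(pos), "gt": int(g)})
        s_rows.append(
            {
                "individual": off_id,
                "allele1": haps.s_alleles[p1[t1]],
                "allele2": haps.s_alleles[p2[t2]],
                "class1": haps.dominance[haps.s_alleles[p1[t1]]],
                "class2": haps.dominance[haps.s_alleles[p2[t2]]],
            }
        )
        manifest.append({"offspring": off_id, "parent1": p1_id, "parent2": p2_id})

    return TrioSet(
        genotypes=pd.DataFrame(geno_rows),
        manifest=pd.DataFrame(manifest),
        s_genotypes=pd.DataFrame(s_rows).drop_duplicates("individual").reset_index(drop=True),
        truth_phase=pd.DataFrame(phase_rows),
        positions=haps.positions,
        ref=haps.ref,
        alt=haps.alt,
        n_errors_injected=n_err,
    )


# ---------------------------------------------------------------------------
# family phenotype tables


def generate_phenotypes(cfg: SynthConfig) -> pd.DataFrame:
    """Family offspring table with survival, one trait, and covariate flags.

    Families are het x het crosses sharing one focal S-allele. Offspring
    are S-locus homozygous with Mendelian probability 0.25; homozygotes
    die before reproduction with probability ``cfg.hom_penalty``. The
    trait is Gaussian with mean shifted by ``trait_hom_shift`` in
    surviving homozygotes and by ``covariate_effect`` when the binary
    covariate (e.g. pathogen attack) is 1.
    """
    if cfg.n_families < 1:
        raise ValueError("no families defined")
    rng = np.random.default_rng(cfg.seed + 555)
    rows = []
    for fam in range(cfg.n_families):
        focal = f"S{fam % 4 + 1}_1"
        other1, other2 = f"S{fam % 4 + 1}_x", f"S{fam % 4 + 1}_y"
        for k in range(cfg.offspring_per_family):
            hom = rng.random() < 0.25
            survived = True
            if hom and rng.random() < cfg.hom_penalty:
                survived = False
            covariate = int(rng.random() < 0.3)
            trait = rng.normal(
                10.0
                + (cfg.trait_hom_shift if hom else 0.0)
                + cfg.covariate_effect * covariate,
                1.0,
            )
            genotype = f"{focal}/{focal}" if hom else f"{focal}/{rng.choice([other1, other2])}"
            rows.append(
                {
                    "offspring_id": f"F{fam + 1}_O{k + 1}",
                    "family": f"F{fam + 1}",
                    "parent1_s": f"{focal}/{other1}",
                    "parent2_s": f"{focal}/{other2}",
                    "focal_allele": focal,
                    "s_genotype": genotype,
                    "homozygous": hom,
                    "survived": survived,
                    "trait": trait,
                    "pathogen_attack": covariate,
                }
            )
    return pd.DataFrame(rows)
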