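"""Site degeneracy, variant filtering, lineage load counts, and dominance trends.

Classifies coding sites of a reference + GFF3 annotation as zerofold or
fourfold degenerate, applies the variant-site filters (quality >= 60,
biallelic SNPs only, per-sample depth bounds from control regions,
removal of population-fixed sites), tabulates fixed vs segregating
putatively deleterious mutations per S-allele lineage within a window of
the S-locus, and tests the dominance trend with Poisson regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "DegeneracyMap",
    "SiteFilterParams",
    "LineageCounts",
    "DominanceTrend",
    "classify_degeneracy",
    "filter_sites",
    "count_lineage_mutations",
    "fit_dominance_trend",
    "ratio_statistic",
]

ZEROFOLD = "zerofold"
FOURFOLD = "fourfold"
OTHER = "other"
CONFLICT = "excluded-conflict"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


def _translate(codon: str) -> str:
    """Amino acid (or '*') for an uppercase DNA codon."""
    return standard_dna_table.forward_table.get(
        codon, "*" if codon in standard_dna_table.stop_codons else "X"
    )


def _codon_site_class(codon: str, offset: int) -> str:
    """Degeneracy of position ``offset`` (0..2) of a codon.

    zerofold: every alternative base changes the amino acid; fourfold: none
    does. Codons containing non-ACGT bases are unclassifiable -> OTHER.
    """
    if any(b not in _BASES for b in codon):
        return OTHER
    aa = _translate(codon)
    changes = 0
    for alt in _BASES:
        if alt == codon[offset]:
            continue
        mutated = codon[:offset] + alt + codon[offset + 1 :]
        if _translate(mutated) != aa:
            changes += 1
    if changes == 3:
        return ZEROFOLD
    if changes == 0:
        return FOURFOLD
    return OTHER


@dataclass
class DegeneracyMap:
    """Per-site degeneracy classes keyed by (seqid, 1-based position)."""

    site_class: dict[tuple[str, int], str] = field(default_factory=dict)
    site_gene: dict[tuple[str, int], str] = field(default_factory=dict)
    skipped_genes: list[str] = field(default_factory=list)

    def classify(self, seqid: str, pos: int) -> str:
        """Class of a site; non-coding sites return ``"other"``."""
        return self.site_class.get((seqid, pos), OTHER)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"seqid": k[0], "pos": k[1], "degeneracy": v, "gene": self.site_gene.get(k, "")}
            for k, v in sorted(self.site_class.items())
        ]
        return pd.DataFrame(rows, columns=["seqid", "pos", "degeneracy", "gene"])


def classify_degeneracy(
    sequences: dict[str, str], cds_features: pd.DataFrame
) -> DegeneracyMap:
    """Classify every CDS site as zerofold / fourfold / other.

    ``sequences`` maps seqid -> uppercase sequence. ``cds_features`` needs
    columns seqid, start, end (1-based inclusive), strand (+/-), phase
    (0/1/2), gene. CDS segments of a gene are concatenated in genomic
    order (reverse order and complemented on the minus strand). Genes
    whose spliced, phase-adjusted CDS length is not a multiple of 3 are
    skipped with a warning; sites claimed by genes with conflicting
    classes are marked ``excluded-conflict``.
    """
    out = DegeneracyMap()
    required = {"seqid", "start", "end", "strand", "phase", "gene"}
    missing = required - set(cds_features.columns)
    if missing:
        raise ValueError(f"cds_features missing columns: {sorted(missing)}")

    for gene, feats in cds_features.groupby("gene", sort=True):
        feats = feats.sort_values("start")
        strand = feats["strand"].iloc[0]
        seqid = feats["seqid"].iloc[0]
        seq = sequences[seqid].upper()
        coords: list[int] = []
        for _, row in feats.iterrows():
            coords.extend(range(int(row["start"]), int(row["end"]) + 1))
        if strand == "-":
            coords = coords[::-1]
            phase_row = feats.sort_values("end").iloc[-1]
        else:
            phase_row = feats.iloc[0]
        phase = int(phase_row["phase"]) if not pd.isna(phase_row["phase"]) else 0
        coords = coords[phase:]
        if len(coords) % 3 != 0:
            warnings.warn(f"gene {gene}: CDS length not a multiple of 3; skipped")
            out.skipped_genes.append(gene)
            continue
        for ci in range(0, len(coords), 3):
            triplet = coords[ci : ci + 3]
            bases = [seq[p - 1] for p in triplet]
            if strand == "-":
                bases = [_COMPLEMENT.get(b, "N") for b in bases]
            codon = "".join(bases)
            for offset, pos in enumerate(triplet):
                cls = _codon_site_class(codon, offset)
                key = (seqid, pos)
                prev = out.site_class.get(key)
                if prev is not None and prev != cls:
                    out.site_class[key] = CONFLICT
                else:
                    out.site_class[key] = cls
                    out.site_gene[key] = gene
    return out


@dataclass(frozen=True)
class SiteFilterParams:
    min_quality: float = 60.0
    min_depth: int = 15
    max_depth_percentile: float = 97.5
    biallelic_only: bool = True
    drop_population_fixed: bool = True

    def __post_init__(self) -> None:
        if self.min_quality <= 0 or self.min_depth <= 0:
            raise ValueError("filter thresholds must be positive")


def filter_sites(
    variants: pd.DataFrame,
    params: SiteFilterParams,
    control_depths: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Apply the site and genotype filters to a variant table.

    ``variants`` is the long-format table produced by
    :func:`shelterload.io_cli.read_vcf`: one row per (site, sample) with
    columns chrom, pos, ref, alt, qual, biallelic_snp, sample, gt
    (dosage 0/1/2, -9 missing), dp. Genotypes failing the depth bounds are
    masked to missing; sites failing quality or biallelic requirements are
    dropped; monomorphic (population-fixed) sites are dropped when
    requested. Per-sample depth ceilings come from ``control_depths``
    (control-region depth vectors), falling back to the sample's own depth
    distribution.
    """
    if "dp" not in variants.columns:
        raise ValueError("variant table lacks a depth (dp) column")
    df = variants.copy()
    df = df[df["qual"] >= params.min_quality]
    if params.biallelic_only and "biallelic_snp" in df.columns:
        df = df[df["biallelic_snp"]]

    ceilings: dict[str, float] = {}
    for sample in df["sample"].unique():
        if control_depths is not None and sample in control_depths:
            src = np.asarray(control_depths[sample], dtype=float)
        else:
            src = df.loc[df["sample"] == sample, "dp"].to_numpy(dtype=float)
        ceilings[sample] = float(np.percentile(src, params.max_depth_percentile))

    missing_dp = df["dp"].isna()
    if missing_dp.any():
        row = df[missing_dp].iloc[0]
        raise ValueError(
            f"missing depth for sample {row['sample']} at {row['chrom']}:{row['pos']}"
        )
    ceiling = df["sample"].map(ceilings)
    bad = (df["dp"] < params.min_depth) | (df["dp"] > ceiling)
    df.loc[bad, "gt"] = -9

    if params.drop_population_fixed:
        def polymorphic(g: pd.Series) -> bool:
            called = g[g != -9]
            if called.empty:
                return False
            return not (
                (called == 0).all() or (called == 2).all()
            )

        poly = df.groupby(["chrom", "pos"])["gt"].transform(polymorphic)
        df = df[poly.astype(bool)]
    return df.reset_index(drop=True)


@dataclass
class LineageCounts:
    """Fixed / segregating / total mutation counts for one lineage x category."""

    population: str
    s_allele: str
    dominance: float
    n_copies: int
    category: str
    n_fixed: int | None
    n_segregating: int | None
    n_total: int


def count_lineage_mutations(
    haplotypes: pd.DataFrame,
    degeneracy: DegeneracyMap | None,
    s_locus: tuple[int, int],
    window: int = 25_000,
    seqid: str | None = None,
    dominance: dict[str, float] | None = None,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per population x S-allele fixed/segregating mutation counts near the S-locus.

    ``haplotypes`` is long format: one row per (haplotype, site) with
    columns haplotype_id, population, s_allele, pos, allele (0 ancestral /
    1 derived, -9 missing). Sites farther than ``window`` bp outward from
    the nearest S-locus boundary are excluded; sites with the derived
    allele on every haplotype of the population sample are excluded from
    the segregating tally. ``categories`` optionally maps category name ->
    degeneracy class to tabulate (defaults: S_0f -> zerofold, S_4f ->
    fourfold); ``dominance`` maps S-allele -> dominance level.
    """
    if categories is None:
        categories = {"S_0f": ZEROFOLD, "S_4f": FOURFOLD}
    lo, hi = s_locus
    df = haplotypes.copy()
    near = ((df["pos"] >= lo - window) & (df["pos"] < lo)) | (
        (df["pos"] > hi) & (df["pos"] <= hi + window)
    )
    df = df[near]
    rows = []
    for pop, pdf in df.groupby("population", sort=True):
        n_hap_pop = pdf["haplotype_id"].nunique()
        derived_per_site = pdf[pdf["allele"] == 1].groupby("pos")["haplotype_id"].nunique()
        pop_fixed = set(derived_per_site[derived_per_site == n_hap_pop].index)
        for sal, ldf in pdf.groupby("s_allele", sort=True):
            n_copies = ldf["haplotype_id"].nunique()
            for cat, cls in categories.items():
                if degeneracy is None:
                    sites = ldf
                else:
                    keep = ldf["pos"].map(
                        lambda p: degeneracy.classify(
                            seqid if seqid is not None else "", int(p)
                        )
                        == cls
                    )
                    sites = ldf[keep]
                per_site = sites[sites["allele"] == 1].groupby("pos")["haplotype_id"].nunique()
                if n_copies >= 2:
                    fixed_sites = set(per_site[per_site == n_copies].index)
                    seg_sites = set(per_site[(per_site > 0) & (per_site < n_copies)].index)
                    seg_sites -= pop_fixed
                    n_fixed: int | None = len(fixed_sites)
                    n_seg: int | None = len(seg_sites)
                    n_total = len(fixed_sites) + len(seg_sites)
                else:
                    n_fixed = None
                    n_seg = None
                    n_total = int((per_site > 0).sum())
                rows.append(
                    {
                        "population": pop,
                        "s_allele": sal,
                        "dominance": (dominance or {}).get(sal, np.nan),
                        "n_copies": n_copies,
                        "category": cat,
                        "n_fixed": n_fixed,
                        "n_segregating": n_seg,
                        "n_total": n_total,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DominanceTrend:
    response: str
    category: str
    slope: float
    p_value: float
    population_adjustment: str
    degenerate: bool = False


def fit_dominance_trend(
    counts: pd.DataFrame, response: str, category: str
) -> DominanceTrend:
    """Poisson GLM of a lineage count on continuous dominance level.

    Population enters as a fixed-effect covariate when more than one
    population is present (approximation of a random effect). Lineages
    with undefined counts (single copies) are excluded. Returns the
    dominance slope on the log scale and its Wald p-value.
    """
    col = {"fixed": "n_fixed", "segregating": "n_segregating", "total": "n_total"}[response]
    df = counts[counts["category"] == category].dropna(subset=[col, "dominance"]).copy()
    if len(df) < 3 or df["dominance"].nunique() < 2:
        raise ValueError("need >=3 lineages spanning >=2 dominance levels")
    y = df[col].to_numpy(dtype=float)
    if np.all(y == 0):
        return DominanceTrend(response, category, 0.0, 1.0, "none", degenerate=True)
    X = pd.DataFrame({"dominance": df["dominance"].to_numpy(dtype=float)})
    adjustment = "none"
    if df["population"].nunique() > 1:
        dummies = pd.get_dummies(df["population"], prefix="pop", drop_first=True, dtype=float)
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
        adjustment = "population fixed effect"
    X = sm.add_constant(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit()
    return DominanceTrend(
        response=response,
        category=category,
        slope=float(res.params["dominance"]),
        p_value=float(res.pvalues["dominance"]),
        population_adjustment=adjustment,
    )


def ratio_statistic(counts: pd.DataFrame) -> pd.DataFrame:
    """S_0f / S_4f total-count ratio per (population, S-allele) lineage.

    Lineages with S_4f == 0 are flagged (ratio NaN, flag True).
    """
    wide = counts.pivot_table(
        index=["population", "s_allele"], columns="category", values="n_total",
        aggfunc="first",
    ).reset_index()
    if "S_0f" not in wide.columns or "S_4f" not in wide.columns:
        raise ValueError("counts must include S_0f and S_4f categories")
    s4 = wide["S_4f"].to_numpy(dtype=float)
    s0 = wide["S_0f"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s4 > 0, s0 / s4, np.nan)
    wide["ratio_0f_4f"] = ratio
    wide["flagged_zero_s4f"] = s4 == 0
    return wide[["population", "s_allele", "S_0f", "S_4f", "ratio_0f_4f", "flagged_zero_s4f"]]
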