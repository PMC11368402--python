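"""Trio-based phasing of S-linked haplotypes.

Parental haplotypes are resolved from parent-offspring trios assuming no
recombination between parent and offspring across the phased interval:
the allelic state shared between a parent and its offspring is attributed
to their shared (transmitted) S-allele and the non-shared state to the
parent's other, untransmitted haplotype. Sites where the attribution is
ambiguous (all three individuals heterozygous, or any genotype missing)
are emitted as missing; Mendelian inconsistencies are masked and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "TrioGenotypes",
    "PhasedHaplotype",
    "TrioQC",
    "AMBIGUOUS",
    "UNINFORMATIVE",
    "transmitted_s_allele",
    "phase_site",
    "phase_trio",
    "dedupe_parents",
]

MISSING = -9  # per-site missing/ambiguous allele code
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = None

#: per-trio flag threshold on the Mendelian error fraction
ERROR_FRACTION_THRESHOLD = 0.05


class MendelianSLocusError(ValueError):
    """Parent and offspring share no S-allele."""


@dataclass(frozen=True)
class TrioGenotypes:
    """Biallelic genotypes of one parent-offspring trio.

    Genotype encoding per site: 0 (hom ref), 1 (het), 2 (hom alt),
    -9 missing. ``*_s`` are unordered pairs of S-allele labels.
    """

    offspring_id: str
    parent1_id: str
    parent2_id: str
    positions: np.ndarray
    parent1_gt: np.ndarray
    parent2_gt: np.ndarray
    offspring_gt: np.ndarray
    parent1_s: tuple[str, str]
    parent2_s: tuple[str, str]
    offspring_s: tuple[str, str]

    def __post_init__(self) -> None:
        n = len(self.positions)
        for arr in (self.parent1_gt, self.parent2_gt, self.offspring_gt):
            if len(arr) != n:
                raise ValueError("genotype vectors must match positions length")


@dataclass
class PhasedHaplotype:
    """One resolved parental haplotype.

    ``alleles`` holds 0/1 per site with MISSING (-9) at ambiguous or masked
    sites.
    """

    parent_id: str
    s_allele: str
    transmitted: bool
    alleles: np.ndarray
    positions: np.ndarray


@dataclass
class TrioQC:
    offspring_id: str
    n_sites: int
    n_ambiguous: int
    n_mendelian_errors: int
    flagged: bool

    @property
    def ambiguous_fraction(self) -> float:
        return self.n_ambiguous / self.n_sites if self.n_sites else 0.0

    @property
    def error_fraction(self) -> float:
        return self.n_mendelian_errors / self.n_sites if self.n_sites else 0.0


def transmitted_s_allele(parent_s, offspring_s, other_parent_s=None):
    """S-allele this parent transmitted to the offspring.

    Resolution enumerates joint assignments (one allele from each parent
    making up the offspring genotype) when the other parent's genotype is
    known. Returns the allele label, ``UNINFORMATIVE`` when several
    assignments transmit different alleles from this parent, and raises
    :class:`MendelianSLocusError` when no assignment exists.
    """
    parent = tuple(parent_s)
    off = tuple(offspring_s)
    shared = set(parent) & set(off)
    if not shared:
        raise MendelianSLocusError(
            f"parent {parent} shares no S-allele with offspring {off}"
        )
    if other_parent_s is None:
        if len(shared) == 1:
            return next(iter(shared))
        return UNINFORMATIVE
    other = tuple(other_parent_s)
    candidates = set()
    for a, b in product(parent, other):
        if tuple(sorted((a, b))) == tuple(sorted(off)):
            candidates.add(a)
    if not candidates:
        raise MendelianSLocusError(
            f"no Mendelian assignment for parents {parent},{other} -> offspring {off}"
        )
    if len(candidates) == 1:
        return next(iter(candidates))
    return UNINFORMATIVE


def _alleles(gt: int):
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(gt)


def phase_site(p1_gt: int, p2_gt: int, off_gt: int):
    """Resolve which allele each parent transmitted at one biallelic site.

    Returns (allele_from_p1, allele_from_p2), the string ``"ambiguous"``
    when more than one assignment is consistent or a genotype is missing,
    and the string ``"mendelian_error"`` when no assignment is consistent.
    """
    a1, a2, ao = _alleles(p1_gt), _alleles(p2_gt), _alleles(off_gt)
    if a1 is None or a2 is None or ao is None:
        return AMBIGUOUS
    target = tuple(sorted(ao))
    assignments = {
        (x, y) for x, y in product(set(a1), set(a2)) if tuple(sorted((x, y))) == target
    }
    if not assignments:
        return "mendelian_error"
    if len(assignments) > 1:
        return AMBIGUOUS
    return next(iter(assignments))


def phase_trio(trio: TrioGenotypes) -> tuple[list[PhasedHaplotype], TrioQC]:
    """Phase both parents of one trio across all sites.

    Raises ``ValueError`` when the S-allele transmission of either parent
    cannot be resolved (the trio is uninformative and should be skipped).
    """
    t1 = transmitted_s_allele(trio.parent1_s, trio.offspring_s, trio.parent2_s)
    t2 = transmitted_s_allele(trio.parent2_s, trio.offspring_s, trio.parent1_s)
    if t1 is UNINFORMATIVE or t2 is UNINFORMATIVE:
        raise ValueError(
            f"trio {trio.offspring_id}: S-allele transmission not uniquely resolvable"
        )

    n = len(trio.positions)
    hap = {
        ("p1", True): np.full(n, MISSING, dtype=np.int8),
        ("p1", False): np.full(n, MISSING, dtype=np.int8),
        ("p2", True): np.full(n, MISSING, dtype=np.int8),
        ("p2", False): np.full(n, MISSING, dtype=np.int8),
    }
    n_amb = 0
    n_err = 0
    for i in range(n):
        res = phase_site(int(trio.parent1_gt[i]), int(trio.parent2_gt[i]),
                         int(trio.offspring_gt[i]))
        if res == AMBIGUOUS:
            n_amb += 1
            continue
        if res == "mendelian_error":
            n_err += 1
            continue
        x1, x2 = res
        hap[("p1", True)][i] = x1
        hap[("p2", True)][i] = x2
        # untransmitted allele = parent genotype minus transmitted allele
        u1 = _alleles(int(trio.parent1_gt[i]))
        u2 = _alleles(int(trio.parent2_gt[i]))
        hap[("p1", False)][i] = sum(u1) - x1
        hap[("p2", False)][i] = sum(u2) - x2

    def other(pair, used):
        a, b = pair
        return b if a == used else a

    haplotypes = [
        PhasedHaplotype(trio.parent1_id, t1, True, hap[("p1", True)], trio.positions),
        PhasedHaplotype(trio.parent1_id, other(trio.parent1_s, t1), False,
                        hap[("p1", False)], trio.positions),
        PhasedHaplotype(trio.parent2_id, t2, True, hap[("p2", True)], trio.positions),
        PhasedHaplotype(trio.parent2_id, other(trio.parent2_s, t2), False,
                        hap[("p2", False)], trio.positions),
    ]
    qc = TrioQC(
        offspring_id=trio.offspring_id,
        n_sites=n,
        n_ambiguous=n_amb,
        n_mendelian_errors=n_err,
        flagged=(n_err / n > ERROR_FRACTION_THRESHOLD) if n else False,
    )
    return haplotypes, qc


def dedupe_parents(trios: list[TrioGenotypes]):
    """Phase each parent once, from its first informative trio.

    Later trios involving an already-phased parent are used only as a
    consistency check. Returns (haplotypes, qc_reports, consistency) where
    ``consistency`` is a DataFrame with per-parent mismatch counts over
    sites resolved in both phasings.
    """
    phased: dict[str, list[PhasedHaplotype]] = {}
    qcs: list[TrioQC] = []
    mismatches: list[dict] = []
    skipped: list[tuple[str, str]] = []
    for trio in trios:
        try:
            haps, qc = phase_trio(trio)
        except ValueError as exc:
            skipped.append((trio.offspring_id, str(exc)))
            continue
        qcs.append(qc)
        for pid in (trio.parent1_id, trio.parent2_id):
            parent_haps = [h for h in haps if h.parent_id == pid]
            if pid not in phased:
                phased[pid] = parent_haps
            else:
                prev = {h.s_allele: h for h in phased[pid]}
                n_cmp = 0
                n_mis = 0
                for h in parent_haps:
                    ref = prev.get(h.s_allele)
                    if ref is None:
                        continue
                    both = (h.alleles != MISSING) & (ref.alleles != MISSING)
                    n_cmp += int(both.sum())
                    n_mis += int((h.alleles[both] != ref.alleles[both]).sum())
                mismatches.append(
                    {"parent_id": pid, "offspring_id": trio.offspring_id,
                     "n_compared": n_cmp, "n_mismatch": n_mis}
                )
    haplotypes = [h for haps in phased.values() for h in haps]
    consistency = pd.DataFrame(
        mismatches, columns=["parent_id", "offspring_id", "n_compared", "n_mismatch"]
    )
    return haplotypes, qcs, consistency, skipped
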