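"""FST profiles in non-overlapping 5-kb windows.

Haplotypes are grouped either by population of origin or by the S-allele
they are linked to. Differentiation per window is the Hudson-type
statistic FST = 1 - pi_within / pi_total. To make FST exactly 0 when all
groups have identical allele frequencies (and exactly 1 when groups are
fixed for distinct alleles), the diversities entering the ratio are
computed from per-site allele frequencies (expected-heterozygosity form,
pairs drawn with replacement); the standalone ``nucleotide_diversity``
uses the classical unbiased mean pairwise difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FstWindowResult",
    "nucleotide_diversity",
    "fst_window",
    "fst_profile",
]

WINDOW_BP = 5000


@dataclass(frozen=True)
class FstWindowResult:
    start: int
    end: int
    grouping_key: str
    fst: float  # NaN when undefined
    group_sizes: dict[str, int]
    pi_within: float
    pi_total: float
    defined: bool


def nucleotide_diversity(matrix: np.ndarray) -> float:
    """Mean pairwise difference per site (unbiased, all unordered pairs).

    ``matrix`` is (n_sequences, n_sites) with integer states; negative
    values are missing and the corresponding pairs are skipped per site.
    Returns NaN with fewer than 2 sequences.
    """
    mat = np.asarray(matrix)
    n, m = mat.shape
    if n < 2 or m == 0:
        return float("nan")
    diff = 0.0
    comp = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            comp += ok.sum()
            diff += np.sum(mat[i][ok] != mat[j][ok])
    n_pairs = n * (n - 1) / 2
    return float(diff / (n_pairs * m))


def _het_sum(mat: np.ndarray) -> float:
    """Sum over sites of expected heterozygosity 1 - sum_a freq(a)^2."""
    total = 0.0
    for col in mat.T:
        called = col[col >= 0]
        if called.size == 0:
            continue
        _, counts = np.unique(called, return_counts=True)
        freqs = counts / called.size
        total += 1.0 - np.sum(freqs**2)
    return total


def fst_window(
    matrix: np.ndarray,
    group_labels,
    grouping_key: str = "population",
    start: int = 0,
    end: int = 0,
) -> FstWindowResult:
    """Hudson-type FST (1 - pi_within / pi_total) for one window.

    ``pi_within`` is the mean over groups, weighted by group size, of the
    per-group heterozygosity sum; ``pi_total`` is the pooled-sample
    heterozygosity sum. Undefined (NaN) when fewer than two groups have
    >= 2 sequences, or when pi_total is zero.
    """
    labels = np.asarray(group_labels)
    mat = np.asarray(matrix)
    uniq, counts = np.unique(labels, return_counts=True)
    sizes = {str(u): int(c) for u, c in zip(uniq, counts)}
    usable = uniq[counts >= 2]
    if len(usable) < 2:
        return FstWindowResult(start, end, grouping_key, float("nan"), sizes,
                               float("nan"), float("nan"), defined=False)
    keep = np.isin(labels, usable)
    mat, labels = mat[keep], labels[keep]
    pi_total = _het_sum(mat)
    if pi_total == 0.0:
        return FstWindowResult(start, end, grouping_key, float("nan"), sizes,
                               0.0, 0.0, defined=False)
    weights = []
    within = []
    for g in usable:
        block = mat[labels == g]
        weights.append(block.shape[0])
        within.append(_het_sum(block))
    pi_within = float(np.average(within, weights=weights))
    fst = 1.0 - pi_within / pi_total
    return FstWindowResult(start, end, grouping_key, float(fst), sizes,
                           pi_within, float(pi_total), defined=True)


def fst_profile(
    matrix: np.ndarray,
    positions: np.ndarray,
    populations,
    s_alleles,
    s_locus: tuple[int, int],
    region: tuple[int, int],
    window_bp: int = WINDOW_BP,
    control_windows: list[np.ndarray] | None = None,
    control_labels=None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-window FST for both grouping keys, tiling outward from the S-locus.

    Windows of ``window_bp`` tile from each S-locus boundary outward to the
    region edges; trailing partial windows are dropped. When control
    window matrices are supplied, the 2.5/97.5 percentiles of their
    by-population FST are returned as the genomic-control band.
    """
    positions = np.asarray(positions)
    lo, hi = s_locus
    rlo, rhi = region
    spans: list[tuple[int, int]] = []
    left = lo - window_bp
    while left >= rlo:
        spans.append((left, left + window_bp))
        left -= window_bp
    right = hi + 1
    while right + window_bp - 1 <= rhi:
        spans.append((right, right + window_bp))
        right += window_bp
    spans.sort()
    rows = []
    for start, end in spans:
        cols = (positions >= start) & (positions < end)
        sub = matrix[:, cols]
        for key, labels in (("population", populations), ("s_allele", s_alleles)):
            res = fst_window(sub, labels, key, start, end)
            rows.append(
                {
                    "start": start,
                    "end": end,
                    "distance": max(lo - end, start - hi, 0),
                    "grouping_key": key,
                    "fst": res.fst,
                    "pi_within": res.pi_within,
                    "pi_total": res.pi_total,
                    "defined": res.defined,
                }
            )
    profile = pd.DataFrame(rows)
    band: dict[str, float] = {}
    if control_windows:
        vals = []
        for sub in control_windows:
            res = fst_window(sub, control_labels, "population")
            if res.defined:
                vals.append(res.fst)
        if vals:
            lo_p, hi_p = np.percentile(vals, [2.5, 97.5])
            band = {"p2_5": float(lo_p), "p97_5": float(hi_p), "n": len(vals)}
    return profile, band
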