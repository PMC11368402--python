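"""Sliding-window comparison of two constrained haplotype topologies.

For each window of SNPs, the log likelihood of the alignment is maximised
over branch lengths on two fixed star-of-rakes topologies: one clustering
haplotypes by the S-allele they are linked to, the other by their
population of origin. Positive differences (by-S-allele minus
by-population) indicate chromosomal positions where linkage to the S-locus
dominates the phylogenetic signal. An empirical null band is obtained from
random draws of equally sized windows out of control regions.

The likelihood kernel is Felsenstein pruning under JC69 (default) or K80
on a two-level topology: a root polytomy over groups, each group a rake
polytomy over its haplotypes. Under JC69 the per-site likelihood is linear
in exp(-4t/3) of any single branch, so coordinate-wise branch optimisation
uses exact one-dimensional searches on that transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

__all__ = [
    "HaplotypeAlignment",
    "GroupingTopology",
    "ScanResult",
    "NullBand",
    "build_grouping_topology",
    "window_iter",
    "loglik",
    "delta_loglik",
    "scan",
    "null_band",
    "distance_correlation",
]

BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING = -1
BRANCH_MIN = 1e-9
BRANCH_MAX = 10.0
BRANCH_INIT = 0.01


@dataclass(frozen=True)
class HaplotypeAlignment:
    """SNP alignment with per-haplotype (S-allele, population) labels.

    ``matrix`` is (n_haplotypes, n_sites) int8: 0..3 for A,C,G,T and -1 for
    missing. ``positions`` are 1-based chromosome coordinates, strictly
    increasing.
    """

    names: tuple[str, ...]
    s_alleles: tuple[str, ...]
    populations: tuple[str, ...]
    matrix: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.matrix.shape
        if not (len(self.names) == len(self.s_alleles) == len(self.populations) == n):
            raise ValueError("label lengths must match number of haplotype rows")
        if len(self.positions) != m:
            raise ValueError("positions length must match number of sites")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = set(np.unique(self.matrix)) - {-1, 0, 1, 2, 3}
        if bad:
            raise ValueError(f"unknown character states in alignment: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_strings(cls, names, s_alleles, populations, seqs, positions):
        """Build from base-character strings; characters outside ACGT are missing."""
        mat = np.full((len(seqs), len(seqs[0])), MISSING, dtype=np.int8)
        offending = set()
        for i, s in enumerate(seqs):
            for j, c in enumerate(s.upper()):
                if c in BASE_TO_INT:
                    mat[i, j] = BASE_TO_INT[c]
                elif c not in "N-?.":
                    offending.add(c)
        if offending:
            raise ValueError(f"unknown character states: {sorted(offending)}")
        return cls(
            names=tuple(names),
            s_alleles=tuple(s_alleles),
            populations=tuple(populations),
            matrix=mat,
            positions=np.asarray(positions, dtype=np.int64),
        )


@dataclass
class GroupingTopology:
    """Two-level constrained topology: root polytomy over rakes of groups.

    ``groups`` maps group name -> list of leaf indices (rows of the
    alignment). ``leaf_bl[i]`` is the branch above leaf i; ``group_bl`` is
    keyed like ``groups``. Group order and within-group leaf order are the
    sorted orders, making construction deterministic.
    """

    key: str
    groups: dict[str, list[int]]
    leaf_names: tuple[str, ...]
    leaf_bl: np.ndarray
    group_bl: np.ndarray

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def newick(self) -> str:
        parts = []
        for gi, (g, members) in enumerate(self.groups.items()):
            leaves = ",".join(
                f"{self.leaf_names[i]}:{self.leaf_bl[i]:.6g}" for i in members
            )
            parts.append(f"({leaves}):{self.group_bl[gi]:.6g}")
        return "(" + ",".join(parts) + ");"


@dataclass
class ScanResult:
    """Per-window topology-contrast rows."""

    window_index: np.ndarray
    midpoint: np.ndarray
    distance: np.ndarray  # bp to the nearest S-locus boundary
    logl_by_s_allele: np.ndarray
    logl_by_population: np.ndarray

    @property
    def delta_logl(self) -> np.ndarray:
        return self.logl_by_s_allele - self.logl_by_population


@dataclass(frozen=True)
class NullBand:
    p2_5: float
    p97_5: float
    n_draws: int

    def __post_init__(self) -> None:
        if self.p2_5 > self.p97_5:
            raise ValueError("p2_5 must be <= p97_5")


def build_grouping_topology(
    names, group_labels, key: str, branch_length: float = BRANCH_INIT
) -> GroupingTopology:
    """Deterministic rake-of-rakes topology for one grouping of the leaves."""
    labels = list(group_labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError(f"grouping by {key!r} yields a single group; topologies would coincide")
    order = {}
    for g in uniq:
        members = sorted(
            (i for i, lab in enumerate(labels) if lab == g), key=lambda i: names[i]
        )
        order[g] = members
    n = len(labels)
    return GroupingTopology(
        key=key,
        groups=order,
        leaf_names=tuple(names),
        leaf_bl=np.full(n, branch_length),
        group_bl=np.full(len(uniq), branch_length),
    )


def window_iter(n_sites: int, size: int = 50, step: int = 10):
    """Start indices of contiguous SNP windows; trailing partial window dropped."""
    if size < 2:
        raise ValueError("window size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if n_sites < size:
        warnings.warn(f"alignment has {n_sites} SNPs < window size {size}; no windows")
        return
    for start in range(0, n_sites - size + 1, step):
        yield start


# ---------------------------------------------------------------------------
# pruning likelihood


def _leaf_partials(sub: np.ndarray) -> np.ndarray:
    """(n_leaves, n_sites, 4) conditional likelihoods; missing rows are all-ones."""
    n, m = sub.shape
    part = np.zeros((n, m, 4))
    obs = sub >= 0
    part[~obs] = 1.0
    ii, jj = np.nonzero(obs)
    part[ii, jj, sub[ii, jj]] = 1.0
    return part


def _jc_message(v: np.ndarray, e: float) -> np.ndarray:
    """P(t) @ v under JC69 where e = exp(-4t/3); v is (..., 4)."""
    s = v.sum(axis=-1, keepdims=True)
    return e * v + (1.0 - e) * 0.25 * s


def _k80_matrix(t: float, kappa: float) -> np.ndarray:
    """K80 transition probability matrix, order A,C,G,T."""
    # rates normalised so t is the expected number of substitutions:
    # alpha + 2*beta = 1 with kappa = alpha/beta
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_b = np.exp(-4.0 * beta * t)
    e_ab = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_b + 0.5 * e_ab
    p_ts = 0.25 + 0.25 * e_b - 0.5 * e_ab
    p_tv = 0.25 - 0.25 * e_b
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    # transitions: A<->G (0,2), C<->T (1,3)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


class _PruningEngine:
    """Likelihood of a two-level GroupingTopology on a fixed site matrix."""

    def __init__(self, sub: np.ndarray, topo: GroupingTopology, model: str = "jc69",
                 kappa: float = 2.0):
        model = model.lower()
        if model not in ("jc69", "k80"):
            raise ValueError(f"unknown substitution model: {model!r}")
        self.model = model
        self.kappa = kappa
        self.topo = topo
        self.leaf_part = _leaf_partials(sub)  # (n, m, 4)
        self.members = [np.array(v) for v in topo.groups.values()]

    def _message(self, v: np.ndarray, t: float) -> np.ndarray:
        if self.model == "jc69":
            return _jc_message(v, np.exp(-4.0 * t / 3.0))
        return v @ _k80_matrix(t, self.kappa).T

    def loglik(self, leaf_bl: np.ndarray, group_bl: np.ndarray) -> float:
        m = self.leaf_part.shape[1]
        root = np.ones((m, 4))
        for gi, members in enumerate(self.members):
            cg = np.ones((m, 4))
            for i in members:
                cg *= self._message(self.leaf_part[i], leaf_bl[i])
            root *= self._message(cg, group_bl[gi])
        site_l = 0.25 * root.sum(axis=1)
        return float(np.sum(np.log(site_l)))

    # -- JC69 exact coordinate updates -------------------------------------
    def _optimize_jc(self, leaf_bl, group_bl, tol: float, max_sweeps: int = 30):
        e_lo, e_hi = np.exp(-4.0 * BRANCH_MAX / 3.0), np.exp(-4.0 * BRANCH_MIN / 3.0)
        m = self.leaf_part.shape[1]

        def messages():
            cgs, mgs = [], []
            for gi, members in enumerate(self.members):
                cg = np.ones((m, 4))
                for i in members:
                    cg *= _jc_message(self.leaf_part[i], np.exp(-4.0 * leaf_bl[i] / 3.0))
                cgs.append(cg)
                mgs.append(_jc_message(cg, np.exp(-4.0 * group_bl[gi] / 3.0)))
            return cgs, mgs

        def opt_linear(a: np.ndarray, b: np.ndarray) -> float:
            # maximise sum(log(a + b e)) for e in [e_lo, e_hi]; concave in e
            def neg(e):
                return -np.sum(np.log(np.maximum(a + b * e, 1e-300)))

            res = minimize_scalar(neg, bounds=(e_lo, e_hi), method="bounded",
                                  options={"xatol": 1e-10})
            return float(res.x)

        prev = -np.inf
        for _ in range(max_sweeps):
            cgs, mgs = messages()
            # group branches
            for gi in range(len(self.members)):
                rest = np.ones((m, 4))
                for gj, mg in enumerate(mgs):
                    if gj != gi:
                        rest *= mg
                cg = cgs[gi]
                s_cg = cg.sum(axis=1)
                # site L = 0.25 * sum_x rest[x] * (e*cg[x] + (1-e)*s_cg/4)
                base = 0.25 * (rest.sum(axis=1) * 0.25 * s_cg)
                lin = 0.25 * ((rest * cg).sum(axis=1) - rest.sum(axis=1) * 0.25 * s_cg)
                e = opt_linear(base, lin)
                group_bl[gi] = min(max(-0.75 * np.log(e), BRANCH_MIN), BRANCH_MAX)
                mgs[gi] = _jc_message(cg, np.exp(-4.0 * group_bl[gi] / 3.0))
            # leaf branches
            for gi, members in enumerate(self.members):
                rest_groups = np.ones((m, 4))
                for gj, mg in enumerate(mgs):
                    if gj != gi:
                        rest_groups *= mg
                for i in members:
                    cg_others = np.ones((m, 4))
                    for j in members:
                        if j != i:
                            cg_others *= _jc_message(
                                self.leaf_part[j], np.exp(-4.0 * leaf_bl[j] / 3.0)
                            )
                    v = self.leaf_part[i]
                    sv = v.sum(axis=1)
                    eg = np.exp(-4.0 * group_bl[gi] / 3.0)
                    # M_h = e*v + (1-e)*sv/4 ; C_g = cg_others * M_h
                    # M_g = eg*C_g + (1-eg)*sum(C_g)/4 ; L = 0.25*sum(rest*M_g)
                    const_part = 0.25 * sv[:, None] * cg_others  # (m,4)
                    lin_part = v * cg_others - const_part
                    rsum = rest_groups.sum(axis=1)
                    a = 0.25 * (
                        eg * (rest_groups * const_part).sum(axis=1)
                        + (1 - eg) * 0.25 * rsum * const_part.sum(axis=1)
                    )
                    b = 0.25 * (
                        eg * (rest_groups * lin_part).sum(axis=1)
                        + (1 - eg) * 0.25 * rsum * lin_part.sum(axis=1)
                    )
                    e = opt_linear(a, b)
                    leaf_bl[i] = min(max(-0.75 * np.log(e), BRANCH_MIN), BRANCH_MAX)
                # refresh this group's message
                cg = np.ones((m, 4))
                for j in members:
                    cg *= _jc_message(self.leaf_part[j], np.exp(-4.0 * leaf_bl[j] / 3.0))
                cgs[gi] = cg
                mgs[gi] = _jc_message(cg, np.exp(-4.0 * group_bl[gi] / 3.0))
            cur = self.loglik(leaf_bl, group_bl)
            if cur - prev < tol:
                break
            prev = cur
        return self.loglik(leaf_bl, group_bl), leaf_bl, group_bl

    def _optimize_generic(self, leaf_bl, group_bl, tol: float, max_sweeps: int = 20):
        prev = -np.inf
        for _ in range(max_sweeps):
            for gi in range(len(self.members)):
                def neg(t, gi=gi):
                    g = group_bl.copy()
                    g[gi] = t
                    return -self.loglik(leaf_bl, g)

                res = minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded", options={"xatol": 1e-8})
                group_bl[gi] = float(res.x)
            for i in range(len(leaf_bl)):
                def neg(t, i=i):
                    l = leaf_bl.copy()
                    l[i] = t
                    return -self.loglik(l, group_bl)

                res = minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded", options={"xatol": 1e-8})
                leaf_bl[i] = float(res.x)
            cur = self.loglik(leaf_bl, group_bl)
            if cur - prev < tol:
                break
            prev = cur
        return self.loglik(leaf_bl, group_bl), leaf_bl, group_bl

    def maximize(self, tol: float = 1e-6):
        leaf_bl = self.topo.leaf_bl.copy()
        group_bl = self.topo.group_bl.copy()
        if self.model == "jc69":
            return self._optimize_jc(leaf_bl, group_bl, tol)
        return self._optimize_generic(leaf_bl, group_bl, tol)


def loglik(
    sub_matrix: np.ndarray,
    topology: GroupingTopology,
    model: str = "jc69",
    tol: float = 1e-6,
) -> float:
    """Maximised log likelihood of a site matrix on a fixed grouping topology.

    Branch lengths are optimised coordinate-wise within [1e-9, 10]; missing
    bases (-1) contribute all-ones partial likelihoods.
    """
    bad = set(np.unique(sub_matrix)) - {-1, 0, 1, 2, 3}
    if bad:
        raise ValueError(f"unknown character states: {sorted(bad)}")
    engine = _PruningEngine(np.asarray(sub_matrix), topology, model=model)
    ll, _, _ = engine.maximize(tol=tol)
    return ll


def delta_loglik(
    sub_matrix: np.ndarray,
    names,
    s_alleles,
    populations,
    model: str = "jc69",
    tol: float = 1e-6,
) -> float:
    """logL(grouped by S-allele) - logL(grouped by population) for one window."""
    t_s = build_grouping_topology(names, s_alleles, key="s_allele")
    t_p = build_grouping_topology(names, populations, key="population")
    if list(t_s.groups.values()) == list(t_p.groups.values()):
        return 0.0
    return loglik(sub_matrix, t_s, model, tol) - loglik(sub_matrix, t_p, model, tol)


def scan(
    alignment: HaplotypeAlignment,
    s_locus: tuple[int, int],
    size: int = 50,
    step: int = 10,
    model: str = "jc69",
) -> ScanResult:
    """Sliding-window topology contrast along the alignment.

    ``s_locus`` is the (start, end) of the S-locus in the same coordinate
    system as alignment positions; window distance is measured from the
    window midpoint to the nearest S-locus boundary (0 inside the locus).
    """
    lo, hi = s_locus
    idx, mids, dists, ls, lp = [], [], [], [], []
    for wi, start in enumerate(window_iter(alignment.n_sites, size, step)):
        cols = slice(start, start + size)
        pos = alignment.positions[cols]
        mid = 0.5 * (pos[0] + pos[-1])
        if mid < lo:
            dist = lo - mid
        elif mid > hi:
            dist = mid - hi
        else:
            dist = 0.0
        t_s = build_grouping_topology(alignment.names, alignment.s_alleles, "s_allele")
        t_p = build_grouping_topology(alignment.names, alignment.populations, "population")
        sub = alignment.matrix[:, cols]
        l_s = loglik(sub, t_s, model)
        l_p = loglik(sub, t_p, model)
        idx.append(wi)
        mids.append(mid)
        dists.append(dist)
        ls.append(l_s)
        lp.append(l_p)
    return ScanResult(
        window_index=np.array(idx),
        midpoint=np.array(mids),
        distance=np.array(dists),
        logl_by_s_allele=np.array(ls),
        logl_by_population=np.array(lp),
    )


def null_band(
    control_alignments: list[HaplotypeAlignment],
    size: int = 50,
    n_draws: int = 1000,
    seed: int = 0,
    model: str = "jc69",
) -> NullBand:
    """Empirical 2.5/97.5 percentile band of delta logL in control regions.

    Draws ``n_draws`` contiguous windows of ``size`` SNPs uniformly over all
    valid window starts across the control alignments.
    """
    rng = np.random.default_rng(seed)
    starts = []
    for ci, aln in enumerate(control_alignments):
        if aln.n_sites >= size:
            starts.extend((ci, s) for s in range(aln.n_sites - size + 1))
    if not starts:
        raise ValueError(f"control regions contain no window of {size} SNPs")
    picks = rng.integers(0, len(starts), size=n_draws)
    deltas = np.empty(n_draws)
    for k, p in enumerate(picks):
        ci, s = starts[p]
        aln = control_alignments[ci]
        deltas[k] = delta_loglik(
            aln.matrix[:, s : s + size],
            aln.names,
            aln.s_alleles,
            aln.populations,
            model=model,
        )
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return NullBand(p2_5=float(lo), p97_5=float(hi), n_draws=n_draws)


def distance_correlation(result: ScanResult) -> tuple[float, float]:
    """Pearson correlation of delta logL with distance to the S-locus.

    Returns (nan, nan) when either variable has zero variance.
    """
    if len(result.window_index) < 3:
        raise ValueError("need at least 3 windows")
    d, y = result.distance, result.delta_logl
    if np.ptp(d) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r, p = pearsonr(d, y)
    return float(r), float(p)
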