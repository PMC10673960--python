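"""Linkage-group assembly and marker ordering.

The mapper is a two-point engine: recombination fractions and LOD scores for
marker pairs, single-linkage grouping over the LOD-thresholded pair graph,
and seriation (greedy nearest-neighbour construction plus restarted 2-opt
refinement) within groups. On top sit the map-refinement rules used for the
snail cross: pruning SNPs whose normalised location-wise LOD support is more
than one standard deviation below the location mean, removal of contigs that
straddle linkage groups, sex-averaging of the two parental maps, and the
digit-pair to F2 genotype-code conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .sim import MISSING, GenotypeCalls, haldane_cm

__all__ = [
    "TwoPointResult", "GroupingParams", "OrderedMap", "Transmissions",
    "estimate_rf", "pairwise_rf", "group_markers", "order_markers",
    "prune_by_lod", "resolve_contig_conflicts", "sex_average", "to_f2_codes",
    "infer_transmissions",
]

_LN10 = np.log(10.0)
# distances are capped here before applying the map function so that a nearly
# uninformative adjacency (r -> 0.5) cannot blow up the map length
_R_CAP = 0.45


@dataclass(frozen=True)
class TwoPointResult:
    r_hat: float
    lod: float
    n_informative: int
    uninformative: bool = False


@dataclass(frozen=True)
class GroupingParams:
    lod_limit: float = 9.5
    size_limit: int = 600
    join_singles_lod: float = 5.0
    distortion_aware: bool = True

    def __post_init__(self):
        if self.join_singles_lod > self.lod_limit:
            raise ValueError("join_singles_lod must not exceed lod_limit")


def _binomial_two_point(k: int, n: int) -> TwoPointResult:
    """ML two-point from recombinant counts of phase-known meioses.

    The linkage phase between the two markers is itself free, so the count is
    folded (min(k, n-k)) before maximising r^k (1-r)^(n-k) over r in [0, 1/2].
    """
    if n == 0:
        return TwoPointResult(0.5, 0.0, 0, uninformative=True)
    k = int(min(k, n - k))
    r = k / n
    with np.errstate(divide="ignore"):
        ll = k * np.log10(r) if k else 0.0
        ll += (n - k) * np.log10(1.0 - r) if k < n else 0.0
    lod = max(ll + n * np.log10(2.0), 0.0)
    return TwoPointResult(float(r), float(lod), int(n))


def _intercross_joint(r: float) -> np.ndarray:
    """P(code1, code2 | r) over {AA, AB, BB}^2 for an intercross pair.

    Codes index transmitted parental strands (AA = haplotype 1 from both
    parents); paternal and maternal meioses recombine independently.
    """
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    code_of = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
    P = np.zeros((3, 3))
    for s in states:
        for t in states:
            p = 0.25
            p *= (1 - r) if s[0] == t[0] else r
            p *= (1 - r) if s[1] == t[1] else r
            P[code_of[s], code_of[t]] += p
    return P


def _intercross_two_point(c1: np.ndarray, c2: np.ndarray) -> TwoPointResult:
    """ML two-point from unphased F2 codes, marginalising transmitted phase."""
    shared = (c1 != MISSING) & (c2 != MISSING)
    n = int(shared.sum())
    if n == 0:
        return TwoPointResult(0.5, 0.0, 0, uninformative=True)
    table = np.zeros((3, 3))
    np.add.at(table, (c1[shared], c2[shared]), 1.0)

    def nll(r):
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(_intercross_joint(r), 1e-300))
        return -(table * logp).sum()

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 0.5), method="bounded",
                                   options={"xatol": 1e-10})
    r_hat = float(res.x)
    lod = max((nll(0.5) - nll(r_hat)) / _LN10, 0.0)
    if r_hat < 1e-7:
        r_hat = 0.0
    return TwoPointResult(r_hat, float(lod), 2 * n)


def estimate_rf(g1, g2, phased: bool = True) -> TwoPointResult:
    """Two-point recombination fraction and LOD for one marker pair.

    With ``phased=True`` the inputs are transmitted-haplotype digits (1/2,
    -1 missing) of a single parent's meioses and the estimate is the folded
    binomial ML. With ``phased=False`` the inputs are F2 genotype codes
    (0=AA, 1=AB, 2=BB, -1 missing) and the likelihood marginalises the
    unobserved transmitted phase of heterozygotes (the EM fixed point,
    obtained here by direct 1-D maximisation). LOD is log10 L(r_hat)/L(1/2),
    clipped at zero.
    """
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    if phased:
        shared = (g1 != MISSING) & (g2 != MISSING)
        n = int(shared.sum())
        k = int((g1[shared] != g2[shared]).sum())
        return _binomial_two_point(k, n)
    return _intercross_two_point(g1, g2)


def pairwise_rf(digits: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs folded two-point estimates from phase-known digit matrices.

    ``digits`` has shape (markers, meioses) with values 1/2 and -1 missing.
    Returns (r_hat, lod, n_informative) matrices; pairs with no shared
    informative meioses get r=0.5, lod=0.
    """
    d = np.asarray(digits)
    V = (d != MISSING).astype(np.float64)
    A = ((d == 2) & (d != MISSING)).astype(np.float64)
    B = ((d == 1) & (d != MISSING)).astype(np.float64)
    N = V @ V.T
    K = A @ B.T + B @ A.T
    Kf = np.minimum(K, N - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, Kf / np.maximum(N, 1.0), 0.5)
        lod = (np.where(Kf > 0, Kf * np.log10(np.maximum(r, 1e-300)), 0.0)
               + np.where(N - Kf > 0, (N - Kf) * np.log10(np.maximum(1.0 - r, 1e-300)), 0.0)
               + N * np.log10(2.0))
    lod = np.where(N > 0, np.maximum(lod, 0.0), 0.0)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, N.astype(np.int64)


def intercross_pairwise_rf(codes: np.ndarray, n_iter: int = 60
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs phase-marginal ML two-point from F2 codes.

    ``codes`` has shape (markers, offspring) over {0, 1, 2, -1}. Each
    offspring carries two meioses; heterozygous transmitted phase is
    marginalised via the EM fixed point, vectorised over pairs through the
    9-category joint code counts:

        P(AA,AA)=P(BB,BB)=t^2/4     (0 recombinant transmissions)
        P(AA,BB)=P(BB,AA)=r^2/4     (2)
        P(hom,AB)=P(AB,hom)=r t / 2 (1)
        P(AB,AB)=(t^2+r^2)/2        (0 or 2),  t = 1 - r.

    Returns (r_hat, lod, n_meioses) matrices; pairs with no shared
    offspring get r=0.5, lod=0.
    """
    c = np.asarray(codes)
    I = [(c == g).astype(np.float64) for g in range(3)]
    n_cat = {(a, b): I[a] @ I[b].T for a in range(3) for b in range(3)}
    A = n_cat[(0, 0)] + n_cat[(2, 2)]
    D = n_cat[(0, 2)] + n_cat[(2, 0)]
    C = n_cat[(0, 1)] + n_cat[(1, 0)] + n_cat[(1, 2)] + n_cat[(2, 1)]
    H = n_cat[(1, 1)]
    N = A + C + D + H
    safeN = np.maximum(N, 1.0)
    r = np.full(A.shape, 0.25)
    for _ in range(n_iter):
        t = 1.0 - r
        hh = np.where(H > 0, H * 2.0 * r * r / np.maximum(t * t + r * r, 1e-300), 0.0)
        r = (C + 2.0 * D + hh) / (2.0 * safeN)
    r = np.minimum(r, 0.5)
    t = 1.0 - r

    def xlog(cnt, ratio):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(cnt > 0, cnt * np.log10(np.maximum(ratio, 1e-300)), 0.0)

    lod = (xlog(A, 4.0 * t * t) + xlog(D, 4.0 * r * r)
           + xlog(C, 4.0 * r * t) + xlog(H, 2.0 * (t * t + r * r)))
    lod = np.where(N > 0, np.maximum(lod, 0.0), 0.0)
    r = np.where(N > 0, r, 0.5)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, (2 * N).astype(np.int64)


def group_markers(lod: np.ndarray, params: GroupingParams | None = None) -> np.ndarray:
    """Assign markers to linkage groups from the all-pairs LOD matrix.

    Single-linkage transitive closure over pairs with LOD >= lod_limit;
    groups smaller than size_limit are dissolved to singletons; singletons
    are then joined to the group of their best-linked marker when that LOD
    clears join_singles_lod. Returns 1-based group labels (0 = unassigned),
    numbered by decreasing group size.
    """
    if params is None:
        params = GroupingParams()
    lod = np.asarray(lod, dtype=float)
    m = lod.shape[0]
    adj = csr_matrix(lod >= params.lod_limit)
    _, labels = connected_components(adj, directed=False)
    assigned = np.full(m, -1, dtype=np.int64)
    for comp in np.unique(labels):
        members = np.flatnonzero(labels == comp)
        if len(members) >= max(params.size_limit, 1):
            assigned[members] = comp
    # join singletons to the group holding their best-linked marker
    grouped = assigned >= 0
    if grouped.any():
        for i in np.flatnonzero(~grouped):
            partners = np.flatnonzero(grouped)
            best = partners[np.argmax(lod[i, partners])]
            if lod[i, best] >= params.join_singles_lod:
                assigned[i] = assigned[best]
    # renumber by size, largest first; ties by smallest member index
    out = np.zeros(m, dtype=np.int64)
    comps = [c for c in np.unique(assigned) if c >= 0]
    comps.sort(key=lambda c: (-int((assigned == c).sum()),
                              int(np.flatnonzero(assigned == c)[0])))
    for rank, c in enumerate(comps, start=1):
        out[assigned == c] = rank
    return out


@dataclass
class OrderedMap:
    order: np.ndarray  # indices into the input marker set
    marker_ids: list[str]
    cm_male: np.ndarray
    cm_female: np.ndarray

    @property
    def cm_avg(self) -> np.ndarray:
        return 0.5 * (self.cm_male + self.cm_female)


def _path_cost(order: np.ndarray, D: np.ndarray) -> float:
    return float(D[order[:-1], order[1:]].sum())


def _greedy_path(D: np.ndarray, ids: list[str], start: int) -> np.ndarray:
    m = D.shape[0]
    used = np.zeros(m, dtype=bool)
    path = [start]
    used[start] = True
    while len(path) < m:
        free = np.flatnonzero(~used)
        d_head = D[path[0], free]
        d_tail = D[path[-1], free]
        # candidate with the smallest attachment cost; ties by marker id
        bh = _argmin_tied(d_head, free, ids)
        bt = _argmin_tied(d_tail, free, ids)
        if D[path[0], bh] < D[path[-1], bt] or (
                D[path[0], bh] == D[path[-1], bt] and ids[bh] < ids[bt]):
            path.insert(0, bh)
            used[bh] = True
        else:
            path.append(bt)
            used[bt] = True
    return np.asarray(path)


def _argmin_tied(dists: np.ndarray, candidates: np.ndarray, ids: list[str]) -> int:
    best = np.flatnonzero(dists == dists.min())
    tied = candidates[best]
    return int(min(tied, key=lambda i: ids[i]))


def _two_opt(order: np.ndarray, D: np.ndarray) -> np.ndarray:
    # reverse segment [i, j): edge deltas evaluated vectorised over j
    order = order.copy()
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            o = order
            js = np.arange(i + 2, m + 1)
            if i == 0:
                js = js[js != m]  # full reversal changes nothing
            if not js.size:
                continue
            inner = js < m
            j_in = np.where(inner, js, m - 1)
            delta = np.where(inner, D[o[i], o[j_in]] - D[o[j_in - 1], o[j_in]], 0.0)
            if i > 0:
                delta += D[o[i - 1], o[js - 1]] - D[o[i - 1], o[i]]
            k = int(np.argmin(delta))
            if delta[k] < -1e-12:
                j = int(js[k])
                order[i:j] = order[i:j][::-1]
                improved = True
    return order


def order_markers(rf: np.ndarray, marker_ids: list[str],
                  rf_male: np.ndarray | None = None,
                  rf_female: np.ndarray | None = None,
                  map_fun=haldane_cm, n_restarts: int = 20,
                  seed: int = 0) -> OrderedMap:
    """Order one linkage group's markers and assign parental cM positions.

    The order minimises the sum of adjacent recombination fractions (greedy
    nearest-neighbour construction, 2-opt refinement, ``n_restarts`` random
    restarts keeping the best). Orientation is canonicalised so the first
    marker id precedes the last lexicographically. Parental cM positions are
    cumulative map-function images of the adjacent per-parent fractions,
    falling back to the sex-combined fraction where a parent is
    uninformative for a given adjacency.
    """
    rf = np.asarray(rf, dtype=float)
    m = rf.shape[0]
    if m < 2:
        raise ValueError("a group must contain at least two markers to order")
    D = np.where(np.isnan(rf), 0.5, rf)
    if np.all(D[~np.eye(m, dtype=bool)] >= 0.5):
        warnings.warn("all marker pairs uninformative; keeping input order")
        zeros = np.zeros(m)
        return OrderedMap(np.arange(m), list(marker_ids), zeros, zeros.copy())

    best: np.ndarray | None = None
    best_cost = np.inf
    for rep in range(max(n_restarts, 1)):
        rng = np.random.default_rng(seed + rep)
        start = int(rng.integers(m))
        order = _two_opt(_greedy_path(D, list(marker_ids), start), D)
        cost = _path_cost(order, D)
        if cost < best_cost - 1e-12:
            best, best_cost = order, cost
    assert best is not None
    if marker_ids[best[0]] > marker_ids[best[-1]]:
        best = best[::-1]

    def positions(r_parent):
        adj = D[best[:-1], best[1:]]
        if r_parent is not None:
            rp = np.asarray(r_parent, dtype=float)[best[:-1], best[1:]]
            adj = np.where(np.isnan(rp) | (rp >= 0.5), adj, rp)
        return np.concatenate([[0.0], np.cumsum(map_fun(np.minimum(adj, _R_CAP)))])

    return OrderedMap(best, [marker_ids[i] for i in best],
                      positions(rf_male), positions(rf_female))


def prune_by_lod(lod_by_location) -> list[np.ndarray]:
    """Location-wise pruning of weakly supported SNPs.

    ``lod_by_location`` is a sequence of 1-D arrays, one per map location,
    giving each co-located SNP's maximum pairwise LOD. Scores are normalised
    to [0, 1] by the location maximum; a SNP is removed iff its normalised
    score falls more than one sample standard deviation below the location
    mean. Locations with a single SNP are never pruned.
    """
    masks = []
    for values in lod_by_location:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            masks.append(np.zeros(v.size, dtype=bool))
            continue
        top = v.max()
        norm = v / top if top > 0 else np.zeros_like(v)
        mu, sd = norm.mean(), norm.std(ddof=1)
        masks.append(norm < mu - sd)
    return masks


def resolve_contig_conflicts(map_df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove SNPs from contigs that straddle linkage groups.

    A contig on >= 2 groups is removed completely when it has <= 10 mapped
    SNPs; otherwise its SNPs are dropped from every group holding < 10% of
    the contig's mapped SNPs. A large contig still straddling groups after
    the 10% rule is removed entirely (logged separately). Single-group
    contigs are untouched.
    """
    drop = np.zeros(len(map_df), dtype=bool)
    log: dict[str, list[str]] = {"small_split_contig": [],
                                 "minor_lg_fraction": [],
                                 "unresolved_split_contig": []}
    for contig, sub in map_df.groupby("contig_id"):
        lgs = sub["lg"].unique()
        if len(lgs) < 2:
            continue
        total = len(sub)
        if total <= 10:
            drop[sub.index] = True
            log["small_split_contig"].append(str(contig))
            continue
        counts = sub["lg"].value_counts()
        minor = counts[counts / total < 0.10].index
        if len(minor):
            drop[sub.index[sub["lg"].isin(minor)]] = True
            log["minor_lg_fraction"].append(str(contig))
        if len(counts) - len(minor) >= 2:
            drop[sub.index] = True
            log["unresolved_split_contig"].append(str(contig))
    kept = map_df.loc[~drop].reset_index(drop=True)
    return kept, {k: sorted(v) for k, v in log.items()}


def sex_average(map_df: pd.DataFrame) -> pd.DataFrame:
    """Average the two parental positions; per-group length follows cm_avg."""
    out = map_df.copy()
    out["cm_avg"] = 0.5 * (out["cm_male"] + out["cm_female"])
    return out


_F2_CODE = {"1 1": 0, "1 2": 1, "2 1": 1, "2 2": 2}


def to_f2_codes(phased) -> np.ndarray:
    """Convert transmitted digit pairs ('1 2' style strings) to F2 codes.

    '1 1' -> AA (0); '1 2' and '2 1' -> AB (1); '2 2' -> BB (2); anything
    else -> missing (-1).
    """
    arr = np.asarray(phased, dtype=object)
    flat = np.array([_F2_CODE.get(str(x).strip(), MISSING) for x in arr.reshape(-1)],
                    dtype=np.int8)
    return flat.reshape(arr.shape)


@dataclass
class Transmissions:
    """Per-offspring transmission digits and F2 codes inferred from calls."""

    offspring: list[str]
    pat_digit: np.ndarray  # (M, n_off) in {1, 2, -1}
    mat_digit: np.ndarray
    f2: np.ndarray  # (M, n_off) in {0, 1, 2, -1}; coded only at both-het markers
    both_het: np.ndarray  # (M,) bool


def infer_transmissions(calls: GenotypeCalls, offspring: list[str],
                        informative_parent: str = "P1",
                        other_parent: str = "P2") -> Transmissions:
    """Resolve transmitted parental haplotypes from called genotypes.

    Requires the informative parent's calls to be heterozygous and phased
    (haplotype 1 listed first). At markers where the other parent is
    homozygous, the paternal digit follows directly from the offspring call;
    at markers heterozygous (and phased) in both parents, homozygous
    offspring resolve both digits and heterozygous offspring yield the
    merged AB code with unresolved digits.
    """
    p1 = calls.sample_index(informative_parent)
    p2 = calls.sample_index(other_parent)
    off_idx = [calls.sample_index(s) for s in offspring]
    G = calls.G[:, off_idx]
    M, n = G.shape

    p1_het = (calls.G[:, p1] == 1) & (calls.PH[:, p1] != MISSING)
    a1p = np.where(calls.PH[:, p1] == 1, 1, 0)  # P1 haplotype-1 allele
    p2_het = (calls.G[:, p2] == 1) & (calls.PH[:, p2] != MISSING)
    a1m = np.where(calls.PH[:, p2] == 1, 1, 0)
    p2_hom = np.isin(calls.G[:, p2], (0, 2))
    c = (calls.G[:, p2] // 2).astype(np.int8)  # other parent's homozygous allele

    pat = np.full((M, n), MISSING, dtype=np.int8)
    mat = np.full((M, n), MISSING, dtype=np.int8)
    f2 = np.full((M, n), MISSING, dtype=np.int8)

    valid = G != MISSING
    # pseudo-testcross markers: paternal digit from the offspring call
    pt = (p1_het & p2_hom)[:, None] & valid
    pat_allele = G - c[:, None]
    ok = pt & np.isin(pat_allele, (0, 1))
    digit = np.where(pat_allele == a1p[:, None], 1, 2).astype(np.int8)
    pat[ok] = digit[ok]

    # fully informative markers: homozygous offspring resolve both meioses
    bh = (p1_het & p2_het)[:, None] & valid
    hom0 = bh & (G == 0)
    hom2 = bh & (G == 2)
    for mask, allele in ((hom0, 0), (hom2, 1)):
        dp = np.broadcast_to(np.where(a1p == allele, 1, 2).astype(np.int8)[:, None], (M, n))
        dm = np.broadcast_to(np.where(a1m == allele, 1, 2).astype(np.int8)[:, None], (M, n))
        pat[mask] = dp[mask]
        mat[mask] = dm[mask]
        code = np.where(dp == dm, np.where(dp == 1, 0, 2), 1).astype(np.int8)
        f2[mask] = code[mask]
    het = bh & (G == 1)
    aligned = (a1p == a1m)[:, None]
    f2[het & aligned] = 1  # AB; digits stay unresolved

    return Transmissions(
        offspring=list(offspring),
        pat_digit=pat, mat_digit=mat, f2=f2,
        both_het=(p1_het & p2_het),
    )
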