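"""Binary-trait genome scan over HMM genotype probabilities.

The scan follows the intercross analysis style of qtl2-like tools: posterior
genotype probabilities over {AA, AB, BB} from a hidden Markov chain with
Haldane transitions and a symmetric genotyping-error emission model; a
per-position logistic-regression LOD against the intercept-only null; a
permutation null distribution of the genome-wide maximum for the
significance threshold; peak calling with a LOD-drop rule; Bayes credible
intervals from normalised 10^LOD mass; per-genotype allele effects on the
log-odds scale; and the raw-genotype segregation validation that rejects
candidate positions incompatible with a fully penetrant dominance model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .sim import MISSING, haldane_r

__all__ = [
    "ScanParams", "CredibleInterval", "Peak",
    "calc_genoprob", "binary_scan", "permutation_threshold", "find_peaks",
    "bayes_interval", "allele_effects", "segregation_check", "candidate_region",
]

_LN10 = np.log(10.0)
_MU_CLAMP = 1e-12
_EFFECT_CAP = 20.0
_MAX_ITER = 100


@dataclass(frozen=True)
class ScanParams:
    genotyping_error: float = 0.002
    n_perm: int = 1000
    alpha: float = 0.05
    peakdrop: float = 1.8
    ci_prob: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.genotyping_error < 0.5:
            raise ValueError("genotyping_error must lie in [0, 0.5)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.peakdrop <= 0:
            raise ValueError("peakdrop must be positive")


def _transition(r: float) -> np.ndarray:
    """Intercross one-step transition matrix over {AA, AB, BB}."""
    s, t = 1.0 - r, r
    return np.array([
        [s * s, 2 * s * t, t * t],
        [s * t, s * s + t * t, s * t],
        [t * t, 2 * s * t, s * s],
    ])


def calc_genoprob(positions_cm, codes, error_prob: float = 0.002) -> np.ndarray:
    """Posterior genotype probabilities along one linkage group.

    ``codes`` has shape (individuals, positions) over {0=AA, 1=AB, 2=BB,
    -1=missing}; ``positions_cm`` must be non-decreasing. The chain starts
    from the intercross prior (1/4, 1/2, 1/4), transitions follow the
    Haldane fraction of each adjacent gap, and the true genotype is observed
    with probability 1 - error_prob (each wrong genotype error_prob / 2);
    missing codes are uninformative. Returns (individuals, positions, 3).
    """
    pos = np.asarray(positions_cm, dtype=float)
    codes = np.atleast_2d(np.asarray(codes))
    n, P = codes.shape
    if P != pos.size:
        raise ValueError("codes and positions differ in length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("map positions must be ordered (non-decreasing)")
    eps = float(error_prob)

    E = np.full((n, P, 3), eps / 2.0)
    for g in range(3):
        E[..., g][codes == g] = 1.0 - eps
    E[codes == MISSING] = 1.0

    T = [_transition(haldane_r(d)) for d in np.diff(pos)]
    pi = np.array([0.25, 0.5, 0.25])

    alpha = np.empty((n, P, 3))
    a = pi * E[:, 0]
    a = _normalize(a)
    alpha[:, 0] = a
    for t in range(1, P):
        a = (a @ T[t - 1]) * E[:, t]
        a = _normalize(a)
        alpha[:, t] = a

    beta = np.empty((n, P, 3))
    b = np.ones((n, 3))
    beta[:, P - 1] = b
    for t in range(P - 2, -1, -1):
        b = (E[:, t + 1] * b) @ T[t].T
        b = _normalize(b)
        beta[:, t] = b

    post = alpha * beta
    return _normalize(post.reshape(-1, 3)).reshape(n, P, 3)


def _normalize(a: np.ndarray) -> np.ndarray:
    s = a.sum(axis=-1, keepdims=True)
    bad = s[..., 0] == 0
    if np.any(bad):
        warnings.warn("zero-probability observation path; using uniform state weights")
        a = a.copy()
        a[bad] = 1.0
        s = a.sum(axis=-1, keepdims=True)
    return a / s


def _fit_logistic(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched capped-IRLS logistic fits.

    X: (P, n, k) design per position; Y: (B, n) binary responses. Returns
    (beta (B, P, k), loglik (B, P)). Separation is handled by capping the
    coefficients at +/-20 log-odds and clamping fitted probabilities, which
    bounds the likelihood instead of diverging.
    """
    P, n, k = X.shape
    B = Y.shape[0]
    beta = np.zeros((B, P, k))
    Yb = Y[:, None, :]
    for _ in range(_MAX_ITER):
        eta = np.einsum("pnk,bpk->bpn", X, beta)
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = np.einsum("pnk,bpn->bpk", X, Yb - mu)
        H = np.einsum("pni,bpn,pnj->bpij", X, W, X)
        H += 1e-9 * np.eye(k)
        delta = np.linalg.solve(H, grad[..., None])[..., 0]
        new = np.clip(beta + delta, -_EFFECT_CAP, _EFFECT_CAP)
        moved = np.max(np.abs(new - beta))
        beta = new
        if moved < 1e-9:  # capped coordinates stop moving once pinned
            break
    eta = np.einsum("pnk,bpk->bpn", X, beta)
    mu = np.clip(expit(eta), _MU_CLAMP, 1.0 - _MU_CLAMP)
    ll = (Yb * np.log(mu) + (1.0 - Yb) * np.log1p(-mu)).sum(axis=-1)
    return beta, ll


def _null_loglik(Y: np.ndarray) -> np.ndarray:
    n = Y.shape[-1]
    s = Y.sum(axis=-1)
    p = np.clip(s / n, _MU_CLAMP, 1.0 - _MU_CLAMP)
    return s * np.log(p) + (n - s) * np.log1p(-p)


def _scan_lod(probs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD profile(s) from genotype-probability covariates.

    The design uses the three class-probability columns directly (their sum
    is 1, so the column space equals intercept + AB/BB contrasts with AA as
    baseline) which keeps the coefficient cap interpretable as a cap on the
    per-class log-odds.
    """
    X = np.transpose(probs, (1, 0, 2))
    _, ll = _fit_logistic(X, Y)
    lod = (ll - _null_loglik(Y)[:, None]) / _LN10
    return np.clip(lod, 0.0, None)


def binary_scan(probs: np.ndarray, phenotype) -> np.ndarray:
    """Per-position LOD of a binary trait given genotype probabilities.

    ``probs`` is (individuals, positions, 3). A phenotype with a single
    class carries no information: the scan is all zeros with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    if probs.shape[0] != y.size:
        raise ValueError("phenotype length does not match genotype probabilities")
    if len(np.unique(y)) < 2:
        warnings.warn("phenotype has a single class; LOD is 0 everywhere")
        return np.zeros(probs.shape[1])
    return _scan_lod(probs, y[None, :])[0]


def permutation_threshold(probs: np.ndarray, phenotype,
                          params: ScanParams | None = None) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted ``n_perm`` times (seeded); the
    threshold is the empirical (1 - alpha) quantile of the permuted
    genome-wide maximum LOD.
    """
    if params is None:
        params = ScanParams()
    if params.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(params.seed)
    perms = np.array([rng.permutation(y) for _ in range(params.n_perm)])
    n, P, _ = probs.shape
    block = max(1, int(2e7 / max(P * n, 1)))  # bound working-set memory
    maxima = np.concatenate([
        _scan_lod(probs, perms[i:i + block]).max(axis=1)
        for i in range(0, params.n_perm, block)
    ])
    return float(np.quantile(maxima, 1.0 - params.alpha))


@dataclass(frozen=True)
class Peak:
    index: int
    position_cm: float
    lod: float


def find_peaks(lod, threshold: float, peakdrop: float = 1.8,
               positions_cm=None) -> list[Peak]:
    """Supra-threshold LOD peaks under the LOD-drop independence rule.

    Adjacent local maxima are independent only if the LOD drops by at least
    ``peakdrop`` below both of them somewhere in between; otherwise they are
    merged and the higher maximum represents the merged peak.
    """
    lod = np.asarray(lod, dtype=float)
    pos = (np.asarray(positions_cm, dtype=float) if positions_cm is not None
           else np.arange(lod.size, dtype=float))
    # local maxima (plateaus collapse to their first index)
    cand = []
    for i in range(lod.size):
        left = lod[i - 1] if i > 0 else -np.inf
        right = lod[i + 1] if i < lod.size - 1 else -np.inf
        if lod[i] > threshold and lod[i] > left and lod[i] >= right:
            cand.append(i)
    kept: list[int] = []
    for c in cand:
        while kept:
            last = kept[-1]
            valley = lod[last:c + 1].min()
            if valley <= min(lod[last], lod[c]) - peakdrop:
                break  # independent
            if lod[c] > lod[last]:
                kept.pop()  # the new maximum absorbs the previous one
                continue
            c = None  # absorbed into the previous (higher or equal) peak
            break
        if c is not None:
            kept.append(c)
    return [Peak(int(i), float(pos[i]), float(lod[i])) for i in kept]


@dataclass(frozen=True)
class CredibleInterval:
    start_cm: float
    end_cm: float
    lo_index: int
    hi_index: int


def bayes_interval(lod, positions_cm, peak_index: int,
                   ci_prob: float = 0.95) -> CredibleInterval:
    """Smallest contiguous span around a peak holding >= ci_prob of the
    posterior mass proportional to 10^LOD over the group's positions.

    Ties on position count are broken by cM width, then leftmost.
    """
    lod = np.asarray(lod, dtype=float)
    pos = np.asarray(positions_cm, dtype=float)
    mass = np.power(10.0, lod - lod.max())
    mass /= mass.sum()
    best = None
    for width in range(lod.size):
        spans = []
        for i in range(max(0, peak_index - width), peak_index + 1):
            j = i + width
            if j >= lod.size or j < peak_index:
                continue
            if mass[i:j + 1].sum() >= ci_prob - 1e-12:
                spans.append((pos[j] - pos[i], i, j))
        if spans:
            _, i, j = min(spans)
            best = CredibleInterval(float(pos[i]), float(pos[j]), i, j)
            break
    if best is None:  # numerically defensive: whole group
        best = CredibleInterval(float(pos[0]), float(pos[-1]), 0, lod.size - 1)
    return best


def allele_effects(probs: np.ndarray, phenotype) -> np.ndarray:
    """Per-position log-odds of the trait for each genotype class.

    Fits the trait on the three genotype-probability columns without an
    intercept, so the coefficients are directly the class effects; they are
    capped at +/-20 log-odds under separation.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn("phenotype has a single class; effects are degenerate")
    X = np.transpose(probs, (1, 0, 2))
    beta, _ = _fit_logistic(X, y[None, :])
    return beta[0]


def segregation_check(codes, phenotype, positions_cm=None,
                      label1_homozygote: int = 2) -> pd.DataFrame:
    """Validate candidate positions against the raw genotype codes.

    Under a fully penetrant dominance model driven by the informative
    parent's transmission, one homozygote class must show phenotype 1 and
    the other phenotype 0, with heterozygotes split. ``label1_homozygote``
    names the class (0=AA or 2=BB) expected to carry phenotype 1 (taken in
    practice from the sign of the allele effects at the peak). Counts
    phenotype-incompatible homozygotes per position; AB never counts.
    """
    if label1_homozygote not in (0, 2):
        raise ValueError("label1_homozygote must be 0 (AA) or 2 (BB)")
    codes = np.atleast_2d(np.asarray(codes))
    y = np.asarray(phenotype)
    other = 2 - label1_homozygote
    viol = (((codes == label1_homozygote) & (y[:, None] == 0))
            | ((codes == other) & (y[:, None] == 1))).sum(axis=0)
    informative = (codes != MISSING).any(axis=0)
    pos = (np.asarray(positions_cm, dtype=float) if positions_cm is not None
           else np.arange(codes.shape[1], dtype=float))
    return pd.DataFrame({
        "position_cm": pos,
        "violations": viol,
        "informative": informative,
        "consistent": (viol == 0) & informative,
    })


def candidate_region(consistent_positions_cm, contigs_by_position=None) -> dict:
    """Report the candidate span of trait-pattern-consistent positions.

    ``consistent_positions_cm`` are the positions that both lie in a
    supported credible interval and pass the segregation check. Width is
    reported to 1 decimal place; contigs are the union over the positions.
    """
    pos = sorted(float(p) for p in consistent_positions_cm)
    if not pos:
        return {"localized": False, "span_cm": None, "width_cm": None,
                "contigs": [], "message": "locus not localised"}
    contigs: set[str] = set()
    if contigs_by_position:
        for p in pos:
            contigs |= set(contigs_by_position.get(p, ()))
    return {
        "localized": True,
        "span_cm": (pos[0], pos[-1]),
        "width_cm": round(pos[-1] - pos[0], 1),
        "contigs": sorted(contigs),
    }
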