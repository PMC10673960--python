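"""Synthetic full-sib cross generator.

Emulates the structure of a two-generation laboratory cross of an outbred,
hermaphroditic snail: two grandparents, two parents (one of which — the
"informative" parent — is heterozygous at both trait loci), and a family of
full-sib offspring genotyped at SNP markers that are heterozygous in the
informative parent. Shell ground colour segregates pink-dominant over yellow;
the mid-band locus is dominant for band suppression. Both phenotypes are
deterministic functions of the transmitted trait alleles.

Meioses follow a Haldane (no-interference) model: crossover counts per linkage
group are Poisson with mean length/100, breakpoints uniform. Genotype calls
are corrupted by a symmetric error process, masked completely at random, and
annotated with negative-binomial read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .published import LG_LENGTHS_CM

__all__ = [
    "MarkerDef",
    "TraitLocus",
    "CrossConfig",
    "GenotypeCalls",
    "SimulatedDataset",
    "haldane_r",
    "haldane_cm",
    "simulate_genome",
    "simulate_meiosis",
    "simulate_cross",
    "default_trait_loci",
]

MISSING = -1  # genotype / depth sentinel


def haldane_r(d_cm):
    """Haldane map function: distance in cM -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, in [0, 0.5). Assumes no crossover
    interference, consistent with the Poisson crossover model used in
    :func:`simulate_meiosis` and with the Markov chain of the genotype HMM.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def haldane_cm(r):
    """Inverse Haldane map function: recombination fraction -> distance in cM."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class MarkerDef:
    """A mapped SNP marker: identity, physical origin and genetic position."""

    marker_id: str
    contig_id: str
    bp_pos: int  # 0-based
    lg: int  # 1-based linkage group index
    cm_pos: float


@dataclass(frozen=True)
class TraitLocus:
    """A Mendelian binary-trait locus segregating in the cross.

    ``dominant_phenotype`` is the binary label (0 or 1) that the dominant
    allele produces: the shell-colour locus C scores yellow (recessive) as 1,
    so its dominant (pink) phenotype is labelled 0; the mid-band locus U
    scores the dominant mid-banded phenotype as 1.
    """

    name: str
    lg: int
    cm_pos: float
    dominant_allele: str = "D"
    dominant_phenotype: int = 0
    informative_parent: str = "P1"


def default_trait_loci() -> list[TraitLocus]:
    """The two study trait loci: colour C (pink > yellow, supergene LG) and
    mid-band U (band suppression dominant), on different linkage groups."""
    return [
        TraitLocus("C", lg=11, cm_pos=32.0, dominant_allele="CP",
                   dominant_phenotype=0, informative_parent="P1"),
        TraitLocus("U", lg=15, cm_pos=40.0, dominant_allele="U3",
                   dominant_phenotype=1, informative_parent="P1"),
    ]


def _default_markers_per_lg() -> list[int]:
    # desk-scale density of ~1 marker/cM on the published group lengths
    return [max(15, int(round(length))) for length in LG_LENGTHS_CM]


@dataclass
class CrossConfig:
    """Knobs of the synthetic cross.

    Defaults replicate the study conditions where the study states them:
    75 offspring, ~10x mean depth, the published 22 linkage-group lengths,
    and the genotyping error rate assumed by the downstream HMM (0.002).
    Marker counts are desk-scale (~1 marker per cM of group length).
    """

    n_offspring: int = 75
    genotyping_error: float = 0.002
    missing_rate: float = 0.05
    mean_depth: float = 10.0
    depth_dispersion: float = 0.1  # variance = m + dispersion * m^2; 0 -> Poisson
    seed: int = 0
    lg_lengths_cm: list[float] = field(default_factory=lambda: list(LG_LENGTHS_CM))
    markers_per_lg: list[int] = field(default_factory=_default_markers_per_lg)
    both_parent_het_fraction: float = 0.5
    markers_per_contig: float = 12.0

    def __post_init__(self):
        for name in ("genotyping_error", "missing_rate", "both_parent_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if len(self.lg_lengths_cm) != len(self.markers_per_lg):
            raise ValueError("lg_lengths_cm and markers_per_lg must have equal length")
        if any(length < 0 for length in self.lg_lengths_cm):
            raise ValueError("linkage-group lengths must be non-negative")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")


@dataclass
class GenotypeCalls:
    """Called genotypes for a set of markers across a set of individuals.

    ``markers`` carries one row per site (marker_id, contig_id, bp_pos,
    is_indel, qual, and — when of simulated origin — lg and cm_pos).
    ``G`` counts alt alleles per call (-1 = missing); ``DP`` is read depth;
    ``PH`` records phased het calls (0 = "0|1", 1 = "1|0", -1 = unphased).
    """

    markers: pd.DataFrame
    samples: list[str]
    G: np.ndarray
    DP: np.ndarray
    PH: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(
                f"unknown individual {name!r}; valid ids: {', '.join(self.samples)}"
            ) from None

    def subset(self, marker_mask) -> "GenotypeCalls":
        idx = np.asarray(marker_mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeCalls(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            G=self.G[idx].copy(),
            DP=self.DP[idx].copy(),
            PH=self.PH[idx].copy(),
        )


@dataclass
class SimulatedDataset:
    """A simulated cross with ground truth attached."""

    markers: list[MarkerDef]
    pedigree: pd.DataFrame
    calls: GenotypeCalls
    phenotypes: pd.DataFrame  # individual_id, trait_name, value
    truth_loci: list[TraitLocus]
    # per-marker parental haplotypes, shape (2, M): [hap1, hap2] alt-allele state
    parent_haplotypes: dict[str, np.ndarray] = field(default_factory=dict)
    # per-offspring transmitted strand (0 = hap1, 1 = hap2), shape (M, n_off)
    truth_paternal_strand: np.ndarray | None = None
    truth_maternal_strand: np.ndarray | None = None
    truth_G: np.ndarray | None = None

    @property
    def offspring(self) -> list[str]:
        return [s for s in self.calls.samples
                if self.pedigree.set_index("individual_id").loc[s, "generation"] == "offspring"]


def simulate_genome(config: CrossConfig, rng: np.random.Generator | None = None) -> list[MarkerDef]:
    """Lay out markers on linkage groups.

    Positions are uniform on [0, L] per group, sorted; contigs span contiguous
    runs of markers (run lengths ~ 1 + Poisson(markers_per_contig - 1)), and
    physical bp coordinates within a contig follow the genetic positions at a
    constant cM/Mb scale with unit-increment tie-breaking.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers: list[MarkerDef] = []
    contig_counter = 0
    for gi, (length, n_mark) in enumerate(zip(config.lg_lengths_cm, config.markers_per_lg), start=1):
        if length < 0:
            raise ValueError("linkage-group length must be non-negative")
        cm = np.sort(rng.uniform(0.0, length, size=n_mark)) if length > 0 else np.zeros(n_mark)
        # contig run lengths
        runs: list[int] = []
        remaining = n_mark
        while remaining > 0:
            run = 1 + int(rng.poisson(max(config.markers_per_contig - 1.0, 0.0)))
            run = min(run, remaining)
            runs.append(run)
            remaining -= run
        k = 0
        for run in runs:
            contig_counter += 1
            contig_id = f"tig{contig_counter:05d}"
            start_cm = cm[k]
            for j in range(run):
                pos_cm = cm[k + j]
                bp = int(round((pos_cm - start_cm) * 1.6e6)) + j  # ~0.6 cM/Mb; +j breaks ties
                markers.append(MarkerDef(
                    marker_id=f"LG{gi}_M{k + j + 1:04d}",
                    contig_id=contig_id,
                    bp_pos=bp,
                    lg=gi,
                    cm_pos=float(pos_cm),
                ))
            k += run
    return markers


def _meiosis_strand(positions_cm: np.ndarray, length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Transmitted-strand indicator (0/1) at each position for one meiosis."""
    n_xo = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    start = int(rng.integers(2))
    if n_xo == 0:
        return np.full(positions_cm.shape, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    n_below = np.searchsorted(breaks, positions_cm, side="right")
    return ((start + n_below) % 2).astype(np.int8)


def simulate_meiosis(haplotypes: np.ndarray, markers: list[MarkerDef],
                     rng_or_seed=None) -> np.ndarray:
    """Generate one gamete from a phased parent.

    ``haplotypes`` has shape (2, M) aligned with ``markers``. Each linkage
    group recombines independently under the Haldane model. Returns the
    gamete allele vector; strand bookkeeping is internal.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    haplotypes = np.asarray(haplotypes)
    if haplotypes.shape[0] != 2 or haplotypes.shape[1] != len(markers):
        raise ValueError("haplotypes must have shape (2, n_markers)")
    lg = np.array([m.lg for m in markers])
    cm = np.array([m.cm_pos for m in markers])
    strand = np.empty(len(markers), dtype=np.int8)
    for g in np.unique(lg):
        sel = lg == g
        length = float(cm[sel].max()) if sel.any() else 0.0
        strand[sel] = _meiosis_strand(cm[sel], length, rng)
    return haplotypes[strand, np.arange(len(markers))]


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int32)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size).astype(np.int32)
    k = 1.0 / dispersion  # NB shape; variance = mean + dispersion * mean^2
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int32)


def simulate_cross(config: CrossConfig,
                   trait_loci: list[TraitLocus] | None = None) -> SimulatedDataset:
    """Simulate the full cross: genome, meioses, phenotypes and noisy calls.

    The informative parent P1 is heterozygous at every marker (haplotype 1
    carries the reference allele) and at every trait locus (haplotype 1
    carries the dominant allele); P2 is heterozygous at a fraction
    ``both_parent_het_fraction`` of markers (phase-aligned so haplotype 1 is
    reference) and homozygous otherwise, and homozygous recessive at the
    trait loci. The two grandparents are the parents of P1 and are rendered
    homozygous for P1's haplotype-1 and haplotype-2 alleles respectively,
    which makes phasing P1 against them trivial, as in the study design.
    """
    rng = np.random.default_rng(config.seed)
    if trait_loci is None:
        trait_loci = default_trait_loci()
    n_lg = len(config.lg_lengths_cm)
    for tl in trait_loci:
        if not 1 <= tl.lg <= n_lg:
            raise ValueError(f"trait locus {tl.name!r} placed on nonexistent group {tl.lg}")
        if tl.informative_parent != "P1":
            raise ValueError("the informative parent of every trait locus must be P1")

    markers = simulate_genome(config, rng)
    M = len(markers)
    n_off = config.n_offspring
    lg_arr = np.array([m.lg for m in markers])
    cm_arr = np.array([m.cm_pos for m in markers])

    # parental haplotypes over markers (alt-allele indicator)
    p1_hap = np.vstack([np.zeros(M, dtype=np.int8), np.ones(M, dtype=np.int8)])
    both_het = rng.random(M) < config.both_parent_het_fraction
    p2_hom_allele = rng.integers(0, 2, size=M).astype(np.int8)
    p2_hap = np.vstack([np.where(both_het, 0, p2_hom_allele),
                        np.where(both_het, 1, p2_hom_allele)]).astype(np.int8)

    # meioses: simulate strand indicators at marker and trait positions jointly
    trait_by_lg: dict[int, list[int]] = {}
    for ti, tl in enumerate(trait_loci):
        trait_by_lg.setdefault(tl.lg, []).append(ti)

    pat_strand = np.empty((M, n_off), dtype=np.int8)
    mat_strand = np.empty((M, n_off), dtype=np.int8)
    trait_pat_strand = np.empty((len(trait_loci), n_off), dtype=np.int8)
    for g in range(1, n_lg + 1):
        sel = lg_arr == g
        t_idx = trait_by_lg.get(g, [])
        pos = np.concatenate([cm_arr[sel], [trait_loci[t].cm_pos for t in t_idx]])
        order = np.argsort(pos, kind="stable")
        length = float(config.lg_lengths_cm[g - 1])
        n_sel = int(sel.sum())
        for j in range(n_off):
            sp = np.empty_like(pos, dtype=np.int8)
            sp[order] = _meiosis_strand(pos[order], length, rng)
            pat_strand[sel, j] = sp[:n_sel]
            for i, t in enumerate(t_idx):
                trait_pat_strand[t, j] = sp[n_sel + i]
            sm = np.empty_like(pos, dtype=np.int8)
            sm[order] = _meiosis_strand(pos[order], length, rng)
            mat_strand[sel, j] = sm[:n_sel]

    off_idx = np.arange(M)[:, None]
    pat_allele = p1_hap[pat_strand, off_idx]
    mat_allele = p2_hap[mat_strand, off_idx]
    G_true_off = (pat_allele + mat_allele).astype(np.int8)

    samples = ["GP1", "GP2", "P1", "P2"] + [f"O{j + 1:03d}" for j in range(n_off)]
    G_true = np.empty((M, len(samples)), dtype=np.int8)
    G_true[:, 0] = 2 * p1_hap[0]  # GP1 homozygous for P1 haplotype-1 allele
    G_true[:, 1] = 2 * p1_hap[1]
    G_true[:, 2] = p1_hap.sum(axis=0)
    G_true[:, 3] = p2_hap.sum(axis=0)
    G_true[:, 4:] = G_true_off

    # corrupt calls: symmetric genotype swap, then missingness
    G = G_true.copy()
    if config.genotyping_error > 0:
        err = rng.random(G.shape) < config.genotyping_error
        # replace with one of the two wrong genotypes uniformly
        shift = rng.integers(1, 3, size=G.shape)
        G = np.where(err, (G + shift) % 3, G).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = MISSING
    DP = _nb_depth(rng, config.mean_depth, config.depth_dispersion, G.shape)
    DP[G == MISSING] = 0

    # phase of parental het calls (haplotype 1 listed first)
    PH = np.full(G.shape, MISSING, dtype=np.int8)
    for col, hap in ((2, p1_hap), (3, p2_hap)):
        het_call = G[:, col] == 1
        PH[het_call, col] = hap[0][het_call]

    marker_df = pd.DataFrame({
        "marker_id": [m.marker_id for m in markers],
        "contig_id": [m.contig_id for m in markers],
        "bp_pos": [m.bp_pos for m in markers],
        "lg": lg_arr,
        "cm_pos": cm_arr,
        "is_indel": False,
        "qual": 999.0,
    })
    calls = GenotypeCalls(markers=marker_df, samples=samples, G=G, DP=DP, PH=PH)

    # phenotypes: dominant label iff >= 1 dominant allele; P1 haplotype 1
    # carries the dominant allele, P2 is homozygous recessive
    rows = []
    for t, tl in enumerate(trait_loci):
        carrier = trait_pat_strand[t] == 0
        value = np.where(carrier, tl.dominant_phenotype, 1 - tl.dominant_phenotype)
        for j in range(n_off):
            rows.append((samples[4 + j], tl.name, int(value[j])))
    phenotypes = pd.DataFrame(rows, columns=["individual_id", "trait_name", "value"])

    pedigree = pd.DataFrame({
        "individual_id": samples,
        "sire": ["."] * 2 + ["GP1", "."] + ["P1"] * n_off,
        "dam": ["."] * 2 + ["GP2", "."] + ["P2"] * n_off,
        "generation": ["grandparent"] * 2 + ["parent"] * 2 + ["offspring"] * n_off,
    })

    return SimulatedDataset(
        markers=markers,
        pedigree=pedigree,
        calls=calls,
        phenotypes=phenotypes,
        truth_loci=list(trait_loci),
        parent_haplotypes={"P1": p1_hap, "P2": p2_hap},
        truth_paternal_strand=pat_strand,
        truth_maternal_strand=mat_strand,
        truth_G=G_true,
    )


def with_seed(config: CrossConfig, seed: int) -> CrossConfig:
    """Convenience: a copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
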