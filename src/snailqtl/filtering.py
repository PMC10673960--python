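"""Marker-retention cascade and informative-marker selection.

A marker survives the cascade iff it clears every rule; the rule order
(QUAL -> indel -> MAF -> missingness -> depth) matters only for attributing
removals in the report, never for the kept set. Minor allele frequency is
computed over the non-missing called alleles of all individuals in the file,
parents and grandparents included; the depth rule bounds the mean depth
across non-missing calls inclusively.

Informative markers are those heterozygous in the informative parent at
which at least one individual carries a non-heterozygous call (a site where
every individual is heterozygous segregates no mappable information and is
suspect of paralogy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sim import MISSING, GenotypeCalls

__all__ = ["FilterCriteria", "FilterReport", "filter_variants", "select_informative"]


@dataclass(frozen=True)
class FilterCriteria:
    qual_min: float = 999.0
    maf_min: float = 0.05
    max_missing_fraction: float = 0.10
    depth_min: float = 10.0
    depth_max: float = 25.0
    drop_indels: bool = True

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")


@dataclass
class FilterReport:
    input_count: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    RULES = ("qual", "indel", "maf", "missingness", "depth")

    def as_dict(self) -> dict:
        return {"input_count": self.input_count,
                "removed": dict(self.removed),
                "output_count": self.output_count}


def _rule_failures(calls: GenotypeCalls, criteria: FilterCriteria) -> dict[str, np.ndarray]:
    mk = calls.markers
    missing = calls.G == MISSING
    n_nonmiss = (~missing).sum(axis=1)

    qual = mk["qual"].to_numpy(dtype=float)
    fail_qual = ~(qual >= criteria.qual_min)  # NaN QUAL fails

    is_indel = (mk["is_indel"].to_numpy(dtype=bool)
                if "is_indel" in mk else np.zeros(calls.n_markers, bool))
    fail_indel = is_indel if criteria.drop_indels else np.zeros_like(is_indel)

    alt = np.where(missing, 0, calls.G).sum(axis=1).astype(float)
    total = 2.0 * n_nonmiss
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf >= criteria.maf_min)

    miss_frac = missing.mean(axis=1)
    fail_missing = miss_frac > criteria.max_missing_fraction

    dp = np.where(missing, 0, calls.DP).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(n_nonmiss > 0, dp / np.maximum(n_nonmiss, 1), np.nan)
    fail_depth = ~((mean_dp >= criteria.depth_min) & (mean_dp <= criteria.depth_max))

    return {"qual": fail_qual, "indel": fail_indel, "maf": fail_maf,
            "missingness": fail_missing, "depth": fail_depth}


def filter_variants(calls: GenotypeCalls,
                    criteria: FilterCriteria | None = None,
                    ) -> tuple[GenotypeCalls, FilterReport]:
    """Apply the retention cascade; return kept markers and the rule report.

    Each removed marker is attributed to the first rule it fails, in the
    fixed order ``qual -> indel -> maf -> missingness -> depth``, so that
    ``input_count - sum(removals) == output_count`` exactly.
    """
    if criteria is None:
        criteria = FilterCriteria()
    report = FilterReport(input_count=calls.n_markers,
                          removed={r: 0 for r in FilterReport.RULES})
    if calls.n_markers == 0:
        return calls.subset(np.zeros(0, dtype=bool)), report

    failures = _rule_failures(calls, criteria)
    attributed = np.zeros(calls.n_markers, dtype=bool)
    for rule in FilterReport.RULES:
        hit = failures[rule] & ~attributed
        report.removed[rule] = int(hit.sum())
        attributed |= failures[rule]
    kept = ~attributed
    report.output_count = int(kept.sum())
    return calls.subset(kept), report


def select_informative(calls: GenotypeCalls, informative_parent: str) -> GenotypeCalls:
    """Keep markers heterozygous in the informative parent at which at least
    one individual (any sample) carries a non-heterozygous, non-missing call."""
    pi = calls.sample_index(informative_parent)
    parent_het = calls.G[:, pi] == 1
    some_non_het = ((calls.G != 1) & (calls.G != MISSING)).any(axis=1)
    return calls.subset(parent_het & some_non_het)
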