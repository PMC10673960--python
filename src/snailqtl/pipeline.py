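"""End-to-end pipeline: cross (simulated or loaded) -> filter -> map ->
statistics -> per-trait scan -> candidate regions -> power table.

Stage order mirrors the study's analysis: marker retention, informative
selection, two-point grouping and ordering, LOD-matrix pruning, contig
conflict resolution, sex-averaging, map statistics, then the binary-trait
scans with permutation thresholds, credible intervals, allele effects and
segregation validation. All randomness descends from a single seed through
named stage streams, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filtering import FilterCriteria, FilterReport, filter_variants, select_informative
from .linkage import (GroupingParams, Transmissions, group_markers,
                      infer_transmissions, intercross_pairwise_rf,
                      order_markers, pairwise_rf, prune_by_lod,
                      resolve_contig_conflicts, sex_average)
from .mapstats import MapSummary, summarize
from .power import PowerSpec, power_threshold_h2, qtl_power
from .scan import (ScanParams, allele_effects, bayes_interval, binary_scan,
                   calc_genoprob, candidate_region, find_peaks,
                   permutation_threshold, segregation_check)
from .sim import CrossConfig, GenotypeCalls, TraitLocus, simulate_cross
from .vcfio import read_pedigree, read_phenotypes, read_vcf

log = logging.getLogger("snailqtl")

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "ConfigError",
           "DataError", "run_pipeline", "desk_grouping_params"]


class PipelineError(RuntimeError):
    """Base pipeline failure; carries the stage name."""

    exit_code = 1

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(PipelineError):
    exit_code = 2


class DataError(PipelineError):
    exit_code = 3


def desk_grouping_params(lod_limit: float = 7.0, size_limit: int = 8,
                         join_singles_lod: float = 5.0) -> GroupingParams:
    """Grouping parameters recalibrated for desk-scale marker densities.

    The full-scale thresholds (LOD 9.5, minimum group 600) presume ~10
    markers per 0.1 cM; at a few hundred simulated markers the same family
    of 75 meioses supports pairwise LODs of at most ~23, and adjacent-marker
    LODs of 7 correspond to the same linkage evidence per unit density.
    """
    return GroupingParams(lod_limit=lod_limit, size_limit=size_limit,
                          join_singles_lod=join_singles_lod)


@dataclass
class PipelineConfig:
    # either simulate=True (cross drives everything) or provide the three paths
    simulate: bool = True
    cross: CrossConfig = field(default_factory=CrossConfig)
    trait_loci: list[TraitLocus] | None = None  # simulation mode; None = study loci
    vcf_path: str | None = None
    phenotype_path: str | None = None
    pedigree_path: str | None = None
    informative_parent: str = "P1"
    other_parent: str = "P2"
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    grouping: GroupingParams = field(default_factory=desk_grouping_params)
    scan: ScanParams = field(default_factory=ScanParams)
    order_restarts: int = 20
    genome_size_mb: float = 3500.0
    power_intervals_cm: tuple[float, ...] = (2.0, 5.0)
    power_alpha: float = 0.01
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            for name in ("vcf_path", "phenotype_path", "pedigree_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError("config", f"{name} is required when simulate=False")
                if not os.path.exists(path):
                    raise ConfigError("config", f"{name} {path!r} does not exist")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        payload = enc(self)
        for transient in ("out_dir", "log_level"):  # not part of the science
            payload.pop(transient, None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_report: FilterReport
    map_df: pd.DataFrame
    summary: MapSummary
    scans: dict[str, pd.DataFrame]
    thresholds: dict[str, float]
    peaks: pd.DataFrame
    regions: dict[str, dict]
    power_table: pd.DataFrame
    removal_log: dict


def _stage_seed(base: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        dataset = simulate_cross(config.cross, config.trait_loci)
        offspring = [s for s in dataset.calls.samples
                     if s not in ("GP1", "GP2", "P1", "P2")]
        return dataset.calls, dataset.phenotypes, offspring
    try:
        calls = read_vcf(config.vcf_path)
    except Exception as exc:
        raise DataError("load", str(exc)) from exc
    phenotypes = read_phenotypes(config.phenotype_path)
    pedigree = read_pedigree(config.pedigree_path)
    offspring = pedigree.loc[pedigree["generation"] == "offspring",
                             "individual_id"].tolist()
    missing = set(offspring) - set(calls.samples)
    if missing:
        raise DataError("load", f"pedigree offspring absent from VCF: {sorted(missing)}")
    return calls, phenotypes, offspring


def _build_map(calls: GenotypeCalls, trans: Transmissions,
               config: PipelineConfig) -> tuple[pd.DataFrame, dict, np.ndarray]:
    r_p, lod_p, n_p = pairwise_rf(trans.pat_digit)
    r_m, lod_m, n_m = pairwise_rf(trans.mat_digit)
    n_tot = n_p + n_m
    with np.errstate(invalid="ignore"):
        r_comb = np.where(n_tot > 0, (r_p * n_p + r_m * n_m) / np.maximum(n_tot, 1), 0.5)
    lod = lod_p + lod_m
    # fully informative marker pairs: phase-marginal ML over all offspring
    # (both meioses jointly) supersedes the hom-resolved digit counts
    bh_pair = np.outer(trans.both_het, trans.both_het)
    r_i, lod_i, n_i = intercross_pairwise_rf(trans.f2)
    lod = np.where(bh_pair, lod_i, lod)
    r_comb = np.where(bh_pair, r_i, r_comb)
    n_tot = np.where(bh_pair, n_i, n_tot)

    labels = group_markers(lod, config.grouping)
    ids = calls.markers["marker_id"].tolist()
    rows = []
    for g in sorted(set(labels) - {0}):
        members = np.flatnonzero(labels == g)
        if len(members) < 2:
            continue
        sub = np.ix_(members, members)
        om = order_markers(
            r_comb[sub], [ids[i] for i in members],
            rf_male=np.where(bh_pair[sub], np.nan,
                             np.where(n_p[sub] > 0, r_p[sub], np.nan)),
            rf_female=np.where(bh_pair[sub], np.nan,
                               np.where(n_m[sub] > 0, r_m[sub], np.nan)),
            n_restarts=config.order_restarts,
            seed=_stage_seed(config.seed, f"order:{g}"),
        )
        for rank, mi in enumerate(members[om.order]):
            rows.append({
                "marker_id": ids[mi], "marker_index": int(mi),
                "contig_id": calls.markers["contig_id"].iat[mi],
                "bp_pos": int(calls.markers["bp_pos"].iat[mi]),
                "lg": int(g),
                "cm_male": float(om.cm_male[rank]),
                "cm_female": float(om.cm_female[rank]),
            })
    if not rows:
        raise DataError("map", "no linkage groups could be formed")
    map_df = sex_average(pd.DataFrame(rows))

    # location-wise LOD pruning on co-located SNPs
    max_lod = lod.max(axis=1)
    map_df["_loc"] = map_df["cm_avg"].round(3)
    groups = list(map_df.groupby(["lg", "_loc"]).groups.values())
    masks = prune_by_lod([max_lod[map_df.loc[g, "marker_index"]] for g in groups])
    drop_idx = [i for g, m in zip(groups, masks) for i, rm in zip(g, m) if rm]
    pruned = map_df.drop(index=drop_idx).drop(columns="_loc").reset_index(drop=True)

    pruned, removal_log = resolve_contig_conflicts(pruned)
    removal_log["lod_pruned"] = int(len(drop_idx))

    # restandardise per-group origins after removals
    for col in ("cm_male", "cm_female"):
        pruned[col] -= pruned.groupby("lg")[col].transform("min")
    pruned = sex_average(pruned.drop(columns="cm_avg"))
    pruned = pruned.sort_values(["lg", "cm_avg", "marker_id"]).reset_index(drop=True)
    return pruned, removal_log, labels


def _scan_trait(trait: str, y: np.ndarray, map_df: pd.DataFrame,
                trans: Transmissions, config: PipelineConfig):
    scan_rows = map_df[map_df["marker_index"].map(
        lambda i: bool(trans.both_het[i]))].reset_index(drop=True)
    if len(scan_rows) < 2:
        raise DataError("scan", f"trait {trait}: fewer than two scan markers")
    codes = trans.f2[scan_rows["marker_index"].to_numpy()]  # (P, n_off)
    lgs = scan_rows["lg"].to_numpy()
    pos = scan_rows["cm_avg"].to_numpy()

    prob_blocks = []
    for g in np.unique(lgs):
        sel = lgs == g
        prob_blocks.append(calc_genoprob(pos[sel], codes[sel].T,
                                         config.scan.genotyping_error))
    probs = np.concatenate(prob_blocks, axis=1)

    lod = binary_scan(probs, y)
    params = dataclasses.replace(config.scan,
                                 seed=_stage_seed(config.seed, f"perm:{trait}"))
    threshold = permutation_threshold(probs, y, params)

    peaks = []
    for g in np.unique(lgs):
        sel = np.flatnonzero(lgs == g)
        for pk in find_peaks(lod[sel], threshold, config.scan.peakdrop, pos[sel]):
            ci = bayes_interval(lod[sel], pos[sel], pk.index, config.scan.ci_prob)
            peaks.append({"trait": trait, "lg": int(g),
                          "position_cm": pk.position_cm, "lod": pk.lod,
                          "start_cm": ci.start_cm, "end_cm": ci.end_cm,
                          "_sel": sel, "_ci": ci, "_pk": pk})

    region = {"trait": trait, "localized": False, "message": "locus not localised"}
    if peaks:
        top = max(peaks, key=lambda p: p["lod"])
        sel = top["_sel"]
        eff = allele_effects(probs[:, sel], y)
        orient = 0 if eff[top["_pk"].index, 0] > eff[top["_pk"].index, 2] else 2
        ci = top["_ci"]
        in_ci = np.arange(ci.lo_index, ci.hi_index + 1)
        seg = segregation_check(codes[sel[in_ci]].T, y, pos[sel[in_ci]],
                                label1_homozygote=orient)
        consistent = seg.loc[seg["consistent"], "position_cm"].tolist()
        contig_map = {}
        for p in consistent:
            at = map_df[(map_df["lg"] == top["lg"]) & (map_df["cm_avg"].round(6) == round(p, 6))]
            contig_map[p] = set(at["contig_id"])
        region = candidate_region(consistent, contig_map)
        region.update({"trait": trait, "lg": top["lg"],
                       "label1_homozygote": "AA" if orient == 0 else "BB",
                       "segregation": seg.to_dict("records")})

    scan_df = pd.DataFrame({"lg": lgs, "position_cm": pos, "lod": lod})
    eff_all = allele_effects(probs, y)
    scan_df[["effect_AA", "effect_AB", "effect_BB"]] = eff_all
    peaks_df = pd.DataFrame([{k: v for k, v in p.items() if not k.startswith("_")}
                             for p in peaks])
    return scan_df, threshold, peaks_df, region


def _power_table(n: int, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for w in config.power_intervals_cm:
        spec = PowerSpec(n=n, h2=1.0, interval_cm=w, alpha=config.power_alpha)
        rows.append({
            "n": n, "interval_cm": w, "alpha": config.power_alpha,
            "power_h2_100": qtl_power(spec),
            "h2_threshold_power100_pct": power_threshold_h2(n, w, config.power_alpha, 1.0),
            "h2_threshold_power95_pct": power_threshold_h2(n, w, config.power_alpha, 0.95),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; write the artifact bundle if ``out_dir`` is set."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    calls, phenotypes, offspring = _load_inputs(config)
    log.info("loaded %d markers x %d individuals", calls.n_markers, calls.n_samples)

    kept, report = filter_variants(calls, config.criteria)
    try:
        informative = select_informative(kept, config.informative_parent)
    except KeyError as exc:
        raise DataError("informative", str(exc)) from exc
    log.info("filter kept %d, informative %d", kept.n_markers, informative.n_markers)
    if informative.n_markers < 4:
        raise DataError("informative", "too few informative markers to map")

    trans = infer_transmissions(informative, offspring,
                                config.informative_parent, config.other_parent)
    map_df, removal_log, _ = _build_map(informative, trans, config)
    summary = summarize(map_df, config.genome_size_mb)

    scans, thresholds, regions = {}, {}, {}
    peak_frames = []
    for trait in sorted(phenotypes["trait_name"].unique()):
        series = (phenotypes[phenotypes["trait_name"] == trait]
                  .set_index("individual_id")["value"])
        try:
            y = series.loc[offspring].to_numpy(dtype=float)
        except KeyError as exc:
            raise DataError("scan", f"trait {trait}: phenotype missing for {exc}") from exc
        scan_df, thr, peaks_df, region = _scan_trait(trait, y, map_df, trans, config)
        scans[trait] = scan_df
        thresholds[trait] = thr
        regions[trait] = region
        if len(peaks_df):
            peak_frames.append(peaks_df)
    peaks = (pd.concat(peak_frames, ignore_index=True) if peak_frames
             else pd.DataFrame(columns=["trait", "lg", "position_cm", "lod",
                                        "start_cm", "end_cm"]))

    power_table = _power_table(len(offspring), config)
    result = PipelineResult(config, report, map_df, summary, scans, thresholds,
                            peaks, regions, power_table, removal_log)
    if config.out_dir:
        _write_bundle(result)
    return result


def _write_bundle(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# snailqtl {__version__} config={result.config.config_hash()}\n"

    def tsv(df: pd.DataFrame, name: str, drop=()):
        with open(out / name, "w") as fh:
            fh.write(header)
            df.drop(columns=[c for c in drop if c in df], errors="ignore") \
              .to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def js(obj, name):
        with open(out / name, "w") as fh:
            json.dump({"snailqtl": __version__,
                       "config": result.config.config_hash(),
                       "payload": obj}, fh, indent=1, default=str)
            fh.write("\n")

    js(result.filter_report.as_dict(), "filter_report.json")
    tsv(result.map_df, "map.tsv", drop=("marker_index",))
    tsv(result.summary.per_lg, "map_per_lg.tsv")
    js(result.summary.rounded(), "map_summary.json")
    for trait, df in result.scans.items():
        tsv(df, f"scan_{trait}.tsv")
    tsv(result.peaks, "peaks.tsv")
    js({t: {k: v for k, v in r.items() if k != "segregation"}
        for t, r in result.regions.items()}, "regions.json")
    js(result.thresholds, "thresholds.json")
    tsv(result.power_table, "power.tsv")
    js(dataclasses.asdict(result.config), "run_log.json")
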