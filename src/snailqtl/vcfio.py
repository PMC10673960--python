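"""VCF and table input/output.

Genotype matrices travel as VCF v4.2 with ``GT:DP`` per sample and a site
``QUAL``; phenotypes and pedigrees as simple TSVs. Reading goes through
cyvcf2 (htslib); writing is plain text emission, since the synthetic matrices
carry exactly the fields the format needs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sim import MISSING, GenotypeCalls, SimulatedDataset

__all__ = ["write_vcf", "read_vcf", "write_phenotypes", "read_phenotypes",
           "write_pedigree", "read_pedigree", "VcfParseError"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; names the offending line."""


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(data: SimulatedDataset | GenotypeCalls, path: str | os.PathLike) -> None:
    """Write calls as VCF v4.2 (FORMAT ``GT:DP``, site ``QUAL``).

    Missing calls become ``./.``; phased het calls (parental phase, recorded
    in ``PH``) are written with ``|`` so phase round-trips. Synthetic SNP
    alleles are A/T; indel records get an AT alternate.
    """
    calls = data.calls if isinstance(data, SimulatedDataset) else data
    mk = calls.markers
    lines = ["##fileformat=VCFv4.2",
             "##source=snailqtl",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">']
    for contig in pd.unique(mk["contig_id"]):
        last = int(mk.loc[mk["contig_id"] == contig, "bp_pos"].max())
        lines.append(f"##contig=<ID={contig},length={last + 1000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(calls.samples))
    is_indel = mk["is_indel"].to_numpy() if "is_indel" in mk else np.zeros(len(mk), bool)
    qual = mk["qual"].to_numpy() if "qual" in mk else np.full(len(mk), 999.0)
    for i in range(calls.n_markers):
        ref, alt = ("A", "AT") if is_indel[i] else ("A", "T")
        fields = [str(mk["contig_id"].iat[i]), str(int(mk["bp_pos"].iat[i]) + 1),
                  str(mk["marker_id"].iat[i]), ref, alt,
                  f"{qual[i]:g}", "PASS", "."]
        fmt = []
        for j in range(calls.n_samples):
            g = int(calls.G[i, j])
            if g == 1 and calls.PH[i, j] != MISSING:
                gt = "0|1" if calls.PH[i, j] == 0 else "1|0"
            else:
                gt = _GT_STR[g]
            dp = int(calls.DP[i, j])
            fmt.append(f"{gt}:{dp}")
        lines.append("\t".join(fields + ["GT:DP"] + fmt))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _locate_malformed_line(path: str | os.PathLike) -> str | None:
    """Best-effort scan for the first structurally invalid VCF body line."""
    n_fixed = 9
    try:
        with open(path) as fh:
            n_samples = None
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    n_samples = len(parts) - n_fixed
                    continue
                if n_samples is None:
                    return f"line {lineno}: data before #CHROM header"
                if len(parts) != n_fixed + n_samples:
                    return (f"line {lineno}: expected {n_fixed + n_samples} "
                            f"columns, found {len(parts)}")
                if not parts[1].isdigit():
                    return f"line {lineno}: POS {parts[1]!r} is not an integer"
    except OSError as exc:
        return str(exc)
    return None


def read_vcf(path: str | os.PathLike) -> GenotypeCalls:
    """Read a VCF into a :class:`GenotypeCalls` (GT and DP per call)."""
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, G_rows, DP_rows, PH_rows = [], [], [], []
        for var in vcf:
            gts = var.genotypes  # [allele0, allele1, phased]
            g = np.empty(len(samples), dtype=np.int8)
            ph = np.full(len(samples), MISSING, dtype=np.int8)
            for j, (a0, a1, *rest) in enumerate(gts):
                if a0 < 0 or a1 < 0:
                    g[j] = MISSING
                else:
                    g[j] = a0 + a1
                    if g[j] == 1 and rest and rest[0]:
                        ph[j] = a0  # allele listed first on the phased call
            dp = var.format("DP")
            dp = (np.zeros(len(samples), dtype=np.int32) if dp is None
                  else np.where(dp.reshape(-1) < 0, 0, dp.reshape(-1)).astype(np.int32))
            rows.append({
                "marker_id": var.ID or f"{var.CHROM}_{var.POS}",
                "contig_id": var.CHROM,
                "bp_pos": var.POS - 1,
                "is_indel": var.is_indel,
                "qual": float(var.QUAL) if var.QUAL is not None else np.nan,
            })
            G_rows.append(g)
            DP_rows.append(dp)
            PH_rows.append(ph)
    except Exception as exc:  # htslib errors are not line-addressed; locate ourselves
        detail = _locate_malformed_line(path)
        raise VcfParseError(
            f"failed to parse {path}" + (f" ({detail})" if detail else f": {exc}")
        ) from exc
    markers = pd.DataFrame(rows)
    shape = (len(rows), len(samples))
    return GenotypeCalls(
        markers=markers,
        samples=samples,
        G=np.vstack(G_rows) if rows else np.empty(shape, np.int8),
        DP=np.vstack(DP_rows) if rows else np.empty(shape, np.int32),
        PH=np.vstack(PH_rows) if rows else np.empty(shape, np.int8),
    )


def write_phenotypes(phenotypes: pd.DataFrame, path: str | os.PathLike) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "trait_name", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    if not df["value"].isin([0, 1]).all():
        raise ValueError("phenotype values must be binary (0/1)")
    return df


def write_pedigree(pedigree: pd.DataFrame, path: str | os.PathLike) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "sire", "dam", "generation"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree table must have columns {sorted(required)}")
    return df
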