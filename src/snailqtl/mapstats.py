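"""Linkage-map summary statistics.

Implements the standard framework-map arithmetic: the average inter-marker
interval s = L_total / (M - G) for M markers on G groups of cumulative length
L_total; the expected genome length obtained by extending every group by 2s
to account for terminal chromosome regions; genome coverage as the ratio of
observed to expected length; and the genome-wide recombination rate as map
length over physical genome size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MapSummary", "summarize", "summarize_table"]


@dataclass
class MapSummary:
    per_lg: pd.DataFrame  # lg, n_markers, length_cm, percent_of_map
    total_markers: int
    total_length_cm: float
    n_groups: int
    s: float  # average inter-marker interval, cM
    expected_length_cm: float
    coverage: float
    recomb_rate_cm_per_mb: float
    mean_markers_per_lg: float
    genome_size_mb: float = field(repr=False, default=0.0)

    def rounded(self) -> dict:
        """Headline figures at reporting precision (lengths 2 dp, s two
        significant figures, rate 2 dp, coverage nearest percent)."""
        from decimal import Decimal

        s_str = f"{self.s:.2g}" if self.s else "0"
        return {
            "total_markers": self.total_markers,
            "total_length_cm": round(self.total_length_cm, 2),
            "s_cm": float(Decimal(s_str)),
            "expected_length_cm": round(self.expected_length_cm, 2),
            "coverage_percent": round(100.0 * self.coverage),
            "recomb_rate_cm_per_mb": round(self.recomb_rate_cm_per_mb, 2),
            "mean_markers_per_lg": round(self.mean_markers_per_lg),
        }


def summarize_table(counts_lengths, genome_size_mb: float) -> MapSummary:
    """Summary statistics from per-group (marker count, length cM) pairs."""
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    counts = [int(c) for c, _ in counts_lengths]
    lengths = [float(length) for _, length in counts_lengths]
    if not counts:
        raise ValueError("the map must contain at least one linkage group")
    G = len(counts)
    M = sum(counts)
    L = sum(lengths)
    if M == G:
        warnings.warn("as many markers as groups: average interval undefined, using 0")
        s = 0.0
    else:
        s = L / (M - G)
    expected = sum(length + 2.0 * s for length in lengths)
    coverage = L / expected if expected > 0 else 1.0
    per_lg = pd.DataFrame({
        "lg": range(1, G + 1),
        "n_markers": counts,
        "length_cm": lengths,
        "percent_of_map": [100.0 * length / L if L > 0 else 0.0 for length in lengths],
    })
    return MapSummary(
        per_lg=per_lg,
        total_markers=M,
        total_length_cm=L,
        n_groups=G,
        s=s,
        expected_length_cm=expected,
        coverage=coverage,
        recomb_rate_cm_per_mb=L / genome_size_mb,
        mean_markers_per_lg=M / G,
        genome_size_mb=genome_size_mb,
    )


def summarize(map_df: pd.DataFrame, genome_size_mb: float,
              position_col: str = "cm_avg") -> MapSummary:
    """Summary statistics from a marker-level genetic map.

    ``map_df`` needs ``lg`` and a cM position column; group length is the
    position span within each group.
    """
    pairs = []
    for _, sub in map_df.groupby("lg"):
        pos = sub[position_col]
        pairs.append((len(sub), float(pos.max() - pos.min()) if len(sub) else 0.0))
    return summarize_table(pairs, genome_size_mb)
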