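"""Published Cepaea nemoralis linkage-group summary (per-LG marker counts and
cM lengths of the 22-group map built from the C451 x C452 cross).

These numbers are inputs: they let the map-statistics arithmetic be recomputed
without the underlying 215k-marker genotype data, and they provide realistic
group lengths for the cross simulator's default genome.
"""

from __future__ import annotations

# (linkage group, number of linked SNPs, linkage length in cM)
CEPAEA_LG_TABLE: list[tuple[int, int, float]] = [
    (1, 59069, 151.48),
    (2, 10648, 92.54),
    (3, 16584, 104.53),
    (4, 9842, 136.18),
    (5, 9096, 70.11),
    (6, 12030, 134.52),
    (7, 6101, 84.33),
    (8, 10653, 126.84),
    (9, 6495, 81.74),
    (10, 9104, 89.21),
    (11, 5746, 74.47),
    (12, 5197, 109.44),
    (13, 7352, 87.46),
    (14, 8217, 104.52),
    (15, 4387, 110.05),
    (16, 5025, 60.85),
    (17, 3683, 90.25),
    (18, 5173, 93.32),
    (19, 10104, 96.44),
    (20, 7000, 116.55),
    (21, 2720, 72.04),
    (22, 1367, 56.84),
]

#: Haploid genome size of C. nemoralis in Mb (draft assembly, ~3.5 Gb).
CEPAEA_GENOME_MB: float = 3500.0

LG_LENGTHS_CM: list[float] = [row[2] for row in CEPAEA_LG_TABLE]
LG_SNP_COUNTS: list[int] = [row[1] for row in CEPAEA_LG_TABLE]
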