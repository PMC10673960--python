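"""Map summary statistics: the published 22-group table and the desk map.

First reproduces the framework-map arithmetic from the published per-group
marker counts and lengths (cumulative 2143 cM, mean interval s = 0.0099 cM,
0.61 cM/Mb against the 3.5 Gb genome, ~9800 markers per group, the largest
group holding ~27% of markers), then applies the same formulas to the map
built in step 03.
"""

import json
import pathlib

import pandas as pd

from snailqtl.mapstats import summarize, summarize_table
from snailqtl.published import CEPAEA_GENOME_MB, CEPAEA_LG_TABLE

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pairs = [(n, length) for _, n, length in CEPAEA_LG_TABLE]
    pub = summarize_table(pairs, CEPAEA_GENOME_MB)
    rounded = pub.rounded()
    share = 100.0 * pub.per_lg["n_markers"].max() / pub.total_markers
    print("published 22-group map:")
    print(f"  markers {pub.total_markers}, cumulative length "
          f"{pub.total_length_cm:.2f} cM (prints as {rounded['total_length_cm']})")
    print(f"  mean inter-marker interval s = {rounded['s_cm']} cM")
    print(f"  expected genome length {pub.expected_length_cm:.1f} cM, "
          f"coverage {rounded['coverage_percent']}%")
    print(f"  genome-wide recombination rate "
          f"{rounded['recomb_rate_cm_per_mb']} cM/Mb")
    print(f"  mean markers per group {rounded['mean_markers_per_lg']}; "
          f"largest group holds {share:.1f}% of markers")
    pub.per_lg.to_csv(OUT / "published_map_per_lg.tsv", sep="\t", index=False)
    with open(OUT / "published_map_summary.json", "w") as fh:
        json.dump(rounded, fh, indent=1)

    map_path = OUT / "pipeline" / "map.tsv"
    if map_path.exists():
        map_df = pd.read_csv(map_path, sep="\t", comment="#")
        desk = summarize(map_df, CEPAEA_GENOME_MB)
        print("desk-scale simulated map:")
        print(f"  {desk.total_markers} markers, {desk.n_groups} groups, "
              f"{desk.total_length_cm:.1f} cM, s = {desk.s:.3f} cM, "
              f"coverage {100 * desk.coverage:.0f}%")
        with open(OUT / "desk_map_summary.json", "w") as fh:
            json.dump(desk.rounded(), fh, indent=1)
    else:
        print("desk map not found; run 03_build_map_and_scan.py first")


if __name__ == "__main__":
    main()
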