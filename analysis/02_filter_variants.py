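"""Apply the marker-retention cascade and informative-marker selection.

Reads the simulated VCF from step 01, applies the strict site filters
(QUAL 999, MAF 0.05, <=10% missing, mean depth 10-25x, indels dropped) and
then keeps only SNPs heterozygous in the informative parent at which not
every individual is heterozygous, mirroring the study's two-stage
reduction. Writes the kept-marker list and the per-rule removal report.
"""

import json
import pathlib

from snailqtl.filtering import FilterCriteria, filter_variants, select_informative
from snailqtl.vcfio import read_vcf

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    calls = read_vcf(OUT / "cross.vcf")
    kept, report = filter_variants(calls, FilterCriteria())
    informative = select_informative(kept, "P1")

    with open(OUT / "filter_report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=1)
    informative.markers[["marker_id", "contig_id", "bp_pos"]].to_csv(
        OUT / "informative_markers.tsv", sep="\t", index=False)

    print(f"site filters: {report.input_count} -> {report.output_count} markers")
    for rule, n in report.removed.items():
        print(f"  removed by {rule}: {n}")
    print(f"informative in P1 (het, not all-het): {informative.n_markers}")
    print(f"wrote {OUT / 'filter_report.json'}, {OUT / 'informative_markers.tsv'}")


if __name__ == "__main__":
    main()
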