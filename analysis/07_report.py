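"""Summarize the direct-effect aDMPs: interval differences and clustering.

Builds the reporting table (per-interval differences of per-time-point
means), tallies directions over the 2 -> 16 end points, orders samples
and CpGs by hierarchical clustering, optionally annotates against CGI /
gene BED files, and exports the ranked gene list when annotation is
available.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from _common import load_filtered_matrix

from methylaging import (annotate_features, cluster_order,
                         direction_and_summary, export_gene_list,
                         interval_mean_differences)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results"))
    ap.add_argument("--cgi-bed", type=Path, default=None)
    ap.add_argument("--gene-bed", type=Path, default=None)
    ap.add_argument("--gene-fdr", type=float, default=0.25)
    args = ap.parse_args()

    m = load_filtered_matrix(args.workdir)
    med = pd.read_csv(args.workdir / "mediation_results.tsv", sep="\t")
    admp_idx = np.flatnonzero(med["significant_DE"].to_numpy())
    table = interval_mean_differences(m, admp_idx)
    table["q_DE"] = med.loc[admp_idx, "q_DE"].to_numpy()
    if args.cgi_bed or args.gene_bed:
        ann = annotate_features(table, cgi_bed=args.cgi_bed,
                                gene_bed=args.gene_bed)
        table = table.merge(ann, on=["chrom", "pos"])
    summary = direction_and_summary(table)
    print(f"direct-effect aDMPs: {summary['n']} "
          f"({summary['pct_increasing']}% increasing, "
          f"{summary['pct_decreasing']}% decreasing over 2 -> 16)")
    for col, stats in summary["intervals"].items():
        print(f"  {col}: median {stats['median']:+.4f}, "
              f"range {stats['min']:+.4f} .. {stats['max']:+.4f}")
    table.round(4).to_csv(args.workdir / "admp_table.tsv", sep="\t",
                          index=False)
    with open(args.workdir / "admp_summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "intervals"}
                  | {"intervals": summary["intervals"]}, fh, indent=2,
                  default=str)

    if admp_idx.size >= 2:
        order = cluster_order(m, admp_idx)
        ordered = m.samples["sample_id"].to_numpy()[order["sample_order"]]
        pd.Series(ordered, name="sample_id").to_csv(
            args.workdir / "heatmap_sample_order.csv", index=False)
        ages = m.samples["age"].to_numpy()[order["sample_order"]]
        print("clustered sample order (ages):",
              " ".join(str(int(a)) for a in ages))

    if "gene" in table.columns:
        ranked, background = export_gene_list(
            med.merge(table[["chrom", "pos", "gene"]], on=["chrom", "pos"],
                      how="left"),
            fdr_cutoff=args.gene_fdr, q_col="q_DE")
        ranked.to_csv(args.workdir / "gene_list.tsv", sep="\t",
                      index=False)
        Path(args.workdir / "gene_background.txt").write_text(
            "\n".join(background) + "\n")
        print(f"gene list: {len(ranked)} genes at FDR <= {args.gene_fdr} "
              f"(background {len(background)})")


if __name__ == "__main__":
    main()
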