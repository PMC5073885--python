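"""Assemble the CpG x sample matrix and apply the standard filters.

Reads the per-sample coverage files, requires >= 10 reads per call,
restricts to autosomal CpGs observed at all three time points in at least
ten subjects, and screens samples by PCA (3 SD on the top components).
Writes the filtered methylation fractions and the QC table.
"""

import argparse
from pathlib import Path

import pandas as pd

from methylaging import (apply_depth_filter, filter_longitudinal,
                         pca_outlier_qc, read_coverage)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results"))
    ap.add_argument("--min-depth", type=int, default=10)
    ap.add_argument("--min-subjects", type=int, default=10)
    ap.add_argument("--qc-sd", type=float, default=3.0)
    args = ap.parse_args()

    cohort = args.workdir / "cohort"
    sheet = pd.read_csv(cohort / "sample_sheet.csv")
    paths = {sid: cohort / "coverage" / f"{sid}.cov"
             for sid in sheet["sample_id"]}
    m = read_coverage(paths, sheet)
    print(f"union of sites: {m.n_sites} across {m.n_samples} samples")
    m = apply_depth_filter(m, args.min_depth)
    m = filter_longitudinal(m, args.min_subjects)
    print(f"after depth >= {args.min_depth} and longitudinal filters: "
          f"{m.n_sites} CpGs")
    qc = pca_outlier_qc(m, threshold_sd=args.qc_sd)
    n_out = int(qc["outlier"].sum())
    print(f"PCA QC: {n_out} outlier sample(s) flagged at {args.qc_sd} SD")

    beta = pd.DataFrame(m.beta, columns=m.samples["sample_id"])
    beta.insert(0, "chrom", m.sites["chrom"])
    beta.insert(1, "pos", m.sites["pos"])
    beta.to_csv(args.workdir / "filtered_beta.tsv", sep="\t", index=False)
    qc.to_csv(args.workdir / "sample_qc.csv", index=False)
    print(f"wrote {args.workdir / 'filtered_beta.tsv'}")


if __name__ == "__main__":
    main()
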