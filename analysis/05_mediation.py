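"""Mediation decomposition of each CpG's age effect through PC1.

Splits the total effect (ages 2 -> 16) into the direct effect and the
effect mediated by cell-type composition, with quasi-Bayesian p-values
and genome-wide BH adjustment of the direct-effect tests, then tallies
the proportion-mediated classes among the TE-significant sites.
"""

import argparse
from pathlib import Path

import pandas as pd

from _common import load_filtered_matrix, load_truth_aligned

from methylaging import (AgeContrast, classify_prop_mediated, compute_pc1,
                         counts_to_proportions_imputed, run_mediation_ewas,
                         run_te_ewas)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results"))
    ap.add_argument("--contrast", type=float, nargs=2, default=(2.0, 16.0))
    ap.add_argument("--draws", type=int, default=4000)
    ap.add_argument("--seed", type=int, default=20260901)
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()

    m = load_filtered_matrix(args.workdir)
    counts = pd.read_csv(args.workdir / "cohort" / "cell_counts.csv")
    pc1 = compute_pc1(counts_to_proportions_imputed(counts))
    med = run_mediation_ewas(
        m, pc1.scores, contrast=AgeContrast(*args.contrast),
        alpha_fdr=args.fdr, n_draws=args.draws, seed=args.seed)
    n_de = int(med["significant_DE"].sum())
    print(f"mediation scan: {n_de} of {len(med)} CpGs DE-significant at "
          f"{args.fdr:.0%} FDR")
    truth = load_truth_aligned(args.workdir, m)
    print("classes among DE-significant CpGs:")
    print(truth.loc[med["significant_DE"].to_numpy(),
                    "cpg_class"].value_counts().to_string())

    te = run_te_ewas(m, alpha_fdr=args.fdr)
    classes = classify_prop_mediated(med.loc[te["significant"].to_numpy()])
    print("proportion mediated among TE-significant CpGs:")
    print(classes.round(3).to_string())
    med.to_csv(args.workdir / "mediation_results.tsv", sep="\t",
               index=False)


if __name__ == "__main__":
    main()
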