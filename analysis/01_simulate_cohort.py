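"""Generate the synthetic longitudinal whole-blood cohort.

Emulated conditions: 19 subjects sampled at 2, 10 and 16 years (57
samples), five leukocyte types with lymphocytes declining and neutrophils
rising across age, RRBS-like binomial read counts, and missing
observations.  Writes per-sample coverage files, the sample sheet, the
cell-count table and the per-CpG ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from methylaging import SimConfig, generate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results"))
    ap.add_argument("--n-cpgs", type=int, default=5000)
    ap.add_argument("--seed", type=int, default=20260901)
    args = ap.parse_args()

    cfg = SimConfig(n_cpgs=args.n_cpgs, seed=args.seed)
    ds = generate_dataset(cfg, args.workdir / "cohort")
    sheet = pd.read_csv(ds.sample_sheet)
    # keep_default_na: the CpG class label "null" is data, not missing
    truth = pd.read_csv(ds.truth_table, sep="\t",
                        keep_default_na=False, na_values=[""])
    print(f"wrote {len(ds.coverage_files)} coverage files to {ds.outdir}")
    print(f"samples: {len(sheet)} ({sheet['subject'].nunique()} subjects "
          f"x {sheet['timepoint'].nunique()} time points)")
    print("planted CpG classes:")
    print(truth["cpg_class"].value_counts().to_string())


if __name__ == "__main__":
    main()
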