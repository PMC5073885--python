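"""Shared loading helpers for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from methylaging import apply_depth_filter, filter_longitudinal, \
    read_coverage


def load_filtered_matrix(workdir: Path, min_depth: int = 10,
                         min_subjects: int = 10):
    cohort = Path(workdir) / "cohort"
    sheet = pd.read_csv(cohort / "sample_sheet.csv")
    paths = {sid: cohort / "coverage" / f"{sid}.cov"
             for sid in sheet["sample_id"]}
    m = read_coverage(paths, sheet)
    return filter_longitudinal(apply_depth_filter(m, min_depth),
                               min_subjects)


def load_truth_aligned(workdir: Path, m) -> pd.DataFrame:
    # keep_default_na: the CpG class label "null" is data, not missing
    truth = pd.read_csv(Path(workdir) / "cohort" / "truth.tsv", sep="\t",
                        keep_default_na=False, na_values=[""])
    truth["key"] = truth["chrom"] + ":" + truth["pos"].astype(str)
    return truth.set_index("key").loc[m.site_ids()].reset_index(drop=True)
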