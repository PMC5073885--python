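import numpy as np
import pandas as pd
import pytest

import methylaging as ma


@pytest.fixture(scope="session")
def cohort_config():
    """Default-condition cohort at a test-friendly number of CpGs."""
    return ma.SimConfig(n_subjects=19, n_cpgs=400, seed=20260901)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory, cohort_config):
    """One generated dataset shared across tests: (dataset, matrix, truth).

    The matrix is depth- and longitudinally filtered the way the pipeline
    would be run; truth rows are aligned to the surviving sites.
    """
    outdir = tmp_path_factory.mktemp("cohort")
    ds = ma.generate_dataset(cohort_config, outdir)
    m = ma.read_coverage(ds.coverage_files, pd.read_csv(ds.sample_sheet))
    m = ma.apply_depth_filter(m, 10)
    m = ma.filter_longitudinal(m, 10)
    # the class label "null" is data, not a missing marker
    truth = pd.read_csv(ds.truth_table, sep="\t",
                        keep_default_na=False, na_values=[""])
    truth["key"] = truth["chrom"] + ":" + truth["pos"].astype(str)
    truth = truth.set_index("key").loc[m.site_ids()].reset_index(drop=True)
    return ds, m, truth


@pytest.fixture(scope="session")
def cohort_pc1(cohort):
    ds, _, _ = cohort
    counts = pd.read_csv(ds.cell_counts)
    ctps = ma.counts_to_proportions_imputed(counts)
    return ma.compute_pc1(ctps)


def balanced_longitudinal(n_subjects, ages=(2.0, 10.0, 16.0)):
    """(age, subject) design arrays for a complete balanced cohort."""
    ages = np.asarray(ages, dtype=float)
    subject = np.repeat(np.arange(n_subjects), ages.size)
    age = np.tile(ages, n_subjects)
    return age, subject
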