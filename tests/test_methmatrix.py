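"""Coverage parsing and the depth/longitudinal/pairwise/QC filters."""

import numpy as np
import pandas as pd
import pytest

import methylaging as ma
from methylaging.methmatrix import MethMatrix, is_autosome


def make_sheet(entries):
    return pd.DataFrame(entries, columns=["sample_id", "subject",
                                          "timepoint", "age", "group"])


def write_cov(path, rows):
    with open(path, "w") as fh:
        for chrom, pos, m, u in rows:
            pct = 100.0 * m / (m + u) if m + u else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct}\t{m}\t{u}\n")
    return path


def matrix_from_counts(meth, total, sheet, chroms=None, pos=None):
    """Build a MethMatrix directly from count arrays."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    n = meth.shape[0]
    sites = pd.DataFrame({
        "chrom": chroms if chroms is not None else ["chr1"] * n,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100})
    return MethMatrix(sites=sites, samples=sheet.reset_index(drop=True),
                      meth=meth, total=total, usable=~np.isnan(total))


class TestReadCoverage:
    def test_disjoint_union(self, tmp_path):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "control"),
                            ("b", "s2", "y2", 2.0, "case")])
        pa = write_cov(tmp_path / "a.cov", [("chr1", 100, 3, 4),
                                            ("chr1", 200, 1, 9)])
        pb = write_cov(tmp_path / "b.cov", [("chr2", 50, 5, 5)])
        m = ma.read_coverage({"a": pa, "b": pb}, sheet)
        assert m.n_sites == 3
        assert np.isnan(m.total).sum() == 3  # each site in one sample only

    def test_counts_and_fraction(self, tmp_path):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "control")])
        pa = write_cov(tmp_path / "a.cov", [("chr1", 100, 5, 7)])
        m = ma.apply_depth_filter(
            ma.read_coverage({"a": pa}, sheet), 10)
        assert m.total[0, 0] == 12
        assert m.beta[0, 0] == pytest.approx(5 / 12)

    def test_empty_file_warns_and_gives_missing_column(self, tmp_path):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "control"),
                            ("b", "s2", "y2", 2.0, "case")])
        pa = write_cov(tmp_path / "a.cov", [("chr1", 100, 3, 4)])
        pb = tmp_path / "b.cov"
        pb.touch()
        with pytest.warns(UserWarning, match="empty"):
            m = ma.read_coverage({"a": pa, "b": pb}, sheet)
        assert np.isnan(m.total[:, 1]).all()

    def test_malformed_line_reports_location(self, tmp_path):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "control")])
        pa = tmp_path / "a.cov"
        pa.write_text("chr1\t100\t100\t50.0\t5\t5\n"
                      "chr1\tfoo\tfoo\t50.0\t5\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            ma.read_coverage({"a": pa}, sheet)

    def test_duplicate_site_rejected(self, tmp_path):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "control")])
        pa = write_cov(tmp_path / "a.cov", [("chr1", 100, 3, 4),
                                            ("chr1", 100, 1, 1)])
        with pytest.raises(ValueError, match="duplicate"):
            ma.read_coverage({"a": pa}, sheet)


class TestDepthFilter:
    def test_boundary_at_min_depth(self):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "g"),
                            ("b", "s2", "y2", 2.0, "g"),
                            ("c", "s3", "y2", 2.0, "g")])
        total = np.array([[9.0, 10.0, 11.0]])
        m = matrix_from_counts([[4.0, 5.0, 6.0]], total, sheet)
        f = ma.apply_depth_filter(m, 10)
        assert list(f.usable[0]) == [False, True, True]
        np.testing.assert_array_equal(f.total, total)  # counts preserved

    def test_min_depth_one_is_identity(self):
        sheet = make_sheet([("a", "s1", "y2", 2.0, "g")])
        m = matrix_from_counts([[1.0]], [[1.0]], sheet)
        f = ma.apply_depth_filter(m, 1)
        np.testing.assert_array_equal(f.usable, m.usable)

    def test_counting_oracle_on_simulation(self, cohort):
        _, m, _ = cohort
        brute = 0
        for i in range(m.n_sites):
            for j in range(m.n_samples):
                t = m.total[i, j]
                if not np.isnan(t) and t >= 10:
                    brute += 1
        assert int(m.usable.sum()) == brute


def longitudinal_sheet(n_subjects):
    rows = []
    for s in range(n_subjects):
        for tp, age in (("y2", 2.0), ("y10", 10.0), ("y16", 16.0)):
            rows.append((f"s{s}_{tp}", f"s{s}", tp, age, "g"))
    return make_sheet(rows)


class TestLongitudinalFilter:
    def test_boundary_at_min_subjects(self):
        sheet = longitudinal_sheet(12)
        total = np.full((2, 36), 30.0)
        # CpG 0: complete in 9 subjects; CpG 1: complete in 10
        total[0, : 3 * 3] = np.nan      # drop subjects 0-2 entirely
        total[1, : 2 * 3] = np.nan      # drop subjects 0-1
        meth = np.where(np.isnan(total), np.nan, 10.0)
        m = matrix_from_counts(meth, total, sheet)
        f = ma.filter_longitudinal(m, min_subjects=10)
        assert f.n_sites == 1
        assert f.sites["pos"].iloc[0] == 200

    def test_sex_chromosomes_dropped(self):
        sheet = longitudinal_sheet(10)
        total = np.full((2, 30), 30.0)
        m = matrix_from_counts(total / 2, total, sheet,
                               chroms=["chrX", "chr7"], pos=[100, 200])
        f = ma.filter_longitudinal(m, min_subjects=1, autosomes_only=True)
        assert list(f.sites["chrom"]) == ["chr7"]
        f2 = ma.filter_longitudinal(m, min_subjects=1, autosomes_only=False)
        assert f2.n_sites == 2

    def test_autosome_name_tolerance(self):
        assert is_autosome("chr22") and is_autosome("22")
        assert not is_autosome("chrX") and not is_autosome("chrM")

    def test_counting_oracle_under_random_missingness(self, cohort):
        """Survivor set equals a brute-force complete-subject count."""
        _, m, _ = cohort  # already filtered at min_subjects=10
        ds, _, _ = cohort
        raw = ma.apply_depth_filter(
            ma.read_coverage(ds.coverage_files,
                             pd.read_csv(ds.sample_sheet)), 10)
        keep = []
        for i in range(raw.n_sites):
            n_complete = 0
            for subj, grp in raw.samples.groupby("subject"):
                tps = {row["timepoint"] for _, row in grp.iterrows()
                       if raw.usable[i, row.name]}
                if tps == set(raw.samples["timepoint"].unique()):
                    n_complete += 1
            if n_complete >= 10 and is_autosome(raw.sites["chrom"][i]):
                keep.append(i)
        assert m.site_ids().tolist() == \
            raw.subset_sites(keep).site_ids().tolist()

    def test_order_stable_with_fused_pass(self, cohort):
        """depth -> longitudinal equals one fused filtering pass."""
        ds, m, _ = cohort
        raw = ma.read_coverage(ds.coverage_files,
                               pd.read_csv(ds.sample_sheet))
        fused = ma.filter_longitudinal(ma.apply_depth_filter(raw, 10), 10)
        assert fused.site_ids().tolist() == m.site_ids().tolist()
        np.testing.assert_array_equal(fused.usable, m.usable)


class TestPairwiseFilter:
    def test_variation_rule(self):
        sheet = longitudinal_sheet(10)
        total = np.full((2, 30), 30.0)
        meth = np.full((2, 30), 15.0)
        # CpG 0: identical differences (all zero); CpG 1: varying
        meth[1] = np.arange(30)
        m = matrix_from_counts(meth, total, sheet)
        idx = ma.filter_pairwise(m, "y2", "y10", min_pairs=10)
        assert idx.tolist() == [1]

    def test_pair_count_boundary(self):
        sheet = longitudinal_sheet(12)
        rng = np.random.default_rng(0)
        total = np.full((1, 36), 30.0)
        meth = rng.integers(5, 25, (1, 36)).astype(float)
        # drop the y10 observation of 3 subjects -> 9 pairs only
        for s in range(3):
            col = sheet.index[(sheet["subject"] == f"s{s}")
                              & (sheet["timepoint"] == "y10")][0]
            total[0, col] = np.nan
            meth[0, col] = np.nan
        m = matrix_from_counts(meth, total, sheet)
        assert ma.filter_pairwise(m, "y2", "y10", min_pairs=10).size == 0
        assert ma.filter_pairwise(m, "y2", "y10", min_pairs=9).size == 1

    def test_membership_matches_brute_force(self, cohort):
        _, m, _ = cohort
        idx = ma.filter_pairwise(m, "y2", "y16", min_pairs=10)
        beta = m.beta
        expected = []
        for i in range(m.n_sites):
            diffs = []
            for subj, grp in m.samples.groupby("subject"):
                pair = {}
                for _, row in grp.iterrows():
                    if row["timepoint"] in ("y2", "y16"):
                        pair[row["timepoint"]] = beta[i, row.name]
                if len(pair) == 2 and not any(np.isnan(v)
                                              for v in pair.values()):
                    diffs.append(pair["y16"] - pair["y2"])
            if len(diffs) >= 10 and np.var(diffs) > 0:
                expected.append(i)
        assert idx.tolist() == expected


class TestPcaQc:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(3)
        sheet = make_sheet([(f"s{j}", f"s{j}", "y2", 2.0, "g")
                            for j in range(20)])
        base = rng.uniform(0.2, 0.8, 50)
        beta = np.tile(base[:, None], (1, 20)) + rng.normal(0, 0.01, (50, 20))
        beta[:, 7] += 0.4  # shifted sample
        total = np.full((50, 20), 100.0)
        m = matrix_from_counts(beta * 100, total, sheet)
        qc = ma.pca_outlier_qc(m, n_components=2, threshold_sd=3.0)
        assert qc.loc[qc["outlier"], "sample_id"].tolist() == ["s7"]

    def test_infinite_threshold_flags_nothing(self, cohort):
        _, m, _ = cohort
        qc = ma.pca_outlier_qc(m, threshold_sd=np.inf)
        assert not qc["outlier"].any()

    def test_gaussian_flag_rate_matches_normal_tail(self):
        """At 3 SD on PC1 the flag rate is near the two-sided tail mass."""
        rng = np.random.default_rng(5)
        n = 10_000
        sheet = make_sheet([(f"s{j}", f"s{j}", "y2", 2.0, "g")
                            for j in range(n)])
        beta = rng.normal(0.5, 0.05, (30, n)).clip(0, 1)
        m = matrix_from_counts(beta * 50, np.full((30, n), 50.0), sheet)
        qc = ma.pca_outlier_qc(m, n_components=1, threshold_sd=3.0)
        expected = 2 * 0.0013499  # P(|Z| > 3)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(qc["outlier"].mean() - expected) < 3 * se


class TestBisulfiteConversion:
    def test_rates(self):
        df = pd.DataFrame({"converted": [990, 0, 995, 0],
                           "unconverted": [10, 100, 5, 0]},
                          index=["a", "b", "c", "d"])
        with pytest.warns(UserWarning, match="zero"):
            rate = ma.bisulfite_conversion_rate(df)
        assert rate["a"] == pytest.approx(0.99)
        assert rate["a"] >= 0.99  # boundary of the >99 % screen
        assert rate["b"] == 0.0
        assert rate["c"] == pytest.approx(0.995)
        assert np.isnan(rate["d"])
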