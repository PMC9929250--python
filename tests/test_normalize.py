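import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multiprot.datamodel import AbundanceMatrix, SampleInfo, ValidationError
from multiprot.normalize import (
    dip_statistic,
    fot_normalize,
    impute_min,
    log2_transform,
    qc_filter_samples,
    quantile_normalize,
)


def _raw(values, columns=None):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = [f"F{i}" for i in range(df.shape[0])]
    df.columns = columns or [f"S{j}" for j in range(df.shape[1])]
    return AbundanceMatrix(df, scale="raw", layer="proteome")


class TestFOT:
    def test_single_feature_column_scales_to_1e6(self):
        out = fot_normalize(_raw([[5.0]]))
        assert out.data.iloc[0, 0] == pytest.approx(1_000_000.0)

    def test_two_equal_features_split_evenly(self):
        out = fot_normalize(_raw([[3.0], [3.0]]))
        assert list(out.data.iloc[:, 0]) == pytest.approx([500_000.0, 500_000.0])

    def test_column_sums_conserved(self, rng):
        vals = rng.lognormal(5, 2, size=(20, 4))
        out = fot_normalize(_raw(vals))
        sums = out.data.sum(axis=0).to_numpy()
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_missing_entries_stay_missing_and_sums_hold(self, rng):
        vals = rng.lognormal(5, 1, size=(30, 3))
        vals[rng.random((30, 3)) < 0.25] = np.nan
        mat = _raw(vals)
        out = fot_normalize(mat)
        pd.testing.assert_frame_equal(out.mask, mat.mask)
        assert np.allclose(out.data.sum(axis=0, skipna=True).to_numpy(), 1e6)

    def test_all_missing_column_names_sample(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValidationError, match="S1"):
            fot_normalize(_raw(vals))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        vals = np.tile([[1.0], [4.0], [2.0]], (1, 3))
        out = quantile_normalize(_raw(vals))
        assert np.allclose(out.values, vals)

    def test_permuted_column_shares_sorted_values(self, rng):
        a = rng.lognormal(3, 1, size=12)
        b = rng.permutation(a)
        out = quantile_normalize(_raw(np.column_stack([a, b])))
        assert np.allclose(
            np.sort(out.data["S0"]), np.sort(out.data["S1"]), rtol=0, atol=0
        )

    def test_tie_gets_mean_of_spanned_reference_values(self):
        # column S1 has a tie at 2.0 (ranks 2 and 3)
        vals = np.array([
            [1.0, 2.0, 1.5],
            [2.0, 2.0, 2.5],
            [3.0, 5.0, 3.5],
            [4.0, 6.0, 4.5],
        ])
        out = quantile_normalize(_raw(vals))
        # reference = row-wise mean of sorted columns
        ref = np.mean(np.sort(vals, axis=0), axis=1)
        expected_tied = (ref[0] + ref[1]) / 2
        assert out.data.loc["F0", "S1"] == pytest.approx(expected_tied)
        assert out.data.loc["F1", "S1"] == pytest.approx(expected_tied)
        assert np.allclose(np.sort(out.data["S0"]), ref)

    def test_all_columns_share_one_multiset(self, rng):
        vals = rng.lognormal(4, 1, size=(25, 5))
        out = quantile_normalize(_raw(vals))
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 5):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_idempotent_without_ties(self, rng):
        vals = rng.lognormal(4, 1, size=(15, 4))
        once = quantile_normalize(_raw(vals))
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_matches_limma_reference_implementation(self, tmp_path, rng):
        """Cross-check against limma::normalizeQuantiles on a tie-free matrix."""
        import subprocess

        vals = np.round(rng.lognormal(3, 1, size=(8, 3)), 6)
        ours = quantile_normalize(_raw(vals))
        infile = tmp_path / "in.tsv"
        outfile = tmp_path / "out.tsv"
        pd.DataFrame(vals).to_csv(infile, sep="\t", index=False)
        script = tmp_path / "qn.R"
        script.write_text(
            f'x <- as.matrix(read.delim("{infile}"))\n'
            f'y <- limma::normalizeQuantiles(x)\n'
            f'write.table(y, "{outfile}", sep="\\t", row.names=FALSE)\n'
        )
        try:
            subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=120)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/limma unavailable")
        theirs = pd.read_csv(outfile, sep="\t").to_numpy()
        assert np.allclose(ours.values, theirs, rtol=1e-8)


class TestLog2AndImpute:
    def test_log2_known_values(self):
        out = log2_transform(_raw([[8.0], [1.0]]))
        assert list(out.data.iloc[:, 0]) == pytest.approx([3.0, 0.0])
        assert out.scale == "log2"

    def test_log2_roundtrip(self, rng):
        vals = rng.lognormal(3, 1, size=(10, 3))
        out = log2_transform(_raw(vals))
        assert np.allclose(2.0 ** out.values, vals)

    def test_log2_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            log2_transform(_raw([[0.0]]))

    def test_impute_no_missing_is_identity(self, rng):
        vals = rng.lognormal(3, 1, size=(5, 3))
        mat = _raw(vals)
        assert np.allclose(impute_min(mat).values, vals)

    def test_impute_uses_global_minimum(self, rng):
        vals = rng.uniform(0.5, 9.0, size=(20, 4))
        vals[0, 0] = 0.2
        mask = rng.random((20, 4)) < 0.2
        mask[0, 0] = False
        vals_missing = vals.copy()
        vals_missing[mask] = np.nan
        out = impute_min(_raw(vals_missing))
        assert np.all(out.values[mask] == 0.2)
        assert not out.mask.any().any()

    def test_fully_missing_rejected(self):
        with pytest.raises(ValidationError):
            impute_min(_raw([[np.nan], [np.nan]]))


def _paired_info(n):
    rows = []
    for i in range(n):
        rows.append((f"P{i}_T", f"P{i}", "tumor", "DGC"))
        rows.append((f"P{i}_N", f"P{i}", "NAT", "DGC"))
    return SampleInfo(pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "histology"]))


class TestQC:
    def test_equal_medians_retain_everyone(self):
        info = _paired_info(3)
        vals = np.ones((10, 6)) * 8.0
        mat = AbundanceMatrix(
            pd.DataFrame(vals, index=[f"F{i}" for i in range(10)], columns=info.sample_ids),
            scale="raw", layer="proteome",
        )
        report = qc_filter_samples(mat, info)
        assert report.excluded == {}
        assert sorted(report.retained) == sorted(info.sample_ids)

    def test_outlier_median_excluded_by_iqr_rule(self):
        info = _paired_info(4)
        # per-sample log2 medians {1,...,1,10}: Q3 + 1.5 IQR < 10 under
        # linear-interpolation quartiles, so the last sample is flagged
        cols = {}
        for j, s in enumerate(info.sample_ids):
            med = 10.0 if j == 7 else 1.0
            cols[s] = np.full(11, 2.0 ** med)
        mat = AbundanceMatrix(pd.DataFrame(cols, index=[f"F{i}" for i in range(11)]),
                              scale="raw", layer="proteome")
        medians = np.array([1.0] * 7 + [10.0])
        q1, q3 = np.quantile(medians, [0.25, 0.75])
        assert q3 + 1.5 * (q3 - q1) < 10
        report = qc_filter_samples(mat, info)
        assert report.excluded.get("P3_N") == "median_outlier"

    def test_exclusion_propagates_to_partner(self):
        info = _paired_info(4)
        cols = {}
        for s in info.sample_ids:
            med = 10.0 if s == "P0_T" else 1.0
            cols[s] = np.full(11, 2.0 ** med)
        mat = AbundanceMatrix(pd.DataFrame(cols, index=[f"F{i}" for i in range(11)]),
                              scale="raw", layer="proteome")
        report = qc_filter_samples(mat, info)
        assert report.excluded["P0_T"] == "median_outlier"
        assert report.excluded["P0_N"] == "partner_failed"
        assert "P0_T" not in report.retained and "P0_N" not in report.retained
        # retained set contains only complete pairs
        retained_patients = {s.split("_")[0] for s in report.retained}
        for p in retained_patients:
            assert f"{p}_T" in report.retained and f"{p}_N" in report.retained

    def test_too_few_samples_rejected(self):
        info = _paired_info(1)
        mat = AbundanceMatrix(
            pd.DataFrame(np.ones((4, 2)), index=list("ABCD"), columns=info.sample_ids),
            scale="raw", layer="proteome",
        )
        with pytest.raises(ValidationError):
            qc_filter_samples(mat, info)


class TestDipStatistic:
    def test_bimodal_exceeds_unimodal(self, rng):
        unimodal = rng.normal(0, 1, 300)
        bimodal = np.concatenate([rng.normal(-4, 0.5, 150), rng.normal(4, 0.5, 150)])
        assert dip_statistic(bimodal) > dip_statistic(unimodal)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_fot_conservation_property(seed):
    """FOT conservation holds for arbitrary positive matrices."""
    r = np.random.default_rng(seed)
    vals = r.lognormal(r.uniform(0, 8), r.uniform(0.2, 2), size=(r.integers(2, 30), r.integers(1, 6)))
    out = fot_normalize(_raw(vals))
    assert np.allclose(out.data.sum(axis=0).to_numpy(), 1e6, rtol=1e-9)
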