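"""Count matrices, filtering, size factors, NB Wald test, significance rules."""

import numpy as np
import pandas as pd
import pytest

from evsmallrna.annotate import AnnotatedRead
from evsmallrna.diffexpr import (CountMatrix, DETestResult, SampleInfo,
                                 build_count_matrix, call_significant,
                                 estimate_size_factors, filter_low_expression,
                                 nb_wald_test)


def _samples(n_per_day=3, cell_type="BMSC", compartment="EV"):
    out = []
    for day in ("D0", "D7"):
        for donor in range(1, n_per_day + 1):
            out.append(SampleInfo(f"{cell_type}_{compartment}_{day}_d{donor}",
                                  cell_type, compartment, day, donor))
    return out


def _cm(counts_by_feature, samples):
    frame = pd.DataFrame(counts_by_feature,
                         index=[s.sample_id for s in samples]).T
    return CountMatrix(frame, samples)


def _mirna_ann(name, n, prefix):
    return [AnnotatedRead(f"{prefix}{i}", "miRNA", name, 0, 22, 0, 0, 22)
            for i in range(n)]


class TestBuildCountMatrix:
    def test_planted_counts_recovered(self):
        samples = _samples(1)  # 2 samples
        ann = {
            samples[0].sample_id: _mirna_ann("miR-a", 3, "x")
            + _mirna_ann("miR-b", 5, "y"),
            samples[1].sample_id: _mirna_ann("miR-a", 7, "z"),
        }
        cm = build_count_matrix(ann, samples, "miRNA")
        assert cm.counts.loc["miR-a"].tolist() == [3, 7]
        assert cm.counts.loc["miR-b"].tolist() == [5, 0]

    def test_column_sums_equal_mirna_read_counts(self):
        rng = np.random.default_rng(0)
        samples = _samples(3)
        ann = {}
        for k, s in enumerate(samples):
            recs = []
            for j in range(int(rng.integers(5, 30))):
                recs += _mirna_ann(f"miR-{rng.integers(4)}", 1, f"{k}_{j}_")
            # non-miRNA reads must not be counted
            recs.append(AnnotatedRead(f"{k}_t", "tRNA", "Gly-GCC", 0, 33, 0,
                                      0, 33))
            ann[s.sample_id] = recs
        cm = build_count_matrix(ann, samples, "miRNA")
        for s in samples:
            n_mirna = sum(a.category == "miRNA" for a in ann[s.sample_id])
            assert cm.counts[s.sample_id].sum() == n_mirna

    def test_duplicate_design_rejected(self):
        s = _samples(1)
        dup = [s[0], SampleInfo("other", s[0].cell_type, s[0].compartment,
                                s[0].day, s[0].donor)]
        frame = pd.DataFrame(0, index=["f"], columns=["a", "other"])
        frame.columns = [dup[0].sample_id, "other"]
        with pytest.raises(ValueError):
            CountMatrix(frame, dup)


class TestFilterLowExpression:
    def test_boundary_rules(self):
        samples = _samples(1)
        cm = _cm({"all49": [49, 49], "one50": [50, 3], "zero": [0, 0],
                  "big": [500, 600]}, samples)
        kept = filter_low_expression(cm, threshold=50)
        assert list(kept.counts.index) == ["one50", "big"]

    def test_matches_one_line_oracle_on_random_matrix(self):
        rng = np.random.default_rng(1)
        samples = _samples(3)
        counts = pd.DataFrame(rng.integers(0, 120, size=(40, 6)),
                              index=[f"f{i}" for i in range(40)],
                              columns=[s.sample_id for s in samples])
        cm = CountMatrix(counts, samples)
        kept = filter_low_expression(cm, threshold=50)
        oracle = [f for f in counts.index if (counts.loc[f] >= 50).any()]
        assert list(kept.counts.index) == oracle


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        samples = _samples(2)
        col = [10, 200, 3000, 50]
        cm = _cm({f"f{i}": [col[i]] * 4 for i in range(4)}, samples)
        sf = estimate_size_factors(cm)
        assert np.allclose(sf.values, 1.0)

    def test_doubled_column_scale_equivariance(self):
        rng = np.random.default_rng(2)
        samples = _samples(2)
        base = rng.integers(10, 500, size=(30, 4))
        base[:, 3] = base[:, 0] * 2
        counts = pd.DataFrame(base, index=[f"f{i}" for i in range(30)],
                              columns=[s.sample_id for s in samples])
        sf = estimate_size_factors(CountMatrix(counts, samples))
        assert np.isclose(sf.iloc[3] / sf.iloc[0], 2.0)

    def test_matches_brute_force_oracle(self):
        # independent median-of-ratios computed with plain python loops
        rng = np.random.default_rng(3)
        for trial in range(5):
            arr = rng.integers(0, 400, size=(20, 6)).astype(float)
            arr[rng.integers(0, 20)] += 1  # ensure some all-positive rows
            counts = pd.DataFrame(arr, index=[f"f{i}" for i in range(20)],
                                  columns=[f"s{j}" for j in range(6)])
            pos_rows = [i for i in range(20) if all(arr[i] > 0)]
            raw = []
            for j in range(6):
                ratios = []
                for i in pos_rows:
                    geo = np.exp(sum(np.log(arr[i])) / 6)
                    ratios.append(arr[i, j] / geo)
                raw.append(float(np.median(ratios)))
            geo_raw = np.exp(np.mean(np.log(raw)))
            oracle = [f / geo_raw for f in raw]
            got = estimate_size_factors(counts)
            assert np.allclose(got.values, oracle, atol=1e-10)

    def test_no_all_positive_feature_raises(self):
        samples = _samples(1)
        cm = _cm({"a": [0, 5], "b": [5, 0]}, samples)
        with pytest.raises(ValueError):
            estimate_size_factors(cm)


def _simulate_counts(rng, mean_d0, mean_d7, dispersion, n_features,
                     samples):
    size = 1.0 / dispersion
    cols = {}
    for s in samples:
        mu = mean_d7 if s.day == "D7" else mean_d0
        p = size / (size + mu)
        cols[s.sample_id] = rng.negative_binomial(size, p, size=n_features)
    frame = pd.DataFrame(cols, index=[f"f{i}" for i in range(n_features)])
    return CountMatrix(frame, samples)


class TestNBWald:
    def test_identical_counts_give_zero_log2fc(self):
        samples = _samples(3)
        cm = _cm({"f": [100] * 6, "g": [40] * 6}, samples)
        res = nb_wald_test(cm, size_factors=pd.Series(
            1.0, index=[s.sample_id for s in samples]))
        for r in res:
            assert r.log2fc == 0.0

    def test_null_rejection_rate_within_band(self):
        rng = np.random.default_rng(100)
        samples = _samples(3)
        cm = _simulate_counts(rng, 1000, 1000, 0.05, 500, samples)
        res = nb_wald_test(cm)
        pvals = [r.wald_p for r in res if np.isfinite(r.wald_p)]
        rate = np.mean([p < 0.05 for p in pvals])
        assert 0.02 <= rate <= 0.09

    def test_null_pvalues_near_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(101)
        samples = _samples(3)
        cm = _simulate_counts(rng, 500, 500, 0.1, 500, samples)
        res = nb_wald_test(cm)
        pvals = [r.wald_p for r in res if np.isfinite(r.wald_p)]
        assert kstest(pvals, "uniform").statistic < 0.08

    def test_log2fc_recovery(self):
        # 30 four-fold features embedded in a null majority, so the
        # median-of-ratios normalization is anchored by unchanged features
        rng = np.random.default_rng(102)
        samples = _samples(3)
        null = _simulate_counts(rng, 1000, 1000, 0.05, 300, samples)
        de = _simulate_counts(rng, 1000, 4000, 0.05, 30, samples)
        de.counts.index = [f"de{i}" for i in range(30)]
        cm = CountMatrix(pd.concat([null.counts, de.counts]), samples)
        res = {r.feature: r for r in nb_wald_test(cm)}
        mean_fc = np.mean([res[f"de{i}"].log2fc for i in range(30)])
        assert abs(mean_fc - 2.0) <= 0.2

    def test_sign_convention_positive_means_up_at_d7(self):
        samples = _samples(3)
        counts = {"f": [10, 12, 11, 100, 110, 95]}  # D0 triplet then D7
        cm = _cm(counts, samples)
        sf = pd.Series(1.0, index=[s.sample_id for s in samples])
        [r] = nb_wald_test(cm, size_factors=sf)
        assert r.log2fc > 0

    def test_all_zero_feature_reported_na(self):
        samples = _samples(3)
        cm = _cm({"z": [0] * 6, "f": [50, 60, 55, 52, 58, 61]}, samples)
        res = {r.feature: r for r in nb_wald_test(cm)}
        assert np.isnan(res["z"].wald_p)
        assert np.isfinite(res["f"].wald_p)

    def test_group_with_too_few_samples_raises(self):
        samples = [SampleInfo("a", "ASC", "EV", "D0", 1),
                   SampleInfo("b", "ASC", "EV", "D0", 2),
                   SampleInfo("c", "ASC", "EV", "D7", 1)]
        frame = pd.DataFrame({"a": [5], "b": [6], "c": [7]}, index=["f"])
        with pytest.raises(ValueError):
            nb_wald_test(CountMatrix(frame, samples))


class TestBH:
    def test_matches_step_up_oracle(self):
        from oracles import bh_step_up
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.random(40)
            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, bh_step_up(list(p)), atol=1e-12)

    def test_padj_assigned_in_results(self):
        rng = np.random.default_rng(103)
        samples = _samples(3)
        cm = _simulate_counts(rng, 300, 300, 0.1, 50, samples)
        res = nb_wald_test(cm)
        assert all(np.isfinite(r.padj) for r in res
                   if np.isfinite(r.wald_p))


class TestCallSignificant:
    def _r(self, log2fc, p, padj):
        return DETestResult("f", 100.0, log2fc, 0.5, p, padj)

    def test_mirna_rule_boundary(self):
        [r] = call_significant([self._r(1.0, 0.049, 0.2)], "mirna")
        assert r.significant
        [r] = call_significant([self._r(0.9, 0.001, 0.001)], "mirna")
        assert not r.significant
        [r] = call_significant([self._r(1.5, 0.051, 0.2)], "mirna")
        assert not r.significant

    def test_tsrna_rule_uses_padj(self):
        [r] = call_significant([self._r(2.0, 0.001, 0.051)], "tsrna")
        assert not r.significant
        [r] = call_significant([self._r(2.0, 0.001, 0.049)], "tsrna")
        assert r.significant

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            call_significant([], "deseq")
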