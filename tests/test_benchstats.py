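"""Benchmark tables, quadrant/ensemble statistics, the pooled t-test and
identity-RMSD trend stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from tcrloops.benchstats import (
    BenchmarkError,
    PairingError,
    RegionRmsdReport,
    REPORT_REGIONS,
    embed_tsne,
    ensemble_best,
    identity_rmsd_trend,
    quadrant_classify,
    region_report,
    rmsd_t_test,
    subthreshold_count,
)
from tcrloops.geometry import DistanceMatrix, loop_rmsd
from tcrloops.model import extract_region
from tcrloops.synthetic import perturb_record


def _report(name, values, region="CDR3_beta"):
    table = pd.DataFrame(
        {r: (values if r == region else [0.0] * len(values)) for r in REPORT_REGIONS},
        index=[f"t{i}" for i in range(len(values))],
    )
    return RegionRmsdReport(model_name=name, table=table)


class TestRegionReport:
    def test_self_comparison_is_identically_zero(self, small_repertoire):
        records, _ = small_repertoire
        report = region_report(records[:5], records[:5], "self")
        assert np.allclose(report.table.to_numpy(), 0.0, atol=1e-9)
        assert list(report.table.columns) == list(REPORT_REGIONS)

    def test_single_displaced_loop_shows_only_in_its_cell(self, small_repertoire):
        records, _ = small_repertoire
        reference = records[0]
        prediction = perturb_record(reference, "beta", "CDR3", 2.0, seed=3)
        report = region_report([prediction], [reference], "m")
        row = report.table.iloc[0]
        assert row["CDR3_beta"] == pytest.approx(2.0, abs=1e-9)
        for region in REPORT_REGIONS:
            if region in ("CDR3_beta", "whole_beta", "FW_beta"):
                continue
            assert row[region] == pytest.approx(0.0, abs=1e-9)
        # the whole-beta superposition refits on all atoms including the
        # displaced loop, so some misfit leaks into the beta framework and
        # whole-chain cells — but far less than the loop displacement
        assert 0 < row["FW_beta"] < row["whole_beta"] < 2.0

    def test_injected_perturbations_match_geometry_oracle(self, small_repertoire):
        records, _ = small_repertoire
        references = records[:5]
        displacements = [0.5, 1.0, 1.5, 2.5, 3.0]
        predictions = [
            perturb_record(rec, "alpha", "CDR2", d, seed=i)
            for i, (rec, d) in enumerate(zip(references, displacements))
        ]
        report = region_report(predictions, references, "m")
        for pred, ref, d in zip(predictions, references, displacements):
            direct = loop_rmsd(
                extract_region(pred, "alpha", "CDR2"),
                extract_region(ref, "alpha", "CDR2"),
            ).value
            cell = report.table.loc[pred.record_id, "CDR2_alpha"]
            assert cell == pytest.approx(direct, abs=1e-12)
            assert cell == pytest.approx(d, abs=1e-9)

    def test_unpaired_ids_rejected(self, small_repertoire):
        records, _ = small_repertoire
        with pytest.raises(PairingError):
            region_report(records[:3], records[1:4], "m")


class TestSubthresholdCount:
    def test_all_below(self):
        report = _report("m", [1.0] * 7)
        assert subthreshold_count(report, "CDR3_beta", 2.0) == (7, 1.0)

    def test_strictly_below(self):
        report = _report("m", [1.9, 2.0, 2.1])
        count, fraction = subthreshold_count(report, "CDR3_beta", 2.0)
        assert count == 1 and fraction == pytest.approx(1 / 3)

    def test_fraction_monotone_in_threshold(self, rng):
        report = _report("m", list(rng.uniform(0, 4, size=50)))
        fractions = [subthreshold_count(report, "CDR3_beta", t)[1]
                     for t in (3.0, 2.0, 1.0, 0.5)]
        assert fractions == sorted(fractions, reverse=True)


class TestQuadrantsAndEnsemble:
    def test_identical_reports_all_green(self):
        report = _report("m", [1.0, 1.5, 0.5])
        summary = quadrant_classify(report, report, "CDR3_beta", 2.0)
        assert summary.both_below == 3 and summary.n == 3

    def test_a_rescues_everything(self):
        a = _report("a", [1.0, 1.0])
        b = _report("b", [3.0, 3.0])
        summary = quadrant_classify(a, b, "CDR3_beta", 2.0)
        assert summary.only_a_below == 2
        assert summary.both_below == summary.only_b_below == 0

    def test_six_record_fixture_spans_all_quadrants(self):
        a = _report("a", [1.0, 1.0, 3.0, 3.0, 1.5, 2.5])
        b = _report("b", [1.0, 3.0, 1.0, 3.0, 1.5, 2.5])
        summary = quadrant_classify(a, b, "CDR3_beta", 2.0)
        assert (summary.both_below, summary.only_a_below,
                summary.only_b_below, summary.both_at_or_above) == (2, 1, 1, 2)
        assert summary.n == 6
        swapped = quadrant_classify(b, a, "CDR3_beta", 2.0)
        assert swapped.only_a_below == summary.only_b_below
        assert swapped.only_b_below == summary.only_a_below

    def test_ensemble_at_least_each_model(self, rng):
        a = _report("a", list(rng.uniform(0, 4, size=40)))
        b = _report("b", list(rng.uniform(0, 4, size=40)))
        best = ensemble_best(a, b, "CDR3_beta", 2.0)
        assert best >= subthreshold_count(a, "CDR3_beta", 2.0)[1] - 1e-12
        assert best >= subthreshold_count(b, "CDR3_beta", 2.0)[1] - 1e-12

    def test_complementary_failures_reach_one(self):
        a = _report("a", [1.0, 3.0, 1.0, 3.0])
        b = _report("b", [3.0, 1.0, 3.0, 1.0])
        assert ensemble_best(a, b, "CDR3_beta", 2.0) == pytest.approx(1.0)


class TestRmsdTTest:
    def test_identical_samples(self):
        comparison = rmsd_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert comparison.t_value == 0.0 and comparison.p_value == pytest.approx(1.0)

    def test_formula_on_known_moments(self):
        # mean difference 1, equal sample variances 1, n = 45:
        # t = 1 / sqrt(2/45)
        rng = np.random.default_rng(5)
        a = rng.normal(size=45)
        a = (a - a.mean()) / a.std(ddof=1)
        b = a + 1.0
        comparison = rmsd_t_test(a, b)
        expected_t = 1.0 / np.sqrt(2.0 / 45.0)
        assert comparison.t_value == pytest.approx(expected_t, abs=1e-10)
        # survival-function oracle through the regularised incomplete beta
        df = 44
        sf = 0.5 * special.betainc(df / 2.0, 0.5, df / (df + expected_t**2))
        assert comparison.p_value == pytest.approx(2 * sf, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.gamma(2.0, size=45), rng.gamma(3.0, size=45)
        fwd, rev = rmsd_t_test(a, b), rmsd_t_test(b, a)
        assert fwd.t_value == rev.t_value and fwd.p_value == rev.p_value

    def test_welch_variant_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.gamma(2.0, size=30), rng.gamma(3.0, size=30)
        ours = rmsd_t_test(a, b, welch=True)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t_value == pytest.approx(abs(t)) and ours.p_value == pytest.approx(p)

    def test_too_short_rejected(self):
        with pytest.raises(BenchmarkError):
            rmsd_t_test([1.0], [2.0])


class TestIdentityRmsdTrend:
    def test_perfect_anticorrelation(self):
        pairs = [(i / 10, 5.0 - i / 10) for i in range(10)]
        trend = identity_rmsd_trend(pairs)
        assert trend.pcc_all == pytest.approx(-1.0)
        assert trend.slope == pytest.approx(-1.0)

    def test_constant_identity_stratum_flagged(self):
        pairs = [(0.9, 1.0), (0.9, 2.0), (0.9, 3.0), (0.2, 1.0), (0.3, 2.0), (0.4, 0.5)]
        trend = identity_rmsd_trend(pairs, split=0.65)
        assert np.isnan(trend.pcc_high) and "high" in trend.undefined_strata
        assert not np.isnan(trend.pcc_low)

    def test_stratum_sizes(self):
        pairs = [(0.5, 1.0)] * 4 + [(0.9, 1.0)] * 6
        trend = identity_rmsd_trend(pairs, split=0.65)
        assert (trend.n_low, trend.n_high, trend.n_all) == (4, 6, 10)


class TestEmbedTsne:
    def _two_block_matrix(self, rng, n_per=20, gap=8.0):
        coords = np.concatenate([
            rng.normal(scale=0.3, size=(n_per, 2)),
            rng.normal(loc=gap, scale=0.3, size=(n_per, 2)),
        ])
        from scipy.spatial.distance import squareform, pdist

        values = squareform(pdist(coords))
        return DistanceMatrix(ids=[f"i{k}" for k in range(2 * n_per)], values=values)

    def test_separated_blocks_keep_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        matrix = self._two_block_matrix(rng)
        labels = np.array([0] * 20 + [1] * 20)
        coords = embed_tsne(matrix, perplexity=10, seed=0, labels=labels)
        score = silhouette_score(coords[["tsne1", "tsne2"]].to_numpy(), labels)
        assert score > 0.5

    def test_deterministic_under_seed_and_label_passthrough(self, rng):
        matrix = self._two_block_matrix(rng)
        labels = np.array([0] * 20 + [1] * 20)
        first = embed_tsne(matrix, perplexity=10, seed=42, labels=labels)
        second = embed_tsne(matrix, perplexity=10, seed=42, labels=labels)
        assert np.array_equal(first.to_numpy(), second.to_numpy())
        assert np.array_equal(first["label"].to_numpy(), labels)

    def test_too_few_items_rejected(self, rng):
        matrix = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2)))
        with pytest.raises(BenchmarkError):
            embed_tsne(matrix, perplexity=10)
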