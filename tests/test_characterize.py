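"""Selected-edge characterization: weighted degrees, network summary, clinical r."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fcmvpa as f
from fcmvpa.atlas import edge_endpoints
from fcmvpa.mvpa import SelectedEdgeSet


def make_set(edges, weights):
    edges = np.asarray(edges, dtype=int)
    return SelectedEdgeSet(
        edges=edges,
        weights=np.asarray(weights, dtype=float),
        frequency=np.ones(edges.size),
        percentage=10,
        n_folds=1,
    )


class TestWeightedDegree:
    def test_single_edge_hits_both_endpoints(self, atlas):
        k = f.edge_index(3, 17, 90)
        deg = f.weighted_degree(make_set([k], [0.5]), atlas)
        pos = deg["positive_degree"].to_numpy()
        assert pos[3] == pytest.approx(0.5) and pos[17] == pytest.approx(0.5)
        assert pos.sum() == pytest.approx(1.0)

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_identity(self, atlas, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 60))
        edges = rng.choice(4005, size=m, replace=False)
        weights = rng.standard_normal(m)
        deg = f.weighted_degree(make_set(edges, weights), atlas)
        assert deg["positive_degree"].sum() == pytest.approx(2 * weights[weights > 0].sum())
        assert deg["negative_degree"].sum() == pytest.approx(2 * weights[weights < 0].sum())

    def test_concentrated_region_exceeds_two_sd(self, atlas):
        edges = [f.edge_index(0, j, 90) for j in range(1, 11)]
        deg = f.weighted_degree(make_set(edges, [1.0] * 10), atlas)
        flagged = deg.loc[deg["pos_above_mean_2sd"], "region"].tolist()
        assert flagged == [atlas.labels[0]]

    def test_absolute_mode_flags_negative_magnitudes(self, atlas):
        edges = [f.edge_index(0, j, 90) for j in range(1, 11)]
        deg = f.weighted_degree(make_set(edges, [-1.0] * 10), atlas, absolute=True)
        assert deg.loc[0, "neg_below_mean_2sd"]


class TestNetworkSummary:
    def test_counts_partition_selected_set(self, atlas):
        rng = np.random.default_rng(0)
        edges = rng.choice(4005, size=120, replace=False)
        s = f.network_summary(edges, atlas)
        assert s.intra_total + s.inter_total == 120
        assert int(np.diag(s.count).sum()) == s.intra_total

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_totals_and_percent_identities(self, atlas, seed):
        rng = np.random.default_rng(seed)
        edges = rng.choice(4005, size=int(rng.integers(1, 300)), replace=False)
        s = f.network_summary(edges, atlas)
        diag_count = np.diag(s.count.to_numpy()).sum()
        diag_poss = np.diag(s.possible.to_numpy()).sum()
        assert s.mean_intra_pct == pytest.approx(100 * diag_count / diag_poss)
        assert s.mean_inter_pct == pytest.approx(
            100 * (edges.size - diag_count) / (4005 - diag_poss)
        )
        valid = s.possible.to_numpy() > 0
        expected = 100 * s.count.to_numpy()[valid] / s.possible.to_numpy()[valid]
        assert np.allclose(s.percent.to_numpy()[valid], expected)

    def test_symmetry(self, atlas):
        edges = np.arange(0, 4005, 97)
        s = f.network_summary(edges, atlas)
        assert np.array_equal(s.count.to_numpy(), s.count.to_numpy().T)


class TestClinicalCorrelation:
    def _patients(self, n, rng):
        x = rng.standard_normal((n, 10))
        table = pd.DataFrame(
            {
                "id": [f"OSA{i:02d}" for i in range(n)],
                "group": "OSA",
                "age": rng.uniform(30, 60, n),
                "ahi": rng.uniform(15, 90, n),
                "pct_tst_below_90": rng.uniform(0, 60, n),
            }
        )
        return x, table

    def test_identical_series_give_unit_r(self):
        rng = np.random.default_rng(1)
        x, table = self._patients(12, rng)
        table["ahi"] = x[:, 3]
        out = f.clinical_correlation(np.array([3]), x, table, variables=("ahi",))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "significant"]

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x, table = self._patients(5, rng)
        out = f.clinical_correlation(np.array([0, 4]), x, table, variables=("ahi",))
        c = table["ahi"].to_numpy()
        for row_i, e in enumerate([0, 4]):
            v = x[:, e]
            num = ((v - v.mean()) * (c - c.mean())).sum()
            den = np.sqrt(((v - v.mean()) ** 2).sum() * ((c - c.mean()) ** 2).sum())
            assert out.loc[row_i, "r"] == pytest.approx(num / den, abs=1e-12)

    def test_constant_variable_flagged(self):
        rng = np.random.default_rng(3)
        x, table = self._patients(8, rng)
        table["ahi"] = 42.0
        out = f.clinical_correlation(np.array([0]), x, table, variables=("ahi",))
        assert out.loc[0, "constant_variable"]
        assert np.isnan(out.loc[0, "r"])
        assert not out.loc[0, "significant"]

    def test_generator_round_trip_recovers_link(self):
        k = f.edge_index(1, 4, 8)
        spec = f.CohortSpec(
            n_per_group=200, n_regions=8, n_timepoints=170,
            effect_edges=(k,), effect_delta=0.2,
            clinical_links=(f.ClinicalLink(edge=k, variable="pct_tst_below_90", r=0.7),),
            seed=13,
        )
        series, records = f.sample_cohort(spec)
        x = f.cohort_edge_matrix(series)
        groups = np.array([r.group for r in records])
        patients = pd.DataFrame([vars(r) for r in records if r.group == "OSA"])
        out = f.clinical_correlation(
            np.array([k]), x[groups == "OSA"], patients, variables=("pct_tst_below_90",)
        )
        assert out.loc[0, "r"] == pytest.approx(0.7, abs=0.1)

    def test_too_few_patients_rejected(self):
        rng = np.random.default_rng(4)
        x, table = self._patients(3, rng)
        with pytest.raises(ValueError, match="4 patients"):
            f.clinical_correlation(np.array([0]), x, table)
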