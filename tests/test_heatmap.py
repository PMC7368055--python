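"""0-10 scaling, subtraction heatmaps, interval kinetics, clustering,
cross-surface correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

from thromboflow.heatmap import (
    cluster_rows,
    correlate_surfaces,
    interval_deltas,
    linkage_to_newick,
    scale_rows,
    subtraction_heatmap,
    summed_scaled_effect,
)


def brute_force_complete_linkage_cophenetic(x: np.ndarray) -> np.ndarray:
    """O(n^3) agglomerative complete linkage; returns the condensed
    cophenetic distance matrix.  Independent of scipy's implementation."""
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = max(
                    np.linalg.norm(x[i] - x[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    iu = np.triu_indices(n, 1)
    return coph[iu]


class TestScaleRows:
    def test_linear_endpoints(self):
        sm = scale_rows(pd.DataFrame([[1.0, 3.0, 5.0]]))
        assert sm.data.iloc[0].tolist() == [0.0, 5.0, 10.0]

    def test_constant_row_flagged_all_zero(self):
        sm = scale_rows(pd.DataFrame([[4.0, 4.0, 4.0]]))
        assert sm.data.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert bool(sm.constant_rows.iloc[0])

    def test_inverse_round_trip(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, (6, 8)))
        sm = scale_rows(table)
        assert np.abs(sm.inverse().to_numpy() - table.to_numpy()).max() < 1e-9

    def test_affine_invariance(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (4, 6)))
        a = scale_rows(table).data.to_numpy()
        b = scale_rows(table * 7.3 - 2.1).data.to_numpy()
        assert np.allclose(a, b)

    def test_min_maps_to_zero_max_to_ten(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (5, 7)))
        sm = scale_rows(table)
        assert np.allclose(sm.data.min(axis=1), 0.0)
        assert np.allclose(sm.data.max(axis=1), 10.0)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            scale_rows(pd.DataFrame())


class TestSubtractionHeatmap:
    def test_identical_matrices_zero_diff(self):
        a = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
        diff = subtraction_heatmap(a, a.copy())
        assert (diff.delta == 0).all().all()

    def test_band_filtering(self):
        a = pd.DataFrame([[2.0, 0.5]])
        b = pd.DataFrame([[0.0, 0.0]])
        diff = subtraction_heatmap(a, b, band_sd=1.0)
        assert diff.delta.iloc[0, 0] == 2.0  # outside mean 0 +/- SD 1
        assert diff.delta.iloc[0, 1] == 0.0  # inside the band

    def test_zero_band_retains_every_nonzero_delta(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        b = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        diff = subtraction_heatmap(a, b, band_sd=0.0)
        raw = a - b.to_numpy()
        assert (diff.delta.to_numpy() == raw.to_numpy()).all()

    def test_infinite_band_retains_nothing(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        b = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        diff = subtraction_heatmap(a, b, band_sd=np.inf)
        assert (diff.delta == 0).all().all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            subtraction_heatmap(pd.DataFrame([[1.0]]), pd.DataFrame([[1.0, 2.0]]))


class TestIntervalDeltas:
    def test_linear_rise_splits_evenly(self):
        frame = pd.DataFrame(
            {"parameter": "P1", "time": [0, 4, 8], "value": [0.0, 5.0, 10.0]}
        )
        d = interval_deltas(frame)
        assert d.loc[0, "dt1"] == 5.0 and d.loc[0, "dt2"] == 5.0

    def test_early_saturating_parameter(self):
        frame = pd.DataFrame(
            {"parameter": "P4", "time": [0, 4, 8], "value": [0.0, 10.0, 10.0]}
        )
        d = interval_deltas(frame)
        assert d.loc[0, "dt1"] == 10.0 and d.loc[0, "dt2"] == 0.0

    def test_missing_anchor_gives_nan(self):
        frame = pd.DataFrame({"parameter": "P1", "time": [0, 8], "value": [0.0, 10.0]})
        d = interval_deltas(frame)
        assert np.isnan(d.loc[0, "dt1"]) and np.isnan(d.loc[0, "dt2"])


class TestSummedScaledEffect:
    def test_fully_filtered_diff_sums_to_zero(self):
        a = pd.DataFrame([[0.1, -0.2]])
        diff = subtraction_heatmap(a, a * 0.0, band_sd=1.0)
        assert summed_scaled_effect(diff) == 0.0

    def test_signed_arithmetic(self):
        delta = pd.DataFrame([[2.0, -0.5]])
        diff = subtraction_heatmap(delta, delta * 0.0, band_sd=0.0)
        assert summed_scaled_effect(diff) == pytest.approx(1.5)

    def test_empty_scope_raises(self):
        diff = subtraction_heatmap(pd.DataFrame([[1.0]]), pd.DataFrame([[0.0]]))
        with pytest.raises(ValueError):
            summed_scaled_effect(diff, rows=[])


class TestClusterRows:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        tree = cluster_rows(m)
        assert tree.linkage[0, 2] == 0.0

    def test_close_pair_merges_first(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=["a", "b", "c"])
        tree = cluster_rows(m)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(2, 6))
            x = rng.normal(0, 1, (n, m))
            tree = cluster_rows(pd.DataFrame(x))
            expected = brute_force_complete_linkage_cophenetic(x)
            got = cophenet(tree.linkage)
            assert np.allclose(got, expected, atol=1e-9)

    def test_missing_values_raise(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            cluster_rows(m)

    def test_newick_serialization(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=["a", "b", "c"])
        nwk = linkage_to_newick(cluster_rows(m))
        assert nwk.endswith(";")
        for label in ("a", "b", "c"):
            assert label in nwk


class TestCorrelateSurfaces:
    @staticmethod
    def _frame(values, subjects, parameter="P1", time=8):
        return pd.DataFrame(
            {
                "parameter": parameter,
                "time": time,
                "subject": subjects,
                "value": values,
            }
        )

    def test_identical_frames_correlate_perfectly(self, rng):
        subjects = [f"S{i}" for i in range(6)]
        a = self._frame(rng.normal(0, 1, 6), subjects)
        out = correlate_surfaces(a, a.copy())
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_reports_missing(self):
        subjects = ["S1", "S2", "S3"]
        a = self._frame([1.0, 1.0, 1.0], subjects)
        b = self._frame([1.0, 2.0, 3.0], subjects)
        out = correlate_surfaces(a, b)
        assert np.isnan(out["r"].iloc[0])

    def test_shared_subject_effect_dominates(self, rng):
        # strong donor-level random effect shared by both surfaces
        subjects = [f"S{i}" for i in range(12)]
        donor = rng.normal(0, 5, 12)
        a = self._frame(donor + rng.normal(0, 0.5, 12), subjects)
        b = self._frame(donor + rng.normal(0, 0.5, 12), subjects)
        out = correlate_surfaces(a, b)
        assert out["r"].iloc[0] > 0.5

    def test_independent_noise_near_zero_mean_r(self, rng):
        subjects = [f"S{i}" for i in range(10)]
        rs = []
        for _ in range(30):
            a = self._frame(rng.normal(0, 1, 10), subjects)
            b = self._frame(rng.normal(0, 1, 10), subjects)
            rs.append(correlate_surfaces(a, b)["r"].iloc[0])
        assert abs(float(np.mean(rs))) < 0.15
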