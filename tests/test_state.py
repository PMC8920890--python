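import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from burstlnc.state import (
    anova_phase_de,
    apoptosis_cluster,
    assign_phase,
    fit_trajectory,
    guilt_by_association,
    log_normalize,
    pam_kmedoids,
    select_variable_genes,
)
from burstlnc.synth import DEFAULT_MARKERS, PHASE_ORDER, generate_cell_cycle_dataset


def marker_map(counts):
    return {
        phase: [g for g in counts.index if g.startswith(prefix)]
        for phase, prefix in DEFAULT_MARKERS.items()
    }


class TestLogNormalize:
    def test_formula(self):
        counts = pd.DataFrame({"c": [1, 9_999]}, index=["g1", "g2"])
        out = log_normalize(counts, scale=10_000)
        assert out.at["g1", "c"] == pytest.approx(math.log(2.0))

    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"c": [0, 10]}, index=["g1", "g2"])
        assert log_normalize(counts).at["g1", "c"] == 0.0

    def test_depth_invariance(self):
        counts = pd.DataFrame({"c": [3, 7, 10]}, index=["a", "b", "c"])
        doubled = counts * 2
        pd.testing.assert_frame_equal(log_normalize(counts), log_normalize(doubled))

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame({"c": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(counts)

    def test_invertible_given_totals(self):
        counts = pd.DataFrame({"c1": [3, 7], "c2": [1, 5]}, index=["a", "b"])
        norm = log_normalize(counts, scale=10_000)
        totals = counts.sum(axis=0)
        back = (np.expm1(norm) / 10_000).mul(totals, axis=1)
        pd.testing.assert_frame_equal(back, counts.astype(float))


class TestVariableGenes:
    def test_inflated_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        n_cells = 200
        means = rng.uniform(2, 60, 60)
        base = rng.poisson(means[:, None], size=(60, n_cells)).astype(float)
        # one mid-mean gene with ~10x the variance the trend predicts
        m = 20.0
        base[0] = np.clip(m + (rng.poisson(m, n_cells) - m) * math.sqrt(10.0), 0, None)
        counts = pd.DataFrame(base, index=[f"g{i}" for i in range(60)])
        ranked = select_variable_genes(log_normalize(counts), n_top=5, counts=counts)
        assert ranked[0] == "g0"

    def test_identity_when_n_top_is_universe(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(5, size=(10, 50)),
                              index=[f"g{i}" for i in range(10)])
        ranked = select_variable_genes(log_normalize(counts), n_top=10, counts=counts)
        assert set(ranked) == set(counts.index)


class TestTrajectory:
    def test_linear_points_keep_order(self):
        rng = np.random.default_rng(2)
        n = 60
        t = np.linspace(0, 1, n)
        mat = pd.DataFrame(
            np.vstack([3 * t, 2 * t + 0.01 * rng.normal(size=n), -t]),
            index=["a", "b", "c"], columns=[f"c{i}" for i in range(n)],
        )
        lam = fit_trajectory(mat, ["a", "b", "c"], n_pcs=2)
        rho = spearmanr(lam.to_numpy(), t).statistic
        assert abs(rho) > 0.99

    def test_duplicate_points_get_identical_coordinates(self):
        mat = pd.DataFrame(
            np.column_stack([np.repeat([[1.0, 5.0, 2.0]], 10, axis=0).T,
                             np.repeat([[4.0, 1.0, 3.0]], 10, axis=0).T]).reshape(3, 20),
            index=["a", "b", "c"],
        )
        # 20 cells: first 10 identical, last 10 identical
        lam = fit_trajectory(mat, ["a", "b", "c"], n_pcs=2)
        assert np.ptp(lam.iloc[:10]) < 1e-9 and np.ptp(lam.iloc[10:]) < 1e-9

    def test_circular_structure_rank_correlates(self):
        # a clean circular manifold: the curve coordinate should recover the
        # latent angle ordering up to rotation and reflection
        n_cells = 300
        counts, truth = generate_cell_cycle_dataset(
            n_cells=n_cells, seed=4, n_noise_genes=20, marker_amplitude=100.0,
            concentration=6.0, markers_per_phase=8,
        )
        norm = log_normalize(counts)
        markers = [g for g in counts.index if not g.startswith("noise")]
        lam = fit_trajectory(norm, markers, n_pcs=3)
        # the generator draws cell angles as its first RNG use; reconstruct
        gen_rng = np.random.default_rng(4)
        true_theta = gen_rng.uniform(0, 2 * math.pi, n_cells)
        best = 0.0
        lamv = lam.to_numpy()
        for shift in np.linspace(0, 2 * math.pi, 72, endpoint=False):
            shifted = (true_theta + shift) % (2 * math.pi)
            best = max(best, abs(spearmanr(lamv, shifted).statistic))
        assert best > 0.8

    def test_too_few_cells_rejected(self):
        mat = pd.DataFrame(np.random.rand(3, 5), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            fit_trajectory(mat, ["a", "b", "c"])


class TestAssignPhase:
    def test_exclusive_markers_recover_phases(self):
        counts, truth = generate_cell_cycle_dataset(
            n_cells=300, seed=5, marker_amplitude=60.0, marker_baseline=0.1,
            concentration=12.0, n_noise_genes=20,
        )
        norm = log_normalize(counts)
        markers = marker_map(counts)
        lam = fit_trajectory(norm, [g for gl in markers.values() for g in gl])
        assigned = assign_phase(lam, norm, markers)
        agreement = (assigned["phase"] == truth.phases).mean()
        assert agreement >= 0.9

    def test_constant_markers_single_phase_with_warning(self):
        cells = [f"c{i}" for i in range(30)]
        norm = pd.DataFrame(1.0, index=["m1", "m2", "m3", "m4"], columns=cells)
        lam = pd.Series(np.arange(30, dtype=float), index=cells)
        markers = dict(zip(PHASE_ORDER, [["m1"], ["m2"], ["m3"], ["m4"]]))
        with pytest.warns(UserWarning, match="constant"):
            out = assign_phase(lam, norm, markers)
        assert out["phase"].nunique() == 1

    def test_window_larger_than_cells_rejected(self):
        lam = pd.Series([0.0, 1.0], index=["a", "b"])
        norm = pd.DataFrame(1.0, index=["m"], columns=["a", "b"])
        with pytest.raises(ValueError, match="window"):
            assign_phase(lam, norm, {p: ["m"] for p in PHASE_ORDER}, window=15)

    def test_missing_marker_named(self):
        lam = pd.Series(np.arange(20, dtype=float), index=[f"c{i}" for i in range(20)])
        norm = pd.DataFrame(1.0, index=["m"], columns=lam.index)
        with pytest.raises(ValueError, match="G1/S"):
            assign_phase(lam, norm, {"G0": ["m"], "G1": ["m"], "G1/S": ["absent"],
                                     "G2/M": ["m"]}, window=5)


class TestAnovaPhaseDe:
    def _phases(self, n_per):
        labels = np.repeat(PHASE_ORDER, n_per)
        return pd.Series(labels, index=[f"c{i}" for i in range(len(labels))])

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(6)
        phases = self._phases(50)
        mat = pd.DataFrame(rng.normal(5, 1, size=(1000, 200)),
                           index=[f"g{i}" for i in range(1000)],
                           columns=phases.index)
        de = anova_phase_de(mat, phases)
        assert de["significant"].mean() <= 0.01

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        phases = self._phases(100)
        mat = pd.DataFrame(rng.normal(2, 0.5, size=(5, 400)),
                           index=[f"g{i}" for i in range(5)],
                           columns=phases.index)
        mat.loc["g0", phases == "G2/M"] += 8.0  # 5x mean shift
        de = anova_phase_de(mat, phases)
        assert de.at["g0", "significant"]
        assert de.at["g0", "top_phase"] == "G2/M"

    def test_single_phase_rejected(self):
        phases = pd.Series(["G1"] * 10, index=[f"c{i}" for i in range(10)])
        mat = pd.DataFrame(np.random.rand(3, 10), columns=phases.index)
        with pytest.raises(ValueError):
            anova_phase_de(mat, phases)


class TestApoptosisCluster:
    def test_k_one_gives_single_cluster(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(10, size=(80, 40)) + 1,
                              index=[f"g{i}" for i in range(80)])
        norm = log_normalize(counts)
        labels = apoptosis_cluster(norm, list(norm.index), n_top=20, k=1)
        assert labels.nunique() == 1

    def test_planted_cluster_recovered(self):
        rng = np.random.default_rng(9)
        n_cells = 100
        counts = rng.poisson(8, size=(80, n_cells)).astype(float)
        truth = np.zeros(n_cells, dtype=int)
        truth[:20] = 1  # 20% of cells with shifted apoptosis-gene means
        counts[:30, truth == 1] = rng.poisson(30, size=(30, 20))
        frame = pd.DataFrame(counts + 1, index=[f"apop{i}" for i in range(30)]
                             + [f"g{i}" for i in range(50)])
        norm = log_normalize(frame)
        labels = apoptosis_cluster(norm, [f"apop{i}" for i in range(30)],
                                   n_top=30, k=2)
        assert adjusted_rand_score(truth, labels.to_numpy()) > 0.7

    def test_fewer_cells_than_clusters_rejected(self):
        norm = pd.DataFrame(np.random.rand(5, 2) + 1.0)
        with pytest.raises(ValueError):
            apoptosis_cluster(norm, list(norm.index), k=3)


class TestPamKmedoids:
    def test_separates_two_blobs(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(5, 0.2, (15, 2))])
        labels = pam_kmedoids(x, 2)
        assert adjusted_rand_score([0] * 15 + [1] * 15, labels) == 1.0


class TestGuiltByAssociation:
    def _norm(self, seed=11, n_cells=120):
        rng = np.random.default_rng(seed)
        target = rng.gamma(2, 1, n_cells)
        partner = target + rng.normal(0, 0.3, n_cells)  # strongly correlated
        indep = rng.gamma(2, 1, n_cells)
        return pd.DataFrame(
            np.clip(np.vstack([target, partner, indep]), 0, None),
            index=["target", "partner", "indep"],
        )

    def test_correlated_and_down_is_retained(self):
        norm = self._norm()
        de = pd.DataFrame({"direction": ["down", "down"]}, index=["partner", "indep"])
        out = guilt_by_association(norm, "target", de)
        assert out.at["partner", "retained"]
        assert out.at["partner", "spearman_rho"] > 0.9

    def test_sign_inconsistent_excluded(self):
        norm = self._norm()
        de = pd.DataFrame({"direction": ["up"]}, index=["partner"])
        out = guilt_by_association(norm, "target", de)
        assert not out.at["partner", "retained"]

    def test_null_retention_is_rare(self):
        rng = np.random.default_rng(12)
        n_cells = 150
        mat = rng.gamma(2, 1, size=(101, n_cells))
        norm = pd.DataFrame(mat, index=["target"] + [f"g{i}" for i in range(100)])
        de = pd.DataFrame({"direction": ["down"] * 100},
                          index=[f"g{i}" for i in range(100)])
        out = guilt_by_association(norm, "target", de)
        assert out["retained"].mean() < 0.15

    def test_rare_target_rejected(self):
        norm = pd.DataFrame(np.zeros((2, 50)), index=["target", "g"])
        de = pd.DataFrame({"direction": ["down"]}, index=["g"])
        with pytest.raises(ValueError, match="target"):
            guilt_by_association(norm, "target", de)
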