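import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from burstlnc.containers import TwoStateKinetics, ValidationError
from burstlnc.synth import (
    generate_allelic_dataset,
    generate_cell_cycle_dataset,
    generate_cis_pairs,
    generate_decay_timecourse,
    sample_beta_poisson,
)


class TestBetaPoissonSampler:
    def test_vanishing_synthesis_rate_gives_all_zeros(self):
        counts = sample_beta_poisson(TwoStateKinetics(1.0, 1.0, 1e-12), 1000, seed=0)
        assert np.all(counts == 0)

    def test_sample_mean_matches_closed_form(self):
        kin = TwoStateKinetics(1.0, 9.0, 100.0)
        n = 50_000
        x = sample_beta_poisson(kin, n, seed=1)
        se = x.std(ddof=1) / math.sqrt(n)
        assert abs(x.mean() - 10.0) < 3 * se

    def test_zero_fraction_matches_integral(self):
        # P(0) = int_0^1 e^-p dp = 1 - e^-1 for k_on = k_off = k_syn = 1
        n = 50_000
        x = sample_beta_poisson(TwoStateKinetics(1.0, 1.0, 1.0), n, seed=2)
        p0 = 1.0 - math.exp(-1.0)
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(np.mean(x == 0) - p0) < 3 * se

    def test_sample_variance_matches_closed_form(self):
        kin = TwoStateKinetics(0.5, 5.0, 50.0)
        n = 50_000
        x = sample_beta_poisson(kin, n, seed=3)
        mean = kin.mean
        s = kin.k_on + kin.k_off
        var = mean + kin.k_syn**2 * kin.k_on * kin.k_off / (s**2 * (s + 1.0))
        # SE of the sample variance via the fourth moment
        m4 = np.mean((x - x.mean()) ** 4)
        se = math.sqrt((m4 - x.var(ddof=1) ** 2) / n)
        assert abs(x.var(ddof=1) - var) < 3 * se

    def test_deterministic_under_seed(self):
        kin = TwoStateKinetics(1.0, 1.0, 10.0)
        assert np.array_equal(
            sample_beta_poisson(kin, 100, seed=7), sample_beta_poisson(kin, 100, seed=7)
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            sample_beta_poisson((0.0, 1.0, 1.0), 10)
        with pytest.raises(ValueError):
            sample_beta_poisson(TwoStateKinetics(1, 1, 1), 0)


class TestAllelicDataset:
    def test_full_snp_capture_leaves_nothing_missing(self):
        cs, _, _ = generate_allelic_dataset(n_mrna=20, n_lnc=20, n_cells=30,
                                            snp_capture_prob=1.0, seed=0)
        assert not cs.missing_mask.to_numpy().any()
        # with every molecule captured, allelic reads sum to totals
        assert ((cs.cast_reads + cs.c57_reads) == cs.totals).all().all()

    def test_zero_snp_capture_makes_every_expressed_entry_missing(self):
        cs, _, _ = generate_allelic_dataset(n_mrna=20, n_lnc=20, n_cells=30,
                                            snp_capture_prob=0.0, seed=0)
        expressed = cs.totals > 0
        assert (cs.missing_mask == expressed).all().all()

    def test_class_median_shifts_match_construction(self):
        _, _, truth = generate_allelic_dataset(n_mrna=200, n_lnc=200, n_cells=5, seed=11)
        k = truth.kinetics
        med = k.groupby("class_label").apply(
            lambda d: pd.Series({
                "k_on": d["k_on"].median(),
                "size": (d["k_syn"] / d["k_off"]).median(),
            }), include_groups=False,
        )
        freq_ratio = med.at["mRNA-like", "k_on"] / med.at["lncRNA-like", "k_on"]
        size_ratio = med.at["mRNA-like", "size"] / med.at["lncRNA-like", "size"]
        assert freq_ratio == pytest.approx(4.0, rel=0.25)
        assert size_ratio == pytest.approx(2.0, rel=0.25)

    def test_every_gene_allele_has_one_truth_record(self):
        cs, gt, truth = generate_allelic_dataset(n_mrna=5, n_lnc=5, n_cells=10, seed=1)
        assert len(truth.kinetics) == 2 * len(cs.genes)
        assert not truth.kinetics.duplicated(["gene_id", "allele"]).any()

    def test_deterministic_under_seed(self):
        a = generate_allelic_dataset(n_mrna=10, n_lnc=10, n_cells=20, seed=9)
        b = generate_allelic_dataset(n_mrna=10, n_lnc=10, n_cells=20, seed=9)
        pd.testing.assert_frame_equal(a[0].totals, b[0].totals)
        pd.testing.assert_frame_equal(a[2].kinetics, b[2].kinetics)


class TestCisPairs:
    def test_rho_one_shares_latent_state_exactly(self):
        kin = TwoStateKinetics(1.0, 5.0, 30.0)
        _, _, latent = generate_cis_pairs(3, 1.0, kin, 100, seed=0,
                                          mrna_kinetics=kin, return_latent=True)
        for allele in ("CAST", "C57"):
            for i in range(3):
                np.testing.assert_allclose(
                    latent[allele].loc[f"lnc{i:04d}"],
                    latent[allele].loc[f"mRNA{i:04d}"],
                )

    def test_rho_zero_pairs_are_independent(self):
        kin = TwoStateKinetics(0.5, 5.0, 10.0)
        counts, _ = generate_cis_pairs(30, 0.0, kin, 300, seed=1, mrna_kinetics=kin)
        ps = []
        for i in range(30):
            l_on = counts["CAST"].loc[f"lnc{i:04d}"].to_numpy() > 0
            m_on = counts["CAST"].loc[f"mRNA{i:04d}"].to_numpy() > 0
            tab = pd.crosstab(l_on, m_on)
            if tab.shape == (2, 2):
                ps.append(chi2_contingency(tab).pvalue)
        # under independence, p-values are roughly uniform
        assert 0.25 < np.mean(ps) < 0.75

    def test_coordination_gives_positive_odds_ratios(self):
        kin = TwoStateKinetics(0.7, 6.0, 40.0)
        counts, _ = generate_cis_pairs(40, 0.6, kin, 400, seed=2)
        positive = 0
        for i in range(40):
            l_on = counts["CAST"].loc[f"lnc{i:04d}"].to_numpy() > 0
            m_on = counts["CAST"].loc[f"mRNA{i:04d}"].to_numpy() > 0
            a = np.sum(l_on & m_on) + 0.5
            b = np.sum(l_on & ~m_on) + 0.5
            c = np.sum(~l_on & m_on) + 0.5
            d = np.sum(~l_on & ~m_on) + 0.5
            positive += (a * d) / (b * c) > 1.0
        assert positive >= 0.95 * 40

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            generate_cis_pairs(1, 1.5, TwoStateKinetics(1, 1, 1), 10)


class TestDecayTimecourse:
    def test_noiseless_evaluation(self):
        expr, _, _ = generate_decay_timecourse({"g": 0.2}, (0, 2, 4, 7, 10))
        assert expr.at["g", "t10_r0"] == pytest.approx(math.exp(-2.0))

    def test_scale_distortion_multiplies_one_timepoint(self):
        rates = {"a": 0.1, "b": 0.5}
        clean, _, _ = generate_decay_timecourse(rates, (0, 2, 4, 7, 10))
        warped, _, _ = generate_decay_timecourse(rates, (0, 2, 4, 7, 10),
                                                 scale_distortion={4.0: 2.0})
        np.testing.assert_allclose(warped["t4_r0"], 2.0 * clean["t4_r0"])
        np.testing.assert_allclose(warped["t7_r0"], clean["t7_r0"])

    def test_control_half_lives_inside_window(self):
        rng = np.random.default_rng(0)
        rates = pd.Series(rng.uniform(0.05, 1.5, 50),
                          index=[f"g{i}" for i in range(50)])
        _, controls, _ = generate_decay_timecourse(rates, (0, 2, 4, 7, 10))
        assert ((controls["half_life"] > 1.0) & (controls["half_life"] < 8.0)).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            generate_decay_timecourse({"g": 0.1}, (-1, 0, 2))


class TestCellCycleDataset:
    def test_marker_means_peak_in_their_phase(self):
        counts, truth = generate_cell_cycle_dataset(n_cells=400, seed=0)
        g2m_cells = truth.phases.index[truth.phases == "G2/M"]
        sub = counts.loc[:, g2m_cells]
        marker_means = {
            prefix: sub.loc[[g for g in counts.index if g.startswith(prefix)]].mean().mean()
            for prefix in ("Gas1_like", "Ccnd1_like", "Ccne2_like", "Ccnb1_like")
        }
        assert max(marker_means, key=marker_means.get) == "Ccnb1_like"

    def test_phase_proportions_respected(self):
        props = {"G0": 0.4, "G1": 0.3, "G1/S": 0.15, "G2/M": 0.15}
        _, truth = generate_cell_cycle_dataset(n_cells=2000, seed=1,
                                               phase_proportions=props)
        obs = truth.phases.value_counts(normalize=True)
        for phase, frac in props.items():
            assert obs[phase] == pytest.approx(frac, abs=0.05)

    def test_deterministic_phases(self):
        _, t1 = generate_cell_cycle_dataset(n_cells=100, seed=3)
        _, t2 = generate_cell_cycle_dataset(n_cells=100, seed=3)
        assert t1.phases.equals(t2.phases)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            generate_cell_cycle_dataset(n_cells=10, markers_per_phase=0)
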