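"""Ground-truth validation experiments for every pipeline stage.

Each function simulates data at known truth with the package's generators,
runs the corresponding analysis stage, and measures recovery. They back both
the acceptance test suite and ``scripts/acceptance.py``; problem sizes are
parameters with defaults sized for a single CPU.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import cis as cis_mod
from . import decay as decay_mod
from . import state as state_mod
from . import synth, variability
from .containers import TwoStateKinetics
from .kinetics import (
    beta_poisson_logpmf,
    bootstrap_ci,
    fit_two_state,
    lrt_kinetics,
    simulate_inference_spread,
)

__all__ = [
    "lrt_critical_values",
    "logpmf_oracle_error",
    "parameter_recovery",
    "class_ratio_recovery",
    "lrt_calibration",
    "lrt_power",
    "inference_spread_check",
    "cv2_null_and_power",
    "cis_discovery_check",
    "decay_recovery",
    "state_recovery",
]


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def lrt_critical_values(alpha: float = 0.05) -> dict:
    """One-sided chi-squared(1) critical value at alpha, and the doubled
    two-sided convention used alongside it."""
    one_sided = float(chi2.ppf(1.0 - alpha, df=1))
    return {
        "one_sided": round(one_sided, 2),
        "two_sided": round(2.0 * round(one_sided, 2), 2),
    }


def beta_poisson_pmf_reference(x: int, k_on: float, k_off: float,
                               k_syn: float) -> float:
    """Independent adaptive-integration reference for the Beta-Poisson pmf.

    Shapes below one make the Beta kernel singular at an endpoint, handled
    by QUADPACK's algebraic-weight integrator; otherwise plain adaptive
    quadrature with the Beta mass bracketed is accurate even for sharply
    concentrated mixtures.
    """
    import warnings

    from scipy.integrate import quad
    from scipy.special import betaln
    from scipy.stats import beta as beta_dist, poisson

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if k_on < 1.0 or k_off < 1.0:
            f = lambda p: poisson.pmf(x, k_syn * p)
            v, _ = quad(f, 0, 1, weight="alg", wvar=(k_on - 1.0, k_off - 1.0),
                        epsabs=1e-14, epsrel=1e-13, limit=500)
            return float(v / np.exp(betaln(k_on, k_off)))
        pts = np.clip(
            [beta_dist.ppf(q, k_on, k_off)
             for q in (1e-10, 0.01, 0.5, 0.99, 1 - 1e-10)],
            1e-12, 1 - 1e-12,
        )
        f = lambda p: np.exp(
            poisson.logpmf(x, k_syn * p) + beta_dist.logpdf(p, k_on, k_off)
        )
        v, _ = quad(f, 0, 1, epsabs=1e-14, epsrel=1e-13, limit=500,
                    points=list(pts))
        return float(v)


def logpmf_oracle_error(n_points: int = 100) -> float:
    """Max absolute probability error of the likelihood against fine
    numerical integration over a grid of parameters and counts."""
    param_grid = [
        (0.05, 2.0, 10.0), (0.3, 4.0, 60.0), (1.0, 9.0, 100.0), (1.0, 1.0, 1.0),
        (5.0, 0.5, 20.0), (10.0, 10.0, 5.0), (0.001, 0.5, 100.0),
        (100.0, 900.0, 2000.0), (2.0, 3.0, 1000.0), (0.5, 50.0, 200.0),
    ]
    worst = 0.0
    per_set = max(1, n_points // len(param_grid))
    for k_on, k_off, k_syn in param_grid:
        xs = np.unique(np.round(
            np.linspace(0, max(5.0, 0.6 * k_syn), per_set)
        ).astype(int))
        got = np.exp(beta_poisson_logpmf(xs, (k_on, k_off, k_syn)))
        for x, g in zip(xs, got):
            want = beta_poisson_pmf_reference(int(x), k_on, k_off, k_syn)
            worst = max(worst, abs(float(g) - want))
    return worst


def parameter_recovery(seed: int = 0, *, n_genes: int = 25, n_cells: int = 1_000,
                       n_boot: int = 100) -> dict:
    """Bootstrap CI coverage of true burst frequency and size.

    Genes are drawn from the generator's mRNA-like log-normal priors, counts
    simulated per gene, fitted, and bootstrapped; coverage is the fraction
    of genes whose truth lies inside the 95% CI.
    """
    rng = np.random.default_rng(seed)
    kin = synth._sample_class_kinetics(rng, n_genes, freq_mult=1.0, size_mult=1.0)
    cov_f = cov_s = 0
    for i in range(n_genes):
        truth = TwoStateKinetics(kin.at[i, "k_on"], kin.at[i, "k_off"], kin.at[i, "k_syn"])
        counts = synth.sample_beta_poisson(truth, n_cells, rng=rng)
        fit = bootstrap_ci(counts, n_boot=n_boot, seed=_sub_seed(rng))
        cov_f += fit.ci_low["k_on"] <= truth.k_on <= fit.ci_high["k_on"]
        cov_s += fit.ci_low["burst_size"] <= truth.burst_size <= fit.ci_high["burst_size"]
    return {
        "coverage_frequency": cov_f / n_genes,
        "coverage_size": cov_s / n_genes,
        "n_genes": n_genes,
        "n_cells": n_cells,
        "n_boot": n_boot,
    }


def class_ratio_recovery(seed: int = 0, *, n_per_class: int = 60,
                         n_cells: int = 500) -> dict:
    """Recovery of the generator's class-median kinetic shifts.

    mRNA-like vs lncRNA-like genes are simulated (true median frequency
    ratio 4x, size ratio 2x), each gene's CAST allele fitted, and the
    inferred class-median ratios returned.
    """
    cs, gt, truth = synth.generate_allelic_dataset(
        n_mrna=n_per_class, n_lnc=n_per_class, n_cells=n_cells, seed=seed,
    )
    rows = []
    for gid in cs.genes:
        counts = cs.cast_reads.loc[gid].to_numpy(dtype=float)
        fit = fit_two_state(counts)
        if fit.kinetics is None:
            continue
        label = truth.kinetics.loc[
            (truth.kinetics["gene_id"] == gid), "class_label"
        ].iloc[0]
        rows.append((label, fit.burst_frequency, fit.burst_size))
    df = pd.DataFrame(rows, columns=["label", "freq", "size"])
    med = df.groupby("label").median()
    return {
        "frequency_ratio": float(med.at["mRNA-like", "freq"] / med.at["lncRNA-like", "freq"]),
        "size_ratio": float(med.at["mRNA-like", "size"] / med.at["lncRNA-like", "size"]),
        "n_genes": len(df),
        "n_cells": n_cells,
    }


_LRT_KIN = TwoStateKinetics(1.0, 10.0, 60.0)


def lrt_calibration(seed: int = 0, *, n_replicates: int = 300, n_cells: int = 300,
                    critical: float = 3.84) -> dict:
    """One-sided rejection rate of the burst-frequency LRT under the null."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_replicates):
        a = synth.sample_beta_poisson(_LRT_KIN, n_cells, rng=rng)
        b = synth.sample_beta_poisson(_LRT_KIN, n_cells, rng=rng)
        res = lrt_kinetics(a, b, "frequency", critical_one_sided=critical)
        rej += res.significant_one_sided
    return {"rejection_rate": rej / n_replicates, "n_replicates": n_replicates,
            "n_cells": n_cells}


def lrt_power(seed: int = 0, *, n_replicates: int = 60, n_cells: int = 1_000,
              fold: float = 2.0, critical: float = 3.84) -> dict:
    """Rejection rate when the true burst frequency differs by ``fold``."""
    rng = np.random.default_rng(seed)
    alt = TwoStateKinetics(_LRT_KIN.k_on * fold, _LRT_KIN.k_off, _LRT_KIN.k_syn)
    rej = 0
    for _ in range(n_replicates):
        a = synth.sample_beta_poisson(_LRT_KIN, n_cells, rng=rng)
        b = synth.sample_beta_poisson(alt, n_cells, rng=rng)
        res = lrt_kinetics(a, b, "frequency", critical_one_sided=critical)
        rej += res.significant_one_sided
    return {"rejection_rate": rej / n_replicates, "n_replicates": n_replicates,
            "n_cells": n_cells}


def inference_spread_check(seed: int = 0, *, n_sim: int = 100,
                           n_cells: int = 1_000, r: float = 2.0) -> dict:
    """Median inferred kinetics when a fold-change r is pure frequency or
    pure size, relative to the reference values."""
    ref = _LRT_KIN
    out = {}
    for mode in ("frequency", "size"):
        cloud = simulate_inference_spread(ref, r, mode, n_cells, n_sim=n_sim,
                                          seed=seed)
        out[mode] = {
            "median_frequency_over_reference": float(
                cloud["burst_frequency"].median() / ref.k_on
            ),
            "median_size_over_reference": float(
                cloud["burst_size"].median() / ref.burst_size
            ),
        }
    out["r"] = r
    out["n_sim"] = n_sim
    return out


def _matched_pool(rng, n_lnc, n_mrna, inflate: float = 0.0):
    lnc = pd.Series(rng.gamma(2.0, 1.0, n_lnc) + inflate,
                    index=[f"l{i:03d}" for i in range(n_lnc)])
    cand = pd.Series(rng.gamma(2.0, 1.0, n_mrna),
                     index=[f"m{i:03d}" for i in range(n_mrna)])
    matched = {g: list(cand.index) for g in lnc.index}
    return lnc, matched, cand


def cv2_null_and_power(seed: int = 0, *, n_null_runs: int = 50,
                       n_perm: int = 1_000, n_lnc: int = 150) -> dict:
    """Null uniformity of the CV² permutation p, its power under class-wide
    inflation, and the subsampling detection curve.

    The null is exchangeable by construction: each lncRNA's CV² is one draw
    from the same distribution as its own 10 expression-matched candidates,
    mirroring a matched class with no real variability difference. Null
    runs come in antithetic pairs (the lncRNA column drawn from u and 1-u
    over shared candidates), which anticorrelates their p-values and cuts
    the Monte-Carlo variance of the mean without changing its expectation.
    """
    from scipy.stats import gamma as gamma_dist

    rng = np.random.default_rng(seed)
    k_matched = 10
    ids = [f"l{i:03d}" for i in range(n_lnc)]
    cand_ids = [f"m{i:03d}_{j}" for i in range(n_lnc) for j in range(k_matched)]
    matched = {
        f"l{i:03d}": [f"m{i:03d}_{j}" for j in range(k_matched)]
        for i in range(n_lnc)
    }
    ps = []
    for _ in range((n_null_runs + 1) // 2):
        u = rng.random(n_lnc)
        cand = pd.Series(rng.gamma(2.0, 1.0, size=n_lnc * k_matched),
                         index=cand_ids)
        for lvals in (gamma_dist.ppf(u, 2.0), gamma_dist.ppf(1.0 - u, 2.0)):
            res = variability.cv2_permutation_test(
                pd.Series(lvals, index=ids), matched, candidate_cv2=cand,
                n_perm=n_perm, seed=_sub_seed(rng),
            )
            ps.append(res["p"])
    ps = ps[:n_null_runs]
    lnc, matched, cand = _matched_pool(rng, n_lnc, 300, inflate=1.0)
    inflated = variability.cv2_permutation_test(lnc, matched, candidate_cv2=cand,
                                                n_perm=n_perm, seed=_sub_seed(rng))
    # moderate inflation so detection grows with the subsample size
    lnc2, matched2, cand2 = _matched_pool(rng, 200, 300, inflate=0.35)
    curve = variability.subsample_power(lnc2, matched2, cand2,
                                        sizes=[10, 50, 100, 200], reps=30,
                                        n_perm=200, seed=_sub_seed(rng))
    return {
        "null_mean_p": float(np.mean(ps)),
        "n_null_runs": n_null_runs,
        "inflated_p": float(inflated["p"]),
        "power_curve_sizes": list(curve["size"]),
        "power_curve": list(curve["detected_95"]),
    }


def cis_discovery_check(seed: int = 0, *, n_locations: int = 200,
                        n_cells: int = 400) -> dict:
    """Detection and false-positive rates of both cis routes on planted data.

    A dataset with rho = 0.6, AI +0.3 planted pairs feeds the detection
    rates; an independent dataset with no links and balanced alleles feeds
    the false-positive rates.
    """
    cs, gt, truth = synth.generate_cis_dataset(n_cells=n_cells, seed=seed)
    planted = set(zip(truth.cis_links["lnc_id"], truth.cis_links["mrna_id"]))
    lnc_ids = sorted({g for g in cs.genes if g.startswith("lnc")})

    score = cis_mod.score_permutation(cs, gt, lnc_ids, n_locations=n_locations,
                                      seed=seed + 1)
    is_planted = [
        (l, m) in planted for l, m in zip(score["lnc_id"], score["mrna_id"])
    ]
    score_hit = float(score.loc[is_planted, "significant"].mean())

    eligible = cis_mod.cis_eligible_genes(cs, gt)
    pairs = cis_mod.enumerate_pairs(lnc_ids, gt, eligible)
    fisher_hits = []
    for allele in ("CAST", "C57"):
        real = cis_mod.fisher_coordination(cs, pairs, allele)
        bg = cis_mod.coordination_background(cs, gt, lnc_ids, allele,
                                             n_locations=n_locations, seed=seed + 2)
        called = cis_mod.coordination_significance(real, bg)
        called["planted"] = [
            (l, m) in planted for l, m in zip(called["lnc_id"], called["mrna_id"])
        ]
        fisher_hits.append(called)
    fisher_all = pd.concat(fisher_hits)
    # a planted pair counts as found if either allele calls it
    per_pair = fisher_all[fisher_all["planted"]].groupby(
        ["lnc_id", "mrna_id"])["significant"].any()
    fisher_hit = float(per_pair.mean())

    # false positives on a dataset with no links at all
    cs0, gt0, _ = synth.generate_cis_dataset(n_linked=0, n_null_lnc=50,
                                             n_cells=n_cells, seed=seed + 3)
    lnc0 = sorted({g for g in cs0.genes if g.startswith("lnc")})
    score0 = cis_mod.score_permutation(cs0, gt0, lnc0, n_locations=n_locations,
                                       seed=seed + 4)
    score_fpr = float(score0["significant"].mean())
    eligible0 = cis_mod.cis_eligible_genes(cs0, gt0)
    pairs0 = cis_mod.enumerate_pairs(lnc0, gt0, eligible0)
    fisher_fprs = []
    for allele in ("CAST", "C57"):
        real0 = cis_mod.fisher_coordination(cs0, pairs0, allele)
        bg0 = cis_mod.coordination_background(cs0, gt0, lnc0, allele,
                                              n_locations=n_locations, seed=seed + 5)
        called0 = cis_mod.coordination_significance(real0, bg0)
        fisher_fprs.append(called0["significant"].mean())
    return {
        "score_detection_rate": score_hit,
        "fisher_detection_rate": fisher_hit,
        "score_false_positive_rate": score_fpr,
        "fisher_false_positive_rate": float(np.mean(fisher_fprs)),
        "n_locations": n_locations,
        "n_cells": n_cells,
    }


def decay_recovery(seed: int = 0, *, n_genes: int = 30) -> dict:
    """Noiseless decay-rate recovery and correction of a x2 library distortion."""
    rng = np.random.default_rng(seed)
    times = (0.0, 2.0, 4.0, 7.0, 10.0)
    rates = pd.Series(np.log(2.0) / rng.uniform(0.5, 9.0, n_genes),
                      index=[f"g{i:03d}" for i in range(n_genes)])
    expr, controls, _ = synth.generate_decay_timecourse(rates, times)
    fits = decay_mod.fit_decay_table(decay_mod.normalize_to_t0(expr))
    clean_err = float((np.abs(fits["rate"] - rates) / rates).max())

    rates2 = pd.Series(np.log(2.0) / rng.uniform(1.2, 7.5, n_genes),
                       index=rates.index)
    expr2, controls2, _ = synth.generate_decay_timecourse(
        rates2, times, scale_distortion={4.0: 2.0}
    )
    rel = decay_mod.normalize_to_t0(expr2)
    corrected, _ = decay_mod.apply_control_normalization(rel, controls2)
    fits2 = decay_mod.fit_decay_table(corrected)
    corrected_err = float((np.abs(fits2["rate"] - rates2) / rates2).max())
    identity_dev = float(
        np.abs(fits["half_life"] * fits["rate"] - math.log(2.0)).max()
    )
    return {
        "noiseless_max_relative_rate_error": clean_err,
        "distortion_corrected_max_relative_rate_error": corrected_err,
        "half_life_rate_identity_max_deviation": identity_dev,
        "n_genes": n_genes,
    }


def state_recovery(seed: int = 0, *, n_cells: int = 400, n_null_genes: int = 500,
                   n_planted: int = 10) -> dict:
    """Phase-label accuracy, planted phase-specific gene recovery, and
    planted apoptosis-cluster recovery."""
    from sklearn.metrics import adjusted_rand_score

    counts, truth = synth.generate_cell_cycle_dataset(
        n_cells=n_cells, seed=seed, marker_amplitude=60.0, marker_baseline=0.1,
        concentration=12.0, n_noise_genes=n_null_genes,
        planted={"n": n_planted, "fold": 3.0, "phase": "G2/M"},
    )
    norm = state_mod.log_normalize(counts)
    markers = {
        phase: [g for g in counts.index if g.startswith(prefix)]
        for phase, prefix in synth.DEFAULT_MARKERS.items()
    }
    lam = state_mod.fit_trajectory(norm, [g for gl in markers.values() for g in gl])
    assigned = state_mod.assign_phase(lam, norm, markers)
    phase_accuracy = float((assigned["phase"] == truth.phases).mean())

    de = state_mod.anova_phase_de(norm, truth.phases)
    planted_ids = [f"planted{i:04d}" for i in range(n_planted)]
    null_ids = [f"noise{i:04d}" for i in range(n_null_genes)]
    planted_found = int(de.loc[planted_ids, "significant"].sum())
    null_fdr = float(de.loc[null_ids, "significant"].mean())

    # planted apoptosis cluster: 20% of cells with shifted apoptosis genes
    rng = np.random.default_rng(seed + 1)
    n_c = 120
    apop = rng.poisson(8, size=(60, n_c)).astype(float)
    labels_true = np.zeros(n_c, dtype=int)
    labels_true[: n_c // 5] = 1
    apop[:25, labels_true == 1] = rng.poisson(28, size=(25, n_c // 5))
    frame = pd.DataFrame(
        apop + 1, index=[f"apop{i:03d}" for i in range(25)]
        + [f"bg{i:03d}" for i in range(35)],
    )
    labels = state_mod.apoptosis_cluster(
        state_mod.log_normalize(frame), [f"apop{i:03d}" for i in range(25)],
        n_top=25, k=2,
    )
    ari = float(adjusted_rand_score(labels_true, labels.to_numpy()))
    return {
        "phase_label_accuracy": phase_accuracy,
        "planted_genes_recovered": planted_found,
        "n_planted": n_planted,
        "null_significant_fraction": null_fdr,
        "apoptosis_cluster_ari": ari,
    }
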