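"""Reproducibility experiments behind the acceptance script and the
acceptance test suite.

Each function recomputes one headline quantity from scratch by running the
package: exact statistics on published group-count tables, analytic score
identities, oracle agreement of the GLM fitter, and Monte-Carlo properties
of the full scan → screen → profile pipeline on synthetic cohorts
(type-I calibration, causal-block recovery, discovery/validation optimism,
Hosmer-Lemeshow calibration).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .assoc_scan import genomic_inflation, scan_both_models, scan_markers, stage1_filter
from .clinical_eval import pearson_chi2
from .glm_core import fit_logistic
from .independence import ScreenConfig, run_screen
from .risk_profile import (
    RiskModel,
    apply_to_cohort,
    hosmer_lemeshow,
    score,
    stepwise_select,
)
from .synthio import DiseaseModelSpec, LdBlockSpec, simulate_cohort

# Published genetic-load group counts (high / medium / low / misclassified)
# used for the exact contingency statistics: carrier-status rows and
# gender rows of the clinical-characteristics table.
DRB1_BY_LOAD_GROUP = np.array([[242, 146, 51, 31], [141, 167, 91, 99]])
GENDER_BY_LOAD_GROUP = np.array([[285, 206, 85, 68], [98, 107, 57, 62]])


def load_group_chi2() -> dict:
    """Pearson chi-squares on the published load-group tables, plus the
    carrier share of the high-load group."""
    drb1 = pearson_chi2(DRB1_BY_LOAD_GROUP)
    gender = pearson_chi2(GENDER_BY_LOAD_GROUP)
    high_pct = float(drb1.group_summaries["percent"].iloc[0])
    return {
        "drb1_chi2": drb1.statistic,
        "gender_chi2": gender.statistic,
        "high_load_drb1_pos_pct": high_pct,
        "df": drb1.df,
    }


def phat_at_zero_linear_predictor() -> float:
    """Score a profile arranged so the linear predictor is exactly 0."""
    import pandas as pd

    from .cohort import Cohort

    model = RiskModel(
        marker_ids=["m"],
        marker_betas=np.array([0.5]),
        covariate_betas={},
        intercept=-1.0,
        center_levels=["A"],
    )
    dosages = pd.DataFrame({"m": [2.0]}, index=pd.Index(["S0"], name="sample_id"))
    samples = pd.DataFrame(
        {"sample_id": ["S0"], "status": [1], "center": ["A"],
         "gender": ["F"], "drb1_status": [0]}
    )
    markers = pd.DataFrame(
        {"id": ["m"], "chrom": [1], "pos": [1], "allele1": ["A"], "allele2": ["G"]}
    )
    sc = score(model, Cohort(dosages, samples, markers))
    return float(sc["p_hat"].iloc[0])


def glm_oracle_gap(seed: int, n_problems: int = 8) -> float:
    """Worst coefficient gap between the IRLS fitter and a direct
    likelihood maximiser (BFGS on the exact binomial log-likelihood)
    over random 1-3 predictor problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_problems):
        p = 1 + i % 3
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta_true = np.r_[0.3, rng.normal(scale=0.6, size=p)]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        fit = fit_logistic(X, y)

        def nll(b):
            eta = X @ b
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        res = minimize(
            nll, np.zeros(X.shape[1]),
            jac=lambda b: X.T @ (1 / (1 + np.exp(-(X @ b))) - y),
            method="BFGS", options={"gtol": 1e-12, "maxiter": 500},
        )
        worst = max(worst, float(np.max(np.abs(fit.coefficients - res.x))))
    return worst


def null_scan_calibration(
    seed: int, n_samples: int = 2000, n_markers: int = 10_000
) -> dict:
    """Scan a null cohort: p < 0.001 hit rate and genomic inflation."""
    blocks = LdBlockSpec(
        n_markers_per_block=5,
        n_blocks=n_markers // 5,
        within_block_r=0.0,
        maf_range=(0.1, 0.5),
    )
    disease = DiseaseModelSpec(
        intercept=-1.0, major_locus_or=1.0, n_causal=0, gender_or=1.0,
        center_effects={"A": 0.0}, imputation_quality=1.0,
    )
    cohort = simulate_cohort(
        blocks, disease, n_samples=n_samples, seed=seed, include_tag=False
    )
    res = scan_markers(cohort, "base")
    p = res["p_value"].to_numpy()
    return {
        "hit_rate": float((p < 0.001).mean()),
        "hit_rate_pct": float(100.0 * (p < 0.001).mean()),
        "inflation_lambda": genomic_inflation(p),
        "n_markers": int(p.size),
    }


def _recovery_cohort(seed: int):
    blocks = LdBlockSpec(
        n_markers_per_block=10, n_blocks=40, within_block_r=0.9,
        maf_range=(0.15, 0.45),
    )
    disease = DiseaseModelSpec(
        intercept=-1.2, major_locus_or=1.0, n_causal=20,
        causal_or_range=(1.3, 1.8), gender_or=1.0,
        center_effects={"A": 0.0}, imputation_quality=0.97,
        protective_fraction=0.5,
    )
    return simulate_cohort(
        blocks, disease, n_cases=2000, n_controls=2000, seed=seed,
        include_tag=False, oversample=3.0,
    )


def block_recovery_experiment(seed: int, reps: int = 20) -> dict:
    """Scan → screen → stepwise on cohorts with 20 causal blocks hidden
    among LD proxies; measures causal-block recovery and per-block
    multiplicity of the selected profile."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(reps)]
    recovered, single_rep = [], []
    for s in child_seeds:
        cohort = _recovery_cohort(s)
        scan = scan_both_models(cohort, 0.001)
        cand = stage1_filter(scan.results, 0.001)
        state = run_screen(
            cohort, cand, ScreenConfig(condition_on_drb1=False)
        )
        model = stepwise_select(cohort, state.accepted, 0.05, 0.05)
        blocks_of = cohort.markers.set_index("id")["block"]
        causal_blocks = {blocks_of[m] for m in cohort.truth.causal_marker_ids}
        sel_blocks = [blocks_of[m] for m in model.marker_ids]
        causal_sel = [b for b in sel_blocks if b in causal_blocks]
        recovered.append(len(set(causal_sel)) / len(causal_blocks))
        single_rep.append(len(causal_sel) == len(set(causal_sel)))
    return {
        "mean_block_recovery": float(np.mean(recovered)),
        "mean_block_recovery_pct": float(100 * np.mean(recovered)),
        "single_rep_fraction": float(np.mean(single_rep)),
        "reps": reps,
    }


def optimism_experiment(seed: int, reps: int = 20) -> dict:
    """Train a profile on one cohort, evaluate on an independent cohort
    drawn from the same generative model; measures how often the
    discovery AUC exceeds the validation AUC (fitting optimism)."""
    blocks = LdBlockSpec(
        n_markers_per_block=5, n_blocks=30, within_block_r=0.0,
        maf_range=(0.2, 0.5),
    )
    disease = DiseaseModelSpec(
        intercept=-0.8, major_locus_or=1.0, n_causal=10,
        causal_or_range=(1.15, 1.35), gender_or=1.0,
        center_effects={"A": 0.0}, imputation_quality=1.0,
    )
    ss = np.random.SeedSequence(seed + 1)
    wins = 0
    gaps = []
    for pair in ss.spawn(reps):
        s1, s2 = [int(x.generate_state(1)[0] % 2**31) for x in pair.spawn(2)]
        train = simulate_cohort(blocks, disease, n_samples=1200, seed=s1,
                                include_tag=False)
        valid = simulate_cohort(blocks, disease, n_samples=1200, seed=s2,
                                include_tag=False)
        scan = scan_markers(train, "base")
        cand = scan[scan["p_value"] < 0.01]["marker_id"].tolist()
        model = stepwise_select(train, cand, 0.05, 0.05)
        _, s_train = apply_to_cohort(model, train, mode="frozen")
        _, s_valid = apply_to_cohort(model, valid, mode="frozen")
        wins += s_train.auc > s_valid.auc
        gaps.append(s_train.auc - s_valid.auc)
    return {
        "optimism_fraction": wins / reps,
        "optimism_fraction_pct": 100.0 * wins / reps,
        "mean_auc_gap": float(np.mean(gaps)),
        "reps": reps,
    }


def hl_calibration_experiment(seed: int, reps: int = 200, n: int = 1200) -> dict:
    """Type-I calibration of the Hosmer-Lemeshow test under a correctly
    specified fitted logistic model."""
    rng = np.random.default_rng(seed + 2)
    rejects = 0
    for _ in range(reps):
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        eta = X @ np.array([-0.3, 0.8, -0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        p_hat = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        rejects += hosmer_lemeshow(p_hat, y).p_value < 0.05
    return {
        "rejection_rate": rejects / reps,
        "rejection_rate_pct": 100.0 * rejects / reps,
        "reps": reps,
    }
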