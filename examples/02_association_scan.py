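"""Stage I: single-marker association scan under two covariate models.

Scans every marker with center + gender covariates (base model) and again
adding the HLA carrier indicator (conditioned model), then applies the
dual-model P < 0.001 filter and reports the genomic inflation factor.
"""

from cumulrisk import (
    DiseaseModelSpec,
    LdBlockSpec,
    scan_both_models,
    simulate_cohort,
)

blocks = LdBlockSpec(n_markers_per_block=10, n_blocks=50, within_block_r=0.9,
                     maf_range=(0.1, 0.5))
disease = DiseaseModelSpec(intercept=-1.8, n_causal=15,
                           causal_or_range=(1.3, 1.8),
                           center_effects={"EU": -0.2, "US": 0.2})
cohort = simulate_cohort(blocks, disease, n_cases=1000, n_controls=2500, seed=7)

scan = scan_both_models(cohort, p_threshold=0.001)
top = (
    scan.by_model("conditioned")
    .sort_values("p_value")
    .head(5)[["neg_log10_p", "odds_ratio", "lower_cl", "upper_cl"]]
)
print(f"genomic inflation lambda: {scan.inflation_lambda:.3f}")
print(f"markers passing P<0.001 in BOTH models: {scan.n_selected}")
print("\ntop conditioned-model hits (-log10 p, OR with 95% CI):")
print(top.round(3))
# Lambda well above 1 here reflects pervasive *true* signal (many causal
# blocks), not stratification — the covariates absorb the stratum effects.
# The dual-model filter keeps only markers whose signal survives
# conditioning on the major locus, the input set for the screen.
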