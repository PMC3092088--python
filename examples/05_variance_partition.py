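"""Partition explained variance (Nagelkerke R²) over predictor blocks.

Adds predictor blocks in a fixed order — center, gender, the major HLA
locus, then the polygenic markers — and reports each block's increment in
Nagelkerke R², the decomposition used to compare how much of disease
liability each layer of the model accounts for.
"""

from cumulrisk import (
    DiseaseModelSpec,
    LdBlockSpec,
    simulate_cohort,
    variance_partition,
)

blocks = LdBlockSpec(n_markers_per_block=5, n_blocks=30, within_block_r=0.0,
                     maf_range=(0.2, 0.5))
disease = DiseaseModelSpec(intercept=-2.2, major_locus_or=4.0,
                           major_control_freq=0.28, n_causal=12,
                           causal_or_range=(1.3, 1.7), gender_or=3.0,
                           center_effects={"EU": -0.3, "US": 0.4})
cohort = simulate_cohort(blocks, disease, n_cases=1000, n_controls=2500, seed=13)

part = variance_partition(
    cohort,
    [
        ("center", "center"),
        ("gender", "gender"),
        ("major locus", "drb1"),
        ("polygenic markers", cohort.truth.causal_marker_ids),
    ],
)
print(part.round(4).to_string(index=False))
total = part["r2_cumulative"].iloc[-1]
print(f"\nfull-model Nagelkerke R2: {total:.3f} "
      "(increments telescope exactly to this total)")
# Each row shows how much liability variance that block explains beyond
# the blocks entered before it; ordering matters, exactly as in a
# sequential analysis of deviance.
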