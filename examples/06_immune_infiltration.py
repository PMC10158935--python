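"""Correlate lncRNA expression with immune-cell infiltration scores.

Infiltration estimates are defined for tumor samples; the generator plants
a chosen correlation ρ between one lncRNA and one cell type.
"""
from cernet import correlate_infiltration, correlation_matrix, generate_cohort
from cernet.synthetic import CohortConfig, PlantedInfiltration

cfg = CohortConfig(
    n_tumor=505, n_normal=58, n_mirna=2, n_mrna=2, n_lncrna=6,
    infiltration=[
        PlantedInfiltration("lnc-0001", "neutrophil", 0.6),
        PlantedInfiltration("lnc-0002", "myeloid dendritic cell", -0.5),
    ],
    seed=6,
)
cohort = generate_cohort(cfg)

long = correlate_infiltration(cohort.lncrna, cohort.infiltration, method="pearson")
mat = correlation_matrix(long)
print("correlation matrix (lncRNA × cell type), planted ρ = +0.6 and −0.5:")
print(mat.round(2).to_string())
hits = long[(long["p_value"] < 0.01) & (long["r"].abs() > 0.3)]
print(f"\n{len(hits)} strong associations (|r| > 0.3, p < 0.01):")
print(hits[["feature_id", "cell_type", "r", "p_value"]].to_string(index=False))
# The two planted pairs stand out; every other combination hovers near the
# null sd ≈ 1/√(n−1) ≈ 0.045 at n = 505.
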