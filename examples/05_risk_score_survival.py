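"""Risk-score prognosis model: RiskScore = Σ_i r_i · Exp_i.

Each gene's weight r_i is its univariate Cox log-hazard coefficient;
patients above the cohort-mean score form the high-risk group, and the two
groups are compared with the log-rank test.
"""
from cernet import fit_risk_model, generate_cohort, risk_group_survival
from cernet.synthetic import CohortConfig, SurvivalConfig

cfg = CohortConfig(
    n_tumor=505, n_normal=58, n_mirna=2, n_mrna=6, n_lncrna=2,
    survival=SurvivalConfig(
        coefficients={"gene-0001": 0.8, "gene-0002": -0.8, "gene-0003": 0.8},
        censoring_rate=0.3,
    ),
    seed=5,
)
cohort = generate_cohort(cfg)

genes = ["gene-0001", "gene-0002", "gene-0003"]
expr = cohort.mrna.values.loc[genes]
model = fit_risk_model(expr, cohort.clinical)

print("univariate Cox coefficients r_i (true values +0.8, −0.8, +0.8):")
for g, r in model.coefficients.items():
    print(f"  {g}: {r:+.3f}")
print(f"mean-score cutoff: {model.cutoff:+.3f}")

comp, high, low = risk_group_survival(model, expr, cohort.clinical)
print(f"\nhigh-risk n={len(high)}, low-risk n={len(low)}")
print(f"log-rank chi² = {comp.chi_square:.1f}, p = {comp.p_value:.3g}")
# p < 0.05 means the risk-score stratification separates survival curves —
# the planted hazard signature is detected.
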