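"""Monte Carlo risk assessment with distribution fitting and convergence.

Generates a survey-like concentration matrix, fits a log-normal to the
sample BaP-equivalent totals (with a Shapiro-Wilk screen of log-normality),
then propagates exposure-parameter and concentration variability through
the ILCR equations and checks iteration convergence.
"""

import numpy as np

from pahrisk import monte_carlo as mc, registry, risk, synthetic

conc = synthetic.generate_from_survey(2000, seed=5)
bapeq_totals = np.array([risk.compute_bapeq(row).sum() for row in conc.values])
mu, sigma, p = mc.fit_lognormal(bapeq_totals)
print(f"BaPeq totals: lognormal fit meanlog={mu:.3f} sdlog={sigma:.3f} "
      f"(Shapiro-Wilk p on logs: {p:.3f})")
# at this sample size the test detects the mild deviation introduced by the
# species multipliers; the log-normal remains the working approximation

specs = mc.default_specs(conc)
result = mc.run_simulation(specs, n_iterations=10_000, seed=11,
                           hq_composition=conc.values.mean(axis=0))
print("TILCR percentiles (5/50/95): "
      + " / ".join(f"{v:.2e}" for v in result.percentiles["tilcr"].loc[[5, 50, 95]]))
print(f"P(TILCR > 1e-6) = {result.exceedance['p_tilcr_gt_1e-6']:.3f}; "
      f"P(TILCR > 1e-4) = {result.exceedance['p_tilcr_gt_1e-4']:.3f}")

stable, table = mc.convergence_check(specs, seed=11)
print(table.to_string(index=False))
print("95th percentile stable at the final iteration counts:", stable)

# Nearly every simulated consumer exceeds the 1e-6 negligible-risk bound,
# while the 1e-4 unacceptable bound is rarely crossed.
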