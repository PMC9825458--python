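"""Derive the five sensitivity scores, with uncertainty, from a fitted curve.

Every posterior draw of (center, slope) yields one value of each score, so
each score comes with a 95% highest-density interval rather than a bare
point estimate.
"""

from curvepool import MCMCConfig, SimScenario, fit_curve, score_posterior, simulate_experiment

data = simulate_experiment(SimScenario(true_a=-1.0, true_k=1.5, seed=3))
chains, summary = fit_curve(data, config=MCMCConfig(master_seed=7))
sc = score_posterior(chains, data.x_min, data.x_max)

print(f"IC50 = {sc.ic50_um:.3f} µM   ({sc.ic50_log2:+.3f} log2 µM, "
      f"HDI [{sc.hdi95_ic50[0]:+.3f}, {sc.hdi95_ic50[1]:+.3f}])")
print(f"IC90 = {sc.ic90_um:.3f} µM   ({sc.ic90_log2:+.3f} log2 µM, "
      f"HDI [{sc.hdi95_ic90[0]:+.3f}, {sc.hdi95_ic90[1]:+.3f}])")
print(f"AUC  = {sc.auc:.3f}        (HDI [{sc.hdi95_auc[0]:.3f}, {sc.hdi95_auc[1]:.3f}])")
print(f"EC50 = {sc.ec50_um:.3f} µM   ({sc.ec50_log2:+.3f} log2 µM)")
print(f"Einf = {sc.einf:.3f}        (fitted response at the top dose)")

# IC50 is the dose halving growth (the curve center); IC90 the dose for 90%
# inhibition, lying log2(9)/k above it; AUC is the mean inhibition over the
# tested window (higher = more sensitive); Einf the response actually reached
# at the highest tested dose; EC50 the dose giving half of Einf.
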