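"""Expression cut-point discovery and survival comparison.

The simulated cohort carries a gene whose hazard quadruples above a planted
40th-percentile threshold.  maxstat scans every admissible cut, picks the
one maximizing the standardized log-rank statistic, and assesses it by
permutation; the two resulting strata are compared by Kaplan-Meier and
log-rank.
"""

import smad4sig as s

ct, truth = s.simulate_cohort(s.CohortSimConfig(n_samples=300, seed=8))
x = ct.expression["SURV1"].to_numpy()
time = ct.survival["time"].to_numpy()
event = ct.survival["event"].to_numpy()

res = s.maxstat_cutpoint(x, time, event, minprop=0.1, n_perm=1000, seed=8)
pct = (x <= res.cutpoint).mean()
print(f"selected cut {res.cutpoint:.1f} (P{100 * pct:.0f} of expression), "
      f"max |z| = {res.max_statistic:.2f}, permutation p = {res.pvalue:.4g}")

low, high = x <= res.cutpoint, x > res.cutpoint
chi2, p = s.logrank_test(time[low], event[low], time[high], event[high])
km_low = s.km_estimate(time[low], event[low])
km_high = s.km_estimate(time[high], event[high])
print(f"log-rank at the cut: chi2 = {chi2:.1f}, p = {p:.3g}")
print(f"median survival low/high: {km_low.times[km_low.survival <= 0.5][0]:.1f} / "
      f"{km_high.times[km_high.survival <= 0.5][0]:.1f}")
# The recovered cut sits near the planted 40th percentile and the high
# group's much shorter median survival reflects the planted hazard ratio.
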