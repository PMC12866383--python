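"""Interval boundaries, one cohort decision, and overdose elimination.

For a target DLT rate of 25% the design escalates while the observed
cohort DLT proportion is at or below lambda_e and de-escalates at or
above lambda_d; 3 DLTs among 5 patients additionally pushes the
beta-binomial posterior Pr(p > 0.25) past the 0.95 elimination cutoff,
removing the level (and everything above it) from the trial.
"""

from scipy import stats

from boindosim import BoinDesign, Decision, DlState, decide, eliminate_check

design = BoinDesign(phi=0.25)
print(f"target DLT rate phi = {design.phi}")
print(f"escalation boundary   lambda_e = {design.lambda_e:.3f}")
print(f"de-escalation boundary lambda_d = {design.lambda_d:.3f}")

cohort = DlState(dl_index=0, n_evaluable=3, n_dlt=0)
print(f"\n0/3 DLTs -> {decide(cohort, design, True, True).value}")

hot = DlState(dl_index=2, n_evaluable=5, n_dlt=3)
decision = decide(hot, design, False, True)
posterior = stats.beta.sf(design.phi, 1 + hot.n_dlt, 1 + hot.n_evaluable - hot.n_dlt)
print(f"3/5 DLTs -> {decision.value}")
print(f"  Pr(p > {design.phi} | Beta(4,3)) = {posterior:.4f} "
      f"(> {design.elim_cutoff}: eliminated = {eliminate_check(5, 3, design.phi)})")
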