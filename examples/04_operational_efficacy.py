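"""Operational-model fitting and expression-corrected efficacy.

Fits functional affinity (pK_A) and efficacy (log tau) to a simulated cAMP
curve, then corrects tau for cell-surface expression measured by FACS:
log tau_c = log tau - log10(expression% / 100).
"""

from ctrpharm import GroundTruth, OperationalParams, PlateLayout
from ctrpharm import correct_tau, fit_operational, predict_ec50, simulate_crc

truth = GroundTruth(
    operational={("hCT", "cAMP"): OperationalParams(pKA=9.54, log_tau=0.18)},
)
curve = simulate_crc(truth, PlateLayout(), seed=5, ligand="hCT", pathway="cAMP")

fit = fit_operational([curve])[0]
print(f"pK_A    = {fit.pKA:.2f} +/- {fit.se_pKA:.2f}")
print(f"log tau = {fit.log_tau:.2f} +/- {fit.se_log_tau:.2f}")
print(f"implied pEC50 (closed form) = {predict_ec50(fit.pKA, fit.log_tau):.2f}")

# a mutant over-expressed 3.2-fold relative to wild type
log_tau_c = correct_tau(fit.log_tau, expression_percent=320.0)
print(f"log tau_c at 320% expression = {log_tau_c:.2f}")
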