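"""Fit a three-parameter logistic to a simulated concentration-response curve.

The 3PL (Hill slope fixed at 1) provides every pEC50/pIC50 and Emax in the
package. Fits that do not meet the reliability rules come back flagged
``not_determined`` instead of raising.
"""

from ctrpharm import GroundTruth, OperationalParams, PlateLayout
from ctrpharm import fit_logistic3, simulate_crc

truth = GroundTruth(
    operational={("hCT", "cAMP"): OperationalParams(pKA=9.54, log_tau=0.18)},
)
curve = simulate_crc(truth, PlateLayout(), seed=7, ligand="hCT", pathway="cAMP")

fit = fit_logistic3(curve, direction="ascending")
print(f"pEC50 = {fit.pec50:.2f} +/- {fit.se_log_ec50:.2f}")
print(f"span  = {fit.bottom:.1f} -> {fit.top:.1f} % of E_max")
print(f"flags : converged={fit.converged}, not_determined={fit.not_determined}")
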