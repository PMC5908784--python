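"""Simulate one functional plate and one competition-binding plate.

Every downstream example starts from data like this: a ground-truth
parameter set, a plate layout (3-fold dilutions from 1 uM, duplicates),
and a seed that makes the run exactly reproducible.
"""

from ctrpharm import GroundTruth, OperationalParams, PlateLayout
from ctrpharm import simulate_competition_plate, simulate_crc

truth = GroundTruth(
    pKd_radioligand=9.70,
    Bmax_sites=22_900.0,
    pKi_true={"sCT": 9.87, "hCT": 6.72},
    operational={("hCT", "cAMP"): OperationalParams(pKA=9.54, log_tau=0.18)},
)
layout = PlateLayout()

curve = simulate_crc(truth, layout, seed=1, ligand="hCT", pathway="cAMP")
print(f"functional plate: {curve.conc.size} wells, "
      f"{curve.n_distinct_conc} concentrations")
print(f"  response at top dose: {curve.response[:2].mean():.1f} % of E_max")

plate = simulate_competition_plate(truth, layout, [25e-12, 100e-12],
                                   "homologous", seed=1)
print(f"binding plate: {plate.cpm.size} sample wells over "
      f"{len(plate.hot_concs)} hot-ligand concentrations")
print(f"  total binding at 100 pM hot: {plate.total_cpm[100e-12].mean():.0f} cpm")
print(f"  non-specific binding:        {plate.nsb_cpm[100e-12].mean():.0f} cpm")
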