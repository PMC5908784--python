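"""Homologous and heterologous competition-binding analysis.

The homologous fit shares Kd and Bmax across two hot-ligand concentrations
and converts counts to receptor sites per cell. The heterologous fit runs a
descending 3PL per curve and applies the Cheng-Prusoff correction.
"""

from ctrpharm import GroundTruth, PlateLayout
from ctrpharm import fit_heterologous, fit_homologous, simulate_competition_plate

truth = GroundTruth(
    pKd_radioligand=9.70,
    Bmax_sites=22_900.0,
    pKi_true={"sCT": 9.87, "hCT": 6.72},
)
layout = PlateLayout()

plate = simulate_competition_plate(truth, layout, [25e-12, 100e-12],
                                   "homologous", seed=3)
hom = fit_homologous(plate)
print(f"homologous fit:  pKd  = {hom.pKi:.2f},  Bmax = {hom.Bmax_sites:,.0f} sites/cell")

for ligand in ("sCT", "hCT"):
    plate = simulate_competition_plate(truth, layout, [1e-10], "heterologous",
                                       seed=3, ligand=ligand)
    het = fit_heterologous(plate, radioligand_kd=10.0 ** -hom.pKi)
    print(f"heterologous {ligand}: pKi = {het.pKi:.2f}"
          + ("  (N.D.)" if het.not_determined else ""))
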