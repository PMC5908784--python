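import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctrpharm.datatypes import GroundTruth, OperationalParams, PlateLayout

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Wild-type generative truth used throughout the recovery tests: radioligand
# pKd 9.70 / Bmax 22,900 sites per cell, competitor affinities pKi 9.87 (sCT)
# and 6.72 (hCT), and cAMP operational parameters (pK_A, log tau) of
# (10.52, 0.25) for sCT and (9.54, 0.18) for hCT on a 100%-of-control scale.
WT_PKD = 9.70
WT_BMAX = 22_900.0
WT_PKI = {"sCT": 9.87, "hCT": 6.72}
WT_OPERATIONAL = {
    ("sCT", "cAMP"): OperationalParams(pKA=10.52, log_tau=0.25),
    ("hCT", "cAMP"): OperationalParams(pKA=9.54, log_tau=0.18),
}


@pytest.fixture
def layout() -> PlateLayout:
    return PlateLayout()


@pytest.fixture
def wt_truth() -> GroundTruth:
    return GroundTruth(
        pKd_radioligand=WT_PKD,
        Bmax_sites=WT_BMAX,
        pKi_true=dict(WT_PKI),
        operational=dict(WT_OPERATIONAL),
    )


@pytest.fixture
def noiseless_truth(wt_truth) -> GroundTruth:
    return GroundTruth(
        pKd_radioligand=WT_PKD,
        Bmax_sites=WT_BMAX,
        pKi_true=dict(WT_PKI),
        operational=dict(WT_OPERATIONAL),
        sd_frac=0.0,
        count_noise="none",
    )


def make_frameset(coords, chain, resid, atom_name, element, resname=None):
    """Build a FrameSet from plain lists (test fixture helper)."""
    from ctrpharm.contacts import FrameSet

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    if resname is None:
        resname = ["ALA"] * n
    return FrameSet(
        coords=coords,
        chain=np.array(chain),
        resid=np.array(resid, dtype=int),
        resname=np.array(resname),
        atom_name=np.array(atom_name),
        element=np.array(element),
    )
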