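"""Synthetic plate generator.

Emulates the three assay families of the pipeline from known ground truth:

* functional concentration-response plates (operational-model mean plus
  additive Gaussian noise expressed as a fraction of the system maximum);
* whole-cell radioligand competition plates, homologous and heterologous,
  with occupancy-model means converted to gamma-counter cpm and counting
  noise;
* FACS mean-fluorescence records with parental (0%) and wild-type (100%)
  anchors.

Everything is deterministic given the seed, so downstream fitters can be
validated by parameter recovery.
"""

from __future__ import annotations

import numpy as np

from .binding import sites_to_counts
from .datatypes import (
    BindingPlate,
    ConcentrationResponseCurve,
    ExpressionRecord,
    GroundTruth,
    PlateLayout,
)
from .operational import operational_response


def simulate_crc(
    truth: GroundTruth,
    layout: PlateLayout,
    seed: int,
    ligand: str = "hCT",
    pathway: str = "cAMP",
    variant: str = "WT",
    experiment: str | int = 0,
) -> ConcentrationResponseCurve:
    """Simulate one functional concentration-response experiment.

    Responses are the operational-model mean at each well concentration plus
    i.i.d. Gaussian noise with SD ``truth.sd_frac * Em``.
    """
    key = (ligand, pathway)
    if key not in truth.operational:
        raise KeyError(f"no operational parameters for ligand/pathway {key!r}")
    params = truth.operational[key]
    rng = np.random.default_rng(seed)

    conc = np.repeat(layout.concentrations, layout.replicates)
    mean = operational_response(conc, params.pKA, params.log_tau, params.Em, params.basal, params.n)
    noise = rng.normal(0.0, truth.sd_frac * params.Em, size=conc.shape) if truth.sd_frac > 0 else 0.0
    replicate = np.tile(np.arange(layout.replicates), layout.concentrations.size)
    return ConcentrationResponseCurve(
        ligand=ligand,
        variant=variant,
        pathway=pathway,
        conc=conc,
        response=mean + noise,
        replicate=replicate,
        experiment=np.full(conc.shape, experiment),
    )


def expected_specific_sites(
    cold_conc: np.ndarray,
    hot_conc: float,
    truth: GroundTruth,
    mode: str,
    ligand: str,
) -> np.ndarray:
    """Occupancy-model specific binding in sites/cell.

    Homologous (competitor chemically identical to the radioligand):
    ``Bmax * L / (L + C + Kd)``.  Heterologous:
    ``Bmax * L / (L + Kd * (1 + C / Ki))``.
    """
    C = np.asarray(cold_conc, dtype=float)
    L = float(hot_conc)
    Kd = 10.0 ** -truth.pKd_radioligand
    if mode == "homologous":
        return truth.Bmax_sites * L / (L + C + Kd)
    if mode == "heterologous":
        if ligand not in truth.pKi_true:
            raise KeyError(f"no pKi_true for competitor {ligand!r}")
        Ki = 10.0 ** -truth.pKi_true[ligand]
        return truth.Bmax_sites * L / (L + Kd * (1.0 + C / Ki))
    raise ValueError("mode must be 'homologous' or 'heterologous'")


def _noisy_counts(mu: np.ndarray, total_mu: float, truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if truth.count_noise == "none":
        return mu.copy()
    if truth.count_noise == "poisson":
        return rng.poisson(mu).astype(float)
    # gamma-counter statistics: sqrt-counts floor plus 2%-of-window term
    sd = np.maximum(np.sqrt(np.maximum(mu, 0.0)), 0.02 * total_mu)
    return mu + rng.normal(0.0, sd, size=mu.shape)


def simulate_competition_plate(
    truth: GroundTruth,
    layout: PlateLayout,
    hot_concs: list[float] | np.ndarray,
    mode: str,
    seed: int,
    ligand: str | None = None,
    variant: str = "WT",
) -> BindingPlate:
    """Simulate a competition-binding plate.

    One cold dilution series per hot-ligand concentration, with total
    (zero-competitor) and NSB (saturating-competitor) control wells. NSB is
    concentration-independent: ``nsb_frac`` of the maximal specific signal.
    """
    hot_concs = np.asarray(hot_concs, dtype=float)
    if hot_concs.size == 0:
        raise ValueError("hot_concs must be non-empty")
    if ligand is None:
        ligand = "sCT(8-32)" if mode == "homologous" else "sCT"
    rng = np.random.default_rng(seed)

    cold_all, hot_all, cpm_all = [], [], []
    total_cpm: dict[float, np.ndarray] = {}
    nsb_cpm: dict[float, np.ndarray] = {}
    for L in hot_concs:
        spec_sites = expected_specific_sites(layout.concentrations, L, truth, mode, ligand)
        spec0_sites = expected_specific_sites(np.array([0.0]), L, truth, mode, ligand)[0]
        to_cpm = lambda s: sites_to_counts(
            s, layout.counter_efficiency, layout.specific_activity, layout.cells_per_well
        )
        nsb_mu = truth.nsb_frac * to_cpm(spec0_sites)
        total_mu = to_cpm(spec0_sites) + nsb_mu

        cold = np.repeat(layout.concentrations, layout.replicates)
        sample_mu = np.repeat(to_cpm(spec_sites), layout.replicates) + nsb_mu
        cpm = _noisy_counts(sample_mu, total_mu, truth, rng)
        tot = _noisy_counts(np.full(layout.n_control_wells, total_mu), total_mu, truth, rng)
        nsb = _noisy_counts(np.full(layout.n_control_wells, nsb_mu), total_mu, truth, rng)

        cold_all.append(cold)
        hot_all.append(np.full(cold.shape, L))
        cpm_all.append(cpm)
        total_cpm[float(L)] = tot
        nsb_cpm[float(L)] = nsb

    return BindingPlate(
        variant=variant,
        ligand=ligand,
        mode=mode,
        hot_concs=hot_concs,
        cold_conc=np.concatenate(cold_all),
        hot_conc=np.concatenate(hot_all),
        cpm=np.concatenate(cpm_all),
        total_cpm=total_cpm,
        nsb_cpm=nsb_cpm,
        cells_per_well=layout.cells_per_well,
        counter_efficiency=layout.counter_efficiency,
        specific_activity=layout.specific_activity,
    )


def simulate_expression(
    true_percent: float,
    n_samples: int,
    seed: int,
    mfi_parental: float = 150.0,
    mfi_wt: float = 1650.0,
    cv: float = 0.08,
) -> list[ExpressionRecord]:
    """Simulate FACS mean-fluorescence records for one variant.

    The sample MFI is placed on the parental-to-WT scale at ``true_percent``
    and jittered with Gaussian noise of SD ``cv * (MFI_WT - MFI_parental)``,
    so normalization recovers ``true_percent`` in expectation. Anchors are
    noiseless (each record carries its own parental/WT controls).
    """
    if true_percent < 0:
        raise ValueError("true_percent must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    window = mfi_wt - mfi_parental
    mu = mfi_parental + window * true_percent / 100.0
    noise = rng.normal(0.0, cv * window, size=n_samples) if cv > 0 else np.zeros(n_samples)
    return [
        ExpressionRecord(MFI_parental=mfi_parental, MFI_WT=mfi_wt, MFI_sample=mu + e)
        for e in noise
    ]
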