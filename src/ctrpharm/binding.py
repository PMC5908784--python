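"""Radioligand competition-binding analysis.

Homologous competition (cold ligand identical to the radioligand) yields the
radioligand Kd and the receptor density Bmax via the one-site model
``B(C; L) = Bmax * L / (L + C + Kd)``; a joint fit across two hot-ligand
concentrations shares Kd and Bmax. Heterologous competition yields an IC50
by descending 3PL fit, corrected for radioligand occupancy with the
Cheng-Prusoff equation ``Ki = IC50 / (1 + L / Kd)``.

Counts are converted between gamma-counter cpm and receptor sites per cell
through the counter efficiency and the radioligand specific activity.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .datatypes import BindingFit, BindingPlate, ConcentrationResponseCurve
from .dose_response import fit_logistic3

# 1 Ci = 2.22e12 dpm, so specific activity in Ci/mmol times 2.22 gives dpm/fmol.
_DPM_PER_FMOL_PER_CI_MMOL = 2.22
# sites per fmol = 6.022e23 / 1e15
_SITES_PER_FMOL = 6.022e8


def counts_to_sites(cpm, efficiency: float, specific_activity: float, cells_per_well: float):
    """Convert gamma-counter cpm to receptor sites per cell.

    cpm -> dpm (counter efficiency) -> fmol (specific activity) -> sites/cell
    (Avogadro over cells per well).
    """
    if efficiency <= 0 or cells_per_well <= 0 or specific_activity <= 0:
        raise ValueError("efficiency, specific_activity and cells_per_well must be > 0")
    cpm = np.asarray(cpm, dtype=float)
    dpm = cpm / efficiency
    fmol = dpm / (specific_activity * _DPM_PER_FMOL_PER_CI_MMOL)
    sites = fmol * _SITES_PER_FMOL / cells_per_well
    return float(sites) if sites.ndim == 0 else sites


def sites_to_counts(sites, efficiency: float, specific_activity: float, cells_per_well: float):
    """Inverse of :func:`counts_to_sites`: sites/cell to cpm."""
    if efficiency <= 0 or cells_per_well <= 0 or specific_activity <= 0:
        raise ValueError("efficiency, specific_activity and cells_per_well must be > 0")
    sites = np.asarray(sites, dtype=float)
    fmol = sites * cells_per_well / _SITES_PER_FMOL
    dpm = fmol * specific_activity * _DPM_PER_FMOL_PER_CI_MMOL
    cpm = dpm * efficiency
    return float(cpm) if cpm.ndim == 0 else cpm


def cheng_prusoff(ic50: float, hot_conc: float, kd: float) -> float:
    """Correct a competition IC50 for radioligand occupancy.

    ``Ki = IC50 / (1 + L / Kd)``. ``hot_conc`` may be zero (no correction);
    ``ic50`` and ``kd`` must be positive.
    """
    if ic50 <= 0 or kd <= 0 or hot_conc < 0:
        raise ValueError("ic50 and kd must be > 0 and hot_conc >= 0")
    return ic50 / (1.0 + hot_conc / kd)


def specific_binding(plate: BindingPlate) -> np.ndarray:
    """Percent specific binding for every sample well.

    Normalized against the mean NSB (0%) and mean total (100%) control wells
    of the well's own hot-concentration series.
    """
    out = np.empty_like(plate.cpm)
    for L in plate.hot_concs:
        key = float(L)
        tot = float(np.mean(plate.total_cpm[key]))
        nsb = float(np.mean(plate.nsb_cpm[key]))
        if tot == nsb:
            raise ValueError("total and NSB control means are equal: no binding window")
        mask = plate.hot_conc == L
        out[mask] = 100.0 * (plate.cpm[mask] - nsb) / (tot - nsb)
    return out


def fit_homologous(plate: BindingPlate, joint: bool = True) -> BindingFit:
    """Joint shared-Kd/Bmax fit of a homologous competition plate.

    Fits cpm of all wells (samples plus total and NSB controls) to
    ``cpm(C; L) = counts(Bmax * L / (L + C + Kd)) + NSB_L`` with Kd and Bmax
    shared across hot concentrations and one NSB level per series. With
    ``joint=False`` each hot-concentration series is fit separately and the
    estimates averaged (kept for comparison with the joint fit).

    For the homologous radioligand the reported pKi equals pKd.
    """
    if plate.mode != "homologous":
        raise ValueError("fit_homologous requires a homologous plate")
    warnings_ = []
    if plate.hot_concs.size < 2:
        warnings_.append(
            "single hot concentration: Kd and Bmax only weakly identifiable; expect wide SEs"
        )

    if not joint and plate.hot_concs.size > 1:
        fits = [
            fit_homologous(_subset_plate(plate, L), joint=True) for L in plate.hot_concs
        ]
        pkis = [f.pKi for f in fits]
        bmaxs = [f.Bmax_sites for f in fits]
        return BindingFit(
            variant=plate.variant, ligand=plate.ligand, mode="homologous",
            pKi=float(np.mean(pkis)), se_pKi=float(np.std(pkis, ddof=1) / np.sqrt(len(pkis))),
            Bmax_sites=float(np.mean(bmaxs)),
            se_Bmax_sites=float(np.std(bmaxs, ddof=1) / np.sqrt(len(bmaxs))),
            pIC50={float(L): f.pIC50[float(L)] for L, f in zip(plate.hot_concs, fits)},
            warnings=["separate-series mode"],
        )

    hot_list = [float(L) for L in plate.hot_concs]
    to_cpm = lambda s: sites_to_counts(
        s, plate.counter_efficiency, plate.specific_activity, plate.cells_per_well
    )

    # data vector: all sample wells, then control wells per series
    y_parts, rows = [], []  # rows: (C, L, kind, series_index)
    for i, L in enumerate(hot_list):
        mask = plate.hot_conc == L
        y_parts.append(plate.cpm[mask])
        rows.append((plate.cold_conc[mask], L, i))
        y_parts.append(np.asarray(plate.total_cpm[L], dtype=float))
        rows.append((np.zeros(len(plate.total_cpm[L])), L, i))
        y_parts.append(np.asarray(plate.nsb_cpm[L], dtype=float))
        rows.append((np.full(len(plate.nsb_cpm[L]), np.inf), L, i))
    y = np.concatenate(y_parts)

    def model(theta):
        pKd, log10_bmax = theta[0], theta[1]
        nsb = theta[2:]
        Kd = 10.0 ** -pKd
        Bmax = 10.0 ** log10_bmax
        parts = []
        for C, L, i in rows:
            with np.errstate(invalid="ignore"):
                spec = np.where(np.isinf(C), 0.0, Bmax * L / (L + C + Kd))
            parts.append(to_cpm(spec) + nsb[i])
        return np.concatenate(parts)

    # initial values from the control windows and half-displacement
    nsb0 = np.array([np.mean(plate.nsb_cpm[L]) for L in hot_list])
    spec0_cpm = np.array([np.mean(plate.total_cpm[L]) for L in hot_list]) - nsb0
    spec0_cpm = np.maximum(spec0_cpm, 1.0)
    kd0 = max(np.median(plate.cold_conc), 1e-12)
    spec0_sites = counts_to_sites(
        spec0_cpm, plate.counter_efficiency, plate.specific_activity, plate.cells_per_well
    )
    bmax0 = float(np.mean(spec0_sites * (np.array(hot_list) + kd0) / np.array(hot_list)))
    theta0 = np.concatenate([[-np.log10(kd0), np.log10(max(bmax0, 1.0))], nsb0])

    try:
        res = least_squares(lambda t: model(t) - y, theta0, method="lm", max_nfev=20000)
    except Exception:
        return BindingFit(
            variant=plate.variant, ligand=plate.ligand, mode="homologous",
            converged=False, not_determined=True, warnings=warnings_,
        )
    pKd = float(res.x[0])
    Bmax = float(10.0 ** res.x[1])

    # asymptotic covariance from the jacobian
    se_pKd = se_bmax = np.nan
    dof = y.size - res.x.size
    if dof > 0:
        try:
            JTJ = res.jac.T @ res.jac
            cov = np.linalg.inv(JTJ) * (2.0 * res.cost / dof)
            se_pKd = float(np.sqrt(cov[0, 0]))
            se_bmax = float(np.sqrt(cov[1, 1]) * Bmax * np.log(10.0))
        except np.linalg.LinAlgError:
            pass

    pic50 = {L: -np.log10(L + 10.0 ** -pKd) for L in hot_list}
    nd = not res.success or not np.isfinite(pKd)
    return BindingFit(
        variant=plate.variant, ligand=plate.ligand, mode="homologous",
        pKi=pKd, se_pKi=se_pKd, Bmax_sites=Bmax, se_Bmax_sites=se_bmax,
        pIC50=pic50, not_determined=nd, converged=res.success, warnings=warnings_,
    )


def _subset_plate(plate: BindingPlate, L: float) -> BindingPlate:
    mask = plate.hot_conc == L
    return BindingPlate(
        variant=plate.variant, ligand=plate.ligand, mode=plate.mode,
        hot_concs=np.array([L]), cold_conc=plate.cold_conc[mask],
        hot_conc=plate.hot_conc[mask], cpm=plate.cpm[mask],
        total_cpm={float(L): plate.total_cpm[float(L)]},
        nsb_cpm={float(L): plate.nsb_cpm[float(L)]},
        cells_per_well=plate.cells_per_well,
        counter_efficiency=plate.counter_efficiency,
        specific_activity=plate.specific_activity,
    )


def fit_heterologous(plate: BindingPlate, radioligand_kd: float) -> BindingFit:
    """Heterologous competition: 3PL pIC50 then Cheng-Prusoff pKi.

    ``radioligand_kd`` (molar) comes from the homologous fit of the same
    variant (wild-type Kd as fallback). When several hot concentrations are
    present, each series is analysed and the pKi values averaged.
    """
    if plate.mode != "heterologous":
        raise ValueError("fit_heterologous requires a heterologous plate")
    if radioligand_kd <= 0:
        raise ValueError("radioligand_kd must be > 0")

    pct = specific_binding(plate)
    pkis, pic50s, flags = [], {}, []
    for L in plate.hot_concs:
        mask = plate.hot_conc == L
        curve = ConcentrationResponseCurve(
            ligand=plate.ligand, variant=plate.variant, pathway="binding",
            conc=plate.cold_conc[mask], response=pct[mask],
            replicate=np.zeros(mask.sum()), experiment=np.zeros(mask.sum()),
        )
        fit = fit_logistic3(curve, direction="descending")
        flags.append(fit.not_determined)
        if fit.not_determined:
            continue
        ic50 = 10.0 ** fit.log_ec50
        ki = cheng_prusoff(ic50, float(L), radioligand_kd)
        pkis.append(-np.log10(ki))
        pic50s[float(L)] = -fit.log_ec50

    if not pkis:
        return BindingFit(
            variant=plate.variant, ligand=plate.ligand, mode="heterologous",
            not_determined=True, pIC50=pic50s,
        )
    se = float(np.std(pkis, ddof=1) / np.sqrt(len(pkis))) if len(pkis) > 1 else np.nan
    return BindingFit(
        variant=plate.variant, ligand=plate.ligand, mode="heterologous",
        pKi=float(np.mean(pkis)), se_pKi=se, pIC50=pic50s,
        not_determined=False, warnings=(["some series N.D."] if any(flags) else []),
    )
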