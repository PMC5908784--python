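"""Black-Leff operational model of agonism.

Separates functional affinity (pK_A) from transduction efficacy (tau):

``E(A) = basal + (Em - basal) * tau^n A^n / ((A + K_A)^n + tau^n A^n)``

where Em is the system maximal response, K_A the functional dissociation
constant of the agonist-receptor complex, tau the efficacy (capacity of the
occupied receptor to drive the pathway) and n the transducer slope.

With n = 1 the model is exactly a one-site logistic in shape (plateau
``Em*tau/(1+tau)``, midpoint ``K_A/(1+tau)``), so Em cannot be identified
from response curves alone; by default Em is fixed at 100 on the
control-normalized scale and only (pK_A, log tau) are estimated per curve.
A shared-Em joint mode is available and guarded by an identifiability flag.

Efficacy is made comparable across receptor variants by correcting tau for
cell-surface expression: ``log tau_c = log tau - log10(expression% / 100)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .datatypes import ConcentrationResponseCurve, ExpressionRecord, OperationalFit


def operational_response(conc, pKA: float, log_tau: float, Em: float = 100.0,
                         basal: float = 0.0, n: float = 1.0):
    """Mean response of the operational model at molar concentration(s)."""
    A = np.asarray(conc, dtype=float)
    KA = 10.0 ** -pKA
    tau = 10.0 ** log_tau
    num = (tau * A) ** n
    out = basal + (Em - basal) * num / ((A + KA) ** n + num)
    return float(out) if out.ndim == 0 else out


def predict_ec50(pKA: float, log_tau: float, n: float = 1.0) -> float:
    """Closed-form pEC50 implied by operational parameters.

    ``EC50 = K_A / ((2 + tau^n)**(1/n) - 1)``; for ``n = 1`` this reduces to
    ``K_A / (1 + tau)``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    KA = 10.0 ** -pKA
    tau = 10.0 ** log_tau
    ec50 = KA / ((2.0 + tau ** n) ** (1.0 / n) - 1.0)
    return -np.log10(ec50)


def fit_operational(
    curves: list[ConcentrationResponseCurve],
    em_policy: str = "fixed",
    em_value: float = 100.0,
    n_value: float = 1.0,
    basal: float = 0.0,
    corr_threshold: float = 0.99,
) -> list[OperationalFit]:
    """Fit the operational model to a family of curves.

    Parameters
    ----------
    curves : one or more concentration-response curves (typically all
        ligands/variants of one pathway within one experiment).
    em_policy : ``"fixed"`` (Em pinned to ``em_value``, the default since the
        responses are control-normalized) or ``"shared"`` (one Em estimated
        jointly across all curves; requires >= 2 curves).
    n_value : transducer slope, fixed (default 1).
    basal : fixed basal response on the normalized scale.
    corr_threshold : |corr(pK_A, log tau)| above which the fit is flagged
        as weakly identified.

    Returns one :class:`OperationalFit` per input curve; non-convergence is
    flagged, never raised.
    """
    if em_policy not in ("fixed", "shared"):
        raise ValueError("em_policy must be 'fixed' or 'shared'")
    if not curves:
        raise ValueError("no curves supplied")
    if em_policy == "shared" and len(curves) < 2:
        raise ValueError("shared-Em estimation requires >= 2 curves")

    shared_em = em_policy == "shared"
    k = len(curves)
    # theta = [log10(Em)]? keep Em linear; layout: ([Em]) + [pKA_i, log_tau_i]*k
    offset = 1 if shared_em else 0

    log_cs = [np.log10(c.conc) for c in curves]
    ys = [c.response for c in curves]

    def unpack(theta):
        Em = theta[0] if shared_em else em_value
        per = theta[offset:].reshape(k, 2)
        return Em, per

    def resid(theta):
        Em, per = unpack(theta)
        parts = []
        for (pKA, lt), c, y in zip(per, curves, ys):
            parts.append(operational_response(c.conc, pKA, lt, Em, basal, n_value) - y)
        return np.concatenate(parts)

    # multi-start over pKA at quartiles of each curve's tested range
    best = None
    for frac in (0.25, 0.5, 0.75):
        theta0 = []
        if shared_em:
            theta0.append(max(max(y.max() for y in ys), em_value))
        for lc, y in zip(log_cs, ys):
            pka0 = -(lc.min() + frac * (lc.max() - lc.min()))
            theta0.extend([pka0, 0.0])
        try:
            res = least_squares(resid, np.array(theta0), method="lm", max_nfev=40000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return [
            OperationalFit(ligand=c.ligand, variant=c.variant, pathway=c.pathway,
                           converged=False, not_determined=True, Em=em_value,
                           basal=basal, n=n_value)
            for c in curves
        ]

    Em, per = unpack(best.x)
    n_obs = sum(y.size for y in ys)
    dof = max(n_obs - best.x.size, 1)
    cov = None
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * (2.0 * best.cost / dof)
    except np.linalg.LinAlgError:
        pass

    fits = []
    for i, ((pKA, lt), c) in enumerate(zip(per, curves)):
        se_pka = se_lt = corr = np.nan
        if cov is not None:
            a, b = offset + 2 * i, offset + 2 * i + 1
            va, vb, cab = cov[a, a], cov[b, b], cov[a, b]
            if va > 0 and vb > 0:
                se_pka, se_lt = float(np.sqrt(va)), float(np.sqrt(vb))
                corr = float(cab / np.sqrt(va * vb))
        ident_warn = np.isfinite(corr) and abs(corr) > corr_threshold
        fits.append(OperationalFit(
            ligand=c.ligand, variant=c.variant, pathway=c.pathway,
            pKA=float(pKA), log_tau=float(lt), Em=float(Em), basal=basal,
            n=n_value, se_pKA=se_pka, se_log_tau=se_lt, param_corr=corr,
            converged=True, not_determined=not np.isfinite(pKA),
            identifiability_warning=bool(ident_warn),
        ))
    return fits


def normalize_expression(record: ExpressionRecord) -> float:
    """Cell-surface expression as percent of wild type.

    ``100 * (MFI_sample - MFI_parental) / (MFI_WT - MFI_parental)`` —
    parental cells anchor 0% and the wild-type receptor 100%.
    """
    return record.percent_of_WT


def correct_tau(log_tau: float, expression_percent: float) -> float:
    """Expression-corrected efficacy ``log tau_c``.

    ``log tau_c = log tau - log10(expression_percent / 100)``. Undetectable
    (zero or non-finite) expression leaves tau_c undefined (NaN); callers
    propagate it as N.D.
    """
    if not np.isfinite(expression_percent) or expression_percent <= 0:
        return np.nan
    if not np.isfinite(log_tau):
        return np.nan
    return float(log_tau - np.log10(expression_percent / 100.0))


def delta_vs_wt(wt_value: float, mutant_value: float) -> float:
    """Difference relative to wild type, ``WT - mutant``.

    Positive values mean a loss versus wild type. NaN (N.D.) in either input
    propagates.
    """
    if not (np.isfinite(wt_value) and np.isfinite(mutant_value)):
        return np.nan
    return float(wt_value - mutant_value)


def correlate_affinities(x, y) -> tuple[float, float, float]:
    """Pearson correlation between paired affinity scales.

    Used e.g. to compare binding pKi against functional pK_A across
    variants. Returns ``(r, two-sided p, least-squares slope)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    slope = sps.linregress(x, y).slope
    return float(r), float(p), float(slope)
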