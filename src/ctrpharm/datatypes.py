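"""Core domain containers shared across the pipeline.

All concentrations are molar internally; affinities are -log10 molar (pKd,
pKi, pK_A); efficacies are log10 of the dimensionless operational tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class OperationalParams:
    """Ground-truth operational-model parameters for one ligand x pathway.

    ``E(A) = basal + (Em - basal) * tau^n A^n / ((A + K_A)^n + tau^n A^n)``
    with ``K_A = 10**-pKA``.
    """

    pKA: float
    log_tau: float
    Em: float = 100.0
    basal: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.pKA):
            raise ValueError("pKA must be finite")
        if self.Em <= self.basal:
            raise ValueError("Em must exceed basal")
        if self.basal < 0:
            raise ValueError("basal must be >= 0")
        if self.n <= 0:
            raise ValueError("transducer slope n must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generative truth for one receptor variant.

    Parameters
    ----------
    pKd_radioligand : -log10 M affinity of the (antagonist) radioligand.
    Bmax_sites : maximal specific binding, receptor sites per cell.
    pKi_true : per-competitor -log10 M inhibition constants.
    operational : ``(ligand, pathway) -> OperationalParams``.
    expression_percent : cell-surface expression, % of wild type.
    sd_frac : functional-response Gaussian noise SD as a fraction of Em.
    count_noise : ``"gaussian"`` (sd = max(sqrt(cpm), 2% of total)),
        ``"poisson"``, or ``"none"`` for exact expected counts.
    nsb_frac : nonspecific binding as a fraction of the maximal specific
        signal (constant across competitor concentrations).
    """

    pKd_radioligand: float = 9.70
    Bmax_sites: float = 22_900.0
    pKi_true: dict[str, float] = field(default_factory=dict)
    operational: dict[tuple[str, str], OperationalParams] = field(default_factory=dict)
    expression_percent: float = 100.0
    sd_frac: float = 0.05
    count_noise: str = "gaussian"
    nsb_frac: float = 0.10

    def __post_init__(self) -> None:
        if not np.isfinite(self.pKd_radioligand):
            raise ValueError("pKd_radioligand must be finite")
        if self.Bmax_sites < 0:
            raise ValueError("Bmax_sites must be >= 0")
        if self.expression_percent < 0:
            raise ValueError("expression_percent must be >= 0")
        if self.count_noise not in ("gaussian", "poisson", "none"):
            raise ValueError("count_noise must be 'gaussian', 'poisson' or 'none'")
        if self.sd_frac < 0:
            raise ValueError("sd_frac must be >= 0")


def threefold_grid(top: float = 1e-6, n_points: int = 13) -> np.ndarray:
    """Descending 3-fold dilution series starting at ``top`` molar.

    The default spans 1 uM down to ~1.9 pM in 13 steps, the dilution scheme
    used throughout the assays emulated here.
    """
    return top / 3.0 ** np.arange(n_points)


@dataclass(frozen=True)
class PlateLayout:
    """Physical layout of a simulated plate."""

    concentrations: np.ndarray = field(default_factory=threefold_grid)
    replicates: int = 2
    n_control_wells: int = 2
    cells_per_well: float = 2.5e4
    counter_efficiency: float = 0.80
    specific_activity: float = 2000.0  # Ci/mmol

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or conc.size < 1:
            raise ValueError("concentration grid must be a 1-D array")
        if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("concentrations must be positive and finite")
        if np.any(np.diff(conc) >= 0):
            raise ValueError("concentration grid must be strictly descending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_control_wells < 2:
            raise ValueError("need >= 2 control wells per role")
        if self.cells_per_well <= 0:
            raise ValueError("cells_per_well must be > 0")
        if not 0 < self.counter_efficiency <= 1:
            raise ValueError("counter_efficiency must be in (0, 1]")
        object.__setattr__(self, "concentrations", conc)


@dataclass
class ConcentrationResponseCurve:
    """One ligand x variant x pathway set of normalized responses."""

    ligand: str
    variant: str
    pathway: str
    conc: np.ndarray  # molar, one entry per well
    response: np.ndarray  # % of control
    replicate: np.ndarray
    experiment: np.ndarray

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate = np.asarray(self.replicate)
        self.experiment = np.asarray(self.experiment)
        if not (self.conc.shape == self.response.shape):
            raise ValueError("conc and response must have equal length")
        if np.any(self.conc <= 0) or np.any(~np.isfinite(self.conc)):
            raise ValueError("concentrations must be positive and finite")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("responses must be finite")

    @property
    def n_distinct_conc(self) -> int:
        return int(np.unique(self.conc).size)


@dataclass
class BindingPlate:
    """Competition-binding wells for one variant (possibly several hot concs).

    ``cold_conc``, ``cpm`` and ``hot_conc`` are parallel arrays over sample
    wells; ``total_cpm``/``nsb_cpm`` map each hot concentration to its
    control-well counts.
    """

    variant: str
    ligand: str  # the competitor
    mode: str  # "homologous" | "heterologous"
    hot_concs: np.ndarray  # molar, distinct
    cold_conc: np.ndarray
    hot_conc: np.ndarray
    cpm: np.ndarray
    total_cpm: dict[float, np.ndarray]
    nsb_cpm: dict[float, np.ndarray]
    cells_per_well: float = 2.5e4
    counter_efficiency: float = 0.80
    specific_activity: float = 2000.0

    def __post_init__(self) -> None:
        self.hot_concs = np.asarray(self.hot_concs, dtype=float)
        if self.hot_concs.size == 0:
            raise ValueError("hot_concs must be non-empty")
        self.cold_conc = np.asarray(self.cold_conc, dtype=float)
        self.hot_conc = np.asarray(self.hot_conc, dtype=float)
        self.cpm = np.asarray(self.cpm, dtype=float)
        if self.mode not in ("homologous", "heterologous"):
            raise ValueError("mode must be homologous or heterologous")


@dataclass
class LogisticFit:
    """Three-parameter logistic fit (Hill slope fixed at unity)."""

    bottom: float
    top: float
    log_ec50: float
    se_bottom: float = np.nan
    se_top: float = np.nan
    se_log_ec50: float = np.nan
    converged: bool = True
    not_determined: bool = False
    n_points: int = 0
    residual_sd: float = np.nan
    sse: float = np.nan
    direction: str = "ascending"

    @property
    def pec50(self) -> float:
        return -self.log_ec50

    @property
    def span(self) -> float:
        return self.top - self.bottom


@dataclass
class BindingFit:
    """Result of a competition-binding analysis."""

    variant: str
    ligand: str
    mode: str
    pKi: float = np.nan
    se_pKi: float = np.nan
    Bmax_sites: float = np.nan
    se_Bmax_sites: float = np.nan
    pIC50: dict[float, float] = field(default_factory=dict)
    not_determined: bool = False
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class OperationalFit:
    """Black-Leff operational-model estimates for one curve family."""

    ligand: str
    variant: str
    pathway: str
    pKA: float = np.nan
    log_tau: float = np.nan
    Em: float = 100.0
    basal: float = 0.0
    n: float = 1.0
    se_pKA: float = np.nan
    se_log_tau: float = np.nan
    param_corr: float = np.nan  # corr(pKA, log_tau) from the fit covariance
    converged: bool = True
    not_determined: bool = False
    identifiability_warning: bool = False


@dataclass
class EfficacyRecord:
    """Efficacy with cell-surface-expression correction."""

    ligand: str
    variant: str
    pathway: str
    log_tau: float
    expression_percent: float
    log_tau_c: float = np.nan
    delta_log_tau_c: float = np.nan
    not_determined: bool = False


@dataclass(frozen=True)
class ExpressionRecord:
    """Mean-fluorescence readings for one FACS sample with its anchors."""

    MFI_parental: float
    MFI_WT: float
    MFI_sample: float

    @property
    def percent_of_WT(self) -> float:
        denom = self.MFI_WT - self.MFI_parental
        if denom == 0:
            raise ValueError("degenerate anchors: MFI_WT equals MFI_parental")
        return 100.0 * (self.MFI_sample - self.MFI_parental) / denom


@dataclass
class ContactResult:
    """Contact/H-bond fractions for one residue pair over a frame set."""

    res_a: str  # "chain:resid"
    res_b: str
    contact_fraction: float  # % of frames
    hbond_fraction: float  # % of frames
    classification: Optional[str] = None  # sb | bs | ss | bb
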