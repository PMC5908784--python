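"""End-to-end orchestration: simulate (or load) plates, fit every stage,
attach Dunnett statistics against the wild type, and render report tables.

The pipeline is fully deterministic given the config seed: per-experiment
seeds are derived from it with ``numpy.random.SeedSequence`` so a rerun with
the same config produces byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .binding import fit_heterologous, fit_homologous
from .datatypes import GroundTruth, OperationalParams, PlateLayout
from .dose_response import fit_logistic3
from .operational import correct_tau, correlate_affinities, delta_vs_wt, fit_operational, normalize_expression
from .stats import anova_dunnett, t_test_two_tailed
from .synthetic import simulate_competition_plate, simulate_crc, simulate_expression


class OperationalTruthCfg(BaseModel):
    pKA: float
    log_tau: float
    Em: float = 100.0
    basal: float = 0.0
    n: float = 1.0


class VariantCfg(BaseModel):
    expression_percent: float = 100.0
    pKd_radioligand: float = 9.70
    Bmax_sites: float = 22_900.0
    pKi: dict[str, float] = Field(default_factory=dict)
    # keyed "ligand|pathway"
    operational: dict[str, OperationalTruthCfg] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Declarative run description (JSON or YAML serializable)."""

    out_dir: str = "results"
    seed: int = 1
    n_experiments: int = 4
    alpha: float = 0.05
    sd_frac: float = 0.05
    control_variant: str = "WT"
    hot_concs_homologous: list[float] = Field(default_factory=lambda: [25e-12, 100e-12])
    hot_conc_heterologous: float = 1e-10
    em_policy: str = "fixed"
    em_value: float = 100.0
    ligands: list[str] = Field(default_factory=lambda: ["sCT", "hCT"])
    pathways: list[str] = Field(default_factory=lambda: ["cAMP"])
    variants: dict[str, VariantCfg] = Field(default_factory=dict)

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        data = self.model_dump()
        if str(path).endswith((".yml", ".yaml")):
            Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def _child_seed(base: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _truth_for(v: VariantCfg, sd_frac: float) -> GroundTruth:
    op = {}
    for key, p in v.operational.items():
        lig, pw = key.split("|")
        op[(lig, pw)] = OperationalParams(pKA=p.pKA, log_tau=p.log_tau, Em=p.Em,
                                          basal=p.basal, n=p.n)
    return GroundTruth(
        pKd_radioligand=v.pKd_radioligand, Bmax_sites=v.Bmax_sites,
        pKi_true=dict(v.pKi), operational=op,
        expression_percent=v.expression_percent, sd_frac=sd_frac,
    )


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run the full synthetic-to-tables analysis.

    Returns a dict of tidy per-experiment parameter DataFrames plus the
    rendered summary tables; with ``write=True`` also writes them (and a run
    log) under ``config.out_dir``.
    """
    if config.control_variant not in config.variants:
        raise ValueError(
            f"control variant {config.control_variant!r} missing from config.variants: "
            "the Dunnett control group is required"
        )
    layout = PlateLayout()
    variants = list(config.variants)
    vidx = {v: i for i, v in enumerate(variants)}
    lidx = {l: i for i, l in enumerate(config.ligands)}
    pidx = {p: i for i, p in enumerate(config.pathways)}

    rows_bind, rows_hom, rows_op, rows_3pl, rows_expr = [], [], [], [], []

    for v, vcfg in config.variants.items():
        truth = _truth_for(vcfg, config.sd_frac)
        detectable = vcfg.expression_percent > 1.0  # no binding/response window below

        for e in range(config.n_experiments):
            # homologous competition (radioligand Kd, Bmax)
            if detectable:
                plate = simulate_competition_plate(
                    truth, layout, config.hot_concs_homologous, "homologous",
                    _child_seed(config.seed, 1, vidx[v], e), variant=v)
                fit = fit_homologous(plate)
                if not fit.not_determined:
                    rows_hom.append({"variant": v, "experiment": e,
                                     "pKd": fit.pKi, "Bmax_sites": fit.Bmax_sites})
            # heterologous competition per ligand
            for lig in config.ligands:
                if not detectable or lig not in vcfg.pKi:
                    continue
                plate = simulate_competition_plate(
                    truth, layout, [config.hot_conc_heterologous], "heterologous",
                    _child_seed(config.seed, 2, vidx[v], lidx[lig], e),
                    ligand=lig, variant=v)
                fit = fit_heterologous(plate, radioligand_kd=10.0 ** -vcfg.pKd_radioligand)
                if not fit.not_determined:
                    rows_bind.append({"variant": v, "ligand": lig, "experiment": e,
                                      "pKi": fit.pKi})
            # functional curves per ligand x pathway
            for lig in config.ligands:
                for pw in config.pathways:
                    if (f"{lig}|{pw}" not in vcfg.operational) or not detectable:
                        continue
                    curve = simulate_crc(
                        truth, layout,
                        _child_seed(config.seed, 3, vidx[v], lidx[lig], pidx[pw], e),
                        ligand=lig, pathway=pw, variant=v, experiment=e)
                    lfit = fit_logistic3(curve, direction="ascending")
                    if not lfit.not_determined:
                        rows_3pl.append({"variant": v, "ligand": lig, "pathway": pw,
                                         "experiment": e, "pEC50": lfit.pec50,
                                         "Emax": lfit.top})
                    ofit = fit_operational([curve], em_policy=config.em_policy,
                                           em_value=config.em_value)[0]
                    if not ofit.not_determined:
                        rows_op.append({"variant": v, "ligand": lig, "pathway": pw,
                                        "experiment": e, "pKA": ofit.pKA,
                                        "log_tau": ofit.log_tau})
            # FACS expression
            rec = simulate_expression(vcfg.expression_percent, 1,
                                      _child_seed(config.seed, 4, vidx[v], e))[0]
            rows_expr.append({"variant": v, "experiment": e,
                              "expression_percent": normalize_expression(rec)})

    bind = pd.DataFrame(rows_bind)
    hom = pd.DataFrame(rows_hom)
    op = pd.DataFrame(rows_op)
    p3 = pd.DataFrame(rows_3pl)
    expr = pd.DataFrame(rows_expr)

    # expression-corrected efficacy per experiment (mean expression per variant)
    expr_mean = expr.groupby("variant").expression_percent.mean()
    if len(op):
        op["log_tau_c"] = [
            correct_tau(r.log_tau, float(expr_mean.get(r.variant, np.nan)))
            for r in op.itertuples()
        ]

    tables = render_tables({
        "binding": bind, "homologous": hom, "operational": op,
        "logistic": p3, "expression": expr,
        "control_variant": config.control_variant, "alpha": config.alpha,
    })

    # delta-vs-WT and pKi <-> pKA correlation summaries
    deltas, corr_rows = [], []
    if len(op):
        mean_op = op.groupby(["ligand", "pathway", "variant"])[["pKA", "log_tau_c"]].mean()
        for (lig, pw), g in mean_op.groupby(level=[0, 1]):
            g = g.droplevel([0, 1])
            if config.control_variant not in g.index:
                continue
            wt = g.loc[config.control_variant]
            for v in g.index:
                deltas.append({
                    "ligand": lig, "pathway": pw, "variant": v,
                    "delta_pKA": delta_vs_wt(wt.pKA, g.loc[v].pKA),
                    "delta_log_tau_c": delta_vs_wt(wt.log_tau_c, g.loc[v].log_tau_c),
                })
        if len(bind):
            mean_ki = bind.groupby(["ligand", "variant"]).pKi.mean()
            for (lig, pw), g in mean_op.groupby(level=[0, 1]):
                g = g.droplevel([0, 1])
                common = [v for v in g.index if (lig, v) in mean_ki.index]
                if len(common) >= 3:
                    x = mean_ki.loc[[(lig, v) for v in common]].to_numpy()
                    y = g.loc[common].pKA.to_numpy()
                    if np.std(x) > 0 and np.std(y) > 0:
                        r, pval, slope = correlate_affinities(x, y)
                        corr_rows.append({"ligand": lig, "pathway": pw,
                                          "r": r, "p": pval, "slope": slope,
                                          "n_variants": len(common)})
    tables["delta_vs_wt"] = pd.DataFrame(deltas)
    tables["correlations"] = pd.DataFrame(corr_rows)

    results = {
        "per_experiment": {"binding": bind, "homologous": hom, "operational": op,
                           "logistic": p3, "expression": expr},
        "tables": tables,
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        for name, df in results["per_experiment"].items():
            df.to_csv(out / f"per_experiment_{name}.csv", index=False)
        from importlib.metadata import version as _dist_version

        try:
            pkg_version = _dist_version("ctrpharm")
        except Exception:
            pkg_version = "unknown"
        log = {
            "seed": config.seed,
            "config": config.model_dump(),
            "software": {"ctrpharm": pkg_version, "numpy": np.__version__},
            "n_rows": {k: int(len(v)) for k, v in results["per_experiment"].items()},
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return results


def _fmt(mean: float, sem: float, n: int, star: bool) -> str:
    if not np.isfinite(mean):
        return "N.D."
    s = f"{mean:.2f}"
    if np.isfinite(sem):
        s += f" ± {sem:.2f}"
    s += f" ({n})"
    if star:
        s += "*"
    return s


def _summarize(df: pd.DataFrame, value: str, by: list[str], control: str,
               alpha: float) -> pd.DataFrame:
    """Mean +/- SEM table with Dunnett asterisks against the control variant."""
    out_rows = []
    fam_cols = [c for c in by if c != "variant"]
    groups = df.groupby(fam_cols) if fam_cols else [((), df)]
    for fam, g in groups:
        fam = fam if isinstance(fam, tuple) else (fam,)
        per_var = {v: gv[value].dropna().to_numpy() for v, gv in g.groupby("variant")}
        sig: dict[str, bool] = {}
        ctrl = per_var.get(control)
        others = [v for v in per_var if v != control and per_var[v].size >= 2]
        if ctrl is not None and ctrl.size >= 2 and others:
            res = anova_dunnett([ctrl] + [per_var[v] for v in others],
                                control_index=0, alpha=alpha)
            sig = dict(zip(others, res.significant.tolist()))
        for v, vals in sorted(per_var.items()):
            mean = float(np.mean(vals)) if vals.size else np.nan
            sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            out_rows.append({
                **dict(zip(fam_cols, fam)), "variant": v,
                value: _fmt(mean, sem, vals.size, bool(sig.get(v, False))),
                f"{value}_mean": mean, f"{value}_sem": sem, "n": vals.size,
            })
    return pd.DataFrame(out_rows)


def render_tables(results: dict) -> dict[str, pd.DataFrame]:
    """Render report-style summary tables from per-experiment estimates.

    Cells are "mean +/- SEM (n)" with a trailing ``*`` when the Dunnett
    (or, for expression, Welch t-test) comparison against the control variant
    is significant at alpha, and "N.D." where nothing was determined.
    """
    control = results["control_variant"]
    alpha = results["alpha"]
    tables: dict[str, pd.DataFrame] = {}

    bind, hom = results["binding"], results["homologous"]
    if len(bind):
        tables["affinity_pKi"] = _summarize(bind, "pKi", ["ligand", "variant"], control, alpha)
    if len(hom):
        t = _summarize(hom, "pKd", ["variant"], control, alpha)
        b = _summarize(hom, "Bmax_sites", ["variant"], control, alpha)
        tables["radioligand_binding"] = t.merge(
            b[["variant", "Bmax_sites", "Bmax_sites_mean", "Bmax_sites_sem"]], on="variant")
    p3 = results["logistic"]
    if len(p3):
        a = _summarize(p3, "pEC50", ["ligand", "pathway", "variant"], control, alpha)
        b = _summarize(p3, "Emax", ["ligand", "pathway", "variant"], control, alpha)
        tables["potency_pEC50"] = a.merge(
            b[["ligand", "pathway", "variant", "Emax", "Emax_mean", "Emax_sem"]],
            on=["ligand", "pathway", "variant"])
    op = results["operational"]
    if len(op):
        tables["functional_affinity_pKA"] = _summarize(
            op, "pKA", ["ligand", "pathway", "variant"], control, alpha)
        if "log_tau_c" in op:
            tables["efficacy_log_tau_c"] = _summarize(
                op, "log_tau_c", ["ligand", "pathway", "variant"], control, alpha)
    expr = results["expression"]
    if len(expr):
        rows = []
        per_var = {v: g.expression_percent.to_numpy() for v, g in expr.groupby("variant")}
        ctrl = per_var.get(control)
        for v, vals in sorted(per_var.items()):
            star = False
            if v != control and ctrl is not None and ctrl.size >= 2 and vals.size >= 2:
                star = t_test_two_tailed(ctrl, vals) < alpha
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            rows.append({"variant": v,
                         "expression_percent": _fmt(mean, sem, vals.size, star),
                         "expression_mean": mean, "expression_sem": sem, "n": vals.size})
        tables["expression_FACS"] = pd.DataFrame(rows)
    return tables
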