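"""Plate CSV dialect: one reader and one writer for every assay family.

A single long-format CSV covers functional, binding and FACS plates with the
columns::

    well, role, ligand, variant, pathway, conc_M, hot_conc_M, readout,
    replicate, experiment_id

``role`` is ``sample`` for wells on the dilution series, ``total``/``nsb``
for binding controls and ``control`` for FACS anchor records. Binding plates
use ``pathway`` values ``binding:homologous`` / ``binding:heterologous`` and
``readout`` in cpm; functional plates carry the normalized percent response;
FACS rows carry mean fluorescence intensities. All concentrations are molar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BindingPlate, ConcentrationResponseCurve, ExpressionRecord

COLUMNS = [
    "well", "role", "ligand", "variant", "pathway",
    "conc_M", "hot_conc_M", "readout", "replicate", "experiment_id",
]


def curve_to_frame(curve: ConcentrationResponseCurve) -> pd.DataFrame:
    n = curve.conc.size
    return pd.DataFrame({
        "well": [f"F{i:03d}" for i in range(n)],
        "role": "sample",
        "ligand": curve.ligand,
        "variant": curve.variant,
        "pathway": curve.pathway,
        "conc_M": curve.conc,
        "hot_conc_M": np.nan,
        "readout": curve.response,
        "replicate": curve.replicate,
        "experiment_id": curve.experiment,
    })


def plate_to_frame(plate: BindingPlate, experiment: str | int = 0) -> pd.DataFrame:
    pathway = f"binding:{plate.mode}"
    # homologous plates have no cold ligand of their own; use a sentinel so the
    # CSV stays groupable (empty cells read back as NaN and break grouping)
    ligand = plate.ligand if plate.ligand else "tracer"
    rows = []
    w = 0
    for c, L, cpm in zip(plate.cold_conc, plate.hot_conc, plate.cpm):
        rows.append(("B%03d" % w, "sample", ligand, plate.variant, pathway,
                     c, L, cpm, 0, experiment))
        w += 1
    for L in plate.hot_concs:
        for cpm in plate.total_cpm[float(L)]:
            rows.append(("B%03d" % w, "total", ligand, plate.variant, pathway,
                         np.nan, float(L), cpm, 0, experiment))
            w += 1
        for cpm in plate.nsb_cpm[float(L)]:
            rows.append(("B%03d" % w, "nsb", ligand, plate.variant, pathway,
                         np.nan, float(L), cpm, 0, experiment))
            w += 1
    return pd.DataFrame(rows, columns=COLUMNS)


def expression_to_frame(records: list[ExpressionRecord], variant: str,
                        experiment: str | int = 0) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        rows.append((f"X{i:03d}p", "control", "parental", variant, "FACS",
                     np.nan, np.nan, rec.MFI_parental, i, experiment))
        rows.append((f"X{i:03d}w", "control", "WT-anchor", variant, "FACS",
                     np.nan, np.nan, rec.MFI_WT, i, experiment))
        rows.append((f"X{i:03d}s", "sample", "anti-tag", variant, "FACS",
                     np.nan, np.nan, rec.MFI_sample, i, experiment))
    return pd.DataFrame(rows, columns=COLUMNS)


def write_plates(frames: list[pd.DataFrame] | pd.DataFrame, path) -> None:
    """Write one or more plate tables to a single CSV."""
    if isinstance(frames, pd.DataFrame):
        df = frames
    else:
        df = pd.concat(frames, ignore_index=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df.to_csv(path, index=False)


class PlateFormatError(ValueError):
    pass


def _parse_conc(series: pd.Series, rows_label: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & out.isna()
    if bad.any():
        lines = [str(i + 2) for i in series.index[bad][:5]]  # +2: header + 0-base
        raise PlateFormatError(
            f"non-numeric {rows_label} (units must be molar, no suffixes) "
            f"at CSV line(s) {', '.join(lines)}"
        )
    return out


def read_plates(manifest) -> dict:
    """Read plate CSV file(s) back into typed objects.

    ``manifest`` is a path or a list of paths. Returns a dict with keys
    ``curves`` (list of ConcentrationResponseCurve), ``plates`` (list of
    BindingPlate) and ``expression`` (``variant -> list of ExpressionRecord``,
    per experiment). Malformed rows raise :class:`PlateFormatError` with CSV
    line numbers.
    """
    paths = [manifest] if isinstance(manifest, (str, Path)) else list(manifest)
    dfs = []
    for p in paths:
        df = pd.read_csv(p)
        if df.empty:
            raise PlateFormatError(f"{p}: empty plate file")
        unknown = [c for c in df.columns if c not in COLUMNS]
        if unknown:
            raise PlateFormatError(f"{p}: unknown column(s) {unknown}")
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise PlateFormatError(f"{p}: missing column(s) {missing}")
        df["conc_M"] = _parse_conc(df["conc_M"], "conc_M")
        df["hot_conc_M"] = _parse_conc(df["hot_conc_M"], "hot_conc_M")
        dfs.append(df)
    df = pd.concat(dfs, ignore_index=True)

    samples = df[df.role == "sample"]
    func = samples[~samples.pathway.str.startswith(("binding", "FACS"))]
    bad = func[~(func.conc_M > 0)]
    if len(bad):
        raise PlateFormatError(
            f"non-positive concentration on sample well(s), e.g. row index {bad.index[0]}"
        )

    curves = []
    for (lig, var, pw, exp), g in func.groupby(
            ["ligand", "variant", "pathway", "experiment_id"], sort=True):
        curves.append(ConcentrationResponseCurve(
            ligand=lig, variant=var, pathway=pw,
            conc=g.conc_M.to_numpy(), response=g.readout.to_numpy(),
            replicate=g.replicate.to_numpy(), experiment=g.experiment_id.to_numpy(),
        ))

    plates = []
    bind = df[df.pathway.astype(str).str.startswith("binding")]
    for (lig, var, pw, exp), g in bind.groupby(
            ["ligand", "variant", "pathway", "experiment_id"], sort=True):
        mode = pw.split(":", 1)[1]
        s = g[g.role == "sample"]
        if (s.conc_M <= 0).any():
            raise PlateFormatError("non-positive cold concentration on binding sample well")
        hot_concs = np.array(sorted(s.hot_conc_M.unique()))
        total = {float(L): g[(g.role == "total") & (g.hot_conc_M == L)].readout.to_numpy()
                 for L in hot_concs}
        nsb = {float(L): g[(g.role == "nsb") & (g.hot_conc_M == L)].readout.to_numpy()
               for L in hot_concs}
        plates.append(BindingPlate(
            variant=var, ligand=lig, mode=mode, hot_concs=hot_concs,
            cold_conc=s.conc_M.to_numpy(), hot_conc=s.hot_conc_M.to_numpy(),
            cpm=s.readout.to_numpy(), total_cpm=total, nsb_cpm=nsb,
        ))

    expression: dict[str, list[ExpressionRecord]] = {}
    facs = df[df.pathway == "FACS"]
    for (var, exp), g in facs.groupby(["variant", "experiment_id"], sort=True):
        for rep, gr in g.groupby("replicate"):
            par = gr[gr.ligand == "parental"].readout
            wt = gr[gr.ligand == "WT-anchor"].readout
            sm = gr[gr.role == "sample"].readout
            if len(par) != 1 or len(wt) != 1 or len(sm) != 1:
                raise PlateFormatError(f"incomplete FACS record for {var!r}")
            expression.setdefault(var, []).append(ExpressionRecord(
                MFI_parental=float(par.iloc[0]), MFI_WT=float(wt.iloc[0]),
                MFI_sample=float(sm.iloc[0]),
            ))

    return {"curves": curves, "plates": plates, "expression": expression}
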