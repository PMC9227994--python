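"""Pipeline orchestration: CSV in, result tables + markdown report out.

``run_pipeline`` wires the pieces together the way the wet-lab workflow does:
(optional) calibration converts detector responses to concentrations, the
transport table is fitted as a :class:`~permkit.study.TransportStudy`, TEER
readings gate the wells, and the aggregate tables are written as CSVs next to
a markdown report.  Every number in the report is recomputable from the
emitted CSVs, and a rerun with the same inputs, config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .calibration import CalibrationModel, CalibrationResults
from .config import PipelineConfig
from .qc import TeerReading, teer_normalize
from .study import TransportStudy, TransportStudyResults

__all__ = ["run_pipeline", "render_report", "quantify_transport_table",
           "teer_qc_table"]


def quantify_transport_table(transport: pd.DataFrame,
                             calibration: CalibrationResults) -> pd.DataFrame:
    """Convert a transport table carrying raw detector responses
    (column ``response``) into concentrations via the calibration line.

    Sub-LLOQ back-calculations become empty cells (the censored convention of
    the transport schema).
    """
    if "response" not in transport.columns:
        raise ValueError("transport table has no 'response' column to quantify")
    out = transport.copy()

    def _conc(resp):
        val = calibration.back_calculate(float(resp))
        return "" if not isinstance(val, float) else val

    out["conc_ug_per_ml"] = out["response"].map(_conc)
    return out.drop(columns=["response"])


def teer_qc_table(teer: pd.DataFrame, area: float) -> pd.DataFrame:
    """Per-well TEER normalisation and pass/fail (teer.csv schema)."""
    rows = []
    for _, r in teer.iterrows():
        res = teer_normalize(TeerReading(
            measured=float(r["measured_ohm"]),
            background=float(r["background_ohm"]),
            area=area, day=int(r.get("day", 0))))
        rows.append({
            "well_id": r["well_id"], "day": r.get("day", 0),
            "teer_ohm_cm2": res.teer_ohm_cm2,
            "passed": res.passed, "valid": res.valid,
        })
    return pd.DataFrame(rows)


def _fmt_papp(mean, sd, n_available) -> str:
    if n_available == 0 or pd.isna(mean):
        return "N.A."
    return f"{mean * 1e6:.1f} ± {sd * 1e6:.1f}"


def render_report(results: TransportStudyResults,
                  teer_qc: "pd.DataFrame | None" = None) -> str:
    """Markdown report: Papp table with ER and significance marks, recovery
    and deconjugation fold-changes.

    Stars compare B→A against A→B within an arm (p < 0.05/0.01/0.001 →
    `*`/`**`/`***`); hash marks compare a dose against the lowest dose of its
    family the same way.  "N.A." denotes an arm fully below the LLOQ
    (non-absorbed).
    """
    papp = results.papp_table()
    lines = ["# Bidirectional permeability report", ""]
    lines += ["## Apparent permeability (Papp × 10⁻⁶ cm/s, mean ± SD)", ""]
    lines += ["| Dose | Arm | Papp A-B | Papp B-A | ER |",
              "| --- | --- | --- | --- | --- |"]
    for (dose, deconj), _ in papp.groupby(["dose_label", "deconjugated"],
                                          sort=True):
        cells = {}
        for direction in ("AB", "BA"):
            sel = papp[(papp["dose_label"] == dose)
                       & (papp["deconjugated"] == deconj)
                       & (papp["direction"] == direction)]
            if len(sel) == 0:
                cells[direction] = "-"
                continue
            txt = _fmt_papp(sel["papp_mean_cm_per_s"].iloc[0],
                            sel["papp_sd_cm_per_s"].iloc[0],
                            sel["n_available"].iloc[0])
            if txt != "N.A.":
                if direction == "BA":
                    txt += f" {results.direction_test(dose, deconj).stars}"
                ref = results.dose_reference(dose)
                if ref is not None:
                    txt += "#" * len(results.dose_test(
                        dose, ref, direction, deconj).stars)
            cells[direction] = txt.strip()
        summ = results.efflux_summary(dose, deconj)
        er = "-" if summ.er is None else f"{summ.er_rounded:.1f}"
        arm = "after deconjugation" if deconj else "before deconjugation"
        lines.append(f"| {dose} | {arm} | {cells['AB']} | {cells['BA']} | {er} |")

    rec = results.recovery_table()
    lines += ["", "## Basolateral recovery (% of initial donor amount)", ""]
    lines += ["| Dose | Arm | Recovery |", "| --- | --- | --- |"]
    for _, r in rec.iterrows():
        arm = "after deconjugation" if r["deconjugated"] else "before deconjugation"
        val = ("N.A." if r["n_available"] == 0 or pd.isna(r["recovery_mean_pct"])
               else f"{r['recovery_mean_pct']:.1f} ± {r['recovery_sd_pct']:.1f} %")
        lines.append(f"| {r['dose_label']} | {arm} | {val} |")

    lines += ["", "## Deconjugation fold-changes (after/before, paired t)", ""]
    lines += ["| Dose | Direction | Metric | Fold | p | |",
              "| --- | --- | --- | --- | --- | --- |"]
    doses = sorted(results.run_table["dose_label"].unique())
    for dose in doses:
        for direction in ("AB", "BA"):
            cmp = results.deconjugation_comparison(dose, direction, "papp")
            fold = "-" if cmp.fold is None else f"{cmp.fold:.2f}"
            p = ("-" if not cmp.test.evaluable
                 else f"{cmp.test.p_value:.4g}")
            lines.append(f"| {dose} | {direction} | papp | {fold} | {p} |"
                         f" {cmp.test.stars} |")

    if teer_qc is not None and len(teer_qc):
        n_pass = int(teer_qc["passed"].sum())
        lines += ["", "## Monolayer QC",
                  "",
                  f"{n_pass}/{len(teer_qc)} wells passed the "
                  f"TEER ≥ 400 Ω·cm² gate."]
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig,
                 transport_csv: "str | Path",
                 standards_csv: "str | Path | None" = None,
                 teer_csv: "str | Path | None" = None,
                 out_dir: "str | Path | None" = None) -> dict:
    """Run the full analysis and write the result directory.

    Emits ``papp.csv``, ``er.csv``, ``recovery.csv``, ``qc.csv``,
    ``report.md`` and ``run.log``.  Returns the in-memory results dict
    (results object + tables) for programmatic use.
    """
    transport = pd.read_csv(transport_csv)
    calibration = None
    if standards_csv is not None:
        calibration = CalibrationModel.from_dataframe(
            pd.read_csv(standards_csv),
            weighting=config.calibration.weighting).fit()
        if "response" in transport.columns:
            transport = quantify_transport_table(transport, calibration)

    study = TransportStudy(transport, config=config)
    results = study.fit()

    teer_qc = None
    if teer_csv is not None:
        teer_qc = teer_qc_table(pd.read_csv(teer_csv),
                                area=config.geometry.area_cm2)

    report = render_report(results, teer_qc)
    out = {
        "results": results,
        "calibration": calibration,
        "papp": results.papp_table(),
        "er": results.efflux_table(),
        "recovery": results.recovery_table(),
        "runs": results.run_table,
        "teer_qc": teer_qc,
        "report": report,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out["papp"].to_csv(out_dir / "papp.csv", index=False)
        out["er"].to_csv(out_dir / "er.csv", index=False)
        out["recovery"].to_csv(out_dir / "recovery.csv", index=False)
        out["runs"].to_csv(out_dir / "runs.csv", index=False)
        if teer_qc is not None:
            teer_qc.to_csv(out_dir / "qc.csv", index=False)
        else:
            pd.DataFrame(columns=["well_id", "teer_ohm_cm2", "passed"]) \
                .to_csv(out_dir / "qc.csv", index=False)
        (out_dir / "report.md").write_text(report)
        cfg_yaml = config.to_yaml()
        log = "\n".join([
            "permkit run log",
            f"transport: {transport_csv}",
            f"standards: {standards_csv}",
            f"teer: {teer_csv}",
            f"config sha256: {hashlib.sha256(cfg_yaml.encode()).hexdigest()}",
            f"seed: {config.seed}",
            f"wells: {len(results.per_run)}",
            "",
        ])
        (out_dir / "run.log").write_text(log)
        (out_dir / "config.yaml").write_text(cfg_yaml)
    return out
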