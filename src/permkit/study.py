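"""Study-level model: a bidirectional transwell dataset → fitted results.

:class:`TransportStudy` is the entry point for a whole experiment: build it
from the long-format transport table (one row per well × timepoint), call
:meth:`~TransportStudy.fit`, and work with the returned
:class:`TransportStudyResults` — per-well permeability estimates, replicate
aggregates (mean ± SD over wells), efflux ratios, basolateral recoveries,
direction/dose significance tests and before/after-deconjugation fold
changes, plus a formatted ``summary()`` table.

Replicate aggregation is per-well-first: Papp is fitted for each well
independently and replicates are summarised afterwards; concentrations are
never pooled across wells before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .censoring import Censored, is_censored
from .config import PipelineConfig
from .simulate import ENZYME_DILUTION_FACTOR
from .stats import (DeconjugationComparison, TestResult, compare_deconjugation,
                    group_compare)
from .transport import (Direction, EffluxSummary, PermeabilityResult,
                        TransportRun, analyze_run, efflux_ratio)

__all__ = ["TransportStudy", "TransportStudyResults"]

REQUIRED_COLUMNS = ("run_id", "dose_label", "direction", "deconjugated",
                    "c0_ug_per_ml", "time_min", "conc_ug_per_ml", "replicate")


def _dose_family(label: str) -> str:
    """Dose-group family used for high-vs-low-dose comparisons
    ("extract-250" → "extract")."""
    return label.rsplit("-", 1)[0] if "-" in label else label


class TransportStudy:
    """Model object for one bidirectional permeability study.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format transport table with columns ``run_id, dose_label,
        direction, deconjugated, c0_ug_per_ml, time_min, conc_ug_per_ml,
        replicate``.  An empty/NaN concentration cell is a below-LLOQ
        (censored) measurement.
    config : PipelineConfig, optional
        Geometry, flux-window, censoring and statistics options.
    """

    def __init__(self, data: pd.DataFrame,
                 config: "PipelineConfig | None" = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"transport table is missing columns: {missing}")
        self.config = config or PipelineConfig()
        self.data = data.copy()
        self.geometry = self.config.geometry.to_geometry()
        self.runs = self._build_runs()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "TransportStudy":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TransportStudy":
        return cls(pd.read_csv(path), **kwargs)

    def _build_runs(self) -> list[tuple[TransportRun, int]]:
        cfg = self.config
        runs: list[tuple[TransportRun, int]] = []
        for run_id, grp in self.data.groupby("run_id", sort=True):
            grp = grp.sort_values("time_min")
            deconj = bool(int(grp["deconjugated"].iloc[0]))
            correction = (ENZYME_DILUTION_FACTOR
                          if deconj and cfg.deconjugation_dilution_correction
                          else 1.0)
            timepoints: list[tuple[float, "float | Censored"]] = []
            for _, row in grp.iterrows():
                raw = row["conc_ug_per_ml"]
                if raw is None or (isinstance(raw, str) and raw.strip() == "") \
                        or (isinstance(raw, float) and math.isnan(raw)):
                    conc: "float | Censored" = Censored(cfg.censoring.lloq)
                else:
                    conc = float(raw) * correction
                timepoints.append((float(row["time_min"]), conc))
            runs.append((
                TransportRun(
                    run_id=str(run_id),
                    direction=Direction.parse(grp["direction"].iloc[0]),
                    c0=float(grp["c0_ug_per_ml"].iloc[0]),
                    timepoints=timepoints,
                    geometry=self.geometry,
                    deconjugated=deconj,
                    dose_label=str(grp["dose_label"].iloc[0]),
                ),
                int(grp["replicate"].iloc[0]),
            ))
        return runs

    def fit(self) -> "TransportStudyResults":
        """Fit every well and assemble the study-level aggregates."""
        cfg = self.config
        per_run: list[PermeabilityResult] = []
        rows = []
        for run, replicate in self.runs:
            res = analyze_run(run, include_origin=cfg.flux.include_origin,
                              window=cfg.flux.window)
            per_run.append(res)
            rows.append({
                "run_id": res.run_id,
                "dose_label": res.dose_label,
                "direction": res.direction.value,
                "deconjugated": res.deconjugated,
                "replicate": replicate,
                "c0_ug_per_ml": run.c0,
                "papp_cm_per_s": res.papp,
                "flux_ug_per_min": res.flux,
                "flux_r_squared": res.flux_r_squared,
                "recovery_pct": res.recovery_pct,
                "sink_ok": res.sink_ok,
                "n_censored": sum(res.q_lower_bound),
            })
        table = pd.DataFrame(rows)
        return TransportStudyResults(model=self, per_run=per_run,
                                     run_table=table)


@dataclass
class TransportStudyResults:
    """Fitted permeability study.

    ``run_table`` holds one row per well (replicate-level estimates); the
    aggregate accessors summarise over replicates.  Papp entries of NaN in
    the aggregate tables mean the arm was entirely below the quantification
    limit ("N.A.": non-absorbed, not zero).
    """

    model: TransportStudy
    per_run: list[PermeabilityResult]
    run_table: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ #
    # aggregates

    def papp_table(self) -> pd.DataFrame:
        """Mean ± SD Papp over replicate wells per (dose, direction, arm)."""
        if "papp" in self._cache:
            return self._cache["papp"]
        rows = []
        for (dose, direction, deconj), grp in self.run_table.groupby(
                ["dose_label", "direction", "deconjugated"], sort=True):
            vals = grp["papp_cm_per_s"].dropna()
            rows.append({
                "dose_label": dose,
                "direction": direction,
                "deconjugated": deconj,
                "n_wells": len(grp),
                "n_available": len(vals),
                "papp_mean_cm_per_s": vals.mean() if len(vals) else np.nan,
                "papp_sd_cm_per_s": vals.std(ddof=1) if len(vals) > 1 else
                    (0.0 if len(vals) == 1 else np.nan),
            })
        out = pd.DataFrame(rows)
        self._cache["papp"] = out
        return out

    def efflux_table(self) -> pd.DataFrame:
        """Efflux ratio per (dose, arm), from the replicate-mean Papp pair."""
        papp = self.papp_table()
        rows = []
        for (dose, deconj), grp in papp.groupby(["dose_label", "deconjugated"],
                                                sort=True):
            ab = grp.loc[grp["direction"] == "AB", "papp_mean_cm_per_s"]
            ba = grp.loc[grp["direction"] == "BA", "papp_mean_cm_per_s"]
            ab = float(ab.iloc[0]) if len(ab) and not math.isnan(ab.iloc[0]) else None
            ba = float(ba.iloc[0]) if len(ba) and not math.isnan(ba.iloc[0]) else None
            summ = efflux_ratio(ab, ba)
            rows.append({
                "dose_label": dose, "deconjugated": deconj,
                "papp_ab_cm_per_s": ab, "papp_ba_cm_per_s": ba,
                "er": summ.er, "er_1dp": summ.er_rounded,
                "classification": summ.classification.value,
            })
        return pd.DataFrame(rows)

    def efflux_summary(self, dose_label: str,
                       deconjugated: bool) -> EffluxSummary:
        papp = self.papp_table()
        sel = papp[(papp["dose_label"] == dose_label)
                   & (papp["deconjugated"] == deconjugated)]
        ab = sel.loc[sel["direction"] == "AB", "papp_mean_cm_per_s"]
        ba = sel.loc[sel["direction"] == "BA", "papp_mean_cm_per_s"]
        ab = float(ab.iloc[0]) if len(ab) and not math.isnan(ab.iloc[0]) else None
        ba = float(ba.iloc[0]) if len(ba) and not math.isnan(ba.iloc[0]) else None
        return efflux_ratio(ab, ba)

    def recovery_table(self) -> pd.DataFrame:
        """Basolateral recovery (absorptive direction) per (dose, arm)."""
        ab = self.run_table[self.run_table["direction"] == "AB"]
        rows = []
        for (dose, deconj), grp in ab.groupby(["dose_label", "deconjugated"],
                                              sort=True):
            vals = grp["recovery_pct"].dropna()
            rows.append({
                "dose_label": dose, "deconjugated": deconj,
                "n_wells": len(grp), "n_available": len(vals),
                "recovery_mean_pct": vals.mean() if len(vals) else np.nan,
                "recovery_sd_pct": vals.std(ddof=1) if len(vals) > 1 else
                    (0.0 if len(vals) == 1 else np.nan),
            })
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ #
    # statistics

    def _replicate_papps(self, dose: str, direction: str,
                         deconj: bool) -> pd.Series:
        t = self.run_table
        sel = t[(t["dose_label"] == dose) & (t["direction"] == direction)
                & (t["deconjugated"] == deconj)].sort_values("replicate")
        return sel.set_index("replicate")["papp_cm_per_s"]

    def direction_test(self, dose_label: str, deconjugated: bool) -> TestResult:
        """Student's t between B→A and A→B replicate Papp within one arm."""
        ab = self._replicate_papps(dose_label, "AB", deconjugated).dropna()
        ba = self._replicate_papps(dose_label, "BA", deconjugated).dropna()
        return group_compare(ab, ba, welch=self.model.config.stats.welch)

    def dose_test(self, dose_label: str, reference_label: str,
                  direction: str, deconjugated: bool) -> TestResult:
        """Student's t between a dose and its reference dose (same arm)."""
        a = self._replicate_papps(dose_label, direction, deconjugated).dropna()
        b = self._replicate_papps(reference_label, direction, deconjugated).dropna()
        return group_compare(a, b, welch=self.model.config.stats.welch)

    def dose_reference(self, dose_label: str) -> "str | None":
        """Lowest-dose arm of the same family (extract/pure), or None if
        *dose_label* is itself the reference."""
        fam = _dose_family(dose_label)
        t = self.run_table
        labels = sorted(set(t.loc[t["dose_label"].map(_dose_family) == fam,
                                  "dose_label"]))
        if len(labels) < 2:
            return None
        c0 = {lab: t.loc[t["dose_label"] == lab, "c0_ug_per_ml"].iloc[0]
              for lab in labels}
        ref = min(labels, key=lambda lab: c0[lab])
        return None if ref == dose_label else ref

    def deconjugation_comparison(self, dose_label: str, direction: str,
                                 metric: str = "papp") -> DeconjugationComparison:
        """Matched before/after-deconjugation fold change and paired t-test.

        Wells are matched by replicate number; replicates censored on either
        side are dropped from the pairing.  metric: "papp" or "recovery".
        """
        col = "papp_cm_per_s" if metric == "papp" else "recovery_pct"
        t = self.run_table
        before = t[(t["dose_label"] == dose_label) & (t["direction"] == direction)
                   & (~t["deconjugated"])].set_index("replicate")[col]
        after = t[(t["dose_label"] == dose_label) & (t["direction"] == direction)
                  & (t["deconjugated"])].set_index("replicate")[col]
        common = before.dropna().index.intersection(after.dropna().index)
        return compare_deconjugation(before.loc[common], after.loc[common],
                                     metric=metric)

    # ------------------------------------------------------------------ #
    # presentation

    def summary(self) -> str:
        """Formatted study summary in the conventional reporting layout.

        Papp is shown as value × 10⁻⁶ cm/s (mean ± SD over wells, one
        decimal), ER to one decimal, with * / ** / *** marking B→A vs A→B
        significance at p < 0.05 / 0.01 / 0.001 and # marks for
        high-vs-low-dose differences.  "N.A." marks arms entirely below the
        LLOQ (non-absorbed).
        """
        papp = self.papp_table()
        lines = ["Bidirectional permeability summary",
                 "Papp in 1e-6 cm/s, mean +/- SD over replicate wells",
                 ""]
        hdr = (f"{'dose':<14}{'arm':<8}{'Papp A-B':<18}{'Papp B-A':<20}"
               f"{'ER':<6}{'class':<26}")
        lines += [hdr, "-" * len(hdr)]
        for (dose, deconj), _ in papp.groupby(["dose_label", "deconjugated"],
                                              sort=True):
            cells = {}
            for direction in ("AB", "BA"):
                sel = papp[(papp["dose_label"] == dose)
                           & (papp["deconjugated"] == deconj)
                           & (papp["direction"] == direction)]
                if len(sel) == 0 or sel["n_available"].iloc[0] == 0:
                    cells[direction] = "N.A."
                    continue
                m = sel["papp_mean_cm_per_s"].iloc[0] * 1e6
                s = sel["papp_sd_cm_per_s"].iloc[0] * 1e6
                txt = f"{m:.1f} +/- {s:.1f}"
                if direction == "BA":
                    txt += f" {self.direction_test(dose, deconj).stars}"
                ref = self.dose_reference(dose)
                if ref is not None:
                    hashes = self.dose_test(dose, ref, direction, deconj)
                    txt += "#" * len(hashes.stars)
                cells[direction] = txt.strip()
            summ = self.efflux_summary(dose, deconj)
            er = "-" if summ.er is None else f"{summ.er_rounded:.1f}"
            lines.append(f"{dose:<14}{('post' if deconj else 'pre'):<8}"
                         f"{cells['AB']:<18}{cells['BA']:<20}{er:<6}"
                         f"{summ.classification.value:<26}")
        return "\n".join(lines)
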