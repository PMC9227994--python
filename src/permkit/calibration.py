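"""Bioanalytical calibration: response → concentration with EMA-style gates.

A detector (HPLC-PDA peak area, absorbance, ...) responds linearly to analyte
concentration over the validated range, ``y = a·x + b``.  The model here is a
plain unweighted ordinary-least-squares line (optionally 1/x or 1/x² weighted)
fitted to calibration standards, exposed statsmodels-style: build a
:class:`CalibrationModel` from standards, call :meth:`~CalibrationModel.fit`,
and get a :class:`CalibrationResults` that back-calculates concentrations,
applies LLOQ censoring, and runs the ±15 % / ±20 %-at-LLOQ accuracy gate.

The LLOQ is the lowest non-blank standard; the LLOD follows the 5×-blank-signal
rule when blanks are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .censoring import Censored

__all__ = [
    "CalibrationStandard",
    "CalibrationModel",
    "CalibrationResults",
    "fit_calibration",
    "llod_from_blank",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: nominal concentration and detector response."""

    nominal_conc: float  # µg/mL
    response: float      # detector units
    run_id: str = ""
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.nominal_conc < 0:
            raise ValueError("nominal_conc must be >= 0")
        if self.is_blank and self.nominal_conc != 0:
            raise ValueError("a blank standard must have nominal_conc == 0")


class CalibrationError(ValueError):
    """Calibration design or input problem."""


def _split(standards: Sequence[CalibrationStandard]):
    cal = [s for s in standards if not s.is_blank]
    blanks = [s for s in standards if s.is_blank]
    return cal, blanks


class CalibrationModel:
    """Linear calibration model ``response = slope·conc + intercept``.

    Parameters
    ----------
    standards : sequence of CalibrationStandard
        At least three non-blank standards at distinct concentrations.
    weighting : {"none", "1/x", "1/x2"}
        Regression weighting.  Unweighted OLS is the default, matching plain
        linear-regression practice for HPLC-PDA calibration.
    """

    def __init__(self, standards: Sequence[CalibrationStandard],
                 weighting: str = "none"):
        if weighting not in ("none", "1/x", "1/x2"):
            raise CalibrationError(f"unknown weighting {weighting!r}")
        cal, blanks = _split(standards)
        if len({s.nominal_conc for s in cal}) < 3:
            raise CalibrationError(
                "need >= 3 non-blank standards at distinct concentrations")
        x = np.array([s.nominal_conc for s in cal], dtype=float)
        if np.ptp(x) == 0:
            raise CalibrationError("zero variance in nominal concentrations")
        self.standards = list(cal)
        self.blanks = list(blanks)
        self.weighting = weighting

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CalibrationModel":
        """Build from the ``standards.csv`` schema
        (nominal_conc_ug_per_ml, response, run_id, is_blank)."""
        std = [
            CalibrationStandard(
                nominal_conc=float(r["nominal_conc_ug_per_ml"]),
                response=float(r["response"]),
                run_id=str(r.get("run_id", "")),
                is_blank=bool(int(r.get("is_blank", 0))),
            )
            for r in df.to_dict("records")
        ]
        return cls(std, **kwargs)

    def fit(self) -> "CalibrationResults":
        x = np.array([s.nominal_conc for s in self.standards], dtype=float)
        y = np.array([s.response for s in self.standards], dtype=float)
        if self.weighting == "none":
            res = stats.linregress(x, y)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
        else:
            w = 1.0 / x if self.weighting == "1/x" else 1.0 / x ** 2
            W = np.diag(w)
            X = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            slope, intercept = beta
            yhat = X @ beta
            ybar = np.average(y, weights=w)
            ss_res = np.sum(w * (y - yhat) ** 2)
            ss_tot = np.sum(w * (y - ybar) ** 2)
            r2 = 1.0 - ss_res / ss_tot
        lloq = float(np.min(x))
        warn: list[str] = []
        if self.blanks and slope > 0:
            llod = llod_from_blank([b.response for b in self.blanks],
                                   slope, intercept)
            if llod > lloq:
                warn.append(f"LLOD {llod:g} exceeds LLOQ {lloq:g}")
        else:
            llod = lloq
        return CalibrationResults(
            model=self, slope=float(slope), intercept=float(intercept),
            r_squared=float(r2), lloq=lloq, llod=float(llod),
            warnings=warn,
        )


@dataclass
class CalibrationResults:
    """Fitted calibration line with quantification limits.

    ``slope`` is detector response per (µg/mL); ``lloq``/``llod`` are in
    µg/mL.  ``validated`` requires a positive slope (a detector that responds
    inversely to concentration is not a usable assay here).
    """

    model: CalibrationModel
    slope: float
    intercept: float
    r_squared: float
    lloq: float
    llod: float
    warnings: list[str] = field(default_factory=list)

    @property
    def validated(self) -> bool:
        return self.slope > 0 and 0 <= self.llod and self.r_squared >= 0

    def predict_response(self, conc: float) -> float:
        """Detector response the line predicts at *conc* µg/mL."""
        return self.slope * conc + self.intercept

    def back_calculate(self, response: float,
                       apply_lloq: bool = True) -> "float | Censored":
        """Convert a detector response to concentration (µg/mL).

        Values below the LLOQ are returned as :class:`Censored` markers when
        *apply_lloq* is set; they never enter flux regressions downstream.
        """
        if not self.validated:
            raise CalibrationError("cannot back-calculate from an unvalidated curve")
        if not math.isfinite(response):
            raise CalibrationError(f"non-finite response {response!r}")
        conc = (response - self.intercept) / self.slope
        if apply_lloq and conc < self.lloq:
            return Censored(self.lloq)
        return float(conc)

    def accuracy_report(self,
                        standards: "Iterable[CalibrationStandard] | None" = None,
                        qc_tolerance: float = 0.15,
                        lloq_tolerance: float = 0.20) -> pd.DataFrame:
        """Per-level back-calculation accuracy with EMA-style pass/fail.

        Relative error must stay within ±15 % at every level except the LLOQ,
        where ±20 % is allowed.  Returns one row per concentration level with
        columns nominal, back_calculated, rel_error_pct, tolerance_pct, ok.
        """
        standards = self.model.standards if standards is None else list(standards)
        rows = []
        for s in standards:
            if s.is_blank:
                continue
            back = self.back_calculate(s.response, apply_lloq=False)
            err = (back - s.nominal_conc) / s.nominal_conc
            tol = lloq_tolerance if math.isclose(s.nominal_conc, self.lloq) else qc_tolerance
            rows.append({
                "nominal_conc_ug_per_ml": s.nominal_conc,
                "back_calculated_ug_per_ml": back,
                "rel_error_pct": 100.0 * err,
                "tolerance_pct": 100.0 * tol,
                "ok": abs(err) <= tol,
            })
        report = pd.DataFrame(rows).sort_values(
            "nominal_conc_ug_per_ml", kind="stable").reset_index(drop=True)
        return report

    def accuracy_ok(self, **kwargs) -> bool:
        """True iff every level passes the accuracy gate."""
        return bool(self.accuracy_report(**kwargs)["ok"].all())

    def summary(self) -> str:
        lines = [
            "Calibration line: response = slope * conc + intercept",
            f"  slope      {self.slope:.6g}  (per µg/mL)",
            f"  intercept  {self.intercept:.6g}",
            f"  r^2        {self.r_squared:.6f}",
            f"  LLOQ       {self.lloq:g} µg/mL",
            f"  LLOD       {self.llod:g} µg/mL",
            f"  validated  {self.validated}",
        ]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def fit_calibration(standards: Sequence[CalibrationStandard],
                    weighting: str = "none") -> CalibrationResults:
    """Convenience wrapper: ``CalibrationModel(standards).fit()``."""
    return CalibrationModel(standards, weighting=weighting).fit()


def llod_from_blank(blank_responses: Sequence[float],
                    slope: float, intercept: float) -> float:
    """Detection limit from the 5×-blank-signal rule.

    The LLOD is the smallest concentration whose predicted response is at
    least five times the mean blank response, solved from the calibration
    line and floored at zero.
    """
    blanks = list(blank_responses)
    if not blanks:
        raise CalibrationError("need at least one blank response")
    if slope <= 0:
        raise CalibrationError("LLOD requires a positive calibration slope")
    target = 5.0 * float(np.mean(blanks))
    return max(0.0, (target - intercept) / slope)
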