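"""Transwell transport arithmetic: cumulative amounts, flux, Papp, ER, recovery.

The transwell protocol samples the receiver chamber repeatedly, replacing each
aliquot with blank buffer.  The receiver concentration measured at the n-th
timepoint therefore under-reports the transported mass: the aliquots removed
at earlier timepoints carried mass out of the chamber.  The cumulative
transported amount is reconstructed as

    Q_n = C_n · V + Σ_{i<n} C_i · S

with V the receiver volume and S the aliquot volume.  Steady-state flux dQ/dt
comes from an OLS line through the (t, Q) points, and the apparent
permeability coefficient is

    Papp = (dQ/dt) / (C_0 · A)        [cm/s]

with C_0 the initial donor concentration and A the insert area.  The efflux
ratio ER = Papp(B→A) / Papp(A→B) classifies transport as passive (ER < 2) or
efflux-suspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .censoring import Censored, is_censored

__all__ = [
    "Direction", "TranswellGeometry", "TransportRun", "PermeabilityResult",
    "EffluxSummary", "cumulative_amount", "estimate_flux", "papp",
    "efflux_ratio", "basolateral_recovery", "analyze_run",
    "SINK_FRACTION", "ER_EFFLUX_THRESHOLD",
]

#: Conventional sink-condition criterion: final receiver concentration should
#: stay below this fraction of the donor concentration.
SINK_FRACTION = 0.10

#: Efflux ratios at or above this value suggest carrier-mediated efflux.
ER_EFFLUX_THRESHOLD = 2.0


class Direction(str, Enum):
    """Transport direction across the monolayer."""

    AB = "AB"  # apical → basolateral (absorptive)
    BA = "BA"  # basolateral → apical (secretory)

    @classmethod
    def parse(cls, value: "str | Direction") -> "Direction":
        if isinstance(value, cls):
            return value
        v = str(value).strip().upper().replace("-", "").replace("_", "")
        v = v.replace("TO", "")
        if v in ("AB", "A2B"):
            return cls.AB
        if v in ("BA", "B2A"):
            return cls.BA
        raise ValueError(f"unrecognised direction {value!r}")


@dataclass(frozen=True)
class TranswellGeometry:
    """Insert geometry and the sampling protocol volumes.

    Defaults are the 24-transwell format used throughout: 1.12 cm² insert,
    400 µL apical / 1200 µL basolateral chamber volumes, with 200 µL / 600 µL
    aliquots withdrawn and replaced at each sampling time.
    """

    area: float = 1.12                 # cm²
    volume_apical: float = 0.4         # mL
    volume_basolateral: float = 1.2    # mL
    aliquot_apical: float = 0.2        # mL
    aliquot_basolateral: float = 0.6   # mL

    def __post_init__(self) -> None:
        for name in ("area", "volume_apical", "volume_basolateral",
                     "aliquot_apical", "aliquot_basolateral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.aliquot_apical > self.volume_apical:
            raise ValueError("apical aliquot exceeds apical volume")
        if self.aliquot_basolateral > self.volume_basolateral:
            raise ValueError("basolateral aliquot exceeds basolateral volume")

    def receiver_volumes(self, direction: Direction) -> tuple[float, float]:
        """(receiver volume V, aliquot S) in mL for a run in *direction*."""
        direction = Direction.parse(direction)
        if direction is Direction.AB:
            return self.volume_basolateral, self.aliquot_basolateral
        return self.volume_apical, self.aliquot_apical

    def donor_volume(self, direction: Direction) -> float:
        direction = Direction.parse(direction)
        return (self.volume_apical if direction is Direction.AB
                else self.volume_basolateral)


@dataclass
class TransportRun:
    """One well × one direction of a transwell transport experiment.

    ``timepoints`` is an ordered list of (time in minutes, receiver
    concentration in µg/mL); concentrations may be :class:`Censored` markers
    for sub-LLOQ measurements.
    """

    run_id: str
    direction: Direction
    c0: float  # donor concentration, µg/mL
    timepoints: "list[tuple[float, float | Censored]]"
    geometry: TranswellGeometry = field(default_factory=TranswellGeometry)
    deconjugated: bool = False
    dose_label: str = ""

    def __post_init__(self) -> None:
        self.direction = Direction.parse(self.direction)
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        times = [t for t, _ in self.timepoints]
        if any(t <= 0 for t in times):
            raise ValueError("sampling times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        for _, c in self.timepoints:
            if not is_censored(c) and c < 0:
                raise ValueError("concentrations must be >= 0 or censored")


@dataclass
class PermeabilityResult:
    """Per-run permeability estimate and diagnostics.

    ``q_series`` is the aliquot-corrected cumulative transported amount (µg)
    at each sampling time; entries reconstructed from series containing
    censored measurements are lower bounds (``q_lower_bound`` flags them).
    ``papp`` is None when the receiver series had fewer than two quantifiable
    points (the not-available / "N.A." path).
    """

    run_id: str
    direction: Direction
    dose_label: str
    deconjugated: bool
    q_series: list[tuple[float, float]]
    q_lower_bound: list[bool]
    flux: "float | None"           # µg/min
    flux_r_squared: "float | None"
    papp: "float | None"           # cm/s
    sink_ok: bool
    recovery_pct: "float | None"
    mass_balance_pct: "float | None" = None

    @property
    def available(self) -> bool:
        return self.papp is not None


class Classification(str, Enum):
    PASSIVE = "passive/no-active-efflux"
    EFFLUX = "efflux-suspected"
    NOT_EVALUABLE = "not-evaluable"


@dataclass(frozen=True)
class EffluxSummary:
    """Bidirectional permeability pair and its efflux ratio."""

    papp_ab: "float | None"
    papp_ba: "float | None"
    er: "float | None"
    classification: Classification

    @property
    def er_rounded(self) -> "float | None":
        """ER at the one-decimal reporting precision."""
        return None if self.er is None else round(self.er, 1)


def cumulative_amount(run: TransportRun) -> tuple[list[tuple[float, float]], list[bool]]:
    """Aliquot-corrected cumulative transported amount Q(t).

    Q_n = C_n·V + Σ_{i=1..n-1} C_i·S: the mass currently resident in the
    receiver plus the mass carried away by all earlier aliquots.  Censored
    concentrations contribute zero, and every Q from the first censored
    point onward is flagged as a lower bound.

    Returns (q_series, lower_bound_flags).
    """
    V, S = run.geometry.receiver_volumes(run.direction)
    q_series: list[tuple[float, float]] = []
    flags: list[bool] = []
    removed = 0.0          # mass carried out by earlier aliquots, µg
    any_censored = False
    for t, c in run.timepoints:
        if is_censored(c):
            any_censored = True
            conc = 0.0
        else:
            conc = float(c)
        q_series.append((t, conc * V + removed))
        flags.append(any_censored or is_censored(c))
        removed += conc * S
    return q_series, flags


def estimate_flux(q_series: Sequence[tuple[float, float]],
                  usable: "Sequence[bool] | None" = None,
                  include_origin: bool = False) -> "tuple[float, float] | None":
    """OLS steady-state flux dQ/dt (µg/min) and its r² from a Q(t) series.

    Points flagged unusable (censored provenance) are dropped.  The origin
    (0, 0) is not forced by default: a loading lag makes a forced-origin fit
    biased.  Returns None when fewer than two usable points remain.
    """
    pts = [(t, q) for i, (t, q) in enumerate(q_series)
           if usable is None or usable[i]]
    if include_origin:
        pts = [(0.0, 0.0)] + pts
    if len(pts) < 2:
        return None
    t = np.array([p[0] for p in pts], dtype=float)
    q = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(t) == 0:
        return None
    res = stats.linregress(t, q)
    # r is nan for a perfectly horizontal fit (zero variance in q): define r²=1,
    # the line explains everything there is to explain.
    r2 = 1.0 if math.isnan(res.rvalue) else res.rvalue ** 2
    return float(res.slope), float(r2)


def papp(flux: "float | None", c0: float, area: float) -> "float | None":
    """Apparent permeability coefficient, cm/s.

    Papp = (dQ/dt) / (C0 · A) with dQ/dt converted from µg/min to µg/s;
    µg/s over (µg/cm³ · cm²) yields cm/s (1 mL ≡ 1 cm³).
    """
    if flux is None:
        return None
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    return (flux / 60.0) / (c0 * area)


def efflux_ratio(papp_ab: "float | None",
                 papp_ba: "float | None") -> EffluxSummary:
    """Efflux ratio ER = Papp(B→A)/Papp(A→B) with the passive/efflux call.

    ER < 2 is read as passive transport with no active efflux; ER ≥ 2 as
    efflux-suspected.  Missing or zero A→B permeability makes the pair
    not-evaluable.  Classification uses the unrounded ratio.
    """
    if papp_ab is None or papp_ba is None or papp_ab <= 0:
        return EffluxSummary(papp_ab, papp_ba, None, Classification.NOT_EVALUABLE)
    er = papp_ba / papp_ab
    cls = (Classification.PASSIVE if er < ER_EFFLUX_THRESHOLD
           else Classification.EFFLUX)
    return EffluxSummary(papp_ab, papp_ba, float(er), cls)


def basolateral_recovery(run: TransportRun, q_final: float) -> float:
    """Receiver-side recovery: 100 · Q(final) / initial donor amount (%)."""
    donor_amount = run.c0 * run.geometry.donor_volume(run.direction)
    if donor_amount <= 0:
        raise ValueError("initial donor amount must be positive")
    return 100.0 * q_final / donor_amount


def mass_balance(run: TransportRun, q_final: float,
                 donor_remaining: float) -> float:
    """Companion mass-balance metric: 100 · (donor residual + Q(final)) /
    initial donor amount.  *donor_remaining* is in µg."""
    donor_amount = run.c0 * run.geometry.donor_volume(run.direction)
    if donor_amount <= 0:
        raise ValueError("initial donor amount must be positive")
    return 100.0 * (donor_remaining + q_final) / donor_amount


def analyze_run(run: TransportRun,
                include_origin: bool = False,
                donor_remaining: "float | None" = None,
                window: "tuple[float, float] | None" = None) -> PermeabilityResult:
    """Full per-run analysis: Q(t) reconstruction, flux fit, Papp, recovery.

    *window* restricts the flux regression to sampling times within
    ``[window[0], window[1]]`` minutes (the Q series itself is always full
    length).  A run whose receiver series has fewer than two quantifiable
    timepoints yields ``papp=None`` — the not-available path that mirrors
    reporting a fully sub-LLOQ compound as non-absorbed rather than as zero
    flux.
    """
    q_series, lb = cumulative_amount(run)
    usable = [not is_censored(c)
              and (window is None or window[0] <= t <= window[1])
              for t, c in run.timepoints]
    fit = estimate_flux(q_series, usable=usable, include_origin=include_origin)
    if fit is None:
        flux = r2 = p = None
    else:
        flux, r2 = fit
        p = papp(flux, run.c0, run.geometry.area)
        if p is not None and p < 0:
            p = 0.0  # noise can drive a near-zero slope negative; floor at 0
    # sink check on the final quantifiable receiver concentration
    final_conc = next((float(c) for _, c in reversed(run.timepoints)
                       if not is_censored(c)), 0.0)
    sink_ok = final_conc < SINK_FRACTION * run.c0
    recovery = None
    balance = None
    if q_series and not lb[-1]:
        recovery = basolateral_recovery(run, q_series[-1][1])
        if donor_remaining is not None:
            balance = mass_balance(run, q_series[-1][1], donor_remaining)
    return PermeabilityResult(
        run_id=run.run_id, direction=run.direction,
        dose_label=run.dose_label, deconjugated=run.deconjugated,
        q_series=q_series, q_lower_bound=lb,
        flux=flux, flux_r_squared=r2, papp=p,
        sink_ok=sink_ok, recovery_pct=recovery, mass_balance_pct=balance,
    )
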