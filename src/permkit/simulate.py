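"""Mechanistic transwell simulator with intracellular phase-II conjugation.

The model is a three-compartment mass balance for one insert: donor chamber,
cell monolayer, receiver chamber.  The parent compound crosses the two cell
membranes by passive, gradient-driven diffusion; inside the cell it is
conjugated (glucuronidation/sulfation) by a saturable Michaelis–Menten step;
the polar conjugate cannot diffuse back and leaves the cell via carrier-like
export, preferentially toward the basolateral side.

    donor  --P--> cell(parent) --P--> receiver
                      | Vmax·C/(Km+C)
                      v
                  cell(conjugate) --export--> basolateral / apical

``papp_parent_ab``/``papp_parent_ba`` are the *overall monolayer* apparent
permeabilities: with two equal membranes in series, each membrane is assigned
permeability 2·Papp so that a pure-passive run in the sink regime recovers
exactly the nominal Papp.

This regime structure reproduces, qualitatively, the hallmarks of a compound
that is extensively conjugated during epithelial transit: parent below the
quantification limit in the receiver while total (parent + conjugate) drug is
readily measurable after enzymatic deconjugation; dose-disproportionate
totals when the conjugation step saturates; and a sub-unity efflux ratio for
totals when conjugate export favours the basolateral membrane.

Integration is fixed-step classical Runge–Kutta (RK4): deterministic,
reproducible, and accurate enough that halving the step changes compartment
masses by far less than 0.1 %.  Negative masses (a step too large for the
fastest rate in the system) raise :class:`StepSizeError`.

The sampling protocol — withdraw an aliquot from the receiver at each
timepoint and replace it with blank buffer — is applied exactly, and every
withdrawn mass is logged to a ledger so that the aliquot-corrected
cumulative-amount reconstruction can be checked against the true transported
mass to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .censoring import Censored, censor
from .transport import Direction, TranswellGeometry

__all__ = [
    "SimulationParams", "SimState", "StudyDesign", "DoseArm",
    "TranswellSimulation", "SampledRun",
    "simulate_transport", "apply_sampling", "apply_noise_and_lloq",
    "simulate_deconjugation_assay", "generate_study",
    "StepSizeError", "default_design",
    "RA_CONTENT_MG_PER_G", "ENZYME_DILUTION_FACTOR",
]

#: Rosmarinic-acid content of the herbal water extract, mg RA per g extract.
RA_CONTENT_MG_PER_G = 13.07

#: Samples treated with the deconjugation enzyme are mixed 1:20
#: (enzyme:sample), diluting the analyte by 20/21.
ENZYME_DILUTION_FACTOR = 21.0 / 20.0


class StepSizeError(RuntimeError):
    """The integrator step is too large for the fastest rate (negative mass)."""


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic and measurement parameters of one simulated arm.

    papp_parent_ab / papp_parent_ba : cm/s
        Overall monolayer permeability of the parent in each direction
        (equal by default: passive diffusion is symmetric).
    conj_vmax : µg/min
        Intracellular conjugation capacity.
    conj_km : µg/mL
        Michaelis constant of the conjugation step, on the intracellular
        concentration scale.
    papp_conj_export : cm/s
        Carrier-like export permeability of the conjugate across the
        basolateral membrane.
    export_asymmetry : dimensionless
        Apical/basolateral export ratio for the conjugate (< 1 means the
        conjugate preferentially exits basolaterally).
    matrix_factor : dimensionless
        Multiplier on parent membrane permeability for extract arms
        (coexisting extract compounds loosening the paracellular route);
        1.0 disables the effect.
    matrix_conj_km_factor : dimensionless
        Multiplier on the conjugation Km for extract arms: co-extracted
        polyphenols are themselves phase-II substrates and competitively
        inhibit conjugation of the analyte, which raises the apparent Km.
        1.0 disables the effect.
    cell_volume : mL
        Accessible aqueous volume of the monolayer (1.12 cm² × ~2 µm
        effective depth).  Sets the loading-lag timescale only: the
        steady-state flux balance, and hence every regime property, is
        independent of it.
    noise_cv : fraction
        Multiplicative measurement CV applied to sampled concentrations.
    lloq : µg/mL
        Censoring limit of the simulated assay.
    dt : s
        RK4 integrator step.
    """

    papp_parent_ab: float = 5e-6
    papp_parent_ba: float = 5e-6
    conj_vmax: float = 0.009
    conj_km: float = 0.25
    papp_conj_export: float = 60e-6
    export_asymmetry: float = 0.1
    matrix_factor: float = 1.0
    matrix_conj_km_factor: float = 1.0
    cell_volume: float = 2.24e-4
    noise_cv: float = 0.05
    lloq: float = 0.025
    seed: int = 0
    dt: float = 0.5

    def __post_init__(self) -> None:
        for name in ("papp_parent_ab", "papp_parent_ba", "conj_vmax",
                     "conj_km", "papp_conj_export", "export_asymmetry",
                     "matrix_factor", "matrix_conj_km_factor", "lloq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        if self.dt <= 0 or self.cell_volume <= 0:
            raise ValueError("dt and cell_volume must be positive")


# state vector indices
_DP, _CP, _RP, _CC, _RC, _DC = range(6)
_SPECIES = ("parent", "conjugate")


@dataclass
class SimState:
    """Species-resolved compartment masses (µg) plus the removed-aliquot ledger.

    The ledger holds (time_min, side, species, mass_ug) for every aliquot
    withdrawn; compartment masses + ledger masses always sum to the initial
    dose (mass conservation is the simulator's primary invariant).
    """

    mass_donor_parent: float = 0.0
    mass_cell_parent: float = 0.0
    mass_receiver_parent: float = 0.0
    mass_cell_conj: float = 0.0
    mass_receiver_conj: float = 0.0
    mass_donor_conj: float = 0.0
    removed_ledger: list[tuple[float, str, str, float]] = field(default_factory=list)

    def as_vector(self) -> list[float]:
        return [self.mass_donor_parent, self.mass_cell_parent,
                self.mass_receiver_parent, self.mass_cell_conj,
                self.mass_receiver_conj, self.mass_donor_conj]

    def set_vector(self, v: Sequence[float]) -> None:
        (self.mass_donor_parent, self.mass_cell_parent,
         self.mass_receiver_parent, self.mass_cell_conj,
         self.mass_receiver_conj, self.mass_donor_conj) = map(float, v)

    def total_mass(self) -> float:
        return sum(self.as_vector()) + sum(m for *_, m in self.removed_ledger)

    def removed_mass(self, species: "str | None" = None) -> float:
        return sum(m for _, _, sp, m in self.removed_ledger
                   if species is None or sp == species)


@dataclass
class SampledRun:
    """Outcome of one simulated protocol run (noise-free).

    ``record`` rows are (time_min, receiver parent conc, receiver conjugate
    conc) measured immediately *before* the aliquot withdrawal at that time.
    ``true_q_parent`` / ``true_q_total`` are the true cumulative transported
    masses into the receiver at each sampling time (resident + withdrawn),
    straight from the mass ledger — the oracle the aliquot-corrected
    reconstruction must reproduce.
    """

    times_min: list[float]
    record: list[tuple[float, float, float]]
    state: SimState
    c0: float
    direction: Direction
    geometry: TranswellGeometry
    true_q_parent: list[float]
    true_q_total: list[float]

    def parent_concentrations(self) -> list[float]:
        return [c for _, c, _ in self.record]

    def total_concentrations(self) -> list[float]:
        return [cp + cc for _, cp, cc in self.record]


class TranswellSimulation:
    """One insert × one direction, integrated with fixed-step RK4.

    Build with kinetic parameters, a donor concentration and a direction;
    :meth:`run` integrates without sampling, :meth:`run_protocol` applies the
    withdraw-and-replace sampling schedule.
    """

    def __init__(self, params: SimulationParams, c0: float,
                 direction: "Direction | str",
                 geometry: "TranswellGeometry | None" = None):
        if c0 <= 0:
            raise ValueError("c0 must be positive")
        self.params = params
        self.c0 = float(c0)
        self.direction = Direction.parse(direction)
        self.geometry = geometry or TranswellGeometry()
        g = self.geometry
        if self.direction is Direction.AB:
            self.v_donor, self.v_receiver = g.volume_apical, g.volume_basolateral
            papp = params.papp_parent_ab
            # receiver is basolateral: full conjugate export permeability
            self._p_exp_receiver = params.papp_conj_export
            self._p_exp_donor = params.papp_conj_export * params.export_asymmetry
        else:
            self.v_donor, self.v_receiver = g.volume_basolateral, g.volume_apical
            papp = params.papp_parent_ba
            # receiver is apical: export scaled by the asymmetry factor
            self._p_exp_receiver = params.papp_conj_export * params.export_asymmetry
            self._p_exp_donor = params.papp_conj_export
        # two equal membranes in series: per-membrane permeability 2·Papp
        self._p_membrane = 2.0 * papp * params.matrix_factor

    # ------------------------------------------------------------------ #

    def _deriv(self, y: Sequence[float]) -> list[float]:
        p = self.params
        A = self.geometry.area
        c_d = y[_DP] / self.v_donor
        c_cell = y[_CP] / p.cell_volume
        c_r = y[_RP] / self.v_receiver
        c_conj = y[_CC] / p.cell_volume

        j_dc = self._p_membrane * A * (c_d - c_cell)     # µg/s, donor→cell
        j_cr = self._p_membrane * A * (c_cell - c_r)     # µg/s, cell→receiver
        km_eff = p.conj_km * p.matrix_conj_km_factor
        r_conj = (p.conj_vmax / 60.0) * c_cell / (km_eff + c_cell) \
            if c_cell > 0 else 0.0
        j_exp_r = self._p_exp_receiver * A * c_conj      # one-way export
        j_exp_d = self._p_exp_donor * A * c_conj

        return [
            -j_dc,                       # donor parent
            j_dc - j_cr - r_conj,        # cell parent
            j_cr,                        # receiver parent
            r_conj - j_exp_r - j_exp_d,  # cell conjugate
            j_exp_r,                     # receiver conjugate
            j_exp_d,                     # donor conjugate
        ]

    def _integrate(self, y: list[float], t0_s: float, t1_s: float) -> list[float]:
        """RK4 from t0 to t1 (seconds); raises StepSizeError on negative mass."""
        dt = self.params.dt
        n_full, rem = divmod(t1_s - t0_s, dt)
        steps = [dt] * int(round(n_full))
        if rem > 1e-9:
            steps.append(rem)
        for h in steps:
            k1 = self._deriv(y)
            y2 = [yi + 0.5 * h * ki for yi, ki in zip(y, k1)]
            k2 = self._deriv(y2)
            y3 = [yi + 0.5 * h * ki for yi, ki in zip(y, k2)]
            k3 = self._deriv(y3)
            y4 = [yi + h * ki for yi, ki in zip(y, k3)]
            k4 = self._deriv(y4)
            y = [yi + (h / 6.0) * (a + 2 * b + 2 * c + d)
                 for yi, a, b, c, d in zip(y, k1, k2, k3, k4)]
            if min(y) < -1e-12 * self.c0 * self.v_donor:
                raise StepSizeError(
                    f"negative compartment mass at dt={dt}; reduce the step")
            y = [max(yi, 0.0) for yi in y]
        return y

    def run(self, duration_min: float) -> SimState:
        """Integrate *duration_min* minutes with no sampling."""
        state = SimState(mass_donor_parent=self.c0 * self.v_donor)
        y = self._integrate(state.as_vector(), 0.0, duration_min * 60.0)
        state.set_vector(y)
        return state

    def run_protocol(self, times_min: Sequence[float]) -> SampledRun:
        """Integrate with withdraw-and-replace sampling at *times_min*.

        At each sampling time the receiver concentration is recorded, an
        aliquot S is withdrawn (its per-species mass logged to the ledger)
        and the chamber is refilled with blank buffer, scaling the resident
        receiver masses by (V − S)/V.
        """
        times = [float(t) for t in times_min]
        if any(b <= a for a, b in zip(times, times[1:])) or (times and times[0] <= 0):
            raise ValueError("sampling times must be strictly increasing and > 0")
        V, S = self.geometry.receiver_volumes(self.direction)
        if S > V:
            raise ValueError("aliquot exceeds receiver volume")
        state = SimState(mass_donor_parent=self.c0 * self.v_donor)
        y = state.as_vector()
        record: list[tuple[float, float, float]] = []
        tq_parent: list[float] = []
        tq_total: list[float] = []
        receiver_side = "B" if self.direction is Direction.AB else "A"
        t_prev = 0.0
        for t in times:
            y = self._integrate(y, t_prev * 60.0, t * 60.0)
            c_parent = y[_RP] / V
            c_conj = y[_RC] / V
            record.append((t, c_parent, c_conj))
            # truth before withdrawal: resident receiver mass + prior aliquots
            state.set_vector(y)
            tq_parent.append(y[_RP] + state.removed_mass("parent"))
            tq_total.append(y[_RP] + y[_RC] + state.removed_mass())
            # withdraw S and replace with blank buffer
            frac = S / V
            state.removed_ledger.append((t, receiver_side, "parent", y[_RP] * frac))
            state.removed_ledger.append((t, receiver_side, "conjugate", y[_RC] * frac))
            y[_RP] *= (1.0 - frac)
            y[_RC] *= (1.0 - frac)
            t_prev = t
        state.set_vector(y)
        return SampledRun(times_min=times, record=record, state=state,
                          c0=self.c0, direction=self.direction,
                          geometry=self.geometry,
                          true_q_parent=tq_parent, true_q_total=tq_total)


def simulate_transport(params: SimulationParams, c0: float,
                       direction: "Direction | str",
                       geometry: "TranswellGeometry | None" = None,
                       duration_min: float = 120.0) -> SimState:
    """Unsampled trajectory endpoint (see :class:`TranswellSimulation`)."""
    return TranswellSimulation(params, c0, direction, geometry).run(duration_min)


def apply_sampling(params: SimulationParams, c0: float,
                   direction: "Direction | str",
                   times_min: Sequence[float],
                   geometry: "TranswellGeometry | None" = None) -> SampledRun:
    """Run the full withdraw-and-replace protocol (noise-free record)."""
    return TranswellSimulation(params, c0, direction, geometry).run_protocol(times_min)


def apply_noise_and_lloq(concentrations: Sequence[float], noise_cv: float,
                         lloq: float,
                         rng: "np.random.Generator | int") -> "list[float | Censored]":
    """Measurement layer: multiplicative lognormal noise then LLOQ censoring.

    The noise is mean-preserving with coefficient of variation *noise_cv*
    (σ² = ln(1 + CV²), factor = exp(N(−σ²/2, σ))), deterministic under a
    fixed seed.  Values below *lloq* become :class:`Censored` markers.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: "list[float | Censored]" = []
    if noise_cv == 0:
        factors = np.ones(len(concentrations))
    else:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                    size=len(concentrations)))
    for c, f in zip(concentrations, factors):
        out.append(censor(float(c) * float(f), lloq))
    return out


def simulate_deconjugation_assay(run: SampledRun, noise_cv: float, lloq: float,
                                 rng: "np.random.Generator | int",
                                 enzyme_dilution: bool = True) -> "list[float | Censored]":
    """Measured total (parent + conjugate) concentrations after enzyme treatment.

    Aliquots are incubated with β-glucuronidase/sulfatase, hydrolysing the
    conjugates back to parent; what the assay then sees at each timepoint is
    the total receiver concentration at the sampling instant.  With
    *enzyme_dilution* the 1:20 enzyme:sample mixing dilutes the analyte by
    20/21 before measurement (the analysis-side correction multiplies it
    back).
    """
    totals = run.total_concentrations()
    if enzyme_dilution:
        totals = [c / ENZYME_DILUTION_FACTOR for c in totals]
    return apply_noise_and_lloq(totals, noise_cv, lloq, rng)


# --------------------------------------------------------------------------- #
# study-level generation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DoseArm:
    """One dose group: an extract dose (RA content converts to the RA
    concentration actually loaded) or an equivalent pure-compound dose."""

    label: str
    c0: float              # µg/mL of the quantified analyte in the donor
    is_extract: bool

    @classmethod
    def extract(cls, extract_conc: float, label: "str | None" = None,
                ra_content: float = RA_CONTENT_MG_PER_G) -> "DoseArm":
        c0 = extract_conc * ra_content / 1000.0
        return cls(label or f"extract-{extract_conc:g}", c0, True)

    @classmethod
    def pure(cls, conc: float, label: "str | None" = None) -> "DoseArm":
        return cls(label or f"pure-{conc:g}", conc, False)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the bidirectional study.

    Defaults follow the protocol this package targets: two extract doses and
    their two pure-compound equivalents, both directions, sampling at
    30/60/90/120 min, three replicate wells, before- and after-deconjugation
    measurement arms.
    """

    doses: tuple[DoseArm, ...] = (
        DoseArm.extract(250.0),
        DoseArm.extract(500.0),
        DoseArm.pure(3.267),
        DoseArm.pure(6.808),
    )
    times_min: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    replicates: int = 3
    directions: tuple[Direction, ...] = (Direction.AB, Direction.BA)
    deconjugation_arms: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("times must be strictly increasing")


def default_design() -> StudyDesign:
    return StudyDesign()


#: Matrix enhancement applied to parent permeability in extract arms:
#: coexisting extract compounds increase paracellular parent flux enough to
#: push receiver parent concentrations above the quantification limit, while
#: the pure compound stays fully conjugated and censored.
EXTRACT_MATRIX_FACTOR = 3.0

#: Competitive inhibition of conjugation by co-extracted phase-II substrates
#: in extract arms, expressed as an apparent-Km multiplier.
EXTRACT_CONJ_KM_FACTOR = 2.0


def params_for_arm(base: SimulationParams, arm: DoseArm) -> SimulationParams:
    """Arm-specific parameters: extract arms get the matrix effects
    (permeability enhancement plus competitive conjugation inhibition)."""
    if arm.is_extract:
        return replace(base, matrix_factor=EXTRACT_MATRIX_FACTOR,
                       matrix_conj_km_factor=EXTRACT_CONJ_KM_FACTOR)
    return replace(base, matrix_factor=1.0, matrix_conj_km_factor=1.0)


def _ols_slope(t: Sequence[float], q: Sequence[float]) -> float:
    t = np.asarray(t, float)
    q = np.asarray(q, float)
    tbar, qbar = t.mean(), q.mean()
    return float(((t - tbar) * (q - qbar)).sum() / ((t - tbar) ** 2).sum())


def generate_study(design: "StudyDesign | None" = None,
                   params: "SimulationParams | None" = None,
                   seed: int = 0,
                   out_dir: "str | Path | None" = None,
                   geometry: "TranswellGeometry | None" = None) -> dict:
    """Generate a complete synthetic bidirectional study.

    Produces (and optionally writes) the CSV inputs the analysis pipeline
    consumes — ``transport.csv``, ``teer.csv``, a geometry config — plus
    ``truth.json`` holding the per-arm ground truth (true Papp of parent and
    of total drug from the mass ledger, transported and conjugated
    fractions) for parameter-recovery tests.

    Noise replicates share each arm's deterministic kinetic trajectory and
    differ only in the measurement layer; all randomness descends from
    *seed*.
    """
    design = design or default_design()
    base = params or SimulationParams()
    geometry = geometry or TranswellGeometry()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    truth: dict[str, dict] = {}
    for arm in design.doses:
        p = params_for_arm(base, arm)
        for direction in design.directions:
            sim = TranswellSimulation(p, arm.c0, direction, geometry)
            srun = sim.run_protocol(design.times_min)
            t = list(design.times_min)
            initial = arm.c0 * sim.v_donor
            papp_true = (p.papp_parent_ab if direction is Direction.AB
                         else p.papp_parent_ba) * p.matrix_factor
            arm_key = f"{arm.label}:{direction.value}"
            truth[arm_key] = {
                "c0_ug_per_ml": arm.c0,
                "direction": direction.value,
                "papp_parent_input": papp_true,
                "papp_parent_true": _ols_slope(t, srun.true_q_parent) / 60.0
                / (arm.c0 * geometry.area),
                "papp_total_true": _ols_slope(t, srun.true_q_total) / 60.0
                / (arm.c0 * geometry.area),
                "fraction_transported": srun.true_q_total[-1] / initial,
                "fraction_conjugated":
                    (srun.state.mass_cell_conj + srun.state.mass_receiver_conj
                     + srun.state.mass_donor_conj
                     + srun.state.removed_mass("conjugate")) / initial,
            }
            arms = [False, True] if design.deconjugation_arms else [False]
            for deconj in arms:
                for rep in range(1, design.replicates + 1):
                    sub = np.random.default_rng(rng.integers(0, 2 ** 31))
                    if deconj:
                        measured = simulate_deconjugation_assay(
                            srun, p.noise_cv, p.lloq, sub)
                    else:
                        measured = apply_noise_and_lloq(
                            srun.parent_concentrations(), p.noise_cv, p.lloq, sub)
                    for tm, conc in zip(design.times_min, measured):
                        rows.append({
                            "run_id": f"{arm.label}_{direction.value}"
                                      f"_{'post' if deconj else 'pre'}_r{rep}",
                            "dose_label": arm.label,
                            "direction": direction.value,
                            "deconjugated": int(deconj),
                            "c0_ug_per_ml": arm.c0,
                            "time_min": tm,
                            "conc_ug_per_ml":
                                "" if isinstance(conc, Censored) else conc,
                            "replicate": rep,
                        })

    transport = pd.DataFrame(rows)
    n_wells = len(design.doses) * len(design.directions) * design.replicates
    teer = pd.DataFrame({
        "well_id": [f"well{i + 1}" for i in range(n_wells)],
        "day": [21] * n_wells,
        "measured_ohm": np.round(rng.uniform(430.0, 520.0, n_wells), 1),
        "background_ohm": np.round(rng.uniform(55.0, 70.0, n_wells), 1),
    })
    geometry_cfg = {
        "area_cm2": geometry.area,
        "vol_a_ml": geometry.volume_apical,
        "vol_b_ml": geometry.volume_basolateral,
        "aliquot_a_ml": geometry.aliquot_apical,
        "aliquot_b_ml": geometry.aliquot_basolateral,
    }
    out = {"transport": transport, "teer": teer,
           "geometry": geometry_cfg, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        transport.to_csv(out_dir / "transport.csv", index=False)
        teer.to_csv(out_dir / "teer.csv", index=False)
        pd.DataFrame([geometry_cfg]).to_csv(out_dir / "geometry.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out
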