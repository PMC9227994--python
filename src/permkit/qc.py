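"""Assay quality-control arithmetic: MTT viability, stability, TEER.

Three small checks gate a transwell run before any permeability number is
trusted: the dose must be non-cytotoxic (MTT viability), the analyte must be
stable under storage and incubation (percent remaining), and the monolayer
must be tight (area-normalised TEER above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AbsorbanceTriple", "StabilityPair", "TeerReading", "TeerResult",
    "percent_viability", "percent_remaining", "teer_normalize",
    "TEER_THRESHOLD_OHM_CM2",
]

#: Monolayer-integrity gate: wells below this area-normalised resistance are
#: excluded from transport experiments.
TEER_THRESHOLD_OHM_CM2 = 400.0


@dataclass(frozen=True)
class AbsorbanceTriple:
    """MTT absorbances for one well: sample, blank (no cells), control (cells,
    no treatment)."""

    a_sample: float
    a_blank: float
    a_control: float


@dataclass(frozen=True)
class StabilityPair:
    """Mean analyte concentration before/after a storage or incubation
    condition (e.g. "RT 24 h", "−80 °C 30 d", "HBSS 37 °C 2 h")."""

    conc_before: float  # µg/mL
    conc_after: float   # µg/mL
    condition: str = ""


@dataclass(frozen=True)
class TeerReading:
    """Raw transepithelial resistance of a well and of the cell-free insert."""

    measured: float    # Ω, insert with monolayer
    background: float  # Ω, insert alone
    area: float        # cm²
    day: int = 0


@dataclass(frozen=True)
class TeerResult:
    teer_ohm_cm2: float
    passed: bool
    valid: bool  # False when background exceeds the measurement


def percent_viability(t: AbsorbanceTriple) -> float:
    """Percent cell viability from an MTT absorbance triple.

    100 · (A_sample − A_blank) / (A_control − A_blank).  Values above 100 %
    are possible (treatment stimulating metabolic activity) and are returned
    as-is.  The result is invariant to adding a constant to all three
    absorbances.
    """
    denom = t.a_control - t.a_blank
    if denom == 0:
        raise ValueError("control and blank absorbances coincide (zero denominator)")
    return 100.0 * (t.a_sample - t.a_blank) / denom


def percent_remaining(pair: StabilityPair) -> float:
    """Percent analyte remaining after a stability condition:
    100 · C_after / C_before."""
    if pair.conc_before <= 0:
        raise ValueError("conc_before must be positive")
    return 100.0 * pair.conc_after / pair.conc_before


def teer_normalize(reading: TeerReading,
                   threshold: float = TEER_THRESHOLD_OHM_CM2) -> TeerResult:
    """Area-normalised TEER with the monolayer-integrity pass/fail.

    Background (cell-free insert) resistance is subtracted and the remainder
    multiplied by the insert area: (measured − background) × area, in Ω·cm².
    A well passes when the result meets *threshold* (default 400 Ω·cm²).
    Readings where background exceeds the measurement are flagged invalid.
    """
    valid = reading.measured >= reading.background >= 0
    teer = (reading.measured - reading.background) * reading.area
    return TeerResult(teer_ohm_cm2=teer,
                      passed=bool(valid and teer >= threshold),
                      valid=bool(valid))
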