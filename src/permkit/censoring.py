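"""Below-LLOQ censored values.

Concentrations that fall below the lower limit of quantification are not
numbers: they carry only the information "somewhere in [0, LLOQ)".  They are
represented explicitly so that downstream code must decide what to do with
them (the flux regression drops them; cumulative-amount series keep them as
lower bounds) instead of silently treating them as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Censored:
    """A measurement below the quantification limit.

    Parameters
    ----------
    bound : float
        The LLOQ that censored the value (µg/mL).  The true value lies in
        ``[0, bound)``.
    """

    bound: float

    def __post_init__(self) -> None:
        if not self.bound >= 0:
            raise ValueError(f"censoring bound must be >= 0, got {self.bound}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LLOQ {self.bound:g}"


def is_censored(value: object) -> bool:
    """True if *value* is a below-LLOQ marker."""
    return isinstance(value, Censored)


def censor(value: float, lloq: float) -> "float | Censored":
    """Apply LLOQ censoring: values below *lloq* become :class:`Censored`."""
    if value < lloq:
        return Censored(lloq)
    return float(value)
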