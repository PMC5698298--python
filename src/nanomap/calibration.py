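"""Length calibration between nanometers and base pairs.

All nm<->bp conversions in the package go through :class:`Calibration` so
there is a single source of truth for the conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Default conversion factor for double-stranded DNA measured in solution
#: deposition conditions (bp per nm of contour).
DEFAULT_BP_PER_NM = 2.94


@dataclass(frozen=True)
class Calibration:
    """Conversion factor between contour nanometers and base pairs."""

    bp_per_nm: float = DEFAULT_BP_PER_NM

    def __post_init__(self) -> None:
        if not self.bp_per_nm > 0:
            raise ValueError(f"bp_per_nm must be positive, got {self.bp_per_nm}")

    def nm_to_bp(self, nm: float) -> float:
        return nm * self.bp_per_nm

    def bp_to_nm(self, bp: float) -> float:
        return bp / self.bp_per_nm


def convert_length(value, direction: str, cal: Calibration | None = None):
    """Convert a non-negative length between nm and bp.

    Parameters
    ----------
    value : float or array-like
        Length to convert; must be >= 0.
    direction : str
        ``"nm->bp"`` (multiply by ``bp_per_nm``) or ``"bp->nm"`` (divide).
        The unicode arrow ``"nm→bp"`` form is accepted too.
    cal : Calibration, optional
        Defaults to the canonical 2.94 bp/nm.
    """
    import numpy as np

    if cal is None:
        cal = Calibration()
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lengths must be non-negative")
    direction = direction.replace("→", "->")
    if direction == "nm->bp":
        out = arr * cal.bp_per_nm
    elif direction == "bp->nm":
        out = arr / cal.bp_per_nm
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out
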