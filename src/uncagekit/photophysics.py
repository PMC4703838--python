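"""Relative fluorescence quantum yield against a reference fluorophore.

Standard relative method: with absorbance A at the excitation wavelength
kept low (< 0.1, avoiding inner-filter effects), integrated emission I and
solvent refractive index η,

    QY = QY_ref · (I / I_ref) · (A_ref / A) · (η² / η_ref²)

The reference here is coumarin 1 in ethanol with QY_ref = 0.73.  The
refractive-index exponent is configurable for auditability; when sample
and reference share the solvent the η term cancels regardless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["PhotophysicsMeasurement", "QYReference", "relative_quantum_yield", "COUMARIN1_QY"]

#: Literature quantum yield of the coumarin 1 reference in ethanol.
COUMARIN1_QY = 0.73


@dataclass(frozen=True)
class PhotophysicsMeasurement:
    """Absorbance, integrated emission intensity and solvent refractive index."""

    absorbance: float
    intensity: float
    refractive_index: float = 1.3614  # ethanol

    def __post_init__(self) -> None:
        if self.absorbance <= 0:
            raise ValueError("absorbance must be > 0")
        if self.intensity <= 0:
            raise ValueError("integrated intensity must be > 0")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.absorbance > 0.1:
            warnings.warn(
                "absorbance above 0.1: inner-filter effects may bias the relative method",
                stacklevel=2,
            )


@dataclass(frozen=True)
class QYReference:
    """A reference compound of known quantum yield with its measurement."""

    qy: float
    measurement: PhotophysicsMeasurement

    def __post_init__(self) -> None:
        if not 0 < self.qy <= 1:
            raise ValueError("reference quantum yield must be in (0, 1]")


def relative_quantum_yield(
    sample: PhotophysicsMeasurement,
    reference: QYReference,
    eta_exponent: float = 2.0,
) -> float:
    """Quantum yield of ``sample`` relative to ``reference``.

    A value above 1 is unphysical and triggers a warning (it indicates
    inconsistent inputs, e.g. mismatched excitation or inner filtering).
    """
    ref = reference.measurement
    qy = (
        reference.qy
        * (sample.intensity / ref.intensity)
        * (ref.absorbance / sample.absorbance)
        * (sample.refractive_index / ref.refractive_index) ** eta_exponent
    )
    if qy > 1:
        warnings.warn(f"computed quantum yield {qy:.3f} > 1 is unphysical", stacklevel=2)
    return qy
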