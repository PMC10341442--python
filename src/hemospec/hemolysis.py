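"""Hemolysis quantification from paired supernatant/suspension spectra.

Free hemoglobin released by lysed cells ends up in the supernatant, so the
hemolysis percentage is the ratio of total hemoglobin (sum of the three
fitted derivative concentrations) in the supernatant to that in the whole
suspension:

    K = 100 · (dilution_ratio · total_supernatant) / total_suspension

Both totals come from the same mixture fit, so K is invariant to rescaling
both spectra by a common factor.  K can exceed 100 under measurement noise;
it is reported as computed, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedHemolysisError, ValidationError
from .unmix import UnmixResult

__all__ = ["HemolysisResult", "hemolysis_pct"]


@dataclass(frozen=True)
class HemolysisResult:
    """Hemolysis percentage with the totals it was computed from."""

    k_pct: float
    total_heme_supernatant: float
    total_heme_suspension: float
    dilution_ratio: float

    def to_dict(self) -> dict:
        return {
            "k_pct": self.k_pct,
            "total_heme_supernatant_mmol_l": self.total_heme_supernatant,
            "total_heme_suspension_mmol_l": self.total_heme_suspension,
            "dilution_ratio": self.dilution_ratio,
        }


def hemolysis_pct(
    supernatant: UnmixResult,
    suspension: UnmixResult,
    dilution_ratio: float = 1.0,
) -> HemolysisResult:
    """Hemolysis percentage K from two mixture fits.

    Both fits should use the same optical path length; ``dilution_ratio``
    rescales the supernatant total if it was measured diluted (default 1, no
    correction).
    """
    if dilution_ratio < 0:
        raise ValidationError("dilution_ratio must be non-negative")
    if supernatant.path_length_cm != suspension.path_length_cm:
        raise ValidationError(
            "supernatant and suspension fits use different path lengths"
        )
    total_sup = supernatant.total_heme
    total_susp = suspension.total_heme
    if total_susp <= 0:
        raise UndefinedHemolysisError("suspension total heme is zero")
    return HemolysisResult(
        k_pct=100.0 * dilution_ratio * total_sup / total_susp,
        total_heme_supernatant=total_sup,
        total_heme_suspension=total_susp,
        dilution_ratio=dilution_ratio,
    )
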