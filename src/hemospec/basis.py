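"""Extinction-coefficient bases for the three hemoglobin derivatives.

An :class:`ExtinctionBasis` holds molar absorptivity curves epsilon(lambda)
for oxyhemoglobin (HbO2), deoxyhemoglobin (Hb) and methemoglobin (MetHb) on a
shared, strictly increasing wavelength grid.  Units are fixed throughout the
package at L·mmol⁻¹·cm⁻¹ so that epsilon·C·L is dimensionless absorbance when
concentrations are in mmol/L and the optical path length is in cm.

Bases can be loaded from delimited text, resampled onto a measured grid, or
synthesised from Gaussian peak specifications placed at the derivatives'
characteristic positions: HbO2 at 542 and 577 nm, Hb at 555 nm, MetHb at
630 nm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, MalformedInputError, ValidationError

__all__ = [
    "ExtinctionBasis",
    "DEFAULT_PEAKS",
    "load_basis",
    "write_basis",
    "resample_basis",
    "synth_basis",
    "default_basis",
]

_COLUMNS = ("wavelength_nm", "eps_hbo2", "eps_hb", "eps_methb")

#: Default Gaussian peak placement, one list of (center nm, width nm, height)
#: per derivative.  Centers follow the characteristic absorbance maxima of the
#: derivatives in the 500-700 nm window; heights are of the order of the
#: millimolar absorptivities tabulated for human hemoglobin.
DEFAULT_PEAKS: Mapping[str, Sequence[tuple[float, float, float]]] = {
    "hbo2": [(542.0, 8.0, 14.6), (577.0, 8.0, 15.4)],
    "hb": [(555.0, 10.0, 13.0)],
    "methb": [(630.0, 12.0, 3.9)],
}


@dataclass(frozen=True)
class ExtinctionBasis:
    """Molar absorptivity curves on a shared wavelength grid.

    Attributes
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nm.
    eps_hbo2, eps_hb, eps_methb
        Molar absorptivity of each derivative, L·mmol⁻¹·cm⁻¹, one value per
        grid point.  Non-negative and finite.
    source_label
        Free-text provenance of the table.
    """

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    eps_methb: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        curves = {}
        for name in ("eps_hbo2", "eps_hb", "eps_methb"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != wl.shape:
                raise ValidationError(
                    f"{name} has length {c.size}, grid has length {wl.size}"
                )
            if not np.all(np.isfinite(c)):
                raise ValidationError(f"{name} contains non-finite values")
            if np.any(c < 0):
                raise ValidationError(f"{name} contains negative absorptivities")
            curves[name] = c
        if wl.ndim != 1 or wl.size < 1:
            raise MalformedInputError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(wl)):
            raise MalformedInputError("wavelength grid contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise MalformedInputError(
                "wavelengths must be strictly increasing (duplicates forbidden)"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        for name, c in curves.items():
            object.__setattr__(self, name, c)

    @property
    def curves(self) -> np.ndarray:
        """(n, 3) array with columns HbO2, Hb, MetHb."""
        return np.column_stack([self.eps_hbo2, self.eps_hb, self.eps_methb])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "eps_hbo2": self.eps_hbo2,
                "eps_hb": self.eps_hb,
                "eps_methb": self.eps_methb,
            }
        )


def load_basis(source, source_label: str | None = None) -> ExtinctionBasis:
    """Read an extinction basis from delimited text.

    ``source`` may be a path, a file object, or a string containing the table
    itself.  The expected header is ``wavelength_nm,eps_hbo2,eps_hb,eps_methb``
    with decimal points, UTF-8.  Units are taken as given in the file
    (L·mmol⁻¹·cm⁻¹ by package convention) and recorded in ``source_label``.
    """
    if isinstance(source, str) and "\n" in source:
        handle: object = io.StringIO(source)
        label = source_label or "<inline table>"
    else:
        handle = source
        label = source_label or str(source)
    try:
        table = pd.read_csv(handle)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise MalformedInputError(f"cannot parse basis table: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise MalformedInputError(f"basis table missing columns: {missing}")
    if len(table) < 2:
        raise MalformedInputError("basis table needs at least 2 rows")
    for col in _COLUMNS:
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise MalformedInputError(f"column {col!r} is not numeric")
    return ExtinctionBasis(
        wavelengths_nm=table["wavelength_nm"].to_numpy(float),
        eps_hbo2=table["eps_hbo2"].to_numpy(float),
        eps_hb=table["eps_hb"].to_numpy(float),
        eps_methb=table["eps_methb"].to_numpy(float),
        source_label=label,
    )


def write_basis(basis: ExtinctionBasis, path) -> None:
    """Write a basis in the dialect :func:`load_basis` reads (round-trips)."""
    basis.to_frame().to_csv(path, index=False, float_format="%.10g")


def resample_basis(basis: ExtinctionBasis, grid) -> ExtinctionBasis:
    """Linearly interpolate all three curves onto ``grid`` (nm).

    The grid must lie inside the basis support; no extrapolation is performed.
    Linear interpolation preserves non-negativity.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = basis.wavelengths_nm[0], basis.wavelengths_nm[-1]
    if grid.size and (grid.min() < lo or grid.max() > hi):
        raise ExtrapolationError(
            f"grid [{grid.min():g}, {grid.max():g}] nm outside basis support "
            f"[{lo:g}, {hi:g}] nm"
        )
    interp = lambda c: np.interp(grid, basis.wavelengths_nm, c)
    return ExtinctionBasis(
        wavelengths_nm=grid,
        eps_hbo2=interp(basis.eps_hbo2),
        eps_hb=interp(basis.eps_hb),
        eps_methb=interp(basis.eps_methb),
        source_label=basis.source_label + " (resampled)",
    )


def synth_basis(
    peak_spec: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
    grid: np.ndarray | None = None,
) -> ExtinctionBasis:
    """Build a synthetic basis from Gaussian peaks.

    Each derivative's curve is a sum of Gaussian bumps
    ``height * exp(-(lambda - center)^2 / (2 width^2))`` evaluated on the
    500-700 nm grid at 1 nm steps (or ``grid`` if given).  The default
    ``peak_spec`` places the peaks at the derivatives' characteristic
    positions (HbO2: 542 and 577 nm; Hb: 555 nm; MetHb: 630 nm).

    Deterministic: the same peak_spec always yields the identical basis.
    """
    peaks = dict(DEFAULT_PEAKS if peak_spec is None else peak_spec)
    if grid is None:
        grid = np.arange(500.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    curves = {}
    for name in ("hbo2", "hb", "methb"):
        spec = list(peaks.get(name, []))
        if not spec:
            raise ValidationError(f"empty peak list for derivative {name!r}")
        curve = np.zeros_like(grid)
        for center, width, height in spec:
            if not 500.0 <= center <= 700.0:
                raise ValidationError(f"peak center {center} nm outside [500, 700]")
            if width <= 0 or height <= 0:
                raise ValidationError("peak width and height must be positive")
            curve += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
        curves[name] = curve
    return ExtinctionBasis(
        wavelengths_nm=grid,
        eps_hbo2=curves["hbo2"],
        eps_hb=curves["hb"],
        eps_methb=curves["methb"],
        source_label="synthetic Gaussian-peak basis",
    )


def default_basis() -> ExtinctionBasis:
    """Load the packaged basis fixture.

    The fixture is a synthetic Gaussian-peak table (no public machine-readable
    absorptivity table ships with the package); it is bit-identical to
    ``synth_basis()`` written through :func:`write_basis`.
    """
    ref = resources.files("hemospec").joinpath("data/extinction_synthetic.csv")
    with ref.open("r", encoding="utf-8") as handle:
        return load_basis(handle, source_label="packaged synthetic basis")
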