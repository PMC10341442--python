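"""Spectral unmixing of hemoglobin derivatives with scattering correction.

The absorbance of a red-blood-cell suspension between 500 and 700 nm is
modelled as a Beer–Lambert mixture of the three hemoglobin derivatives plus
two scattering terms:

    D(λ) = ε_HbO2(λ)·C_HbO2·L + ε_Hb(λ)·C_Hb·L + ε_MetHb(λ)·C_MetHb·L
           + M + S/λ⁴

where L is the optical path length (cm), M is a wavelength-independent
scattering/offset term (cells large compared with λ) and S/λ⁴ is a Rayleigh
term from membrane roughness small compared with λ.  The model is linear in
all five unknowns, so fitting is bounded linear least squares: the three
concentrations and S are constrained non-negative, M is free (it absorbs
blank/baseline drift and may legitimately be negative).

Standard errors come from the curvature of the unconstrained problem
restricted to the active set: parameters pinned at a bound report NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .basis import ExtinctionBasis, resample_basis
from .errors import (
    AlignmentError,
    DegenerateFitError,
    MalformedInputError,
    UndefinedFractionError,
    ValidationError,
)

__all__ = [
    "Spectrum",
    "UnmixResult",
    "Fractions",
    "FitOptions",
    "design_matrix",
    "fit_spectrum",
    "fractions",
    "batch_fit",
    "read_spectrum",
    "write_spectrum",
]

#: Reference wavelength used to scale the Rayleigh column; raw nm⁻⁴ values are
#: ~1e-11 and would wreck the conditioning of the normal equations.
_S_REF_NM = 550.0
_PARAM_NAMES = ("c_hbo2", "c_hb", "c_methb", "m_offset", "s_rayleigh")
#: Relative tolerance below which a bounded parameter counts as pinned at 0.
_ACTIVE_TOL = 1e-10


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance measurement on a wavelength grid.

    ``meta`` carries the sample annotations used for batching: ``sample_id``,
    storage ``day``, storage-solution fraction ``sts_pct``, ``tube``
    (closed/open) and ``kind`` (suspension/supernatant).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise MalformedInputError("wavelengths and absorbance must match 1-D")
        if np.any(np.diff(wl) <= 0):
            raise MalformedInputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise MalformedInputError("absorbance contains non-finite values")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "meta", dict(self.meta))


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_spectrum`.

    window_nm
        Wavelengths outside this window are cropped (not resampled) before
        fitting; defaults to the measured 500-700 nm range.
    components
        Which derivative concentrations to fit; excluded ones are reported
        as exactly 0 with SE NaN.
    fit_offset, fit_rayleigh
        Whether to include the M offset and the S/λ⁴ term.
    """

    window_nm: tuple[float, float] = (500.0, 700.0)
    components: tuple[str, ...] = ("hbo2", "hb", "methb")
    fit_offset: bool = True
    fit_rayleigh: bool = True

    def column_mask(self) -> np.ndarray:
        unknown = set(self.components) - {"hbo2", "hb", "methb"}
        if unknown:
            raise ValidationError(f"unknown components: {sorted(unknown)}")
        return np.array(
            [
                "hbo2" in self.components,
                "hb" in self.components,
                "methb" in self.components,
                self.fit_offset,
                self.fit_rayleigh,
            ]
        )


@dataclass(frozen=True)
class UnmixResult:
    """Fitted concentrations and scattering coefficients with uncertainties.

    Concentrations are mmol/L; ``m_offset`` is AU; ``s_rayleigh`` is AU·nm⁴
    (divide by λ⁴ in nm to recover its absorbance contribution).  Standard
    errors are NaN for parameters pinned at a bound.
    """

    c_hbo2: float
    c_hb: float
    c_methb: float
    m_offset: float
    s_rayleigh: float
    se: dict
    r_squared: float
    residuals: np.ndarray
    path_length_cm: float
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def total_heme(self) -> float:
        """Total hemoglobin, the sum of the three derivative concentrations."""
        return self.c_hbo2 + self.c_hb + self.c_methb

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    def summary(self) -> str:
        """Value ± SE lines plus R², the conventional reporting format."""
        lines = []
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            err = self.se.get(name, float("nan"))
            err_txt = f"{err:.4g}" if np.isfinite(err) else "n/a (at bound)"
            lines.append(f"{name} = {value:.4g} ± {err_txt}")
        lines.append(f"R² = {self.r_squared:.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            **{name: float(getattr(self, name)) for name in _PARAM_NAMES},
            "se": {k: float(v) for k, v in self.se.items()},
            "r_squared": float(self.r_squared),
            "path_length_cm": float(self.path_length_cm),
            "window_nm": list(self.options.window_nm),
            "constraints": "c_hbo2, c_hb, c_methb, s_rayleigh >= 0; m_offset free",
        }


@dataclass(frozen=True)
class Fractions:
    """Derivative percentages of total heme; they sum to 100."""

    hbo2_pct: float
    hb_pct: float
    methb_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.hbo2_pct, self.hb_pct, self.methb_pct)


def design_matrix(
    wavelengths_nm: np.ndarray, basis: ExtinctionBasis, path_length_cm: float
) -> np.ndarray:
    """Columns of the mixture model, single source of truth for forward and
    inverse use.

    Column order: ε_HbO2·L, ε_Hb·L, ε_MetHb·L, 1, (550/λ)⁴.  The Rayleigh
    column is pre-scaled to its value at 550 nm; the fitted coefficient is
    converted back to AU·nm⁴ by multiplying with 550⁴.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.shape != basis.wavelengths_nm.shape or not np.allclose(
        wl, basis.wavelengths_nm, rtol=0, atol=1e-9
    ):
        raise AlignmentError(
            "spectrum and basis wavelength grids differ; resample the basis first"
        )
    if path_length_cm <= 0:
        raise ValidationError("path_length_cm must be positive")
    ones = np.ones_like(wl)
    rayleigh = (_S_REF_NM / wl) ** 4
    return np.column_stack(
        [
            basis.eps_hbo2 * path_length_cm,
            basis.eps_hb * path_length_cm,
            basis.eps_methb * path_length_cm,
            ones,
            rayleigh,
        ]
    )


def forward_model(
    wavelengths_nm: np.ndarray,
    basis: ExtinctionBasis,
    path_length_cm: float,
    c_hbo2: float,
    c_hb: float,
    c_methb: float,
    m: float = 0.0,
    s_au_nm4: float = 0.0,
) -> np.ndarray:
    """Noise-free model absorbance for given parameters (S in AU·nm⁴)."""
    design = design_matrix(wavelengths_nm, basis, path_length_cm)
    coef = np.array([c_hbo2, c_hb, c_methb, m, s_au_nm4 / _S_REF_NM**4])
    return design @ coef


def _check_rank(design: np.ndarray, names: Sequence[str]) -> None:
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0):
        dead = [n for n, s in zip(names, scale) if s == 0]
        raise DegenerateFitError(f"all-zero design columns: {dead}", columns=dead)
    normed = design / scale
    p = design.shape[1]
    rank = np.linalg.matrix_rank(normed, tol=1e-10)
    if rank < p:
        # name near-collinear column pairs to point at the culprit
        gram = normed.T @ normed
        pairs = [
            (names[i], names[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(gram[i, j]) > 1 - 1e-10
        ]
        flat = sorted({name for pair in pairs for name in pair})
        raise DegenerateFitError(
            f"rank-deficient design (rank {rank} of {p}); "
            f"near-identical columns: {flat or 'not pairwise'}",
            columns=flat,
        )


def fit_spectrum(
    spectrum: Spectrum,
    basis: ExtinctionBasis,
    path_length_cm: float = 0.1,
    options: FitOptions | None = None,
) -> UnmixResult:
    """Fit the five-parameter mixture model to one spectrum.

    Minimises the sum of squared residuals over (C_HbO2, C_Hb, C_MetHb, M, S)
    with C's and S constrained non-negative.  The basis must already be on the
    spectrum's grid (use :func:`hemospec.basis.resample_basis`).

    Returns an :class:`UnmixResult` with per-parameter standard errors from
    σ̂²·(XᵀX)⁻¹ of the active-set-reduced design and R² = 1 − SSres/SStot.
    """
    options = options or FitOptions()
    mask = options.column_mask()
    n_free = int(mask.sum())
    if n_free == 0:
        raise ValidationError("no free parameters selected")
    lo, hi = options.window_nm
    keep = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
    wl = spectrum.wavelengths_nm[keep]
    y = spectrum.absorbance[keep]
    if wl.size < n_free:
        raise ValidationError(
            f"only {wl.size} wavelengths in window; "
            f"need at least {n_free} for {n_free} parameters"
        )
    keep_basis = (basis.wavelengths_nm >= lo) & (basis.wavelengths_nm <= hi)
    basis_win = ExtinctionBasis(
        wavelengths_nm=basis.wavelengths_nm[keep_basis],
        eps_hbo2=basis.eps_hbo2[keep_basis],
        eps_hb=basis.eps_hb[keep_basis],
        eps_methb=basis.eps_methb[keep_basis],
        source_label=basis.source_label,
    )
    design_full = design_matrix(wl, basis_win, path_length_cm)
    design = design_full[:, mask]
    names = [n for n, use in zip(_PARAM_NAMES, mask) if use]
    _check_rank(design, names)

    lower_full = np.array([0.0, 0.0, 0.0, -np.inf, 0.0])
    sol = lsq_linear(
        design, y, bounds=(lower_full[mask], np.full(n_free, np.inf)), tol=1e-14
    )
    coef = np.zeros(5)
    coef[mask] = sol.x
    # snap solver fuzz at the bound to exactly zero
    bounded = np.array([True, True, True, False, True])
    scale = np.maximum(np.abs(coef).max(), 1.0)
    coef = np.where(bounded & (coef < _ACTIVE_TOL * scale), 0.0, coef)

    fitted = design_full @ coef
    residuals = y - fitted
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    se = _standard_errors(design_full, coef, ss_res, bounded, mask)
    return UnmixResult(
        c_hbo2=float(coef[0]),
        c_hb=float(coef[1]),
        c_methb=float(coef[2]),
        m_offset=float(coef[3]),
        s_rayleigh=float(coef[4] * _S_REF_NM**4),
        se=se,
        r_squared=r_squared,
        residuals=residuals,
        path_length_cm=path_length_cm,
        options=options,
    )


def _standard_errors(
    design: np.ndarray,
    coef: np.ndarray,
    ss_res: float,
    bounded: np.ndarray,
    mask: np.ndarray,
) -> dict:
    free = mask & ~(bounded & (coef == 0.0))
    n, p_free = design.shape[0], int(free.sum())
    se = {name: float("nan") for name in _PARAM_NAMES}
    dof = n - p_free
    if dof <= 0 or p_free == 0:
        return se
    sigma2 = ss_res / dof
    x_free = design[:, free]
    try:
        cov = sigma2 * np.linalg.inv(x_free.T @ x_free)
    except np.linalg.LinAlgError:
        return se
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    for value, idx in zip(diag, np.flatnonzero(free)):
        name = _PARAM_NAMES[idx]
        se[name] = float(value * _S_REF_NM**4) if name == "s_rayleigh" else float(value)
    return se


def fractions(result: UnmixResult) -> Fractions:
    """Derivative percentages of total heme from a fit."""
    total = result.total_heme
    if total <= 0:
        raise UndefinedFractionError("total heme concentration is zero")
    return Fractions(
        hbo2_pct=100.0 * result.c_hbo2 / total,
        hb_pct=100.0 * result.c_hb / total,
        methb_pct=100.0 * result.c_methb / total,
    )


_TUBE_ORDER = {"closed": 0, "open": 1}


def batch_fit(
    spectra: Iterable[Spectrum],
    basis: ExtinctionBasis,
    path_length_cm: float = 0.1,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit a collection of spectra, one row per spectrum.

    Rows are ordered by (tube, sts_pct, day).  Per-spectrum failures are
    recorded in the ``error`` column without aborting the batch.  The basis is
    resampled to each spectrum's grid as needed.
    """
    rows = []
    for spectrum in spectra:
        meta = spectrum.meta
        row = {
            "sample_id": meta.get("sample_id"),
            "day": meta.get("day"),
            "sts_pct": meta.get("sts_pct"),
            "tube": meta.get("tube"),
            "kind": meta.get("kind"),
        }
        try:
            local = basis
            if not np.array_equal(local.wavelengths_nm, spectrum.wavelengths_nm):
                local = resample_basis(basis, spectrum.wavelengths_nm)
            result = fit_spectrum(spectrum, local, path_length_cm, options)
            row.update(
                c_hbo2=result.c_hbo2,
                c_hb=result.c_hb,
                c_methb=result.c_methb,
                m_offset=result.m_offset,
                s_rayleigh=result.s_rayleigh,
                r_squared=result.r_squared,
                total_heme=result.total_heme,
            )
            try:
                fr = fractions(result)
                row.update(
                    hbo2_pct=fr.hbo2_pct, hb_pct=fr.hb_pct, methb_pct=fr.methb_pct
                )
            except UndefinedFractionError:
                pass
            row["error"] = None
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["_tube_order"] = table["tube"].map(_TUBE_ORDER).fillna(2)
    table = (
        table.sort_values(["_tube_order", "sts_pct", "day"], kind="stable")
        .drop(columns="_tube_order")
        .reset_index(drop=True)
    )
    return table


def read_spectrum(path, meta: dict | None = None) -> Spectrum:
    """Read a spectrum file: columns ``wavelength_nm,absorbance`` plus optional
    metadata columns (``sample_id,day,sts_pct,tube,kind``) or a ``.json``
    sidecar next to the file."""
    path = Path(path)
    table = pd.read_csv(path)
    for col in ("wavelength_nm", "absorbance"):
        if col not in table.columns:
            raise MalformedInputError(f"spectrum file missing column {col!r}")
    merged: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        merged.update(json.loads(sidecar.read_text()))
    for col in ("sample_id", "day", "sts_pct", "tube", "kind"):
        if col in table.columns:
            merged[col] = table[col].iloc[0]
    if meta:
        merged.update(meta)
    return Spectrum(
        wavelengths_nm=table["wavelength_nm"].to_numpy(float),
        absorbance=table["absorbance"].to_numpy(float),
        meta=merged,
    )


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum with its metadata as extra constant columns."""
    table = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, "absorbance": spectrum.absorbance}
    )
    for col in ("sample_id", "day", "sts_pct", "tube", "kind"):
        if col in spectrum.meta:
            table[col] = spectrum.meta[col]
    table.to_csv(path, index=False, float_format="%.10g")
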