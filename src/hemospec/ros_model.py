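"""Quadratic oxidant/antioxidant ROS-balance model.

The net rate of reactive-oxygen-species accumulation in stored red cells is
modelled as the balance of an oxidant system whose output grows quadratically
with oxygen concentration and an antioxidant system whose capacity grows
linearly with it, plus a constant baseline production:

    dC_ROS/dt = F(C) = F_os(C) − F_aos(C) + F0,
    F_os(C) = a·C²,   F_aos(C) = b·C,

so F(C) = a·C² − b·C + F0.  For a > 0 the parabola has a unique minimum at
C_opt = b/(2a) with minimal rate F_min = F0 − b²/(4a): an intermediate
("optimal hypoxemia") oxygen level at which ROS generation — and hence
storage damage — is smallest.  Oxygen concentration is kept in arbitrary
units tracking oxygen partial pressure (mmHg); the model is qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, NoMinimumError, ValidationError

__all__ = [
    "RosParams",
    "RosOptimum",
    "ros_rate",
    "oxidant_rate",
    "antioxidant_rate",
    "optimum",
    "curve",
]


@dataclass(frozen=True)
class RosParams:
    """Model parameters.

    a : oxidant-system performance constant (rate·conc⁻²), a > 0 for a
        minimum to exist.
    b : antioxidant-system performance constant (rate·conc⁻¹), b ≥ 0.
    f0 : baseline ROS production rate, unrestricted.
    """

    a: float
    b: float
    f0: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValidationError("antioxidant constant b must be non-negative")


@dataclass(frozen=True)
class RosOptimum:
    """The analytic minimum of the ROS-rate parabola."""

    c_opt: float
    f_min: float


def _as_conc(c_o2) -> np.ndarray:
    c = np.asarray(c_o2, dtype=float)
    if np.any(c < 0):
        raise DomainError("oxygen concentration must be non-negative")
    return c


def oxidant_rate(c_o2, params: RosParams):
    """Oxidant-system ROS generation rate, a·C²."""
    c = _as_conc(c_o2)
    return params.a * c**2


def antioxidant_rate(c_o2, params: RosParams):
    """Antioxidant-system ROS elimination rate, b·C."""
    c = _as_conc(c_o2)
    return params.b * c


def ros_rate(c_o2, params: RosParams):
    """Net ROS accumulation rate F(C) = a·C² − b·C + F0."""
    c = _as_conc(c_o2)
    out = params.a * c**2 - params.b * c + params.f0
    return float(out) if np.isscalar(c_o2) else out


def optimum(params: RosParams) -> RosOptimum:
    """Closed-form minimum: C_opt = b/(2a), F_min = F0 − b²/(4a)."""
    if params.a <= 0:
        raise NoMinimumError(f"no minimum for a = {params.a:g} <= 0")
    return RosOptimum(
        c_opt=params.b / (2 * params.a),
        f_min=params.f0 - params.b**2 / (4 * params.a),
    )


def curve(
    params: RosParams,
    c_grid,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Sample F over a grid for plotting or tabulation.

    Returns a DataFrame with columns ``c_o2`` and ``ros_rate``; the analytic
    optimum (for a > 0) and any user-supplied reference points (e.g.
    normoxemia/anoxemia oxygen levels, which carry no canonical numeric
    values) are attached under ``DataFrame.attrs['annotations']``.
    """
    grid = _as_conc(c_grid)
    if grid.size == 0:
        raise ValidationError("grid must be non-empty")
    table = pd.DataFrame({"c_o2": grid, "ros_rate": ros_rate(grid, params)})
    notes = dict(annotations or {})
    if params.a > 0:
        opt = optimum(params)
        notes.setdefault("c_opt", opt.c_opt)
        notes.setdefault("f_min", opt.f_min)
    table.attrs["annotations"] = notes
    return table
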