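"""Synthetic storage-study data with the structure the analysis assumes.

The generator emulates a closed/open-tube RBC storage experiment sampled on
days 0, 7, 14, 21 and 29: the deoxyhemoglobin fraction follows a Normal-CDF
transition (oxygen depletion in closed tubes), methemoglobin appears after an
onset day and ramps linearly to its end-of-storage level (seen at high
storage-solution fractions), and oxyhemoglobin is the remainder.  Fraction
trajectories are rendered into absorbance spectra through the same design
matrix the unmixing fit uses — a single code path for the forward model —
with an additive offset M, a Rayleigh S/λ⁴ term, and seeded homoscedastic
Gaussian noise in absorbance.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .basis import ExtinctionBasis, default_basis
from .errors import ConfigError, ValidationError
from .kinetics import cdf_model
from .unmix import Fractions, Spectrum, design_matrix

__all__ = [
    "TrajectoryConfig",
    "make_trajectory",
    "make_spectrum",
    "make_series",
    "make_hemolysis_pair",
    "default_study",
    "DEFAULT_DAYS",
]

#: Measurement schedule of the emulated storage study.
DEFAULT_DAYS: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 29.0)

_S_REF_NM4 = 550.0**4


@dataclass(frozen=True)
class TrajectoryConfig:
    """Per-condition generative parameters.

    Deoxyhemoglobin follows base + (plateau − base)·Φ((t − tm)/σ); the
    defaults (base 20%, plateau 85%, tm 11 d, σ 3 d) emulate a closed tube
    without storage solution, which starts ~80% oxygenated and deoxygenates
    around day 11.  MetHb is zero before ``methb_onset_day`` then linear to
    ``methb_final_pct`` on the last day.  ``total_heme_mmol_l`` of 0.66 gives
    peak suspension absorbance near 1 AU at a 1 mm path for the packaged
    basis, matching a dilute (~1.3% hematocrit) suspension.
    """

    days: tuple[float, ...] = DEFAULT_DAYS
    hb_base_pct: float = 20.0
    hb_plateau_pct: float = 85.0
    hb_tm_days: float = 11.0
    hb_sigma_days: float = 3.0
    methb_onset_day: float = 7.0
    methb_final_pct: float = 0.0
    total_heme_mmol_l: float = 0.66
    scatter_m_au: float = 0.02
    scatter_s_au_nm4: float = 0.03 * _S_REF_NM4  # ~0.03 AU at 550 nm
    noise_sd_au: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if len(days) < 1 or any(d < 0 for d in days) or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise ConfigError("days must be non-negative and strictly increasing")
        object.__setattr__(self, "days", days)
        if not (0 <= self.hb_base_pct <= 100 and 0 <= self.hb_plateau_pct <= 100):
            raise ConfigError("hb base/plateau must lie in [0, 100]%")
        if self.hb_sigma_days <= 0:
            raise ConfigError("hb_sigma_days must be positive")
        if not 0 <= self.methb_final_pct <= 100:
            raise ConfigError("methb_final_pct must lie in [0, 100]%")
        if self.total_heme_mmol_l < 0:
            raise ConfigError("total_heme_mmol_l must be non-negative")
        if self.noise_sd_au < 0:
            raise ConfigError("noise_sd_au must be non-negative")
        # every sampled day must leave a non-negative HbO2 remainder
        tbl = _fractions_table(self)
        if (tbl["hbo2_pct"] < 0).any():
            bad = tbl.loc[tbl["hbo2_pct"] < 0, "day"].tolist()
            raise ConfigError(
                f"Hb + MetHb exceed 100% on day(s) {bad}; negative HbO2 implied"
            )


def _methb_at(config: TrajectoryConfig, day: np.ndarray) -> np.ndarray:
    last = config.days[-1]
    onset = config.methb_onset_day
    if config.methb_final_pct == 0 or last <= onset:
        return np.zeros_like(day)
    ramp = (day - onset) / (last - onset)
    return config.methb_final_pct * np.clip(ramp, 0.0, 1.0)


def _fractions_table(config: TrajectoryConfig) -> pd.DataFrame:
    day = np.asarray(config.days, dtype=float)
    if config.hb_plateau_pct == config.hb_base_pct:
        hb = np.full_like(day, config.hb_base_pct)
    else:
        hb = cdf_model(
            day,
            config.hb_base_pct,
            config.hb_plateau_pct,
            config.hb_tm_days,
            config.hb_sigma_days,
        )
    methb = _methb_at(config, day)
    hbo2 = 100.0 - hb - methb
    return pd.DataFrame(
        {"day": day, "hbo2_pct": hbo2, "hb_pct": hb, "methb_pct": methb}
    )


def make_trajectory(config: TrajectoryConfig) -> pd.DataFrame:
    """Per-day derivative fractions implied by a configuration.

    Columns: ``day, hbo2_pct, hb_pct, methb_pct``; the three percentages sum
    to 100 on every row.
    """
    return _fractions_table(config)


def make_spectrum(
    fr: Fractions,
    total_heme: float,
    basis: ExtinctionBasis | None = None,
    path_length_cm: float = 0.1,
    m: float = 0.0,
    s_au_nm4: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    meta: dict | None = None,
) -> Spectrum:
    """Render derivative fractions into an absorbance spectrum.

    absorbance(λ) = L·Σ ε_x(λ)·C_x + M + S/λ⁴ + N(0, noise_sd²), with
    C_x = total_heme·fraction_x/100.  Uses the unmixing design matrix, so a
    noise-free spectrum is exactly recoverable by the fit.
    """
    if total_heme < 0:
        raise ValidationError("total_heme must be non-negative")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if basis is None:
        basis = default_basis()
    coef = np.array(
        [
            total_heme * fr.hbo2_pct / 100.0,
            total_heme * fr.hb_pct / 100.0,
            total_heme * fr.methb_pct / 100.0,
            m,
            s_au_nm4 / _S_REF_NM4,
        ]
    )
    design = design_matrix(basis.wavelengths_nm, basis, path_length_cm)
    absorbance = design @ coef
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, absorbance.shape)
    return Spectrum(
        wavelengths_nm=basis.wavelengths_nm.copy(),
        absorbance=absorbance,
        meta=dict(meta or {}),
    )


def _condition_items(study) -> list[tuple[tuple[str, float], TrajectoryConfig]]:
    items = list(study.items()) if isinstance(study, Mapping) else list(study)
    seen = set()
    for key, _ in items:
        if key in seen:
            raise ConfigError(f"duplicate condition key {key!r}")
        seen.add(key)
    return items


def make_series(
    study,
    basis: ExtinctionBasis | None = None,
    path_length_cm: float = 0.1,
) -> list[Spectrum]:
    """Generate one suspension spectrum per condition and day.

    ``study`` maps ``(tube, sts_pct)`` to a :class:`TrajectoryConfig` (a
    mapping, or an iterable of pairs — duplicate keys are rejected).  Each
    spectrum carries full metadata, ready for ``batch_fit`` and downstream
    CDF fitting.  Per-spectrum noise seeds are derived deterministically from
    each condition's seed.
    """
    if basis is None:
        basis = default_basis()
    spectra: list[Spectrum] = []
    for (tube, sts_pct), config in _condition_items(study):
        if tube not in ("closed", "open"):
            raise ConfigError(f"tube must be 'closed' or 'open', got {tube!r}")
        traj = make_trajectory(config)
        child_seeds = np.random.SeedSequence(config.seed).generate_state(len(traj))
        for (_, row), child in zip(traj.iterrows(), child_seeds):
            fr = Fractions(
                hbo2_pct=row["hbo2_pct"],
                hb_pct=row["hb_pct"],
                methb_pct=row["methb_pct"],
            )
            day = int(row["day"]) if float(row["day"]).is_integer() else row["day"]
            spectra.append(
                make_spectrum(
                    fr,
                    config.total_heme_mmol_l,
                    basis=basis,
                    path_length_cm=path_length_cm,
                    m=config.scatter_m_au,
                    s_au_nm4=config.scatter_s_au_nm4,
                    noise_sd=config.noise_sd_au,
                    seed=int(child),
                    meta={
                        "sample_id": f"{tube}-sts{sts_pct:g}-day{day}",
                        "day": day,
                        "sts_pct": sts_pct,
                        "tube": tube,
                        "kind": "suspension",
                    },
                )
            )
    return spectra


def make_hemolysis_pair(
    k_true_pct: float,
    suspension_total_heme: float,
    sup_fractions: Fractions,
    susp_fractions: Fractions,
    basis: ExtinctionBasis | None = None,
    path_length_cm: float = 0.1,
    m: float = 0.0,
    s_au_nm4: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum]:
    """Supernatant/suspension pair with a prescribed true hemolysis level.

    The supernatant carries ``k_true_pct/100`` of the suspension's total
    heme; both spectra share the scattering terms and are rendered through
    :func:`make_spectrum` with independent sub-seeds.
    """
    if not 0 <= k_true_pct <= 100:
        raise ValidationError("k_true_pct must lie in [0, 100]")
    seed_sup, seed_susp = np.random.SeedSequence(seed).generate_state(2)
    supernatant = make_spectrum(
        sup_fractions,
        suspension_total_heme * k_true_pct / 100.0,
        basis=basis,
        path_length_cm=path_length_cm,
        m=m,
        s_au_nm4=s_au_nm4,
        noise_sd=noise_sd,
        seed=int(seed_sup),
        meta={"kind": "supernatant"},
    )
    suspension = make_spectrum(
        susp_fractions,
        suspension_total_heme,
        basis=basis,
        path_length_cm=path_length_cm,
        m=m,
        s_au_nm4=s_au_nm4,
        noise_sd=noise_sd,
        seed=int(seed_susp),
        meta={"kind": "suspension"},
    )
    return supernatant, suspension


def default_study(noise_sd_au: float = 0.0, seed: int = 0) -> dict:
    """The 2 tubes × 4 StS fractions × 5 days storage design.

    Closed tubes at 0/30/60% StS deoxygenate with transition times 11.0,
    15.2 and 17.7 days (later onset at higher storage-solution fraction);
    closed 100% StS keeps Hb flat at 20% but accumulates 25% MetHb from day
    7.  Open tubes stay oxygenated at 0% StS; at 30/60/100% StS Hb rises to
    62/85/70% and 100% StS additionally accumulates 27% MetHb.
    """
    seeds = np.random.SeedSequence(seed).generate_state(8)
    common = dict(noise_sd_au=noise_sd_au)
    flat = dict(hb_plateau_pct=20.0, hb_base_pct=20.0)
    study = {
        ("closed", 0.0): TrajectoryConfig(hb_tm_days=11.0, **common, seed=int(seeds[0])),
        ("closed", 30.0): TrajectoryConfig(hb_tm_days=15.2, **common, seed=int(seeds[1])),
        ("closed", 60.0): TrajectoryConfig(
            hb_tm_days=17.7, methb_final_pct=5.0, **common, seed=int(seeds[2])
        ),
        ("closed", 100.0): TrajectoryConfig(
            **flat, methb_final_pct=25.0, **common, seed=int(seeds[3])
        ),
        ("open", 0.0): TrajectoryConfig(**flat, **common, seed=int(seeds[4])),
        ("open", 30.0): TrajectoryConfig(
            hb_plateau_pct=62.0, **common, seed=int(seeds[5])
        ),
        ("open", 60.0): TrajectoryConfig(
            hb_plateau_pct=85.0, **common, seed=int(seeds[6])
        ),
        ("open", 100.0): TrajectoryConfig(
            hb_plateau_pct=70.0, methb_final_pct=27.0, **common, seed=int(seeds[7])
        ),
    }
    return study
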