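"""Polyamine quantitation: HPLC standard curves, intracellular concentration
from CFU counts and cell volume, free-fraction estimates, and detection-limit
censoring.

Inputs are chromatographic peak areas (chromatogram integration itself is out
of scope).  Calibration follows the classical serial-dilution design: a top
standard per species (20 mM putrescine, 10 mM spermidine, 10 mM spermine)
diluted in 4-fold steps, fitted with an ordinary least-squares line of UV
peak area against concentration.

Total intracellular concentration converts a measured molar amount to the
cytoplasmic scale via the number of cells (CFU) and a per-cell volume of
4 um^3 (phase-microscopy estimate for the strains and growth conditions the
pipeline targets).  Only part of each polyamine is free in the cell — the
rest is bound to DNA, RNA, ATP and phospholipids — so physiological dosing
uses the free concentration: 40% of total putrescine and 5% of total
spermidine by default (literature binding-equilibrium estimates, configured
constants here, not recomputed).  No default free fraction exists for
spermine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, InvalidParameterError

__all__ = [
    "DEFAULT_FREE_FRACTIONS",
    "DEFAULT_CELL_VOLUME_UM3",
    "DEFAULT_DETECTION_LIMIT_MM",
    "StandardCurve",
    "CensoredValue",
    "build_dilution_series",
    "fit_standard_curve",
    "quantify_sample",
    "intracellular_concentration",
    "free_concentration",
    "apply_detection_limit",
]

#: Fraction of each polyamine not bound to nucleic acids, ATP or phospholipids.
DEFAULT_FREE_FRACTIONS: dict[str, float] = {"putrescine": 0.40, "spermidine": 0.05}

#: Cell volume in cubic micrometres used to convert amounts to concentrations.
DEFAULT_CELL_VOLUME_UM3 = 4.0

#: HPLC detection limit in mM; values below it are reported censored.
DEFAULT_DETECTION_LIMIT_MM = 0.2


@dataclass(frozen=True)
class StandardCurve:
    """Linear HPLC calibration for one polyamine species."""

    species: str
    slope: float  # response units per mM
    intercept: float  # response units
    r_squared: float
    points: tuple[tuple[float, float], ...]  # (concentration mM, response)

    def predict(self, concentration_mM: float) -> float:
        return self.slope * concentration_mM + self.intercept

    def invert(self, response: float) -> float:
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class CensoredValue:
    """A concentration that may lie below the detection limit."""

    value_mM: float
    censored: bool
    lod_mM: float

    def __str__(self) -> str:
        if self.censored:
            return f"<{self.lod_mM:g} mM"
        return f"{self.value_mM:.1f} mM"


def build_dilution_series(
    top_concentrations_mM: Mapping[str, float],
    n_levels: int = 5,
    fold: float = 4.0,
) -> pd.DataFrame:
    """Serial-dilution design table: level k holds ``top / fold**k``.

    The default 4-fold series mirrors the standard mixture used for HPLC
    calibration.  Returns a tidy frame (species, level, concentration_mM).
    """
    if fold <= 1:
        raise InvalidParameterError(f"fold must be > 1, got {fold}")
    n_levels = int(n_levels)
    if n_levels < 2:
        raise InvalidParameterError("n_levels must be >= 2")
    rows = []
    for species, top in top_concentrations_mM.items():
        if top <= 0:
            raise InvalidParameterError(f"top concentration for {species!r} must be positive")
        for k in range(n_levels):
            rows.append(
                {"species": species, "level": k, "concentration_mM": top / fold**k}
            )
    return pd.DataFrame(rows)


def fit_standard_curve(
    points: Sequence[tuple[float, float]], species: str = "unknown"
) -> StandardCurve:
    """Ordinary least-squares calibration line, response = slope*conc + b.

    Requires at least three distinct concentrations; a nonpositive fitted
    slope is refused as a calibration failure (response must increase with
    concentration).
    """
    pts = [(float(c), float(r)) for c, r in points]
    concs = np.array([c for c, _ in pts])
    if np.any(concs < 0):
        raise InvalidParameterError("concentrations must be nonnegative")
    if np.unique(concs).size < 3:
        raise CalibrationError(
            f"need >= 3 distinct concentrations, got {np.unique(concs).size}"
        )
    resp = np.array([r for _, r in pts])
    fit = stats.linregress(concs, resp)
    if fit.slope <= 0:
        raise CalibrationError(
            f"calibration failure for {species!r}: fitted slope {fit.slope:.4g} <= 0"
        )
    return StandardCurve(
        species=species,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        points=tuple(pts),
    )


def quantify_sample(response: float, curve: StandardCurve) -> float:
    """Invert the calibration line to an extract concentration in mM.

    A response below the intercept would extrapolate to a negative
    concentration; it is floored at 0 with a warning.
    """
    conc = curve.invert(float(response))
    if conc < 0:
        warnings.warn(
            f"response {response:g} below calibration intercept for "
            f"{curve.species!r}; concentration floored at 0 mM",
            stacklevel=2,
        )
        return 0.0
    return conc


def intracellular_concentration(
    amount_mol: float, cfu: int, cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3
) -> float:
    """Convert a molar amount distributed over ``cfu`` cells into an
    intracellular concentration in mM.

    One um^3 is 1e-15 L, so the concentration is
    ``amount_mol / (cfu * cell_volume_um3 * 1e-15 L)``, returned in mM.
    """
    if amount_mol <= 0 or cfu <= 0 or cell_volume_um3 <= 0:
        raise InvalidParameterError(
            "amount_mol, cfu and cell_volume_um3 must all be positive"
        )
    molar = amount_mol / (cfu * cell_volume_um3 * 1e-15)
    return molar * 1e3


def free_concentration(
    total_mM: float,
    species: str,
    free_fractions: Mapping[str, float] | None = None,
) -> float:
    """Free (unbound) concentration of a polyamine from its total.

    Defaults: 40% of putrescine and 5% of spermidine are free; other species
    need an explicit fraction via ``free_fractions``.
    """
    if total_mM < 0:
        raise InvalidParameterError("total_mM must be nonnegative")
    fractions = DEFAULT_FREE_FRACTIONS if free_fractions is None else free_fractions
    try:
        fraction = fractions[species]
    except KeyError:
        raise InvalidParameterError(
            f"no configured free fraction for species {species!r}; "
            f"known: {sorted(fractions)}"
        ) from None
    return fraction * total_mM


def apply_detection_limit(
    conc_mM: float, lod_mM: float = DEFAULT_DETECTION_LIMIT_MM
) -> CensoredValue:
    """Censor a concentration at the detection limit.

    The boundary is inclusive: a value equal to the limit passes through
    uncensored; anything below is reported as ``< lod``.
    """
    if lod_mM < 0:
        raise InvalidParameterError("lod_mM must be nonnegative")
    return CensoredValue(float(conc_mM), bool(conc_mM < lod_mM), float(lod_mM))
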