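"""Refractive-index → buoyant-density standard curves.

Fraction densities in a CsCl gradient are measured indirectly: a digital
refractometer reads the refractive index (RI) of each fraction, and a linear
standard curve fitted on serial dilutions of the CsCl stock maps RI to buoyant
density (BD, g/ml).  This module fits that curve by ordinary least squares,
applies it, and ships the published coefficients (BD = 10.302·RI − 12.747) as
a default model for users without their own standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CalibrationStandard",
    "CalibrationModel",
    "DegenerateFitError",
    "DEFAULT_MODEL",
    "fit_density_calibration",
    "ri_to_bd",
    "bd_to_ri",
    "read_standards",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# Physically plausible windows for CsCl refractometry of DNA gradients.
_RI_RANGE = (1.3, 1.5)
_BD_RANGE = (1.0, 2.0)


class DegenerateFitError(ValueError):
    """Raised when a standard curve cannot be fitted (too few or collinear-in-x points)."""


@dataclass(frozen=True)
class CalibrationStandard:
    """One refractometer standard: an RI reading paired with a known density."""

    refractive_index: float
    density: float  # g/ml

    def __post_init__(self) -> None:
        lo, hi = _RI_RANGE
        if not lo < self.refractive_index < hi:
            raise ValueError(
                f"refractive_index {self.refractive_index} outside plausible range {_RI_RANGE}"
            )
        lo, hi = _BD_RANGE
        if not lo < self.density < hi:
            raise ValueError(f"density {self.density} g/ml outside plausible range {_BD_RANGE}")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear RI→BD map: BD = slope·RI + intercept.

    ``r`` is the Pearson correlation of (RI, density) for the fitted standards;
    ``n_points`` the number of standards used.
    """

    slope: float  # g/ml per RI unit
    intercept: float  # g/ml
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration model needs at least 2 points")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.slope == 0:
            raise DegenerateFitError("calibration slope must be nonzero")


#: Published coefficients, bundled for users with no standards file.  The
#: dilution series behind the printed curve is not distributed, so n_points
#: is the minimal marker value.
DEFAULT_MODEL = CalibrationModel(slope=10.302, intercept=-12.747, r=0.99, n_points=2)


def fit_density_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationModel:
    """Ordinary-least-squares fit of density on refractive index.

    Parameters
    ----------
    standards
        At least two (RI, density) pairs with distinct refractive indices.

    Raises
    ------
    DegenerateFitError
        Fewer than 2 points, all RI identical, or a zero fitted slope.
    """
    if len(standards) < 2:
        raise DegenerateFitError("need at least 2 calibration standards")
    ri = np.asarray([s.refractive_index for s in standards], dtype=float)
    bd = np.asarray([s.density for s in standards], dtype=float)
    if np.ptp(ri) == 0:
        raise DegenerateFitError("all refractive indices identical; slope undefined")
    fit = stats.linregress(ri, bd)
    if fit.slope == 0:
        raise DegenerateFitError("fitted slope is zero; standards carry no density signal")
    # rvalue from linregress is the Pearson correlation of (RI, density).
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_points=len(standards),
    )


def ri_to_bd(ri: float | np.ndarray, model: CalibrationModel = DEFAULT_MODEL):
    """Map refractive index to buoyant density (g/ml) with a fitted model.

    Values falling outside the plausible density window (1.0, 2.0) g/ml are
    returned unchanged but logged as a warning — a reading error is more
    likely than genuinely exotic DNA.
    """
    bd = model.slope * np.asarray(ri, dtype=float) + model.intercept
    out_of_range = (bd <= _BD_RANGE[0]) | (bd >= _BD_RANGE[1])
    if np.any(out_of_range):
        logger.warning(
            "ri_to_bd produced %d density value(s) outside %s g/ml; check refractometer readings",
            int(np.count_nonzero(out_of_range)),
            _BD_RANGE,
        )
    if np.isscalar(ri):
        return float(bd)
    return bd


def bd_to_ri(bd: float | np.ndarray, model: CalibrationModel = DEFAULT_MODEL):
    """Inverse map: buoyant density (g/ml) back to refractive index."""
    ri = (np.asarray(bd, dtype=float) - model.intercept) / model.slope
    if np.isscalar(bd):
        return float(ri)
    return ri


def read_standards(path: str | Path) -> list[CalibrationStandard]:
    """Read a standards TSV with named columns ``refractive_index`` and ``density_g_per_ml``."""
    df = pd.read_csv(path, sep="\t")
    required = {"refractive_index", "density_g_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"standards file {path} lacks column(s): {sorted(missing)}")
    return [
        CalibrationStandard(refractive_index=float(row.refractive_index),
                            density=float(row.density_g_per_ml))
        for row in df.itertuples(index=False)
    ]


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a calibration model to YAML (keys slope, intercept, r, n_points)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(model), fh, sort_keys=False)


def load_model(path: str | Path) -> CalibrationModel:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return CalibrationModel(
        slope=float(payload["slope"]),
        intercept=float(payload["intercept"]),
        r=float(payload["r"]),
        n_points=int(payload["n_points"]),
    )
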