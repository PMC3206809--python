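"""Sign-corrected area-under-curve (SAUC) summarisation of KR profiles.

Each drug × marker block of a KR profile is reduced to a single SAUC score:
the sum over the marker's features of the trapezoidal area under the KR
versus concentration curve, multiplied by the marker's anti-fibrotic
direction so that anti-fibrotic responses always *increase* SAUC, and by a
cosmetic scale constant.

The concentration axis is normalised to [0, 1] before integration and each
feature's curve is anchored at (0, 0): the KR of the control against itself
is identically zero. The default axis places the serial-dilution steps at
equal spacing (dilution index), which makes SAUC comparable across drugs
whose absolute concentration ranges differ (each drug is screened up to its
own IC50-anchored maximum). Raw-µM and log2 axes are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import MarkerDirectionTable
from .kr import KRProfile

__all__ = ["feature_auc", "compute_sauc", "SAUCMatrix", "AXIS_MODES", "DEFAULT_SCALE"]

AXIS_MODES = ("index", "log2", "raw_um")

#: cosmetic multiplier applied to SAUC values
DEFAULT_SCALE = 1000.0


def _axis_positions(concentrations: np.ndarray, axis_mode: str) -> np.ndarray:
    """Map [0, c_1, ..., c_K] (c's strictly increasing, >0) onto [0, 1]."""
    if axis_mode == "index":
        pos = np.arange(concentrations.size + 1, dtype=float)
    elif axis_mode == "raw_um":
        pos = np.concatenate([[0.0], concentrations])
    elif axis_mode == "log2":
        pos = np.concatenate(
            [[0.0], 1.0 + np.log2(concentrations / concentrations[0])]
        )
    else:
        raise ConfigurationError(f"unknown axis mode {axis_mode!r}; use one of {AXIS_MODES}")
    return pos / pos[-1]


def feature_auc(concentrations, kr_values, axis_mode: str = "index") -> float:
    """Normalised trapezoidal area under one feature's KR curve.

    The series is implicitly anchored at (0, 0) for the drug-free control and
    the concentration axis is normalised to unit length, so a constant KR of
    1 integrates to 1 and a linear 0→1 ramp to 0.5.
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    kr = np.asarray(kr_values, dtype=float).ravel()
    if conc.size != kr.size:
        raise ValidationError("concentrations and KR values differ in length")
    if conc.size < 2:
        raise ValidationError("feature_auc needs at least 2 concentration points")
    if (np.diff(conc) <= 0).any() or conc[0] <= 0:
        raise ValidationError("concentrations must be strictly increasing and positive")
    x = _axis_positions(conc, axis_mode)
    y = np.concatenate([[0.0], kr])
    return float(np.trapezoid(y, x))


class SAUCMatrix:
    """Drugs × markers matrix of SAUC scores."""

    def __init__(self, frame: pd.DataFrame, axis_mode: str = "index",
                 scale: float = DEFAULT_SCALE):
        if axis_mode not in AXIS_MODES:
            raise ConfigurationError(f"unknown axis mode {axis_mode!r}")
        if not np.isfinite(frame.to_numpy(dtype=float)).all():
            raise ValidationError("SAUC matrix contains non-finite values")
        self._frame = frame.astype(float)
        self.axis_mode = axis_mode
        self.scale = float(scale)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def drugs(self) -> list[str]:
        return list(self._frame.index)

    @property
    def markers(self) -> list[str]:
        return list(self._frame.columns)

    def row(self, drug_id: str) -> pd.Series:
        return self._frame.loc[drug_id]

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index_label="drug_id")

    @classmethod
    def read_csv(cls, path, axis_mode: str = "index") -> "SAUCMatrix":
        return cls(pd.read_csv(path, index_col="drug_id"), axis_mode=axis_mode)


def compute_sauc(
    profile: KRProfile,
    directions: MarkerDirectionTable,
    axis_mode: str = "index",
    scale: float = DEFAULT_SCALE,
) -> SAUCMatrix:
    """Summarise a KR profile into a drugs × markers SAUC matrix.

    ``SAUC(drug, marker) = scale × direction(marker) × Σ_features AUC(feature)``.
    Every feature inherits its marker's direction.
    """
    for marker in profile.markers:
        if marker not in directions:
            raise ConfigurationError(
                f"marker {marker!r} missing from the direction table"
            )
    frame = profile.frame
    values: dict[str, dict[str, float]] = {}
    grouped = frame.sort_values("concentration_um").groupby(
        ["drug_id", "marker", "feature"], sort=False
    )
    for (drug, marker, _feature), sub in grouped:
        auc = feature_auc(
            sub["concentration_um"].to_numpy(), sub["kr"].to_numpy(), axis_mode
        )
        row = values.setdefault(drug, {})
        row[marker] = row.get(marker, 0.0) + directions[marker] * auc
    matrix = pd.DataFrame(values).T * scale
    matrix = matrix.loc[profile.drugs, profile.markers]
    return SAUCMatrix(matrix, axis_mode=axis_mode, scale=scale)
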