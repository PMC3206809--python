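"""Readers, writers and the canonical in-memory containers for screen data.

The pipeline consumes three kinds of tables, all plain CSV (comma separated,
UTF-8, header row mandatory, ``.`` decimal separator):

* per-cell feature tables — one row per segmented cell per staining set,
  identified by drug, concentration (µM), marker and cell id, followed by one
  numeric column per cytological feature (16 for two-channel staining sets,
  25 for three-channel ones);
* marker-direction tables mapping each fibrotic marker to the sign (+1/−1)
  in which an anti-fibrotic response moves its intensity features;
* in vivo literature tables of pathologist-graded histological scores
  (untreated control score Sc and drug-treated score St on the study's
  original scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

#: identifier columns of a per-cell feature table, in file order
ID_COLUMNS = ["drug_id", "concentration_um", "marker", "cell_id"]

#: feature counts of the two standard staining-set layouts
STANDARD_FEATURE_COUNTS = (16, 25)

#: recognized in vivo fibrosis model labels
MODELS = ("CCl4_treatment", "CCl4_preventive", "DMN_treatment", "other")


class CellFeatureTable:
    """Validated per-cell feature table.

    Wraps a :class:`pandas.DataFrame` whose first four columns are
    ``drug_id, concentration_um, marker, cell_id`` and whose remaining columns
    are numeric feature values. Every (drug, marker) group must contain a
    drug-free control at concentration exactly 0, and all drugs must share
    the same marker set.
    """

    def __init__(self, frame: pd.DataFrame, strict_feature_count: bool = False):
        missing = [c for c in ID_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing identifier columns: {missing}")
        feature_cols = [c for c in frame.columns if c not in ID_COLUMNS]
        if not feature_cols:
            raise ValidationError("table has no feature columns")
        if strict_feature_count and len(feature_cols) not in STANDARD_FEATURE_COUNTS:
            raise ValidationError(
                f"feature column count {len(feature_cols)} does not match a "
                f"standard staining-set layout {STANDARD_FEATURE_COUNTS}"
            )
        frame = frame[ID_COLUMNS + feature_cols].copy()
        for col in feature_cols:
            if not np.issubdtype(frame[col].dtype, np.number):
                raise ValidationError(f"feature column {col!r} is not numeric")
        if (frame["concentration_um"] < 0).any():
            raise ValidationError("negative concentrations present")

        # each (drug, marker) group needs its own concentration-0 control
        has_control = (
            frame.assign(_is_ctrl=frame["concentration_um"] == 0)
            .groupby(["drug_id", "marker"], sort=False)["_is_ctrl"]
            .any()
        )
        if not has_control.all():
            bad = sorted({d for d, _ in has_control[~has_control].index})
            raise ValidationError(
                f"missing concentration-0 control rows for drug(s): {bad}"
            )
        marker_sets = frame.groupby("drug_id", sort=False)["marker"].agg(frozenset)
        if marker_sets.nunique() != 1:
            raise ValidationError("drugs do not share a common marker set")

        self._frame = frame
        self._feature_names = feature_cols

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def feature_names(self) -> list[str]:
        return list(self._feature_names)

    @property
    def drugs(self) -> list[str]:
        return list(self._frame["drug_id"].unique())

    @property
    def markers(self) -> list[str]:
        return list(self._frame["marker"].unique())

    def concentrations(self, drug_id: str) -> np.ndarray:
        """Sorted unique concentrations (µM) measured for ``drug_id``."""
        sel = self._frame.loc[self._frame["drug_id"] == drug_id, "concentration_um"]
        return np.sort(sel.unique())

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellFeatureTable):
            return NotImplemented
        return self._frame.reset_index(drop=True).equals(
            other._frame.reset_index(drop=True)
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g guarantees binary round-trip of the feature values
        self._frame.to_csv(path, index=False, float_format="%.17g")


def read_cell_features(
    path: str | Path, strict_feature_count: bool = True
) -> CellFeatureTable:
    """Read and validate a per-cell feature CSV.

    Non-numeric feature values are reported with their file line numbers.
    ``strict_feature_count`` enforces the standard 16/25-feature layouts.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    feature_cols = [c for c in frame.columns if c not in ID_COLUMNS]
    bad_lines: list[int] = []
    for col in feature_cols:
        if np.issubdtype(frame[col].dtype, np.number):
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        # +2: header line plus 1-based numbering
        bad_lines.extend((frame.index[bad] + 2).tolist())
        frame[col] = coerced
    if bad_lines:
        raise ParseError(
            f"{path.name}: non-numeric feature values at line(s) {sorted(set(bad_lines))}"
        )
    if frame[feature_cols].isna().any().any():
        raise ParseError(f"{path.name}: missing feature values")
    return CellFeatureTable(frame, strict_feature_count=strict_feature_count)


class MarkerDirectionTable:
    """Anti-fibrotic direction (+1 or −1) per fibrotic marker.

    ``direction[marker] = +1`` means an anti-fibrotic response *increases*
    the marker's intensity features (e.g. caspase 3 activation), ``−1`` that
    it decreases them (e.g. collagen III or BrdU incorporation).
    """

    def __init__(self, directions: Mapping[str, int]):
        if not directions:
            raise ValidationError("empty marker-direction table")
        clean: dict[str, int] = {}
        for marker, d in directions.items():
            if d not in (-1, 1):
                raise ValidationError(
                    f"direction for marker {marker!r} must be +1 or -1, got {d}"
                )
            if marker in clean:
                raise ValidationError(f"duplicate marker {marker!r}")
            clean[str(marker)] = int(d)
        self._directions = clean

    def __getitem__(self, marker: str) -> int:
        try:
            return self._directions[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not in direction table") from None

    def __contains__(self, marker: str) -> bool:
        return marker in self._directions

    def __iter__(self):
        return iter(self._directions)

    def __len__(self) -> int:
        return len(self._directions)

    @property
    def markers(self) -> list[str]:
        return list(self._directions)

    def as_dict(self) -> dict[str, int]:
        return dict(self._directions)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"marker": list(self._directions), "direction": list(self._directions.values())}
        ).to_csv(path, index=False)


def read_marker_directions(path: str | Path) -> MarkerDirectionTable:
    frame = pd.read_csv(path)
    for col in ("marker", "direction"):
        if col not in frame.columns:
            raise ParseError(f"marker-direction file lacks column {col!r}")
    if frame["marker"].duplicated().any():
        dupes = frame.loc[frame["marker"].duplicated(), "marker"].tolist()
        raise ValidationError(f"duplicate marker(s) in direction table: {dupes}")
    return MarkerDirectionTable(dict(zip(frame["marker"], frame["direction"])))


@dataclass(frozen=True)
class InVivoRecord:
    """One literature study of a drug in a rat fibrosis model.

    ``sc_raw`` and ``st_raw`` are the pathologist-graded histological scores
    of untreated fibrotic controls and drug-treated animals, on the study's
    original scale with maximum ``scale_max``.
    """

    drug_id: str
    model: str
    study_id: str
    sc_raw: float
    st_raw: float
    scale_max: float

    def __post_init__(self):
        if self.scale_max <= 0:
            raise ValidationError(f"{self.drug_id}: scale_max must be positive")
        for name, value in (("sc_raw", self.sc_raw), ("st_raw", self.st_raw)):
            if not 0 <= value <= self.scale_max:
                raise ValidationError(
                    f"{self.drug_id} ({self.study_id}): {name}={value} outside "
                    f"[0, {self.scale_max}]"
                )


INVIVO_COLUMNS = ["drug_id", "model", "study_id", "sc_raw", "st_raw", "scale_max"]


def read_invivo_table(path: str | Path) -> list[InVivoRecord]:
    """Read an in vivo histology CSV into validated records.

    Validation is total: any out-of-bounds score raises and nothing is
    returned.
    """
    frame = pd.read_csv(path)
    missing = [c for c in INVIVO_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"in vivo table lacks column(s) {missing}")
    return [
        InVivoRecord(
            drug_id=str(row.drug_id),
            model=str(row.model),
            study_id=str(row.study_id),
            sc_raw=float(row.sc_raw),
            st_raw=float(row.st_raw),
            scale_max=float(row.scale_max),
        )
        for row in frame.itertuples(index=False)
    ]


def write_invivo_table(records: Iterable[InVivoRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=INVIVO_COLUMNS).to_csv(
        path, index=False
    )
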