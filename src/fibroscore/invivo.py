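"""In vivo drug-efficacy index from pathologist-graded histological scores.

The index weights the score reduction achieved by a drug with the severity
of untreated fibrosis:

    E_in_vivo = (Sc − St) × Sc

where Sc is the histological score of fibrotic animals without treatment and
St the score with treatment, both linearly rescaled to the common 0–4 range
used by scoring systems such as Metavir, Knodell and Ludwig. More severe
models demand more efficacious drugs, hence the extra factor of Sc. When a
drug has several studies within one fibrosis model, the most favourable
(highest) index is kept; indices are never compared across models, because
the severity induced by different hepatotoxins differs.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError
from .io import InVivoRecord

__all__ = [
    "rescale_score",
    "efficacy_index",
    "build_invivo_index",
    "InVivoIndex",
    "round_half_away",
]

RESCALED_MAX = 4.0


def rescale_score(raw: float, scale_max: float) -> float:
    """Linearly map a histological score from [0, scale_max] to [0, 4]."""
    if scale_max <= 0:
        raise ValidationError("scale_max must be positive")
    if not 0 <= raw <= scale_max:
        raise ValidationError(f"score {raw} outside [0, {scale_max}]")
    return raw * RESCALED_MAX / scale_max


def efficacy_index(sc: float, st: float) -> float:
    """(Sc − St) × Sc on the 0–4 scale; negative when the drug worsens fibrosis."""
    for name, value in (("sc", sc), ("st", st)):
        if not 0 <= value <= RESCALED_MAX:
            raise ValidationError(f"{name}={value} outside [0, {RESCALED_MAX}]")
    return (sc - st) * sc


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for displayed indices."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class InVivoIndex:
    """E_in_vivo per (drug, model), keeping the best study per pair."""

    COLUMNS = ["drug_id", "model", "e_invivo", "sc_scaled", "st_scaled", "study_id"]

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            frame = pd.DataFrame(columns=self.COLUMNS)
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"in vivo index lacks column(s) {missing}")
        if frame.duplicated(["drug_id", "model"]).any():
            raise ValidationError("more than one entry per (drug, model)")
        self._frame = frame[self.COLUMNS].reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def models(self) -> list[str]:
        return list(self._frame["model"].unique())

    def for_model(self, model: str) -> pd.Series:
        """E_in_vivo per drug within one fibrosis model."""
        sel = self._frame[self._frame["model"] == model]
        return sel.set_index("drug_id")["e_invivo"]

    def value(self, drug_id: str, model: str) -> float:
        sel = self._frame[
            (self._frame["drug_id"] == drug_id) & (self._frame["model"] == model)
        ]
        if sel.empty:
            raise KeyError(f"no entry for ({drug_id!r}, {model!r})")
        return float(sel["e_invivo"].iloc[0])

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)


def build_invivo_index(records: Iterable[InVivoRecord] | Sequence[InVivoRecord]) -> InVivoIndex:
    """Compute E_in_vivo for every record and keep the max per (drug, model).

    Rescaling to 0–4 happens before the index, and the max-over-studies rule
    is applied within a model only.
    """
    rows = []
    for rec in records:
        sc = rescale_score(rec.sc_raw, rec.scale_max)
        st = rescale_score(rec.st_raw, rec.scale_max)
        rows.append(
            {
                "drug_id": rec.drug_id,
                "model": rec.model,
                "e_invivo": efficacy_index(sc, st),
                "sc_scaled": sc,
                "st_scaled": st,
                "study_id": rec.study_id,
            }
        )
    if not rows:
        return InVivoIndex(pd.DataFrame(columns=InVivoIndex.COLUMNS))
    frame = pd.DataFrame(rows)
    best = frame.loc[
        frame.groupby(["drug_id", "model"], sort=False)["e_invivo"].idxmax()
    ]
    return InVivoIndex(best.reset_index(drop=True))
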