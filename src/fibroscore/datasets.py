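"""Packaged reference tables.

* ``load_invivo_records`` — the 18 literature studies of anti-fibrotic drugs
  in rat fibrosis models (DMN treatment, CCl4 treatment, CCl4 preventive)
  with pathologist-graded histological scores, already on the 0–4 scale;
* ``load_published_epredict`` — the published E_predict value of each of the
  49 screened drugs (the original per-cell data and optimized weights are
  not public, so these serve as fixed inputs to the correlation analyses);
* ``load_marker_directions`` — default anti-fibrotic directions of the 10
  markers, user-overridable since they encode biology (e.g. caspase 3
  activation is anti-fibrotic, collagen III accumulation is fibrotic).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import InVivoRecord, MarkerDirectionTable, read_invivo_table, read_marker_directions

__all__ = [
    "load_invivo_records",
    "load_published_epredict",
    "load_marker_directions",
]


def _data_path(name: str):
    return resources.files("fibroscore.data").joinpath(name)


def load_invivo_records() -> list[InVivoRecord]:
    """Literature histology records (18 studies, 3 fibrosis models)."""
    with resources.as_file(_data_path("invivo_histology.csv")) as path:
        return read_invivo_table(path)


def load_published_epredict() -> pd.Series:
    """Published E_predict per drug (49 drugs), as a drug-indexed Series."""
    with resources.as_file(_data_path("epredict_published.csv")) as path:
        frame = pd.read_csv(path)
    return frame.set_index("drug_id")["e_predict"].astype(float)


def load_marker_directions() -> MarkerDirectionTable:
    """Default anti-fibrotic direction (+1/−1) per marker."""
    with resources.as_file(_data_path("marker_directions.csv")) as path:
        return read_marker_directions(path)
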