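"""Synthetic high-content screens with known ground-truth efficacy.

No per-cell data is published for the original screen, so this module
emulates its structure: a panel of drugs, each screened over a 2-fold serial
dilution series plus a drug-free control, against the 10 fibrotic markers,
with 16 cytological features per cell and on the order of 10³ cells per
condition.

Each drug carries a latent ``true_efficacy`` in [0, 1]. Feature
distributions respond through a Hill dose–response term
``h(c) = c^n / (c^n + EC50^n)``:

* unimodal features are Gaussian with a marker-specific σ whose mean shifts
  by ``effect_size × σ × direction × efficacy × susceptibility × h(c)`` —
  the shift follows the marker-direction table, so anti-fibrotic drugs
  yield positive SAUC by construction;
* bimodal features (BrdU positivity) are a two-Gaussian mixture with
  well-separated modes whose responder fraction shifts by the same factor.

Matched synthetic in vivo records use the identity link between true
efficacy and fractional score reduction: St = clip(Sc − e·Sc + ε, 0, Sc).

Not emulated: pixel-level images, segmentation error, plate/edge effects,
well-to-well drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import CellFeatureTable, InVivoRecord, MarkerDirectionTable

__all__ = [
    "DEFAULT_MARKERS",
    "ScreenDesign",
    "SyntheticDrug",
    "graded_panel",
    "generate_screen",
    "generate_invivo",
]

#: the 10 fibrotic markers of the reference panel
DEFAULT_MARKERS = (
    "BrdU",
    "F-actin",
    "dPsim",
    "caspase3",
    "collagenIII",
    "MMP-2",
    "TIMP-1",
    "DHE",
    "Smad3",
    "pCREB",
)

_NUCLEAR_FEATURES = (
    "nuc_area",
    "nuc_shape_p2a",
    "nuc_elongation",
    "nuc_total_intensity",
    "nuc_avg_intensity",
)
_CYTO_FEATURES = (
    "cyto_area",
    "cyto_shape_p2a",
    "cyto_elongation",
    "cyto_total_intensity",
    "cyto_avg_intensity",
    "cyto_intensity_sd",
    "cyto_nuc_intensity_ratio",
    "cyto_texture_contrast",
    "cyto_texture_entropy",
    "cyto_radial_moment",
    "cyto_edge_intensity",
)


def feature_names(features_per_marker: int) -> list[str]:
    """Canonical feature names: 5 nuclear + 11 cytoplasmic for the 16-feature
    two-channel layout; generic names otherwise."""
    if features_per_marker == 16:
        return list(_NUCLEAR_FEATURES + _CYTO_FEATURES)
    return [f"feature_{i:02d}" for i in range(features_per_marker)]


#: default bimodal feature: BrdU incorporation splits cells into
#: positive/negative populations
DEFAULT_BIMODAL_FEATURES = frozenset({("BrdU", "cyto_avg_intensity")})

#: nuclear shape features respond more weakly than cytoplasmic readouts
_NUCLEAR_RESPONSE = 0.4


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a synthetic screen.

    ``n_concentrations`` counts the drug-free control plus the 2-fold serial
    dilution steps up to ``top_concentration_um``.
    """

    n_concentrations: int = 11
    markers: tuple[str, ...] = DEFAULT_MARKERS
    features_per_marker: int = 16
    cells_per_condition: int = 1000
    top_concentration_um: float = 10.0
    effect_size: float = 2.0
    seed: int = 0
    bimodal_features: frozenset = DEFAULT_BIMODAL_FEATURES

    def __post_init__(self):
        if self.n_concentrations < 2:
            raise ValidationError("need the control plus at least one concentration")
        if min(self.features_per_marker, self.cells_per_condition, len(self.markers)) < 1:
            raise ValidationError("all design counts must be >= 1")
        if self.top_concentration_um <= 0:
            raise ValidationError("top concentration must be positive")

    def concentration_grid(self) -> np.ndarray:
        """Strictly increasing grid: 0 then the 2-fold dilution series."""
        steps = self.n_concentrations - 1
        series = self.top_concentration_um / 2.0 ** np.arange(steps - 1, -1, -1)
        return np.concatenate([[0.0], series])


@dataclass(frozen=True)
class SyntheticDrug:
    """Ground-truth description of one simulated drug."""

    drug_id: str
    true_efficacy: float
    marker_susceptibility: dict = field(default_factory=dict)
    ec50: float = 2.5
    hill_n: float = 1.5
    nonspecific_collagen: bool = False

    def __post_init__(self):
        if not 0 <= self.true_efficacy <= 1:
            raise ValidationError(f"{self.drug_id}: true_efficacy outside [0, 1]")
        for marker, s in self.marker_susceptibility.items():
            if not 0 <= s <= 1:
                raise ValidationError(
                    f"{self.drug_id}: susceptibility for {marker!r} outside [0, 1]"
                )
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ValidationError(f"{self.drug_id}: ec50 and hill_n must be positive")

    def susceptibility(self, marker: str) -> float:
        return self.marker_susceptibility.get(marker, 1.0)

    def hill(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        cn = concentration**self.hill_n
        return cn / (cn + self.ec50**self.hill_n)


def graded_panel(
    n_drugs: int,
    seed: int = 0,
    max_efficacy: float = 0.9,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> list[SyntheticDrug]:
    """Panel with efficacies evenly graded from 0 to ``max_efficacy``.

    Susceptibilities are drawn once per marker (shared by all drugs), so the
    per-marker responses remain rank-consistent with true efficacy.
    """
    rng = np.random.default_rng(seed)
    susceptibility = {m: float(s) for m, s in zip(markers, rng.uniform(0.5, 1.0, len(markers)))}
    efficacies = np.linspace(0.0, max_efficacy, n_drugs)
    return [
        SyntheticDrug(
            drug_id=f"drug{i:02d}",
            true_efficacy=float(e),
            marker_susceptibility=dict(susceptibility),
        )
        for i, e in enumerate(efficacies)
    ]


def _marker_sigma(marker_index: int) -> float:
    return 15.0 + 2.0 * marker_index


def generate_screen(
    design: ScreenDesign,
    drugs: list[SyntheticDrug],
    directions: MarkerDirectionTable | None = None,
) -> CellFeatureTable:
    """Simulate per-cell feature values for a whole screen.

    Returns one row per cell per staining set: drugs × concentrations ×
    markers × cells_per_condition rows, with one numeric column per feature.
    Identical design and seed give identical tables.
    """
    if not drugs:
        raise ValidationError("drug list must be non-empty")
    if directions is None:
        from .datasets import load_marker_directions

        directions = load_marker_directions()
    grid = design.concentration_grid()
    if (np.diff(grid) <= 0).any():
        raise ValidationError("concentration grid must be strictly increasing")
    names = feature_names(design.features_per_marker)
    rng = np.random.default_rng(design.seed)
    n_cells = design.cells_per_condition

    id_blocks: list[pd.DataFrame] = []
    value_blocks: list[np.ndarray] = []
    cell_ids = np.arange(n_cells)
    for drug in drugs:
        for marker_index, marker in enumerate(design.markers):
            sigma = _marker_sigma(marker_index)
            direction = directions[marker] if marker in directions else -1
            base_mu = 100.0 + 10.0 * np.arange(len(names))
            for conc in grid:
                h = drug.hill(conc)
                shift = (
                    design.effect_size
                    * sigma
                    * direction
                    * drug.true_efficacy
                    * drug.susceptibility(marker)
                    * h
                )
                block = np.empty((n_cells, len(names)))
                for j, feature in enumerate(names):
                    if (marker, feature) in design.bimodal_features:
                        # responder/non-responder mixture, modes >= 4 sigma apart
                        p0 = 0.5
                        p = float(
                            np.clip(
                                p0
                                + direction
                                * drug.true_efficacy
                                * drug.susceptibility(marker)
                                * 0.45
                                * h,
                                0.02,
                                0.98,
                            )
                        )
                        hi = rng.random(n_cells) < p
                        block[:, j] = np.where(
                            hi,
                            rng.normal(140.0, 10.0, n_cells),
                            rng.normal(60.0, 10.0, n_cells),
                        )
                        continue
                    response = (
                        _NUCLEAR_RESPONSE if feature.startswith("nuc_") else 1.0
                    )
                    mu = base_mu[j] + response * shift
                    if (
                        drug.nonspecific_collagen
                        and marker == "collagenIII"
                        and "intensity" in feature
                    ):
                        # stress response: collagen rises with dose regardless
                        # of the drug's anti-fibrotic efficacy
                        mu = base_mu[j] + 2.0 * sigma * h
                    block[:, j] = rng.normal(mu, sigma, n_cells)
                id_blocks.append(
                    pd.DataFrame(
                        {
                            "drug_id": drug.drug_id,
                            "concentration_um": conc,
                            "marker": marker,
                            "cell_id": cell_ids,
                        }
                    )
                )
                value_blocks.append(block)

    ids = pd.concat(id_blocks, ignore_index=True)
    values = pd.DataFrame(np.concatenate(value_blocks), columns=names)
    return CellFeatureTable(pd.concat([ids, values], axis=1))


def generate_invivo(
    drugs: list[SyntheticDrug],
    model_label: str = "CCl4_treatment",
    sc_range: tuple[float, float] = (2.5, 4.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    g=None,
) -> list[InVivoRecord]:
    """Matched synthetic histology records on the 0–4 scale.

    ``Sc ~ Uniform(sc_range)``; ``St = clip(Sc − g(e)·Sc + ε, 0, Sc)`` with
    ``g`` the identity by default and ``ε ~ Normal(0, noise_sd)``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    lo, hi = sc_range
    if not (0 <= lo <= hi <= 4):
        raise ValidationError("sc_range must lie within [0, 4]")
    if g is None:
        g = lambda e: e  # noqa: E731 - identity link
    rng = np.random.default_rng(seed)
    records = []
    for drug in drugs:
        sc = float(rng.uniform(lo, hi))
        eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        st = float(np.clip(sc - g(drug.true_efficacy) * sc + eps, 0.0, sc))
        records.append(
            InVivoRecord(
                drug_id=drug.drug_id,
                model=model_label,
                study_id="synthetic",
                sc_raw=sc,
                st_raw=st,
                scale_max=4.0,
            )
        )
    return records
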