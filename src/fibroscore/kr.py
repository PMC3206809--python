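"""Per-feature effect statistics (KR values) relative to drug-free controls.

Every cytological feature at every non-zero drug concentration is reduced to
a single *KR* value in [−1, 1]:

* features whose control distribution is **unimodal** get a signed two-sample
  Kolmogorov–Smirnov score: magnitude ``D = max |ECDF_treated − ECDF_control|``,
  sign taken from the median shift (negative = the feature decreased under
  treatment);
* features whose control distribution is **bimodal** (e.g. BrdU positivity,
  where cells split into responder/non-responder populations) get a ratio
  score: the difference in the fraction of cells above a threshold separating
  the two control modes.

Only the effect sizes are used; no hypothesis-test p-value enters the
pipeline.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .exceptions import InsufficientDataError, ValidationError
from .io import CellFeatureTable

__all__ = [
    "classify_modality",
    "signed_ks_score",
    "bimodal_ratio_score",
    "bimodal_threshold",
    "compute_kr_profile",
    "KRProfile",
]

#: minimum sample size for a modality call
MIN_MODALITY_N = 50


def _fit_two_component(values: np.ndarray) -> GaussianMixture:
    return GaussianMixture(
        n_components=2, covariance_type="full", random_state=0, n_init=1
    ).fit(values.reshape(-1, 1))


def classify_modality(
    control_values,
    min_separation: float = 2.0,
    min_weight: float = 0.05,
) -> str:
    """Classify a control feature distribution as ``"unimodal"`` or ``"bimodal"``.

    A two-component Gaussian mixture is fitted and compared against a single
    Gaussian by BIC. The sample is called bimodal only when the two-component
    fit wins *and* the components are genuinely separated, measured by
    Ashman's D = |µ1 − µ2| / sqrt((σ1² + σ2²)/2) ≥ ``min_separation`` with
    both mixing weights ≥ ``min_weight``. For an equal-weight two-Gaussian
    mixture the density itself stops being bimodal below a separation of
    about 2σ, which motivates the default.

    Deterministic given the sample (fixed mixture initialisation).
    """
    values = np.asarray(control_values, dtype=float).ravel()
    if values.size < MIN_MODALITY_N:
        raise InsufficientDataError(
            f"modality classification needs >= {MIN_MODALITY_N} values, "
            f"got {values.size}"
        )
    if np.ptp(values) == 0:
        return "unimodal"
    column = values.reshape(-1, 1)
    g1 = GaussianMixture(n_components=1, random_state=0).fit(column)
    g2 = _fit_two_component(values)
    if g2.bic(column) >= g1.bic(column):
        return "unimodal"
    mu = g2.means_.ravel()
    sd = np.sqrt(g2.covariances_.ravel())
    ashman_d = abs(mu[0] - mu[1]) / np.sqrt((sd[0] ** 2 + sd[1] ** 2) / 2.0)
    if ashman_d >= min_separation and g2.weights_.min() >= min_weight:
        return "bimodal"
    return "unimodal"


def bimodal_threshold(control_values) -> float:
    """Threshold separating the two modes of a bimodal control distribution.

    Midpoint between the two component means of a two-Gaussian mixture fit;
    falls back to an Otsu split on a 256-bin histogram when the mixture fit
    degenerates (components closer than machine tolerance).
    """
    values = np.asarray(control_values, dtype=float).ravel()
    g2 = _fit_two_component(values)
    mu = np.sort(g2.means_.ravel())
    if mu[1] - mu[0] > 1e-9 * max(1.0, abs(mu).max()):
        return float(mu.mean())
    return _otsu(values)


def _otsu(values: np.ndarray, bins: int = 256) -> float:
    counts, edges = np.histogram(values, bins=bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * mids)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return float(mids[np.argmax(sigma_b)])


def _ks_distance(treated: np.ndarray, control: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic max|ECDF_t − ECDF_c|."""
    t = np.sort(treated)
    c = np.sort(control)
    grid = np.concatenate([t, c])
    cdf_t = np.searchsorted(t, grid, side="right") / t.size
    cdf_c = np.searchsorted(c, grid, side="right") / c.size
    return float(np.abs(cdf_t - cdf_c).max())


def signed_ks_score(treated, control) -> float:
    """Signed Kolmogorov–Smirnov score in [−1, 1].

    Magnitude is the two-sample KS statistic; the sign is that of
    ``median(treated) − median(control)``. When medians are exactly equal the
    mean difference breaks the tie; if that is zero too, the score is 0.
    """
    t = np.asarray(treated, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if t.size == 0 or c.size == 0:
        raise ValidationError("signed_ks_score requires non-empty samples")
    d = _ks_distance(t, c)
    delta = np.median(t) - np.median(c)
    if delta == 0:
        delta = t.mean() - c.mean()
    if delta == 0:
        return 0.0
    return float(np.sign(delta) * d)


def bimodal_ratio_score(treated, control, threshold: float) -> float:
    """Difference in positive-cell fractions, in [−1, 1].

    ``p_treated − p_control`` where p is the fraction of cells whose feature
    value exceeds ``threshold``. A threshold outside the observed range is
    allowed (the score is still defined) but warned about.
    """
    t = np.asarray(treated, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if t.size == 0 or c.size == 0:
        raise ValidationError("bimodal_ratio_score requires non-empty samples")
    combined_lo = min(t.min(), c.min())
    combined_hi = max(t.max(), c.max())
    if not combined_lo <= threshold <= combined_hi:
        warnings.warn(
            f"threshold {threshold} outside observed value range "
            f"[{combined_lo}, {combined_hi}]",
            stacklevel=2,
        )
    return float((t > threshold).mean() - (c > threshold).mean())


class KRProfile:
    """KR values per (drug, marker, feature, non-control concentration).

    Backed by a long-format :class:`pandas.DataFrame` with columns
    ``drug_id, marker, feature, concentration_um, kr, modality``. Modality is
    constant across concentrations for a given (marker, feature): it is
    decided once on pooled control cells.
    """

    COLUMNS = ["drug_id", "marker", "feature", "concentration_um", "kr", "modality"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"KR profile lacks column(s) {missing}")
        if (frame["kr"].abs() > 1 + 1e-12).any():
            raise ValidationError("KR values outside [-1, 1]")
        if (frame["concentration_um"] <= 0).any():
            raise ValidationError("KR profile must only contain non-control concentrations")
        n_modalities = frame.groupby(["marker", "feature"])["modality"].nunique()
        if (n_modalities > 1).any():
            raise ValidationError("modality not constant within (marker, feature)")
        self._frame = frame[self.COLUMNS].reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def drugs(self) -> list[str]:
        return list(self._frame["drug_id"].unique())

    @property
    def markers(self) -> list[str]:
        return list(self._frame["marker"].unique())

    def modality(self) -> dict[tuple[str, str], str]:
        """Modality label per (marker, feature)."""
        sub = self._frame.drop_duplicates(["marker", "feature"])
        return {(r.marker, r.feature): r.modality for r in sub.itertuples()}

    def series(self, drug_id: str, marker: str, feature: str) -> pd.Series:
        """KR versus concentration for one feature, indexed by concentration."""
        sel = self._frame[
            (self._frame["drug_id"] == drug_id)
            & (self._frame["marker"] == marker)
            & (self._frame["feature"] == feature)
        ]
        return sel.set_index("concentration_um")["kr"].sort_index()

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "KRProfile":
        return cls(pd.read_csv(path))


def compute_kr_profile(
    table: CellFeatureTable,
    modality_overrides: Mapping[tuple[str, str], str] | None = None,
) -> KRProfile:
    """Reduce a per-cell feature table to a KR profile.

    For every (marker, feature), modality is classified once on control cells
    pooled across drugs; for bimodal features a single positive/negative
    threshold is derived from the same pooled controls. Each drug's treated
    conditions are then scored against that drug's own drug-free control.

    ``modality_overrides`` maps (marker, feature) to a forced label, for
    features whose biology is known a priori.
    """
    frame = table.frame
    features = table.feature_names
    records: list[tuple] = []
    overrides = dict(modality_overrides or {})

    for marker, marker_frame in frame.groupby("marker", sort=False):
        controls = marker_frame[marker_frame["concentration_um"] == 0]
        for feature in features:
            pooled = controls[feature].to_numpy()
            # modality needs only the distribution shape; cap the mixture-fit
            # sample by deterministic striding to keep large screens fast
            if pooled.size > 4000:
                pooled = pooled[:: pooled.size // 2000]
            key = (marker, feature)
            modality = overrides.get(key) or classify_modality(pooled)
            threshold = bimodal_threshold(pooled) if modality == "bimodal" else None

            for drug, drug_frame in marker_frame.groupby("drug_id", sort=False):
                values = drug_frame[["concentration_um", feature]]
                ctrl = values.loc[
                    values["concentration_um"] == 0, feature
                ].to_numpy()
                for conc, cond in values.groupby("concentration_um", sort=True):
                    if conc == 0:
                        continue
                    treated = cond[feature].to_numpy()
                    if modality == "bimodal":
                        kr = bimodal_ratio_score(treated, ctrl, threshold)
                    else:
                        kr = signed_ks_score(treated, ctrl)
                    records.append((drug, marker, feature, conc, kr, modality))

    return KRProfile(pd.DataFrame(records, columns=KRProfile.COLUMNS))
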