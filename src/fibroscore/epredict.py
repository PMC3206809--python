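"""E_predict: exhaustive marker-weight optimization against in vivo efficacy.

The in vitro predictor is a weighted linear combination of the 10 per-marker
SAUC scores with integer weights in {0, 1, 2}, clipped at zero:

    E_predict(drug) = max(0, Σ_m w_m × SAUC_m(drug))

The weight vector is chosen by brute force: all 3^10 = 59049 lattice vectors
are scored by Spearman rank correlation between candidate E_predict values
and the training in vivo index, allowing at most one drug to be discarded as
an outlier (the training sets from the literature are small). Among all
vectors reaching perfect concordance (rho = 1), the optimized weight of each
marker is the value it takes most frequently; a tie goes to the smaller
weight (parsimony).

Drugs flagged as non-specific — those whose collagen III expression *rises*
with concentration, indicating a stress response rather than an
anti-fibrotic one — have their E_predict forced to 0.

:class:`EfficacyModel` / :class:`EfficacyResults` wrap the procedure in the
usual model/results idiom; the module-level functions are the underlying
primitives.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigurationError, OptimizationError, ValidationError
from .invivo import InVivoIndex
from .kr import KRProfile
from .sauc import SAUCMatrix

__all__ = [
    "enumerate_weight_vectors",
    "spearman_with_outlier",
    "compute_epredict",
    "flag_nonspecific",
    "flag_nonspecific_all",
    "optimize_weights",
    "weight_robustness",
    "EfficacyModel",
    "EfficacyResults",
]

WEIGHT_LEVELS = (0, 1, 2)
_RHO_ONE_TOL = 1e-9


def enumerate_weight_vectors(n_markers: int) -> np.ndarray:
    """All weight vectors in {0,1,2}^n_markers, lexicographic, shape (3^n, n)."""
    if n_markers < 1:
        raise ValidationError("n_markers must be >= 1")
    return np.array(
        list(itertools.product(WEIGHT_LEVELS, repeat=n_markers)), dtype=np.int8
    )


def _rowwise_spearman(E: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tie-corrected Spearman rho of each row of ``E`` against ``y``.

    Pearson correlation on (average-tied) ranks; rows with zero rank variance
    yield NaN.
    """
    rx = rankdata(E, axis=1)
    ry = rankdata(y)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    num = rxc @ ryc
    den = np.sqrt((rxc**2).sum(axis=1) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return rho


def _best_rhos(E: np.ndarray, y: np.ndarray, max_outliers: int = 1) -> np.ndarray:
    """Per row: best Spearman rho over the full set and all leave-one-out subsets."""
    best = _rowwise_spearman(E, y)
    if max_outliers >= 1:
        n = y.size
        for drop in range(n):
            keep = np.arange(n) != drop
            best = np.fmax(best, _rowwise_spearman(E[:, keep], y[keep]))
    return best


def spearman_with_outlier(x, y, max_outliers: int = 1):
    """Spearman rho allowing at most one point to be discarded.

    Returns ``(rho, outlier_index)`` where ``outlier_index`` is ``None`` when
    the full-sample rho is already maximal, otherwise the 0-based index of
    the removed point (ties on rho broken by the smallest index).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if max_outliers not in (0, 1):
        raise ValidationError("max_outliers must be 0 or 1")
    min_n = 4 if max_outliers else 3
    if x.size < min_n:
        raise ValidationError(
            f"need at least {min_n} points (got {x.size}) with max_outliers={max_outliers}"
        )
    rho_full = float(_rowwise_spearman(x[None, :], y)[0])
    if max_outliers == 0:
        return rho_full, None
    best_rho, best_idx = rho_full, None
    for drop in range(x.size):
        keep = np.arange(x.size) != drop
        rho = float(_rowwise_spearman(x[None, keep], y[keep])[0])
        if np.isnan(rho):
            continue
        if np.isnan(best_rho) or rho > best_rho + 1e-12:
            best_rho, best_idx = rho, drop
    return best_rho, best_idx


def compute_epredict(sauc_row, weights, nonspecific: bool = False) -> float:
    """E_predict for one drug: max(0, w · SAUC); 0 for non-specific drugs."""
    s = np.asarray(sauc_row, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if s.size != w.size:
        raise ValidationError("weights and SAUC row differ in length")
    if nonspecific:
        return 0.0
    return float(max(0.0, float(w @ s)))


def flag_nonspecific(
    profile: KRProfile,
    drug: str,
    marker: str = "collagenIII",
    feature: str = "cyto_total_intensity",
    threshold: float = 0.2,
    top_n: int = 2,
    monotone_tol: float = 0.05,
) -> bool:
    """Flag a drug whose collagen III expression rises with concentration.

    True iff the cytoplasmic total-intensity KR of the collagen marker
    exceeds ``threshold`` at the ``top_n`` highest concentrations *and* is
    non-decreasing (within ``monotone_tol``) over the upper half of the
    concentration range. Null drugs (|KR| well under the threshold) can
    never trip the flag.
    """
    if marker not in profile.markers:
        raise ConfigurationError(f"marker {marker!r} absent from the KR profile")
    series = profile.series(drug, marker, feature)
    if series.empty:
        candidates = sorted(
            {
                f
                for (m, f) in profile.modality()
                if m == marker and "total_intensity" in f
            }
        )
        if not candidates:
            raise ConfigurationError(
                f"no collagen intensity feature found for marker {marker!r}"
            )
        series = profile.series(drug, marker, candidates[0])
    kr = series.to_numpy()
    if kr.size == 0:
        raise ConfigurationError(f"drug {drug!r} has no KR values for {marker!r}")
    if (kr[-top_n:] <= threshold).any():
        return False
    upper = kr[kr.size // 2:]
    return bool((np.diff(upper) >= -monotone_tol).all())


def flag_nonspecific_all(profile: KRProfile, **kwargs) -> pd.Series:
    """Non-specific flag per drug in the profile."""
    return pd.Series(
        {drug: flag_nonspecific(profile, drug, **kwargs) for drug in profile.drugs},
        name="nonspecific",
    )


class EfficacyResults:
    """Fitted marker weights and the resulting per-drug E_predict values.

    Attributes
    ----------
    weights : pandas.Series
        Optimized weight (0, 1 or 2) per marker.
    e_predict : pandas.Series
        Non-negative E_predict per drug (all drugs in the SAUC matrix).
    nonspecific_flags : pandas.Series
        Per-drug boolean; flagged drugs have E_predict forced to 0.
    rho_achieving_count : int
        Number of lattice vectors that reached rho = 1 on the training set.
    weight_frequency : pandas.DataFrame
        Markers × weight levels histogram over the rho = 1 vectors.
    """

    def __init__(
        self,
        weights: pd.Series,
        e_predict: pd.Series,
        nonspecific_flags: pd.Series,
        rho_achieving_count: int,
        weight_frequency: pd.DataFrame,
        training_drugs: list[str],
        training_model: str | None,
        max_outliers: int,
    ):
        self.weights = weights
        self.e_predict = e_predict
        self.nonspecific_flags = nonspecific_flags
        self.rho_achieving_count = int(rho_achieving_count)
        self.weight_frequency = weight_frequency
        self.training_drugs = list(training_drugs)
        self.training_model = training_model
        self.max_outliers = max_outliers

    @property
    def weight_vector(self) -> np.ndarray:
        return self.weights.to_numpy()

    def summary(self) -> str:
        lines = [
            "E_predict weight optimization",
            "=" * 45,
            f"training model:        {self.training_model or '(unspecified)'}",
            f"training drugs:        {len(self.training_drugs)}",
            f"lattice size:          {3 ** len(self.weights)}",
            f"vectors with rho = 1:  {self.rho_achieving_count}",
            f"outliers allowed:      {self.max_outliers}",
            "",
            "optimized weights (mode over rho = 1 vectors):",
        ]
        freq = self.weight_frequency
        for marker, w in self.weights.items():
            counts = "  ".join(f"w{lvl}:{int(freq.loc[marker, lvl]):>6d}" for lvl in WEIGHT_LEVELS)
            lines.append(f"  {marker:<14s} w* = {int(w)}   ({counts})")
        lines.append("")
        lines.append("E_predict (descending):")
        for drug, e in self.e_predict.sort_values(ascending=False).items():
            flag = "  [non-specific]" if bool(self.nonspecific_flags.get(drug, False)) else ""
            lines.append(f"  {drug:<24s} {e:>12.1f}{flag}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<EfficacyResults: {len(self.e_predict)} drugs, "
            f"rho_achieving_count={self.rho_achieving_count}>"
        )


def _aligned_training(
    sauc: SAUCMatrix, training: InVivoIndex, model: str | None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    y_all = training.for_model(model) if model is not None else (
        training.frame.set_index("drug_id")["e_invivo"]
    )
    common = [d for d in sauc.drugs if d in y_all.index]
    if len(common) < 4:
        raise ValidationError(
            f"need >= 4 training drugs present in both tables, got {len(common)}"
        )
    S = sauc.frame.loc[common].to_numpy(dtype=float)
    y = y_all.loc[common].to_numpy(dtype=float)
    return common, S, y


def _candidate_matrix(
    W: np.ndarray, S: np.ndarray, flags: np.ndarray | None, clip: bool
) -> np.ndarray:
    E = W.astype(float) @ S.T
    if clip:
        E = np.maximum(E, 0.0)
    if flags is not None and flags.any():
        E[:, flags] = 0.0
    return E


def optimize_weights(
    sauc: SAUCMatrix,
    training: InVivoIndex,
    model: str | None = None,
    nonspecific_flags: pd.Series | None = None,
    clip: bool = True,
    max_outliers: int = 1,
) -> EfficacyResults:
    """Exhaustive weight search for perfect rank concordance with E_in_vivo.

    Every vector in {0,1,2}^n_markers is scored; vectors reaching rho = 1
    (one outlier allowed) vote for the per-marker optimized weight by
    majority. Raises :class:`OptimizationError`, reporting the best rho
    attained, when no vector reaches 1.
    """
    markers = sauc.markers
    common, S, y = _aligned_training(sauc, training, model)
    flags_all = (
        nonspecific_flags.reindex(sauc.drugs).fillna(False).astype(bool)
        if nonspecific_flags is not None
        else pd.Series(False, index=sauc.drugs)
    )
    train_flags = flags_all.loc[common].to_numpy()

    W = enumerate_weight_vectors(len(markers))
    E = _candidate_matrix(W, S, train_flags, clip)
    best = _best_rhos(E, y, max_outliers=max_outliers)
    achieved = best >= 1.0 - _RHO_ONE_TOL
    if not achieved.any():
        best_rho = float(np.nanmax(best))
        raise OptimizationError(
            f"no weight vector achieved rho = 1; best rho attained = {best_rho:.4f}",
            best_rho=best_rho,
        )

    W_hit = W[achieved]
    freq = pd.DataFrame(
        {lvl: (W_hit == lvl).sum(axis=0) for lvl in WEIGHT_LEVELS}, index=markers
    )
    # mode per marker; np.argmax takes the first (= smallest) level on ties
    weights = pd.Series(
        np.argmax(freq.to_numpy(), axis=1).astype(int), index=markers, name="weight"
    )

    e_predict = pd.Series(
        {
            drug: compute_epredict(
                sauc.row(drug).to_numpy(), weights.to_numpy(), bool(flags_all[drug])
            )
            for drug in sauc.drugs
        },
        name="e_predict",
    )
    return EfficacyResults(
        weights=weights,
        e_predict=e_predict,
        nonspecific_flags=flags_all,
        rho_achieving_count=int(achieved.sum()),
        weight_frequency=freq,
        training_drugs=common,
        training_model=model,
        max_outliers=max_outliers,
    )


def weight_robustness(
    sauc: SAUCMatrix,
    training: InVivoIndex,
    model: str | None = None,
    n_random: int = 0,
    seed: int | None = None,
    clip: bool = True,
    max_outliers: int = 1,
):
    """Fraction of the weight lattice reaching rho = 1, with a permuted control.

    Returns ``(fraction_rho1, random_fraction_rho1)``; the second element is
    the same fraction averaged over ``n_random`` random permutations of the
    in vivo ranks (``None`` when ``n_random`` is 0).
    """
    markers = sauc.markers
    _, S, y = _aligned_training(sauc, training, model)
    W = enumerate_weight_vectors(len(markers))
    E = _candidate_matrix(W, S, None, clip)

    def fraction(target: np.ndarray) -> float:
        best = _best_rhos(E, target, max_outliers=max_outliers)
        return float((best >= 1.0 - _RHO_ONE_TOL).mean())

    frac = fraction(y)
    if n_random <= 0:
        return frac, None
    rng = np.random.default_rng(seed)
    random_fracs = [fraction(rng.permutation(y)) for _ in range(n_random)]
    return frac, float(np.mean(random_fracs))


class EfficacyModel:
    """In vitro efficacy predictor fitted to an in vivo training index.

    Parameters
    ----------
    sauc : SAUCMatrix
        Drugs × markers SAUC scores from the high-content screen.
    invivo : InVivoIndex
        Histology-derived efficacy indices; only drugs shared with ``sauc``
        train the weights.
    model : str, optional
        Fibrosis model whose entries form the training set
        (e.g. ``"CCl4_treatment"``).
    nonspecific_flags : pandas.Series, optional
        Per-drug flags from :func:`flag_nonspecific_all`.

    Examples
    --------
    >>> results = EfficacyModel(sauc, invivo, model="CCl4_treatment").fit()
    >>> results.e_predict.sort_values(ascending=False).head()
    """

    def __init__(
        self,
        sauc: SAUCMatrix,
        invivo: InVivoIndex,
        model: str | None = None,
        nonspecific_flags: pd.Series | None = None,
    ):
        self.sauc = sauc
        self.invivo = invivo
        self.model = model
        self.nonspecific_flags = nonspecific_flags

    @classmethod
    def from_profile(
        cls,
        profile: KRProfile,
        directions,
        invivo: InVivoIndex,
        model: str | None = None,
        **sauc_kwargs,
    ) -> "EfficacyModel":
        """Build the model straight from a KR profile (computes SAUC and flags)."""
        from .sauc import compute_sauc

        sauc = compute_sauc(profile, directions, **sauc_kwargs)
        flags = flag_nonspecific_all(profile)
        return cls(sauc, invivo, model=model, nonspecific_flags=flags)

    def fit(self, clip: bool = True, max_outliers: int = 1) -> EfficacyResults:
        return optimize_weights(
            self.sauc,
            self.invivo,
            model=self.model,
            nonspecific_flags=self.nonspecific_flags,
            clip=clip,
            max_outliers=max_outliers,
        )
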