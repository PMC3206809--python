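"""In vitro–in vivo correlation (IVIVC), prediction and drug profiling.

The per-model relation between the in vitro predictor E_predict and the
histology-derived E_in_vivo is summarised by an ordinary least-squares line,
optionally after excluding one named (or automatically detected) outlier.
The fitted line converts an E_predict value into a predicted E_in_vivo,
which in turn can be inverted to a predicted post-treatment histological
score via St = Sc − E/Sc.

Profiling utilities stratify drugs into negative / positive / very-positive
efficacy groups, run PCA on the SAUC matrix to expose the marker axes that
carry the most variation, quantify how mean attainable rank correlation
saturates with the number of markers, and summarise per-group intensity KR
distributions as boxplot statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .epredict import _best_rhos, _candidate_matrix, enumerate_weight_vectors
from .exceptions import ValidationError
from .invivo import InVivoIndex
from .kr import KRProfile
from .sauc import SAUCMatrix

__all__ = [
    "LinearFit",
    "fit_ivivc",
    "predict_einvivo",
    "predict_treated_score",
    "IVIVC",
    "IVIVCResults",
    "DrugGroups",
    "assign_groups",
    "pca_on_sauc",
    "marker_saturation",
    "group_intensity_summary",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS line of E_in_vivo on E_predict (computed on included points only)."""

    slope: float
    intercept: float
    r_squared: float
    excluded_drug: str | None
    n_points: int


def _ols(x: np.ndarray, y: np.ndarray):
    model = sm.OLS(y, sm.add_constant(x))
    return model.fit()


def fit_ivivc(epredict: pd.Series, einvivo: pd.Series, exclude=None) -> LinearFit:
    """OLS of E_in_vivo on E_predict over the drugs common to both series.

    ``exclude`` may be a drug name, ``"auto"`` or ``None``. Auto mode drops
    the point with the largest absolute (externally) studentized residual,
    but only if doing so improves R² by more than 0.1.
    """
    common = [d for d in epredict.index if d in einvivo.index]
    if len(common) < 4:
        raise ValidationError(f"need >= 4 drugs before exclusion, got {len(common)}")
    x_all = epredict.loc[common].to_numpy(dtype=float)
    y_all = einvivo.loc[common].to_numpy(dtype=float)

    excluded: str | None = None
    if exclude == "auto":
        res_full = _ols(x_all, y_all)
        student = res_full.get_influence().resid_studentized_external
        candidate = int(np.argmax(np.abs(student)))
        keep = np.arange(len(common)) != candidate
        res_drop = _ols(x_all[keep], y_all[keep])
        if res_drop.rsquared > res_full.rsquared + 0.1:
            excluded = common[candidate]
    elif exclude is not None:
        if exclude not in common:
            raise ValidationError(f"excluded drug {exclude!r} not among fitted drugs")
        excluded = exclude

    if excluded is not None:
        mask = np.array([d != excluded for d in common])
        x, y = x_all[mask], y_all[mask]
    else:
        x, y = x_all, y_all
    if x.size < 3:
        raise ValidationError("fewer than 3 points after exclusion")
    res = _ols(x, y)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        excluded_drug=excluded,
        n_points=int(x.size),
    )


def predict_einvivo(e_predict_value: float, fit: LinearFit) -> float:
    """Predicted E_in_vivo for one E_predict value under a fitted line."""
    return fit.intercept + fit.slope * float(e_predict_value)


def predict_treated_score(e_invivo_pred: float, sc: float) -> float:
    """Invert E = (Sc − St) × Sc for the treated score St, clipped to [0, Sc]."""
    if sc <= 0:
        raise ValidationError("sc must be positive")
    return float(np.clip(sc - e_invivo_pred / sc, 0.0, sc))


class IVIVCResults:
    """Fitted IVIVC line plus prediction helpers."""

    def __init__(self, fit: LinearFit, drugs: list[str], model_label: str | None):
        self.fit = fit
        self.drugs = drugs
        self.model_label = model_label

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def intercept(self) -> float:
        return self.fit.intercept

    @property
    def r_squared(self) -> float:
        return self.fit.r_squared

    def predict(self, e_predict_value: float) -> float:
        return predict_einvivo(e_predict_value, self.fit)

    def predict_treated_score(self, e_predict_value: float, sc: float) -> float:
        return predict_treated_score(self.predict(e_predict_value), sc)

    def summary(self) -> str:
        f = self.fit
        return "\n".join(
            [
                "In vitro-in vivo correlation (OLS)",
                "=" * 40,
                f"model:          {self.model_label or '(unspecified)'}",
                f"n points:       {f.n_points}"
                + (f" (excluded: {f.excluded_drug})" if f.excluded_drug else ""),
                f"E_in_vivo = {f.intercept:.4g} + {f.slope:.4g} x E_predict",
                f"R^2:            {f.r_squared:.3f}",
            ]
        )

    def plot(self, epredict: pd.Series, einvivo: pd.Series, ax=None):
        """Scatter of the fitted drugs with the regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        common = [d for d in epredict.index if d in einvivo.index]
        x = epredict.loc[common].to_numpy(dtype=float)
        y = einvivo.loc[common].to_numpy(dtype=float)
        ax.scatter(x, y, color="tab:blue")
        for d, xi, yi in zip(common, x, y):
            style = dict(color="tab:red") if d == self.fit.excluded_drug else {}
            ax.annotate(d, (xi, yi), fontsize=8, **style)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.fit.intercept + self.fit.slope * grid, "k--")
        ax.set_xlabel("E_predict")
        ax.set_ylabel("E_in_vivo")
        ax.set_title(
            f"{self.model_label or ''}  R$^2$={self.fit.r_squared:.2f}".strip()
        )
        return ax

    def __repr__(self) -> str:
        return (
            f"<IVIVCResults: slope={self.slope:.3g}, intercept={self.intercept:.3g}, "
            f"R2={self.r_squared:.3f}>"
        )


class IVIVC:
    """Model object for the E_predict → E_in_vivo regression.

    Examples
    --------
    >>> results = IVIVC(e_predict, e_invivo, model_label="CCl4_treatment").fit(
    ...     exclude="taurine")
    >>> results.predict(39437)
    """

    def __init__(self, epredict: pd.Series, einvivo: pd.Series,
                 model_label: str | None = None):
        self.epredict = epredict
        self.einvivo = einvivo
        self.model_label = model_label

    @classmethod
    def from_index(cls, epredict: pd.Series, index: InVivoIndex, model: str) -> "IVIVC":
        return cls(epredict, index.for_model(model), model_label=model)

    def fit(self, exclude=None) -> IVIVCResults:
        fit = fit_ivivc(self.epredict, self.einvivo, exclude=exclude)
        common = [d for d in self.epredict.index if d in self.einvivo.index]
        return IVIVCResults(fit, common, self.model_label)


@dataclass(frozen=True)
class DrugGroups:
    """Efficacy strata: n (E_predict = 0), p (positive), vp (top ``vp_size``)."""

    assignments: dict
    vp_size: int

    def drugs_in(self, group: str) -> list[str]:
        return sorted(d for d, g in self.assignments.items() if g == group)

    def __getitem__(self, drug: str) -> str:
        return self.assignments[drug]


def assign_groups(epredict: pd.Series | dict, vp_size: int = 7) -> DrugGroups:
    """Partition drugs by E_predict: zero → n; top ``vp_size`` positive → vp.

    Ties at the vp boundary include the alphabetically-first drug.
    """
    series = pd.Series(epredict, dtype=float)
    positive = series[series > 0]
    if vp_size >= len(positive):
        raise ValidationError(
            f"vp_size={vp_size} must be smaller than the number of drugs with "
            f"positive E_predict ({len(positive)})"
        )
    ranked = sorted(positive.items(), key=lambda item: (-item[1], item[0]))
    vp = {drug for drug, _ in ranked[:vp_size]}
    assignments = {
        drug: ("n" if value == 0 else ("vp" if drug in vp else "p"))
        for drug, value in series.items()
    }
    return DrugGroups(assignments=assignments, vp_size=vp_size)


def pca_on_sauc(sauc_rows, unit_variance: bool = False):
    """PCA of a drugs × markers SAUC matrix.

    Columns are mean-centered (optionally scaled to unit variance); returns
    ``(components, variance_ratios)`` where ``components`` is a DataFrame of
    loadings (components × markers) and ``variance_ratios`` sum to 1 in
    descending order.
    """
    frame = (
        sauc_rows.frame if isinstance(sauc_rows, SAUCMatrix) else pd.DataFrame(sauc_rows)
    )
    if len(frame) < 2:
        raise ValidationError("PCA needs at least 2 drugs")
    X = frame.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("SAUC matrix has no variance; PCA is degenerate")
    if unit_variance:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA()
    pca.fit(X)
    components = pd.DataFrame(
        pca.components_,
        columns=frame.columns,
        index=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
    )
    return components, pca.explained_variance_ratio_


def marker_saturation(
    sauc: SAUCMatrix,
    training: InVivoIndex,
    model: str | None,
    subset_size: int,
    n_subsets: int = 20,
    seed: int | None = None,
    max_outliers: int = 1,
) -> float:
    """Mean best attainable rho over random marker subsets of a given size.

    For each sampled subset the whole {0,1,2}^k weight lattice restricted to
    those markers is scored and the best rho (one outlier allowed) is kept;
    the mean over subsets measures how informative panels of that size are.
    """
    from .epredict import _aligned_training

    markers = sauc.markers
    if not 1 <= subset_size <= len(markers):
        raise ValidationError(
            f"subset_size must be in [1, {len(markers)}], got {subset_size}"
        )
    _, S, y = _aligned_training(sauc, training, model)
    rng = np.random.default_rng(seed)
    if subset_size == len(markers):
        subsets = [np.arange(len(markers))]
    else:
        subsets = [
            rng.choice(len(markers), size=subset_size, replace=False)
            for _ in range(n_subsets)
        ]
    W = enumerate_weight_vectors(subset_size)
    best_rhos = []
    for idx in subsets:
        E = _candidate_matrix(W, S[:, idx], None, clip=True)
        best = _best_rhos(E, y, max_outliers=max_outliers)
        best_rhos.append(float(np.nanmax(best)))
    return float(np.mean(best_rhos))


def group_intensity_summary(
    profile: KRProfile,
    groups: DrugGroups,
    feature_pattern: str = "avg_intensity",
    which: tuple[str, ...] = ("n", "p", "vp", "all", "positive"),
) -> pd.DataFrame:
    """Boxplot statistics of mean intensity KR per efficacy group and marker.

    For each drug and marker the KR values of features matching
    ``feature_pattern`` are averaged over features and concentrations; the
    distribution of these per-drug means within each group is summarised by
    median, quartiles, 1.5×IQR whiskers and the list of outlying drugs.
    ``"all"`` pools every group, ``"positive"`` pools p and vp.
    """
    frame = profile.frame
    matching = frame[frame["feature"].str.contains(feature_pattern, regex=False)]
    if matching.empty:
        raise ValidationError(
            f"no features matching {feature_pattern!r} in the profile"
        )
    per_drug = (
        matching.groupby(["drug_id", "marker"], sort=False)["kr"].mean().reset_index()
    )
    membership = {
        "n": {"n"},
        "p": {"p"},
        "vp": {"vp"},
        "all": {"n", "p", "vp"},
        "positive": {"p", "vp"},
    }
    rows = []
    for group in which:
        wanted = membership[group]
        drugs = {d for d, g in groups.assignments.items() if g in wanted}
        sub = per_drug[per_drug["drug_id"].isin(drugs)]
        for marker, mk in sub.groupby("marker", sort=False):
            v = mk["kr"].to_numpy()
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = mk.loc[(mk["kr"] < lo) | (mk["kr"] > hi), "drug_id"].tolist()
            rows.append(
                {
                    "group": group,
                    "marker": marker,
                    "n": int(v.size),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": max(lo, v.min()),
                    "whisker_high": min(hi, v.max()),
                    "outliers": sorted(outliers),
                }
            )
    return pd.DataFrame(rows)
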