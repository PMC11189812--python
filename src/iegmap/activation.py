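"""Brain-wide IEG count classification and forward-model activation patterns.

Workflow (the two-comparison design: drug vs vehicle, drug vs enantiomer):

1. z-score each region's cell counts across the full three-group cohort;
2. fit a soft-margin linear SVM on the two groups of a comparison;
3. transform the backward-model weights ``W`` into a forward-model
   activation pattern ``A = Sigma_x W Sigma_s^-1`` with
   ``Sigma_s = W^T Sigma_x W`` (Haufe et al. transform), which is
   interpretable as each region's contribution to the discriminated signal;
4. rank regions by ``|A|`` and nominate the top region as the discriminator.

The module also bins insular-cortex cell coordinates along the
anteroposterior axis (aIC = +2.50 to +1.45 mm anterior to bregma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.svm import SVC

from .errors import ConfigurationError, DegenerateInputError, FormatError
from .simulate import AIC_AP_RANGE, IC_AP_RANGE

__all__ = [
    "CountStandardizer",
    "ActivationPatternMapper",
    "ZScoreMatrix",
    "ClassifierModel",
    "ActivationPattern",
    "APDistribution",
    "standardize_counts",
    "fit_linear_svm",
    "haufe_activation",
    "rank_regions",
    "classify_and_map",
    "bin_ap_distribution",
    "default_ap_edges",
    "validate_count_table",
]

META_COLS = ("animal_id", "group")


def validate_count_table(table: pd.DataFrame) -> list[str]:
    """Check a counts table (animal_id, group, one column per region).

    Returns the region column names; raises :class:`FormatError` on missing
    metadata columns, non-integer or negative counts, or missing cells.
    """
    for col in META_COLS:
        if col not in table.columns:
            raise FormatError(f"counts table lacks required column {col!r}")
    regions = [c for c in table.columns if c not in META_COLS]
    if not regions:
        raise FormatError("counts table has no region columns")
    block = table[regions]
    if block.isna().any().any():
        r, c = next(zip(*np.where(block.isna().to_numpy())))
        raise FormatError(f"missing count at row {r + 1}, region {regions[c]!r}")
    vals = block.to_numpy()
    if np.any(vals < 0):
        r, c = map(int, next(zip(*np.where(vals < 0))))
        raise FormatError(
            f"negative count at row {r + 1}, region {regions[c]!r}"
        )
    return regions


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScoreMatrix:
    """Animals x regions z-scores plus the per-region standardization constants."""

    z: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    region_names: tuple[str, ...]
    animal_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=list(self.region_names))
        df.insert(0, "group", list(self.groups))
        df.insert(0, "animal_id", list(self.animal_ids))
        return df


class CountStandardizer(TransformerMixin, BaseEstimator):
    """Per-region z-scoring transformer (sample SD, denominator n - 1).

    Unlike ``StandardScaler`` this uses the unbiased SD and refuses
    zero-variance regions by name, which for small cohorts (n = 15 animals)
    is the convention reported alongside the counts.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise DegenerateInputError("need a 2-D table with >= 2 animals")
        if not np.all(np.isfinite(X)):
            raise FormatError("non-finite values in count table")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        names = getattr(self, "feature_names_in_", None)
        bad = np.flatnonzero(self.scale_ == 0)
        if bad.size:
            label = names[bad[0]] if names is not None else f"column {bad[0]}"
            raise DegenerateInputError(
                f"region {label} has zero variance across the cohort"
            )
        return self

    def fit_frame(self, df: pd.DataFrame):
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self.fit(df.to_numpy(dtype=float))

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


def standardize_counts(table: pd.DataFrame) -> ZScoreMatrix:
    """z-score a counts table per region across all animals of the cohort."""
    regions = validate_count_table(table)
    scaler = CountStandardizer(ddof=1)
    scaler.fit_frame(table[regions])
    z = scaler.transform(table[regions].to_numpy(dtype=float))
    return ZScoreMatrix(
        z=z,
        mean=scaler.mean_,
        sd=scaler.scale_,
        region_names=tuple(regions),
        animal_ids=tuple(table["animal_id"].astype(str)),
        groups=tuple(table["group"].astype(str)),
    )


# ---------------------------------------------------------------------------
# Linear SVM (backward model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierModel:
    """Fitted soft-margin linear SVM in backward-model form."""

    w: np.ndarray                 # (M,) weight vector
    intercept: float
    positive_label: str
    negative_label: str
    C: float
    training_accuracy: float
    margin: float                 # geometric margin 2 / ||w||

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.intercept

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.positive_label, self.negative_label)


def fit_linear_svm(
    X,
    labels,
    C: float = 1.0,
    positive_label: str | None = None,
    tol: float = 1e-10,
) -> ClassifierModel:
    """Fit a two-class soft-margin linear SVM, deterministically.

    The dual problem is solved by libsvm's SMO on a canonical +/-1 encoding
    anchored to the first sample's class; the returned ``(w, b)`` are then
    oriented so that ``positive_label`` (default: the first sample's class)
    scores positive.  Swapping the two class designations therefore negates
    ``(w, b)`` bit-exactly.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise FormatError("feature matrix and labels are misaligned")
    if not np.all(np.isfinite(X)):
        raise FormatError("non-finite features passed to the SVM")
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise DegenerateInputError(
            f"need exactly two classes, got {list(classes)}"
        )
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise DegenerateInputError("each class needs >= 2 animals")
    if C <= 0:
        raise ConfigurationError("C must be > 0")

    anchor = labels[0]
    other = classes[1] if classes[0] == anchor else classes[0]
    y_canon = np.where(labels == anchor, 1.0, -1.0)
    svc = SVC(kernel="linear", C=C, tol=tol, shrinking=False, cache_size=64)
    svc.fit(X, y_canon)
    # sklearn orders classes_ as [-1, 1]; decision > 0 means class +1 (anchor)
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])

    if positive_label is None:
        positive_label = anchor
    if positive_label == anchor:
        pos, neg = anchor, other
    elif positive_label == other:
        w, b = -w, -b
        pos, neg = other, anchor
    else:
        raise ConfigurationError(
            f"positive_label {positive_label!r} not among {list(classes)}"
        )
    pred = np.where(X @ w + b >= 0, pos, neg)
    acc = float(np.mean(pred == labels))
    wn = float(np.linalg.norm(w))
    if wn == 0:
        raise DegenerateInputError("SVM fit produced a zero weight vector")
    return ClassifierModel(
        w=w, intercept=b, positive_label=str(pos), negative_label=str(neg),
        C=float(C), training_accuracy=acc, margin=2.0 / wn,
    )


# ---------------------------------------------------------------------------
# Forward-model activation pattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationPattern:
    """Forward-model pattern ``A = Sigma_x W Sigma_s^-1`` for a binary decoder.

    ``Sigma_x`` is the data covariance of the features used for the fit and
    ``Sigma_s = W^T Sigma_x W`` is the (scalar, K = 1) variance of the
    latent decision value.
    """

    A: np.ndarray                 # (M,)
    sigma_x: np.ndarray           # (M, M)
    sigma_s: float                # scalar latent-factor variance
    region_names: tuple[str, ...] = ()


def haufe_activation(
    model: ClassifierModel,
    X,
    region_names: tuple[str, ...] = (),
) -> ActivationPattern:
    """Transform classifier weights into a forward-model activation pattern.

    ``X`` must be the exact feature matrix the classifier was fitted on; the
    covariance is the unbiased (n - 1) sample covariance of those rows, with
    classes pooled.  Raises :class:`DegenerateInputError` when the latent
    variance ``W^T Sigma_x W`` is not positive.
    """
    X = np.asarray(X, dtype=float)
    sigma_x = np.cov(X, rowvar=False, ddof=1)
    sigma_x = np.atleast_2d(sigma_x)
    w = model.w
    sigma_s = float(w @ sigma_x @ w)
    if not np.isfinite(sigma_s) or sigma_s <= 0:
        raise DegenerateInputError(
            f"latent-factor variance W'Sigma_x W = {sigma_s:g} is not positive"
        )
    A = (sigma_x @ w) / sigma_s
    return ActivationPattern(
        A=A, sigma_x=sigma_x, sigma_s=sigma_s,
        region_names=tuple(region_names),
    )


def rank_regions(
    pattern: ActivationPattern,
    region_names: tuple[str, ...] | None = None,
) -> list[tuple[str, float]]:
    """Rank regions by |activation|, descending; ties keep input order.

    The first entry is the nominated discriminating region.
    """
    names = tuple(region_names) if region_names is not None else pattern.region_names
    A = np.asarray(pattern.A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise DegenerateInputError("non-finite activation pattern")
    if not names:
        names = tuple(f"R{i + 1:02d}" for i in range(A.size))
    if len(names) != A.size:
        raise FormatError("region_names length does not match the pattern")
    order = np.argsort(-np.abs(A), kind="stable")
    return [(names[i], float(abs(A[i]))) for i in order]


# ---------------------------------------------------------------------------
# Multi-comparison driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    comparison: tuple[str, str]
    model: ClassifierModel
    pattern: ActivationPattern
    ranking: list[tuple[str, float]]

    @property
    def nominated_region(self) -> str:
        return self.ranking[0][0]


def classify_and_map(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]] = (("R-ket", "saline"), ("R-ket", "S-ket")),
    C: float = 1.0,
    covariance_on: str = "z",
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Run standardize -> subset -> SVM -> activation -> rank per comparison.

    z-scores are computed once across all animals of the full cohort; each
    comparison then uses only the rows of its two groups (the first group of
    each pair is the positive class).  Returns the per-comparison results and
    a joint region x comparison table of |A| with a ``min_abs`` column — the
    tabular form of the two-classification scatter, whose top ``min_abs``
    rows are the regions contributing to both discriminations.

    ``covariance_on`` selects the data entering Sigma_x: ``"z"`` (default)
    uses the z-scored features the SVM saw; ``"raw"`` uses the raw counts of
    the same animals, for sensitivity analysis of the forward model.
    """
    if covariance_on not in ("z", "raw"):
        raise ConfigurationError(f"covariance_on must be 'z' or 'raw', got {covariance_on!r}")
    zmat = standardize_counts(table)
    raw = table[list(zmat.region_names)].to_numpy(dtype=float)
    groups = np.asarray(zmat.groups, dtype=object)
    present = set(groups)
    results = []
    joint = pd.DataFrame(index=list(zmat.region_names))
    for pos, neg in comparisons:
        for g in (pos, neg):
            if g not in present:
                raise ConfigurationError(f"group {g!r} absent from the table")
        mask = (groups == pos) | (groups == neg)
        Xp = zmat.z[mask]
        model = fit_linear_svm(Xp, groups[mask], C=C, positive_label=pos)
        X_cov = Xp if covariance_on == "z" else raw[mask]
        pattern = haufe_activation(model, X_cov, region_names=zmat.region_names)
        ranking = rank_regions(pattern)
        results.append(ComparisonResult((pos, neg), model, pattern, ranking))
        joint[f"{pos}_vs_{neg}"] = np.abs(pattern.A)
    joint["min_abs"] = joint.min(axis=1)
    joint = joint.sort_values("min_abs", ascending=False, kind="stable")
    return results, joint


# ---------------------------------------------------------------------------
# Anteroposterior distribution
# ---------------------------------------------------------------------------

def default_ap_edges(n_bins: int = 10) -> np.ndarray:
    """Equal bins over the IC extent, decreasing anterior -> posterior."""
    return np.linspace(IC_AP_RANGE[0], IC_AP_RANGE[1], n_bins + 1)


def _subdivision(upper: float) -> str:
    # aIC = (+1.45, +2.50]; mIC = (+0.40, +1.45]; pIC = (-1.00, +0.40]
    if upper > AIC_AP_RANGE[1] + 1e-9:
        return "aIC"
    if upper > 0.40 + 1e-9:
        return "mIC"
    return "pIC"


@dataclass(frozen=True)
class APDistribution:
    """Per-bin, per-treatment counts of cells along the AP axis."""

    edges: np.ndarray                      # decreasing, len = n_bins + 1
    counts: pd.DataFrame                   # n_bins x treatments
    overflow: pd.Series                    # per-treatment out-of-range count
    subdivisions: tuple[str, ...]          # aIC/mIC/pIC per bin
    aic_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def total(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.overflow


def bin_ap_distribution(
    cells: pd.DataFrame,
    edges: np.ndarray | None = None,
) -> APDistribution:
    """Histogram IC cells along the anteroposterior axis, per treatment.

    Bin ``i`` covers ``(edges[i+1], edges[i]]`` with ``edges`` decreasing
    from anterior to posterior; the anterior-most edge is inclusive.  Cells
    outside the edge span are tallied in an overflow bucket, never dropped.
    The aIC aggregate counts cells with AP in (+1.45, +2.50].
    """
    edges = default_ap_edges() if edges is None else np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) >= 0):
        raise ConfigurationError("edges must be a strictly decreasing 1-D array")
    n_bins = edges.size - 1
    treatments = list(pd.unique(cells["group"].astype(str))) if len(cells) else []
    counts = pd.DataFrame(0, index=range(1, n_bins + 1), columns=treatments)
    overflow = pd.Series(0, index=treatments)
    aic = pd.Series(0, index=treatments)
    for g in treatments:
        ap = cells.loc[cells["group"].astype(str) == g, "ap_mm"].to_numpy(dtype=float) \
            if len(cells) else np.empty(0)
        inside = (ap <= edges[0]) & (ap > edges[-1])
        overflow[g] = int((~inside).sum())
        # searchsorted on the descending edges: bin i <=> edges[i+1] < ap <= edges[i]
        idx = np.searchsorted(-edges, -ap[inside], side="right") - 1
        idx = np.clip(idx, 0, n_bins - 1)
        for i in idx:
            counts.loc[int(i) + 1, g] += 1
        aic[g] = int(((ap > AIC_AP_RANGE[1]) & (ap <= AIC_AP_RANGE[0])).sum())
    subdivisions = tuple(_subdivision(edges[i]) for i in range(n_bins))
    return APDistribution(
        edges=edges, counts=counts, overflow=overflow,
        subdivisions=subdivisions, aic_counts=aic,
    )


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class ActivationPatternMapper(ClassifierMixin, BaseEstimator):
    """Linear-SVM decoder with a forward-model activation pattern.

    A scikit-learn classifier: ``fit(X, y)`` on a two-class (animals x
    regions) matrix fits the soft-margin linear SVM and stores both the
    backward model (``coef_``, ``intercept_``) and the forward model
    (``activation_pattern_``, ``sigma_x_``, ``sigma_s_``) plus the
    |A|-ranking of features (``ranking_``).

    Parameters
    ----------
    C : float
        Soft-margin penalty of the SVM.
    positive_label : str or None
        Class mapped to positive decision values; default is the class of
        the first training sample.
    """

    def __init__(self, C: float = 1.0, positive_label: str | None = None):
        self.C = C
        self.positive_label = positive_label

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        model = fit_linear_svm(X, y, C=self.C, positive_label=self.positive_label)
        names = tuple(getattr(self, "feature_names_in_", ()))
        pattern = haufe_activation(model, X, region_names=names)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.asarray([model.negative_label, model.positive_label],
                                   dtype=object)
        self.coef_ = model.w
        self.intercept_ = model.intercept
        self.model_ = model
        self.activation_pattern_ = pattern.A
        self.sigma_x_ = pattern.sigma_x
        self.sigma_s_ = pattern.sigma_s
        self.pattern_ = pattern
        self.ranking_ = rank_regions(pattern)
        self.training_accuracy_ = model.training_accuracy
        return self

    def decision_function(self, X):
        if hasattr(X, "to_numpy"):
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])

    @property
    def nominated_region_(self) -> str:
        return self.ranking_[0][0]
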