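"""Second-order polynomial anxiety estimator and exhaustive subset search.

The anxiety level reported on the 0-10 SUD scale is estimated by a full
quadratic (second-order Taylor-type) function of a small subset of the 32
physiological features::

    ANX* = sum_{i<=j} alpha_ij x_i x_j + sum_i beta_i x_i + gamma

For a subset of P features the function has P(P+1)/2 + P + 1 coefficients,
identified by least squares on an identification set and validated on a
held-out validation set.  The subset itself is chosen by exhaustive search:
every one of the C(32, P) subsets is fitted on the identification set and the
subset with the smallest sum of squared residuals wins (ties broken by the
lexicographically first subset in canonical feature order).

The identification/validation split is stratified by reported anxiety level
so both subsets carry (nearly) the same rating distribution: with the study
proportions (90 of 105 points for identification) each level k contributes
``round(6/7 * N_k)`` points to the identification set, rounding halves away
from zero.

Estimates are real-valued; classification into 2 or 3 anxiety classes is a
separate thresholding step (:func:`classify`), with the extreme intervals
extended to cover out-of-range estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "PolyModel",
    "SplitPlan",
    "SearchResult",
    "ClassScheme",
    "ConfusionReport",
    "AnxietyRegression",
    "AnxietyRegressionResults",
    "n_coefficients",
    "n_combinations",
    "build_design_row",
    "build_design_matrix",
    "fit",
    "predict",
    "ssr",
    "stratified_split",
    "exhaustive_search",
    "classify",
    "confusion",
]


def n_coefficients(p: int) -> int:
    """Coefficient count of the quadratic estimator for a size-``p`` subset.

    ``p(p+1)/2`` pairwise-product terms, ``p`` linear terms and the intercept;
    e.g. 171 coefficients for a 17-feature subset.
    """
    if p < 1 or int(p) != p:
        raise ValueError(f"subset size must be a positive integer, got {p}")
    p = int(p)
    return p * (p + 1) // 2 + p + 1


def n_combinations(n: int, p: int) -> int:
    """Exact binomial coefficient C(n, p)."""
    if p < 0 or n < 0 or p > n:
        raise ValueError(f"invalid pool/subset sizes ({n}, {p})")
    return math.comb(n, p)


def build_design_row(x: Sequence[float]) -> np.ndarray:
    """Expand one feature vector into the quadratic design row.

    Terms are ordered: products ``x_i * x_j`` for ``i <= j`` in lexicographic
    (i, j) order, then the linear terms, then the constant 1.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    prods = [x[i] * x[j] for i in range(p) for j in range(i, p)]
    return np.concatenate([prods, x, [1.0]])


def build_design_matrix(X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`build_design_row` over the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    cols = [X[:, i] * X[:, j] for i in range(p) for j in range(i, p)]
    cols.extend(X[:, i] for i in range(p))
    cols.append(np.ones(n))
    return np.column_stack(cols)


@dataclass
class PolyModel:
    """Coefficients of the quadratic estimator over a named feature subset."""

    feature_names: list[str]
    coef: np.ndarray  # aligned with build_design_row order

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        p = len(self.feature_names)
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be distinct")
        if self.coef.size != n_coefficients(p):
            raise ValueError(
                f"expected {n_coefficients(p)} coefficients for {p} features, "
                f"got {self.coef.size}"
            )

    @property
    def p(self) -> int:
        return len(self.feature_names)

    @property
    def alpha(self) -> dict[tuple[int, int], float]:
        """Quadratic coefficients keyed by 1-based (i, j) with i <= j."""
        p = self.p
        out = {}
        k = 0
        for i in range(p):
            for j in range(i, p):
                out[(i + 1, j + 1)] = float(self.coef[k])
                k += 1
        return out

    @property
    def beta(self) -> dict[int, float]:
        p = self.p
        n_alpha = p * (p + 1) // 2
        return {i + 1: float(self.coef[n_alpha + i]) for i in range(p)}

    @property
    def gamma(self) -> float:
        return float(self.coef[-1])

    def to_json(self, path=None) -> str:
        payload = {
            "features": self.feature_names,
            "alpha": {f"{i},{j}": v for (i, j), v in self.alpha.items()},
            "beta": {str(i): v for i, v in self.beta.items()},
            "gamma": self.gamma,
            "p": self.p,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PolyModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        names = list(payload["features"])
        p = len(names)
        coef = np.zeros(n_coefficients(p))
        k = 0
        for i in range(1, p + 1):
            for j in range(i, p + 1):
                coef[k] = payload["alpha"].get(f"{i},{j}", 0.0)
                k += 1
        for i in range(1, p + 1):
            coef[k] = payload["beta"].get(str(i), 0.0)
            k += 1
        coef[-1] = payload["gamma"]
        return cls(feature_names=names, coef=coef)


def fit(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str]) -> PolyModel:
    """Least-squares identification of the quadratic coefficients.

    Minimizes ``S = sum (ANX - ANX*)^2``; rank-deficient designs return the
    minimum-norm minimizer so enumeration over many subsets never aborts.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("cannot fit on an empty dataset")
    if X.shape[0] != y.size:
        raise ValueError("row count of X must match length of y")
    A = build_design_matrix(X)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return PolyModel(feature_names=list(feature_names), coef=coef)


def predict(model: PolyModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the estimator; returns unclamped real-valued estimates."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(
            f"model expects {model.p} features, got {X.shape[1]} columns"
        )
    return build_design_matrix(X) @ model.coef


def ssr(model: PolyModel, X: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared residuals of the model on a dataset."""
    resid = np.asarray(y, dtype=float).ravel() - predict(model, X)
    return float(resid @ resid)


@dataclass
class SplitPlan:
    """Stratified identification/validation partition of the dataset rows."""

    per_level_counts: dict[int, tuple[int, int]]
    identification_indices: np.ndarray
    validation_indices: np.ndarray
    seed: int

    @property
    def n_identification(self) -> int:
        return int(self.identification_indices.size)

    @property
    def n_validation(self) -> int:
        return int(self.validation_indices.size)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    ratings: Sequence[int], train_fraction: float = 6 / 7, seed: int = 0
) -> SplitPlan:
    """Split rows into identification/validation sets, stratified by rating.

    Level ``k`` with ``N_k`` occurrences contributes
    ``round(train_fraction * N_k)`` rows to the identification set (halves
    rounded away from zero) and the remainder to validation; membership
    within a level is chosen uniformly at random under ``seed``.
    """
    ratings = np.asarray(ratings)
    if ratings.size == 0:
        raise ValueError("cannot split an empty set of ratings")
    if np.any((ratings < 0) | (ratings > 10)):
        raise ValueError("ratings must lie in 0..10")
    rng = np.random.default_rng(seed)
    ident: list[int] = []
    valid: list[int] = []
    per_level: dict[int, tuple[int, int]] = {}
    for level in sorted(set(int(r) for r in ratings)):
        idx = np.flatnonzero(ratings == level)
        n_total = idx.size
        n_ident = _round_half_away(train_fraction * n_total)
        n_ident = min(n_ident, n_total)
        perm = rng.permutation(idx)
        ident.extend(perm[:n_ident].tolist())
        valid.extend(perm[n_ident:].tolist())
        per_level[level] = (n_ident, n_total - n_ident)
    return SplitPlan(
        per_level_counts=per_level,
        identification_indices=np.array(sorted(ident), dtype=int),
        validation_indices=np.array(sorted(valid), dtype=int),
        seed=seed,
    )


@dataclass
class SearchResult:
    """Outcome of the exhaustive subset search at one subset size."""

    best_subset: tuple[str, ...]
    best_model: PolyModel
    ssr_identification: float
    ssr_validation: float
    ssr_total: float
    evaluated_count: int
    p: int
    log: list[tuple[tuple[str, ...], np.ndarray, float]] = field(default_factory=list)


def exhaustive_search(
    X: np.ndarray,
    y: np.ndarray,
    split: SplitPlan,
    p: int,
    feature_names: Sequence[str] | None = None,
    pool: Sequence[str] | None = None,
    keep_log: bool = False,
) -> SearchResult:
    """Fit every size-``p`` subset on the identification set; keep the best.

    The winner minimizes the identification-set sum of squared residuals;
    ties go to the lexicographically first subset in canonical feature order
    (the enumeration order of ``itertools.combinations``), making the result
    deterministic regardless of execution strategy.  The validation-set
    residual of the winner is reported for honesty about generalization.
    """
    if p < 1:
        raise ValueError("subset size must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    if X.shape[1] != len(names):
        raise ValueError("feature matrix width must match feature_names")
    pool_names = list(pool) if pool is not None else names
    pool_idx = [names.index(f) for f in pool_names]
    if n_coefficients(p) > split.n_identification:
        import warnings

        warnings.warn(
            f"{n_coefficients(p)} coefficients exceed the identification-set "
            f"size {split.n_identification}; fits are minimum-norm"
        )
    Xi = X[split.identification_indices]
    yi = y[split.identification_indices]
    Xv = X[split.validation_indices]
    yv = y[split.validation_indices]

    best: tuple[float, tuple[int, ...], PolyModel] | None = None
    log: list[tuple[tuple[str, ...], np.ndarray, float]] = []
    count = 0
    for subset in combinations(pool_idx, p):
        count += 1
        sub_names = [names[i] for i in subset]
        model = fit(Xi[:, subset], yi, sub_names)
        s = ssr(model, Xi[:, subset], yi)
        if keep_log:
            log.append((tuple(sub_names), model.coef.copy(), s))
        if best is None or s < best[0]:
            best = (s, subset, model)
    assert best is not None
    s_best, subset, model = best
    s_valid = ssr(model, Xv[:, subset], yv) if split.n_validation else 0.0
    s_total = s_best + s_valid
    return SearchResult(
        best_subset=tuple(names[i] for i in subset),
        best_model=model,
        ssr_identification=s_best,
        ssr_validation=s_valid,
        ssr_total=s_total,
        evaluated_count=count,
        p=p,
        log=log,
    )


@dataclass(frozen=True)
class ClassScheme:
    """Partition of the 0-10 anxiety scale into ordered intensity classes.

    ``boundaries`` are the closed upper bounds of all classes but the last;
    estimates at or below a bound fall in the lower class, and the extreme
    intervals extend to +/- infinity so every real estimate maps to exactly
    one class.
    """

    labels: tuple[str, ...]
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.labels) - 1:
            raise ValueError("need exactly one boundary fewer than labels")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def level_count(self) -> int:
        return len(self.labels)

    @classmethod
    def two_level(cls) -> "ClassScheme":
        return cls(labels=("low", "high"), boundaries=(5.0,))

    @classmethod
    def three_level(cls) -> "ClassScheme":
        return cls(labels=("low", "mild", "high"), boundaries=(3.0, 7.0))

    @classmethod
    def from_level_count(cls, n: int) -> "ClassScheme":
        if n == 2:
            return cls.two_level()
        if n == 3:
            return cls.three_level()
        raise ValueError("only 2- and 3-class schemes are defined")


def classify(estimate: float, scheme: ClassScheme) -> str:
    """Threshold a real-valued estimate into its anxiety class label."""
    for label, bound in zip(scheme.labels, scheme.boundaries):
        if estimate <= bound:
            return label
    return scheme.labels[-1]


@dataclass
class ConfusionReport:
    """Counts and row-normalized confusion matrix with overall accuracy (%)."""

    labels: tuple[str, ...]
    counts: np.ndarray
    matrix: np.ndarray  # row-normalized; NaN rows for empty true classes
    overall_accuracy: float
    empty_classes: tuple[str, ...] = ()

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        data = self.matrix if normalized else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str], scheme: ClassScheme
) -> ConfusionReport:
    """Row-normalized confusion matrix (true class x estimated class)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    k = scheme.level_count
    index = {label: i for i, label in enumerate(scheme.labels)}
    counts = np.zeros((k, k), dtype=int)
    for t, p_ in zip(true_labels, predicted_labels):
        counts[index[t], index[p_]] += 1
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / row_sums[:, None]
    empty = tuple(scheme.labels[i] for i in np.flatnonzero(row_sums == 0))
    total = counts.sum()
    accuracy = 100.0 * np.trace(counts) / total if total else float("nan")
    return ConfusionReport(
        labels=scheme.labels,
        counts=counts,
        matrix=matrix,
        overall_accuracy=float(accuracy),
        empty_classes=empty,
    )


class AnxietyRegression:
    """Quadratic anxiety estimator over a chosen feature subset.

    A thin modelling object in the statsmodels mould: construct from data,
    call :meth:`fit` to obtain an :class:`AnxietyRegressionResults`.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Feature values, columns in the order of ``feature_names``.
    y : array-like, shape (n,)
        Reported anxiety levels (SUD, 0-10).
    feature_names : sequence of str
        Names of the subset columns (a subset of the 32 canonical names).
    """

    def __init__(self, X, y, feature_names: Sequence[str]):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        self.feature_names = list(feature_names)
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix width must match feature_names")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, feature_names: Sequence[str], target: str = "anx"
    ) -> "AnxietyRegression":
        return cls(
            frame[list(feature_names)].to_numpy(dtype=float),
            frame[target].to_numpy(dtype=float),
            feature_names,
        )

    def fit(self) -> "AnxietyRegressionResults":
        model = fit(self.X, self.y, self.feature_names)
        return AnxietyRegressionResults(self, model)


class AnxietyRegressionResults:
    """Fitted quadratic estimator: coefficients, residuals, diagnostics."""

    def __init__(self, model_spec: AnxietyRegression, model: PolyModel):
        self.model_spec = model_spec
        self.model = model
        self.fittedvalues = predict(model, model_spec.X)
        self.resid = model_spec.y - self.fittedvalues
        self.ssr = float(self.resid @ self.resid)

    @property
    def nobs(self) -> int:
        return self.model_spec.y.size

    @property
    def ssr_per_point(self) -> float:
        return self.ssr / self.nobs

    @property
    def resid_std(self) -> float:
        return float(np.std(self.resid, ddof=1)) if self.nobs > 1 else 0.0

    def predict(self, X) -> np.ndarray:
        return predict(self.model, X)

    def classify(self, X=None, scheme: ClassScheme | None = None) -> list[str]:
        scheme = scheme or ClassScheme.two_level()
        est = self.fittedvalues if X is None else self.predict(X)
        return [classify(v, scheme) for v in est]

    def confusion(self, scheme: ClassScheme, X=None, y=None) -> ConfusionReport:
        y_true = self.model_spec.y if y is None else np.asarray(y, dtype=float)
        preds = self.classify(X=X, scheme=scheme)
        truths = [classify(v, scheme) for v in y_true]
        return confusion(truths, preds, scheme)

    def summary(self) -> str:
        lines = [
            "Second-order anxiety estimator",
            "=" * 46,
            f"features (P = {self.model.p}): {', '.join(self.model.feature_names)}",
            f"n coefficients: {n_coefficients(self.model.p)}",
            f"n obs: {self.nobs}",
            f"SSR: {self.ssr:.4f}   SSR/n: {self.ssr_per_point:.4f}",
            f"residual std: {self.resid_std:.4f}",
            "-" * 46,
            "gamma (intercept): " f"{self.model.gamma:+.5g}",
        ]
        beta = self.model.beta
        for i, name in enumerate(self.model.feature_names, start=1):
            lines.append(f"beta[{name}]: {beta[i]:+.5g}")
        alpha = self.model.alpha
        names = self.model.feature_names
        for (i, j), v in alpha.items():
            lines.append(f"alpha[{names[i - 1]} * {names[j - 1]}]: {v:+.5g}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Reported vs estimated anxiety scatter (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model_spec.y, self.fittedvalues, s=18, alpha=0.7)
        ax.plot([0, 10], [0, 10], "k--", lw=1)
        ax.set_xlabel("reported anxiety (SUD)")
        ax.set_ylabel("estimated anxiety")
        return ax
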