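"""EH/NEH channel classification with leave-one-hippocampus-out validation.

Features whose ROC is significantly different from chance (Hanley-McNeil
p < alpha) in the rest, task or rest-minus-task scope form the input
matrix. Each cross-validation fold holds out all channels of one
hippocampus; on the training rows only, the pipeline imputes missing
values (median), standardizes, decorrelates with PCA (all components) and
fits a probability-emitting SVM (Platt calibration inside the fold).
Held-out channel probabilities are pooled across folds into a single ROC;
a hippocampus is called pathologic when the mean probability of its
channels exceeds 0.5.

A per-fold ROC is undefined whenever a fold contains a single hippocampus
(one class), so the pooled-probability ROC is the well-defined reading of
a cross-validated mean ROC; see the methods note.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.impute import SimpleImputer
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .filtering import ParameterError
from .stats import roc_auc


class FeatureSelectionError(ValueError):
    """No feature passed the ROC-significance screen."""


SCOPES = ("rest", "task", "diff")


def select_features(
    roc_results: pd.DataFrame,
    alpha: float = 0.05,
    scopes: tuple[str, ...] = SCOPES,
) -> list[tuple[str, str]]:
    """(feature, scope) pairs whose ROC differs from chance at level alpha.

    ``scopes`` restricts the candidate pool (e.g. rest-only or diff-only
    models); selection always uses the grouped-task ROC results.
    """
    bad = set(scopes) - set(SCOPES)
    if bad:
        raise ParameterError(f"unknown scopes {sorted(bad)}")
    sub = roc_results[roc_results["scope"].isin(scopes)]
    sel = sub[sub["p_vs_chance"] < alpha]
    if len(sel) == 0:
        raise FeatureSelectionError(
            f"no feature has ROC p < {alpha} in scopes {scopes}; "
            "inspect the ROC table or relax alpha"
        )
    return list(map(tuple, sel[["feature", "scope"]].itertuples(index=False)))


def build_feature_matrix(
    features: pd.DataFrame, selected: list[tuple[str, str]]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Channel x selected-(feature, scope) matrix plus labels and groups.

    Input is a grouped-task feature table (one rest and one task row per
    channel); columns are named ``feature@scope``. Returns
    ``(X, y, groups)`` with y = 1 for EH and groups = hippocampus ids.
    """
    meta = features.drop_duplicates("channel_id").set_index("channel_id")
    cols = {}
    for feat, scope in selected:
        wide = features.pivot_table(index="channel_id", columns="condition", values=feat)
        if scope == "diff":
            vals = wide["rest"] - wide["task"]
        else:
            vals = wide[scope]
        cols[f"{feat}@{scope}"] = vals
    X = pd.DataFrame(cols)
    X = X.loc[meta.index.intersection(X.index)]
    y = (meta.loc[X.index, "label"] == "EH").astype(int)
    groups = meta.loc[X.index, "hippocampus_id"]
    return X, y, groups


class LohoSvmClassifier(ClassifierMixin, BaseEstimator):
    """Standardize -> PCA -> SVM channel classifier.

    A scikit-learn estimator: ``fit(X, y)`` learns imputation,
    standardization, PCA rotation (all components retained) and a
    probability-emitting SVM on the given rows; ``predict_proba`` yields
    the channel's probability of being epileptic. Cross-validated
    evaluation with hippocampus-level folds is provided by
    :func:`fit_loho`, which clones this estimator per fold.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma: float | str = "scale",
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def _make_pipeline(self) -> Pipeline:
        return Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=None, random_state=self.random_state)),
                (
                    "svm",
                    # Platt-style sigmoid calibration fitted inside the
                    # training fold provides the channel probabilities
                    CalibratedClassifierCV(
                        SVC(
                            kernel=self.kernel,
                            C=self.C,
                            gamma=self.gamma if self.kernel == "rbf" else "scale",
                            random_state=self.random_state,
                        ),
                        method="sigmoid",
                        cv=3,
                        ensemble=False,
                    ),
                ),
            ]
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.pipeline_ = self._make_pipeline().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def transform_checksum(self, X) -> str:
        """Digest of the fitted training-fold transforms (leakage audit).

        Hashes the imputer statistics, scaler mean/SD and PCA components;
        independent of anything outside the training rows.
        """
        check_is_fitted(self, "pipeline_")
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.pipeline_["impute"].statistics_).tobytes())
        h.update(np.ascontiguousarray(self.pipeline_["scale"].mean_).tobytes())
        h.update(np.ascontiguousarray(self.pipeline_["scale"].scale_).tobytes())
        h.update(np.ascontiguousarray(self.pipeline_["pca"].components_).tobytes())
        return h.hexdigest()


@dataclass
class CvReport:
    """Pooled leave-one-hippocampus-out evaluation."""

    kernel: str
    C: float
    gamma: float | str
    probabilities: pd.Series  # held-out probability per channel
    auc: float
    hippocampus_probs: pd.DataFrame  # hippocampus_id, mean_prob, true/pred label
    fold_checksums: dict[str, str] = field(default_factory=dict)

    @property
    def hippocampus_accuracy(self) -> float:
        hp = self.hippocampus_probs
        return float((hp["predicted_label"] == hp["true_label"]).mean())


def fit_loho(
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> CvReport:
    """Leave-one-hippocampus-out cross-validation of the SVM channel model.

    Every channel is scored exactly once, by the model trained without its
    hippocampus; pooled probabilities give the ROC/AUC; each hippocampus
    is predicted pathologic when its channels' mean probability > 0.5.
    """
    if groups[y == 1].nunique() < 2 or groups[y == 0].nunique() < 2:
        raise ParameterError("need >= 2 hippocampi per class for leave-one-out folds")
    Xv = X.values.astype(float)
    yv = y.values.astype(int)
    gv = groups.values
    logo = LeaveOneGroupOut()
    probs = pd.Series(index=X.index, dtype=float)
    checksums: dict[str, str] = {}
    for train, test in logo.split(Xv, yv, gv):
        if len(np.unique(yv[train])) < 2:
            continue  # cannot train a single-class fold
        est = LohoSvmClassifier(kernel=kernel, C=C, gamma=gamma, random_state=seed).fit(
            Xv[train], yv[train]
        )
        p = est.predict_proba(Xv[test])[:, list(est.classes_).index(1)]
        probs.iloc[test] = p
        checksums[str(gv[test][0])] = est.transform_checksum(Xv[train])
    scored = probs.dropna()
    auc = roc_auc(scored.values, y.loc[scored.index].values)
    hp = (
        pd.DataFrame({"prob": scored, "group": groups.loc[scored.index], "y": y.loc[scored.index]})
        .groupby("group")
        .agg(mean_prob=("prob", "mean"), true_label=("y", "max"))
        .reset_index()
        .rename(columns={"group": "hippocampus_id"})
    )
    hp["predicted_label"] = (hp["mean_prob"] > 0.5).astype(int)
    return CvReport(kernel, C, gamma, probs, float(auc), hp, checksums)


def _grid_cells(
    kernels: tuple[str, ...], c_grid: tuple[float, ...], gamma_grid: tuple[float, ...]
) -> list[tuple[str, float, float | str]]:
    cells: list[tuple[str, float, float | str]] = []
    for k in kernels:
        for c in c_grid:
            if k == "rbf":
                cells.extend(("rbf", c, g) for g in gamma_grid)
            else:
                cells.append((k, c, "scale"))
    return cells


def grid_search(
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series,
    kernels: tuple[str, ...] = ("linear", "rbf"),
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0),
    gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0),
    seed: int = 0,
    refine: bool = True,
) -> tuple[CvReport, pd.DataFrame]:
    """Iterative grid search over kernel/C/gamma, scored by pooled LOHO AUC.

    After the coarse pass, one zoom level (factor 10^±0.5 around the best
    C and gamma) refines the optimum. Ties are broken toward smaller C,
    then linear before rbf. Returns the best report plus the full grid
    table.
    """
    if not kernels or not len(c_grid):
        raise ParameterError("grids must be non-empty")

    def kernel_rank(k: str) -> int:
        return 0 if k == "linear" else 1

    results: dict[tuple, CvReport] = {}

    def evaluate(cells):
        rows = []
        for kernel, c, g in cells:
            key = (kernel, float(c), g if g == "scale" else float(g))
            if key not in results:
                results[key] = fit_loho(X, y, groups, kernel, c, g, seed)
            rows.append(key)
        return rows

    cells = _grid_cells(tuple(kernels), tuple(c_grid), tuple(gamma_grid))
    evaluate(cells)

    def best_key():
        return min(
            results,
            key=lambda k: (-results[k].auc, k[1], kernel_rank(k[0]),
                           k[2] if k[2] != "scale" else 0.0),
        )

    if refine:
        bk = best_key()
        kernel, c, g = bk
        zoom_c = [c * 10**e for e in (-0.5, 0.5)]
        if kernel == "rbf":
            zoom = [(kernel, cc, gg) for cc in [c] + zoom_c
                    for gg in [g] + [g * 10**e for e in (-0.5, 0.5)]]
        else:
            zoom = [(kernel, cc, "scale") for cc in zoom_c]
        evaluate(zoom)

    bk = best_key()
    table = pd.DataFrame(
        [
            {"kernel": k[0], "C": k[1], "gamma": k[2], "auc": r.auc,
             "hippocampus_accuracy": r.hippocampus_accuracy}
            for k, r in sorted(results.items(), key=lambda kv: -kv[1].auc)
        ]
    )
    return results[bk], table
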