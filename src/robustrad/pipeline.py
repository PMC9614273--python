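"""The experiment engine: repeated stratified CV, robustness filtering,
selection, classifier training and the robustness/generalizability analysis.

For every train-test split, per-feature ICC is computed from the training
patients' perturbation replicates only (no test leakage), features are
filtered at each robustness threshold, selected, and a classifier is trained
and evaluated.  Model robustness is the ICC(1,1) of the continuous test-set
scores across perturbation replicates; generalizability is the test-minus-
train AUC.  Thresholds are then compared across splits with paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import select as sel
from .stats import auc, generalizability_gap, icc_1_1, icc_matrix, paired_ttest

__all__ = [
    "CVScheme",
    "ExperimentConfig",
    "FittedModel",
    "make_cv_splits",
    "train_classifier",
    "evaluate_model",
    "run_experiment",
    "compare_thresholds",
    "CLASSIFIERS",
]


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified cross-validation scheme.

    ``folds x repetitions`` train-test splits; e.g. stratified 2-fold with
    30 repetitions gives 60 splits.
    """

    folds: int = 2
    repetitions: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def n_splits(self) -> int:
        return self.folds * self.repetitions


def make_cv_splits(labels: pd.Series,
                   scheme: CVScheme) -> list[tuple[list[str], list[str]]]:
    """Enumerate the (train ids, test ids) pairs of the CV scheme.

    Folds are stratified; every test fold must receive at least two
    minority-class members (otherwise the scheme is infeasible and an error
    is raised).  Per repetition the folds partition the cohort.
    """
    y = labels.to_numpy()
    ids = np.asarray(labels.index)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    if counts.min() // scheme.folds < 2:
        raise ValueError(
            f"infeasible stratification: {counts.min()} minority members "
            f"cannot give every one of {scheme.folds} test folds >= 2")
    splits: list[tuple[list[str], list[str]]] = []
    rep_seeds = np.random.SeedSequence([scheme.seed, 0xCF]).generate_state(
        scheme.repetitions)
    for rep_seed in rep_seeds:
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True,
                              random_state=int(rep_seed % (2 ** 31)))
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            n_min_test = min(np.bincount(y[test_idx], minlength=2))
            if n_min_test < 2:
                raise ValueError("a test fold received < 2 minority members")
            splits.append((list(ids[train_idx]), list(ids[test_idx])))
    return splits


# ---------------------------------------------------------------------------
# classifiers

def _classifier_and_grid(name: str, seed: int):
    """The five supported classifiers with their small tuning grids."""
    if name == "ridge":
        return RidgeClassifier(), {"clf__alpha": np.logspace(-2, 2, 5)}
    if name == "svc":
        return SVC(kernel="rbf", gamma="scale"), {
            "clf__C": np.logspace(-1, 2, 4)}
    if name == "knn":
        return KNeighborsClassifier(), {"clf__n_neighbors": [3, 5, 7, 9]}
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed), {
            "clf__max_depth": [2, 3, 5, None]}
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                             random_state=seed), {
            "clf__alpha": [1e-4, 1e-2, 1.0]}
    raise ValueError(f"unknown classifier {name!r}")


CLASSIFIERS = ("ridge", "svc", "knn", "tree", "mlp")


@dataclass
class FittedModel:
    """A fitted predictor exposing continuous scores for new samples."""

    name: str
    features: list[str]
    pipeline: Pipeline
    best_params: dict

    def predict_scores(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.features].to_numpy(dtype=float)
        est = self.pipeline
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(x), dtype=float)
        return np.asarray(est.predict_proba(x)[:, 1], dtype=float)


def train_classifier(name: str, features: pd.DataFrame, labels: pd.Series,
                     seed: int = 0, inner_folds: int = 3) -> FittedModel:
    """Train one of the five classifiers with inner-CV hyperparameter tuning.

    Features are standardized on training statistics inside the pipeline;
    hyperparameters are chosen by stratified inner CV maximizing AUC over a
    small grid.  If the minority class is too small for the inner CV, the
    grid's default (first) values are used without search.
    """
    if features.shape[1] < 1:
        raise ValueError("at least one feature required")
    y = labels.loc[features.index].to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present in training labels")
    est, grid = _classifier_and_grid(name, seed)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    n_min = int(np.bincount(y).min())
    folds = min(inner_folds, n_min)
    x = features.to_numpy(dtype=float)
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1)
        search.fit(x, y)
        fitted, params = search.best_estimator_, search.best_params_
    else:
        fitted = clone(pipe).fit(x, y)
        params = {}
    return FittedModel(name=name, features=list(features.columns),
                       pipeline=fitted, best_params=params)


def evaluate_model(model: FittedModel, train: pd.DataFrame,
                   train_labels: pd.Series, test: pd.DataFrame,
                   test_labels: pd.Series,
                   perturbed_test: list[pd.DataFrame]) -> dict:
    """Train/test AUC, generalizability gap and model-robustness ICC.

    The model ICC is the ICC(1,1) of the test patients x perturbations
    matrix of continuous scores obtained by re-scoring every perturbation
    replicate of the test table.
    """
    missing = [i for i, rep in enumerate(perturbed_test)
               if not test.index.isin(rep.index).all()]
    if missing:
        raise ValueError(f"perturbation replicates missing test ids: {missing}")
    train_auc = auc(model.predict_scores(train),
                    train_labels.loc[train.index])
    test_auc = auc(model.predict_scores(test), test_labels.loc[test.index])
    scores = np.column_stack([
        model.predict_scores(rep.loc[test.index]) for rep in perturbed_test])
    try:
        model_icc = icc_1_1(scores).icc
    except ValueError:  # constant scores: perfectly stable or degenerate
        per_patient_const = np.allclose(scores, scores[:, [0]])
        model_icc = 1.0 if per_patient_const else np.nan
    return {
        "train_auc": train_auc,
        "test_auc": test_auc,
        "gap": generalizability_gap(train_auc, test_auc),
        "model_icc": float(model_icc),
        "features": list(model.features),
    }


# ---------------------------------------------------------------------------
# the full experiment

@dataclass
class ExperimentConfig:
    """Configuration of the threshold-comparison experiment."""

    thresholds: tuple[float, ...] = (0.0, 0.75, 0.95)
    classifiers: tuple[str, ...] = ("ridge",)
    cv: CVScheme = field(default_factory=CVScheme)
    selector: str = "anova"  # or "mrmr"
    n_boot: int = 100
    p_cut: float = 0.1
    top_frac: float = 0.1
    r_cut: float = 0.6
    k_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")
        if self.selector not in ("anova", "mrmr"):
            raise ValueError("selector must be 'anova' or 'mrmr'")


def _select_features(features: pd.DataFrame, labels: pd.Series,
                     survivors: list[str], config: ExperimentConfig,
                     seed: int) -> list[str]:
    sub = features[survivors]
    if config.selector == "mrmr":
        return sel.mrmr_select(sub, labels, k=config.k_max)
    ranked = sel.bootstrap_anova_rank(sub, labels, n_iter=config.n_boot,
                                      p_cut=config.p_cut,
                                      top_frac=config.top_frac, seed=seed)
    return sel.prune_correlated(sub, list(ranked.index), r_cut=config.r_cut,
                                k_max=config.k_max)


def run_experiment(features: pd.DataFrame, replicates: list[pd.DataFrame],
                   labels: pd.Series,
                   config: ExperimentConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full threshold-comparison experiment on feature tables.

    Parameters
    ----------
    features
        Unperturbed patients x features table.
    replicates
        Perturbation-replicate tables (same shape/index as ``features``);
        their count ``k`` is the number of "raters" in every ICC.
    labels
        Binary outcome per patient.
    config
        Thresholds, classifiers, CV scheme, selection parameters, seed.

    Returns
    -------
    (records, comparisons)
        ``records`` has one row per (split, threshold, classifier) with
        train/test AUC, gap, model ICC and the selected features;
        ``comparisons`` holds paired t-tests of model ICC and |gap| between
        the lowest threshold and each higher one, per classifier.
    """
    config = config or ExperimentConfig()
    if not replicates:
        raise ValueError("at least one perturbation replicate required")
    scheme = CVScheme(config.cv.folds, config.cv.repetitions, config.seed)
    splits = make_cv_splits(labels, scheme)
    split_seeds = np.random.SeedSequence([config.seed, 0x5711]).generate_state(
        len(splits))

    rep_arrays = [rep for rep in replicates]
    rows = []
    for s_idx, ((train_ids, test_ids), s_seed) in enumerate(
            zip(splits, split_seeds)):
        s_seed = int(s_seed % (2 ** 31))
        train_x = features.loc[train_ids]
        test_x = features.loc[test_ids]
        train_y = labels.loc[train_ids]
        test_y = labels.loc[test_ids]
        # feature robustness from TRAINING patients only
        stack = np.stack([rep.loc[train_ids].to_numpy(dtype=float)
                          for rep in rep_arrays], axis=1)
        icc_table = pd.Series(icc_matrix(stack), index=features.columns)
        for threshold in config.thresholds:
            survivors = sel.robustness_filter(icc_table, threshold)
            final = _select_features(train_x, train_y, survivors, config,
                                     seed=s_seed)
            if not final:
                raise RuntimeError(
                    f"no features selected (split {s_idx}, "
                    f"threshold {threshold})")
            for clf_name in config.classifiers:
                model = train_classifier(clf_name, train_x[final], train_y,
                                         seed=s_seed)
                try:
                    rec = evaluate_model(model, train_x[final], train_y,
                                         test_x[final], test_y,
                                         [rep[final] for rep in rep_arrays])
                except Exception as exc:
                    raise RuntimeError(
                        f"evaluation failed (split {s_idx}, threshold "
                        f"{threshold}, classifier {clf_name})") from exc
                rows.append({
                    "split": s_idx, "threshold": threshold,
                    "classifier": clf_name, "k_perturbations": len(rep_arrays),
                    "n_features_survived": len(survivors),
                    "n_features_final": len(final),
                    "selected_features": ";".join(final),
                    **{k: rec[k] for k in ("train_auc", "test_auc", "gap",
                                           "model_icc")},
                })
    records = pd.DataFrame(rows)
    comparisons = compare_thresholds(records)
    return records, comparisons


def cohort_feature_tables(cohort, n_perturbations: int = 20,
                          grid=None, preprocess_config=None,
                          texture_kinds=("glcm",), bin_counts=None,
                          seed: int = 0, perturb_kwargs: dict | None = None
                          ) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Extract feature tables from a phantom cohort and its perturbations.

    For every patient, ``n_perturbations`` grid cells are drawn (a pure
    function of the seed and patient id) and the full perturbation —
    rigid transform, noise field, contour randomization — is applied before
    re-extraction.  Returns the unperturbed table plus one replicate table
    per perturbation index.  This is the image-space route; it is orders of
    magnitude slower than :func:`robustrad.synthetic.generate_feature_table`
    and is meant for small cohorts.
    """
    from .features import extract_all
    from .perturb import apply_perturbation, default_grid, sample_perturbations
    from .preprocess import PreprocessConfig

    grid = grid or default_grid()
    config = preprocess_config or PreprocessConfig()
    if bin_counts is not None:
        config.bin_counts = tuple(bin_counts)
    base_rows, rep_rows = {}, [dict() for _ in range(n_perturbations)]
    for patient in cohort.patients:
        base_rows[patient.id] = extract_all(patient.image, patient.mask,
                                            config,
                                            texture_kinds=texture_kinds)
        specs = sample_perturbations(grid, n_perturbations, patient.id, seed)
        for r, spec in enumerate(specs):
            img, msk = apply_perturbation(patient.image, patient.mask, spec,
                                          noise_seed=seed,
                                          **(perturb_kwargs or {}))
            rep_rows[r][patient.id] = extract_all(img, msk, config,
                                                  texture_kinds=texture_kinds)
    features = pd.DataFrame.from_dict(base_rows, orient="index")
    replicates = [pd.DataFrame.from_dict(rows, orient="index").loc[
        features.index, features.columns] for rows in rep_rows]
    return features, replicates


def compare_thresholds(records: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of model ICC and |gap| between thresholds, per classifier.

    The baseline is the lowest threshold present; each higher threshold is
    compared against it across splits.  P-values are reported raw (no
    multiple-testing correction).
    """
    thresholds = sorted(records["threshold"].unique())
    base = thresholds[0]
    rows = []
    for clf in records["classifier"].unique():
        sub = records[records["classifier"] == clf]
        pivot_icc = sub.pivot(index="split", columns="threshold",
                              values="model_icc")
        pivot_gap = sub.pivot(index="split", columns="threshold",
                              values="gap").abs()
        for thr in thresholds[1:]:
            row = {"classifier": clf, "baseline": base, "threshold": thr,
                   "mean_icc_base": pivot_icc[base].mean(),
                   "mean_icc_thr": pivot_icc[thr].mean(),
                   "mean_absgap_base": pivot_gap[base].mean(),
                   "mean_absgap_thr": pivot_gap[thr].mean()}
            for metric, pivot in (("icc", pivot_icc), ("absgap", pivot_gap)):
                try:
                    t, p = paired_ttest(pivot[thr], pivot[base])
                except ValueError:
                    t, p = np.nan, np.nan
                row[f"t_{metric}"] = t
                row[f"p_{metric}"] = p
            rows.append(row)
    return pd.DataFrame(rows)
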