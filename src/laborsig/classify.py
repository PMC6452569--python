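"""Repeated sparse-regression classification of labor phenotype.

Within-study evaluation uses repeated stratified k-fold cross-validation
(fresh folds every run) of L1-penalized ("lasso") or elastic-net logistic
regression, with the penalty strength chosen per fold by nested
cross-validation on the training portion only and features standardized with
training-fold statistics only. Cross-study evaluation trains repeatedly on
one full study (stochasticity from the inner folds) and scores every sample
of another study over the genes the two share.

Reported per task: per-run AUC (labor vs non-labor, with early and
established labor pooled for scoring), per-sample classification counts over
runs (three-way for the multinomial study), and per-model selected genes
with coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .containers import LABOR_LABELS, ExpressionStudy

DEFAULT_C_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


class FoldError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    algorithm: str = "lasso"  # "lasso" (L1) or "elastic_net" (L1+L2)
    mixing: float = 0.5  # elastic-net L1 share; lasso is mixing = 1
    k_folds: int = 5
    n_runs: int = 100
    family: str = "binomial"  # or "multinomial"
    inner_folds: int = 5
    seed: int = 0
    standardize: bool = True
    c_grid: tuple = DEFAULT_C_GRID

    def __post_init__(self) -> None:
        if self.algorithm not in ("lasso", "elastic_net"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.family not in ("binomial", "multinomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.k_folds < 2:
            raise FoldError("k_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.mixing <= 1:
            raise ValueError("mixing must lie in (0, 1]")


@dataclass
class ClassifierReport:
    task_id: str
    classes: list[str]
    n_runs: int
    k_folds: int  # 0 in cross-study mode
    per_run_auc: list[float]
    #: samples x classes counts of per-run assignments
    class_counts: pd.DataFrame
    #: one record per fitted model: run, fold, test_samples, coef
    models: list[dict]
    given_labels: pd.Series

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_run_auc))


def roc_auc(scores, binary_labels) -> float:
    """P[random positive outscores random negative], ties counted 1/2."""
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _make_estimator(config: ClassifierConfig, C: float) -> LogisticRegression:
    if config.algorithm == "lasso" and config.family == "binomial":
        return LogisticRegression(
            l1_ratio=1, C=C, solver="liblinear", max_iter=500, random_state=0
        )
    # saga tolerance is loose: it only has to rank penalty strengths and
    # produce stable signs/supports, not converge to machine precision
    if config.algorithm == "lasso":
        return LogisticRegression(
            l1_ratio=1, C=C, solver="saga", max_iter=200, tol=1e-2, random_state=0
        )
    return LogisticRegression(
        l1_ratio=config.mixing,
        C=C,
        solver="saga",
        max_iter=200,
        tol=1e-2,
        random_state=0,
    )


def _inner_select_C(
    X: np.ndarray, y: np.ndarray, config: ClassifierConfig, seed: int
) -> float:
    """Penalty strength minimizing mean inner-fold deviance (log loss)."""
    _, counts = np.unique(y, return_counts=True)
    n_inner = min(config.inner_folds, counts.min())
    if n_inner < 2:
        # degenerate training set: fall back to the grid midpoint
        return config.c_grid[len(config.c_grid) // 2]
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(X, y))
    classes = np.unique(y)
    best_C, best_loss = None, np.inf
    for C in config.c_grid:
        losses = []
        for tr, va in splits:
            mean, sd = _standardize_fit(X[tr]) if config.standardize else (0.0, 1.0)
            est = _make_estimator(config, C)
            est.fit((X[tr] - mean) / sd, y[tr])
            proba = est.predict_proba((X[va] - mean) / sd)
            losses.append(log_loss(y[va], proba, labels=classes))
        loss = float(np.mean(losses))
        if loss < best_loss - 1e-12:
            best_loss, best_C = loss, C
    return best_C


def _fit_one_model(
    X: np.ndarray, y: np.ndarray, config: ClassifierConfig, seed: int
):
    """Nested-CV penalty choice then a final fit; returns (est, mean, sd, C)."""
    C = _inner_select_C(X, y, config, seed)
    mean, sd = _standardize_fit(X) if config.standardize else (0.0, 1.0)
    est = _make_estimator(config, C)
    est.fit((X - mean) / sd, y)
    return est, mean, sd, C


def _coef_record(est: LogisticRegression, genes, classes) -> dict:
    """Nonzero coefficients; keyed by class for multinomial models."""
    coef = est.coef_
    if coef.shape[0] == 1:
        nz = np.flatnonzero(coef[0])
        return {genes[j]: float(coef[0, j]) for j in nz}
    out: dict = {}
    for i, cls in enumerate(est.classes_):
        nz = np.flatnonzero(coef[i])
        out[str(cls)] = {genes[j]: float(coef[i, j]) for j in nz}
    return out


def _class_order(labels: pd.Series) -> list[str]:
    present = list(pd.unique(labels))
    order = [c for c in ("NL", "ILEa", "ILEs", "IL") if c in present]
    return order + [c for c in present if c not in order]


def _labor_score(est: LogisticRegression, Xs: np.ndarray) -> np.ndarray:
    """Score = predicted probability of labor (1 - P(NL) when multiclass)."""
    proba = est.predict_proba(Xs)
    classes = [str(c) for c in est.classes_]
    if "NL" in classes:
        return 1.0 - proba[:, classes.index("NL")]
    return proba[:, -1]


def _predicted_class(est: LogisticRegression, Xs: np.ndarray, order: list[str]) -> list[str]:
    """Highest-probability class; exact ties break toward the earliest entry
    of ``order`` (NL first)."""
    proba = est.predict_proba(Xs)
    classes = [str(c) for c in est.classes_]
    reindex = [classes.index(c) for c in order if c in classes]
    sub = proba[:, reindex]
    names = [order[i] for i, c in enumerate(order) if c in classes]
    return [names[int(np.argmax(row))] for row in sub]


def repeated_cv(study: ExpressionStudy, config: ClassifierConfig) -> ClassifierReport:
    """100-runs-style repeated stratified k-fold CV on one study.

    AUC is computed per run over the pooled test folds with all labor labels
    collapsed to one class; classification counts keep the three groups
    separate in multinomial mode.
    """
    labels = study.labels()
    if config.family == "binomial":
        y_series = labels.map(lambda l: "IL" if l in LABOR_LABELS else "NL")
    else:
        y_series = labels.copy()
    order = _class_order(y_series)
    if len(order) < 2:
        raise ValueError("single-class input")
    counts = y_series.value_counts()
    if counts.min() < config.k_folds:
        raise FoldError(
            f"smallest class ({counts.min()}) is smaller than k_folds={config.k_folds}"
        )

    X = study.values.T.to_numpy(dtype=float)
    genes = list(study.genes)
    samples = list(study.samples)
    y = y_series.to_numpy()
    y_binary = labels.isin(LABOR_LABELS).astype(int).to_numpy()

    class_counts = pd.DataFrame(0, index=samples, columns=order)
    per_run_auc: list[float] = []
    models: list[dict] = []
    for run in range(config.n_runs):
        skf = StratifiedKFold(
            n_splits=config.k_folds, shuffle=True, random_state=(config.seed + run) % (2**31)
        )
        scores = np.zeros(len(samples))
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            est, mean, sd, C = _fit_one_model(
                X[tr], y[tr], config, seed=config.seed * 1000 + run * 10 + fold
            )
            Xs_te = (X[te] - mean) / sd
            scores[te] = _labor_score(est, Xs_te)
            for idx, cls in zip(te, _predicted_class(est, Xs_te, order)):
                class_counts.loc[samples[idx], cls] += 1
            models.append(
                {
                    "run": run,
                    "fold": fold,
                    "C": C,
                    "test_samples": [samples[i] for i in te],
                    "coef": _coef_record(est, genes, order),
                }
            )
        per_run_auc.append(roc_auc(scores, y_binary))
    return ClassifierReport(
        task_id=f"cv:{study.study_id}",
        classes=order,
        n_runs=config.n_runs,
        k_folds=config.k_folds,
        per_run_auc=per_run_auc,
        class_counts=class_counts,
        models=models,
        given_labels=y_series,
    )


def cross_study_classify(
    train_study: ExpressionStudy, test_study: ExpressionStudy, config: ClassifierConfig
) -> ClassifierReport:
    """Train on one full study, score every sample of another.

    Features are the shared genes. A three-group training study is reduced
    to its NL and ILEs samples so training is always binomial; test labels
    are pooled to labor / non-labor for AUC.
    """
    shared = train_study.genes.intersection(test_study.genes)
    if len(shared) == 0:
        raise ValueError("no shared genes between studies")
    shared = sorted(shared)

    tr_labels = train_study.labels()
    if set(tr_labels.unique()) >= {"ILEa", "ILEs"}:
        keep = tr_labels.isin(["NL", "ILEs"])
        tr_cols = tr_labels.index[keep]
    else:
        tr_cols = tr_labels.index
    y_train = (
        train_study.labels(tr_cols).isin(LABOR_LABELS).map({True: "IL", False: "NL"}).to_numpy()
    )
    X_train = train_study.values.loc[shared, tr_cols].T.to_numpy(dtype=float)
    X_test = test_study.values.loc[shared].T.to_numpy(dtype=float)
    samples = list(test_study.samples)
    y_test = test_study.binary_labor().to_numpy()

    cfg = ClassifierConfig(
        algorithm=config.algorithm,
        mixing=config.mixing,
        k_folds=config.k_folds,
        n_runs=config.n_runs,
        family="binomial",
        inner_folds=config.inner_folds,
        seed=config.seed,
        standardize=config.standardize,
        c_grid=config.c_grid,
    )
    order = ["NL", "IL"]
    class_counts = pd.DataFrame(0, index=samples, columns=order)
    per_run_auc: list[float] = []
    models: list[dict] = []
    for run in range(cfg.n_runs):
        est, mean, sd, C = _fit_one_model(
            X_train, y_train, cfg, seed=cfg.seed * 1000 + run
        )
        Xs = (X_test - mean) / sd
        scores = _labor_score(est, Xs)
        for s, cls in zip(samples, _predicted_class(est, Xs, order)):
            class_counts.loc[s, cls] += 1
        models.append(
            {"run": run, "fold": 0, "C": C, "test_samples": samples,
             "coef": _coef_record(est, shared, order)}
        )
        per_run_auc.append(roc_auc(scores, y_test))
    return ClassifierReport(
        task_id=f"cross:{train_study.study_id}->{test_study.study_id}",
        classes=order,
        n_runs=cfg.n_runs,
        k_folds=0,
        per_run_auc=per_run_auc,
        class_counts=class_counts,
        models=models,
        given_labels=test_study.labels(),
    )


def classification_frequencies(report: ClassifierReport) -> pd.DataFrame:
    """Per-sample counts and fractions of runs assigned to each phenotype."""
    counts = report.class_counts.copy()
    out = counts.copy()
    for cls in counts.columns:
        out[f"freq_{cls}"] = counts[cls] / report.n_runs
    out.insert(0, "given", report.given_labels.reindex(counts.index))
    return out


def aggregate_model_features(report: ClassifierReport) -> pd.DataFrame:
    """Per-gene selection counts and mean coefficients across all models.

    Multinomial reports carry one row per (gene, class). Rows are ordered by
    selection count (descending) then gene identifier; genes never selected
    are absent.
    """
    multinomial = any(
        isinstance(v, dict) for m in report.models for v in m["coef"].values()
    )
    records: dict[tuple, list[float]] = {}
    for m in report.models:
        if multinomial:
            for cls, coefs in m["coef"].items():
                for gene, c in coefs.items():
                    records.setdefault((gene, cls), []).append(c)
        else:
            for gene, c in m["coef"].items():
                records.setdefault((gene, ""), []).append(c)
    rows = [
        {
            "gene": gene,
            **({"class": cls} if multinomial else {}),
            "n_models_selected": len(cs),
            "mean_coefficient": float(np.mean(cs)),
        }
        for (gene, cls), cs in records.items()
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(
            ["n_models_selected", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return frame


__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "repeated_cv",
    "cross_study_classify",
    "roc_auc",
    "classification_frequencies",
    "aggregate_model_features",
    "ConvergenceWarning",
]
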