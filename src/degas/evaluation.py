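"""Cross-validation harness, metrics, baselines, and ablation procedures.

Metric conventions: PR-AUC is average precision (step-wise, not
trapezoidal — the two differ at small n); ROC-AUC is the normalised
Mann-Whitney U statistic.  Survival stratification splits patients at
the median hazard score (ties to the low-risk group) and reports a
two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines.statistics import logrank_test
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import average_precision_score, roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold

from .config import DegasConfig
from .containers import ExpressionMatrix, LabelSet
from .model import DegasEnsemble, train
from .postprocessing import AssociationScores, to_corr_coeff
from .synthetic import DISEASE_GROUPS, SimulatedData

# ------------------------------------------------------------- metrics --


def _check_binary(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return truth


def pr_auc(scores: np.ndarray, binary_truth: np.ndarray) -> float:
    """Average-precision PR-AUC of scores against 0/1 truth."""
    return float(average_precision_score(_check_binary(binary_truth), scores))


def roc_auc(scores: np.ndarray, binary_truth: np.ndarray) -> float:
    """ROC-AUC (Mann-Whitney U normalisation)."""
    return float(roc_auc_score(_check_binary(binary_truth), scores))


def per_class_aucs(P: np.ndarray, Y: np.ndarray, class_names: list[str]) -> dict:
    """One-vs-rest PR-AUC and ROC-AUC per class column."""
    out = {"pr_auc": {}, "roc_auc": {}}
    for j, name in enumerate(class_names):
        out["pr_auc"][name] = pr_auc(P[:, j], Y[:, j])
        out["roc_auc"][name] = roc_auc(P[:, j], Y[:, j])
    return out


def km_logrank_median_split(
    hazards: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Two-group log-rank test after a median split on hazard scores.

    Samples with hazard <= median go to the low-risk group.  Returns
    (chi2, p, is_high_risk).  Invariant to monotone transforms of the
    hazards.
    """
    hazards = np.asarray(hazards, float).reshape(-1)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    high = hazards > np.median(hazards)
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty group")
    res = logrank_test(time[~high], time[high], event_observed_A=event[~high],
                       event_observed_B=event[high])
    return float(res.test_statistic), float(res.p_value), high


def association_error(predicted, expected: np.ndarray) -> np.ndarray:
    """Elementwise predicted - expected disease association."""
    values = predicted.values if isinstance(predicted, AssociationScores) else predicted
    values = np.asarray(values, float).reshape(-1)
    expected = np.asarray(expected, float).reshape(-1)
    if values.shape != expected.shape:
        raise ValueError("predicted and expected lengths differ")
    return values - expected


# ----------------------------------------------------- deconvolution ----


def group_centroids(X: ExpressionMatrix, labels: LabelSet) -> tuple[np.ndarray, list[str]]:
    """Mean expression profile per class, ordered by class_names."""
    names = labels.labels()
    cents = np.vstack([X.values[names == c].mean(axis=0) for c in labels.class_names])
    return cents, list(labels.class_names)


def deconvolve_least_squares(X_pat: ExpressionMatrix, centroids: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares mixture estimate per patient, renormalised
    to sum to 1.  ``centroids`` is groups x genes on the shared gene space."""
    centroids = np.asarray(centroids, float)
    if np.linalg.matrix_rank(centroids) < centroids.shape[0]:
        raise ValueError("centroid matrix is rank-deficient")
    A = centroids.T  # genes x groups
    props = np.zeros((X_pat.n_samples, centroids.shape[0]))
    for i in range(X_pat.n_samples):
        coef, _ = nnls(A, X_pat.values[i])
        s = coef.sum()
        props[i] = coef / s if s > 0 else 1.0 / len(coef)
    return props


# ---------------------------------------------------------- clustering --


def embed_2d(X, seed: int = 0, n_pcs: int = 50, perplexity: float = 30.0) -> np.ndarray:
    """Standard 2-d embedding for visualisation/clustering: log-transform
    raw counts, PCA, then tSNE.  Coordinates only; no model involvement."""
    if isinstance(X, ExpressionMatrix):
        values = np.log2(X.values + 1.0) if X.stage == "raw" else X.values
    else:
        values = np.asarray(X, float)
    if values.shape[1] > 2:
        n_pcs = min(n_pcs, values.shape[1], values.shape[0] - 1)
        values = PCA(n_components=n_pcs, random_state=seed).fit_transform(values)
        perplexity = min(perplexity, (values.shape[0] - 1) / 3)
        values = TSNE(n_components=2, random_state=seed, init="pca",
                      perplexity=perplexity).fit_transform(np.asarray(values, np.float32))
    return np.asarray(values, float)


def kmedoids(coords: np.ndarray, k: int, seed: int = 0, max_iter: int = 100,
             n_init: int = 5) -> np.ndarray:
    """Plain k-medoids (Voronoi iteration) with k-medoids++ seeding on
    Euclidean distances; the best of ``n_init`` restarts (lowest total
    within-cluster distance) is returned as integer cluster labels.
    Restarts matter: a single init can settle in a poor local optimum
    that badly understates the silhouette of the true partition."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    rng = np.random.default_rng([seed, k])
    D = cdist(coords, coords)
    best_assign, best_cost = None, np.inf
    for _ in range(max(1, n_init)):
        medoids = [int(rng.integers(n))]
        for _ in range(1, k):
            d2 = D[:, medoids].min(axis=1) ** 2
            probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
            medoids.append(int(rng.choice(n, p=probs)))
        medoids = np.asarray(medoids)
        for _ in range(max_iter):
            assign = np.argmin(D[:, medoids], axis=1)
            new = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(assign == c)
                if members.size:
                    new[c] = members[np.argmin(D[np.ix_(members, members)].sum(axis=1))]
            if np.array_equal(new, medoids):
                break
            medoids = new
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[assign]].sum()
        if cost < best_cost:
            best_assign, best_cost = assign, cost
    return best_assign


def silhouette_optimal_k(
    cells_embedding_input, k_range=range(2, 9), seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Embed in 2-d (if needed), k-medoids for each k, and pick the k with
    the highest average silhouette width (ties -> smallest k)."""
    coords = embed_2d(cells_embedding_input, seed=seed)
    widths: dict[int, float] = {}
    for k in k_range:
        labels = kmedoids(coords, k, seed=seed)
        if len(np.unique(labels)) < 2:
            widths[k] = -1.0
            continue
        widths[k] = float(silhouette_score(coords, labels))
    best = min(widths, key=lambda k: (-widths[k], k))
    return best, widths


# ---------------------------------------------------- cross-validation --


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and metrics from one CV run."""

    n_folds: int
    cell_fold: np.ndarray
    patient_fold: np.ndarray
    cell_probs: np.ndarray               # OOF cell-head on cells
    cell_impressions: np.ndarray         # OOF patient-head on cells
    patient_out: np.ndarray              # OOF patient-head on patients
    cell_metrics: dict = field(default_factory=dict)
    patient_metrics: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)

    @property
    def cell_macro_pr_auc(self) -> float:
        return float(np.mean(list(self.cell_metrics["pr_auc"].values())))


def _center_by_fold(arr: np.ndarray, fold: np.ndarray) -> np.ndarray:
    """Subtract the per-fold mean (per output column) from pooled
    out-of-fold scores.

    Fold models are fit on different data, so only within-fold score
    calibration is meaningful; centering aligns the fold-specific offsets
    before rank-based pooled metrics (mirroring the per-CV-step centering
    applied to survival outputs).
    """
    out = np.asarray(arr, float).copy()
    for f in np.unique(fold):
        out[fold == f] -= out[fold == f].mean(axis=0)
    return out


def _fold_vector(n: int, n_folds: int, strata: np.ndarray, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(n), strata)):
        fold[test] = f
    return fold


def cross_validate(
    X_cell: ExpressionMatrix,
    Y_cell: LabelSet,
    X_pat: ExpressionMatrix,
    Y_pat: LabelSet,
    config: DegasConfig,
    n_folds: int = 10,
) -> CVResult:
    """k-fold CV partitioning cells and patients independently.

    For each fold the model trains on the complements and predicts the
    held-out cells' types, the held-out patients' labels, and patient-head
    impressions on the held-out cells; metrics are pooled out-of-fold.
    Folds are stratified by class label (classification heads) or event
    status (Cox head).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    cell_strata = np.argmax(Y_cell.onehot, axis=1)
    if config.patient_head == "cox":
        pat_strata = Y_pat.event.astype(int)
    else:
        pat_strata = np.argmax(Y_pat.onehot, axis=1)
    cell_fold = _fold_vector(X_cell.n_samples, n_folds, cell_strata, config.seed)
    pat_fold = _fold_vector(X_pat.n_samples, n_folds, pat_strata, config.seed + 1)
    if config.patient_head == "cox":
        for f in range(n_folds):
            if Y_pat.event[pat_fold != f].sum() == 0:
                warnings.warn("a training fold had zero events; refolding")
                pat_fold = _fold_vector(X_pat.n_samples, n_folds, pat_strata,
                                        config.seed + 4099)
                break

    n_cells, n_pats = X_cell.n_samples, X_pat.n_samples
    cell_probs = np.zeros((n_cells, len(Y_cell.class_names)))
    if config.patient_head == "class":
        patient_out = np.zeros((n_pats, len(Y_pat.class_names)))
        impressions = np.zeros((n_cells, len(Y_pat.class_names)))
    else:
        patient_out = np.zeros(n_pats)
        impressions = np.zeros(n_cells)

    for f in range(n_folds):
        tr_c, te_c = np.flatnonzero(cell_fold != f), np.flatnonzero(cell_fold == f)
        tr_p, te_p = np.flatnonzero(pat_fold != f), np.flatnonzero(pat_fold == f)
        cfg = config.replace(seed=config.seed + 100 * (f + 1))
        ens = train(X_cell.subset_samples(tr_c), Y_cell.subset(tr_c),
                    X_pat.subset_samples(tr_p), Y_pat.subset(tr_p), cfg, log_every=0)
        cell_probs[te_c] = ens.predict_cell_head(X_cell.subset_samples(te_c))
        patient_out[te_p] = ens.predict_patient_head(X_pat.subset_samples(te_p))
        impressions[te_c] = ens.predict_patient_head(X_cell.subset_samples(te_c))

    result = CVResult(n_folds, cell_fold, pat_fold, cell_probs, impressions, patient_out)
    result.cell_metrics = per_class_aucs(_center_by_fold(cell_probs, cell_fold),
                                         Y_cell.onehot, Y_cell.class_names)
    if config.patient_head == "class":
        result.patient_metrics = per_class_aucs(
            _center_by_fold(patient_out, pat_fold), Y_pat.onehot, Y_pat.class_names)
    else:
        chi2, p, high = km_logrank_median_split(
            _center_by_fold(patient_out, pat_fold), Y_pat.time, Y_pat.event)
        hr_direction = "high_scores_higher_risk" if (
            Y_pat.event[high].mean() >= Y_pat.event[~high].mean()
        ) else "high_scores_lower_risk"
        result.survival = {"chi2": chi2, "p": p, "direction": hr_direction}
    return result


# ------------------------------------------------- simulation wrappers --


def prepare_unit_inputs(data: SimulatedData) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Scale raw simulated cells and pseudo-patients to unit stage."""
    from .preprocessing import scale_pipeline

    return scale_pipeline(data.cells), scale_pipeline(data.patients)


def disease_association_from_impressions(
    impressions: np.ndarray, patient_classes: list[str]
) -> AssociationScores:
    """Convert OOF patient-head probabilities on cells to disease
    associations (disease-class column, k = number of patient classes)."""
    j = patient_classes.index("disease")
    return to_corr_coeff(np.asarray(impressions)[:, j], k=len(patient_classes))


def median_association_by_group(assoc: AssociationScores, group_names: np.ndarray) -> dict[str, float]:
    values = assoc.values.reshape(-1)
    return {g: float(np.median(values[group_names == g]))
            for g in np.unique(group_names.astype(str))}


def top_association_groups(medians: dict[str, float], n: int) -> set[str]:
    return set(sorted(medians, key=medians.get, reverse=True)[:n])


def prioritization_correct(data: SimulatedData, assoc: AssociationScores) -> bool:
    """The designed disease group(s) have the highest median association."""
    medians = median_association_by_group(assoc, data.cell_groups.labels())
    targets = set(DISEASE_GROUPS[data.scenario])
    return top_association_groups(medians, len(targets)) == targets


# ----------------------------------------------- domain-shift experiment --


def domain_adaptation_experiment(
    data: SimulatedData,
    config: DegasConfig,
    subtype: str,
    n_bias_cells: int = 300,
    multiplier: float = 1000.0,
) -> dict[str, float]:
    """One bias-injection experiment: add a large fixed subtype bias to
    every patient, train with and without the MMD penalty on all cells
    and all patients, and report the mean |association error| of the
    transferred disease associations on cells for each arm."""
    from .preprocessing import scale_pipeline
    from .synthetic import add_subtype_bias

    biased = add_subtype_bias(data.patients, data.pool, data.pool_groups, subtype,
                              n_cells=n_bias_cells, multiplier=multiplier,
                              seed=config.seed)
    Xc = scale_pipeline(data.cells)
    Xp = scale_pipeline(biased)
    out: dict[str, float] = {}
    for arm, cfg in (("with_mmd", config), ("without_mmd", config.replace(lambda2=0.0))):
        ens = train(Xc, data.cell_types, Xp, data.patient_labels, cfg, log_every=0)
        imp = ens.predict_patient_head(Xc)
        assoc = disease_association_from_impressions(imp,
                                                     data.patient_labels.class_names)
        out[arm] = float(np.abs(association_error(assoc, data.expected)).mean())
    return out


# ------------------------------------------------------------ ablation --


def unregularized(config: DegasConfig) -> DegasConfig:
    """Strip L2, dropout, and bootstrap aggregation from a config."""
    return config.replace(lambda3=0.0, dropout_keep=1.0, n_bootstrap=1)


@dataclass
class AblationReport:
    per_scenario: dict[str, dict[str, float]]

    def pooled_cell_pr_auc(self, arm: str) -> float:
        return float(np.mean([v[f"cell_pr_auc_{arm}"] for v in self.per_scenario.values()]))

    @property
    def cell_pr_auc_deficit_pct(self) -> float:
        """Regularized minus unregularized pooled cell-type PR-AUC, in
        percentage points (positive = regularization helps)."""
        return 100.0 * (self.pooled_cell_pr_auc("reg") - self.pooled_cell_pr_auc("unreg"))

    def patient_deltas(self) -> dict[str, float]:
        return {s: v["patient_pr_auc_reg"] - v["patient_pr_auc_unreg"]
                for s, v in self.per_scenario.items()}


def ablation_regularization(
    datasets: list[SimulatedData], config: DegasConfig, n_folds: int = 10
) -> AblationReport:
    """Paired CV with and without {L2, dropout, bagging} per simulation.

    Both arms share fold assignments and base seeds.  Reports per-scenario
    patient disease PR-AUC, macro cell-type PR-AUC, and mean |association
    error| of transferred disease associations on cells.
    """
    report: dict[str, dict[str, float]] = {}
    for data in datasets:
        Xc, Xp = prepare_unit_inputs(data)
        row: dict[str, float] = {}
        for arm, cfg in (("reg", config), ("unreg", unregularized(config))):
            res = cross_validate(Xc, data.cell_types, Xp, data.patient_labels,
                                 cfg, n_folds=n_folds)
            assoc = disease_association_from_impressions(
                res.cell_impressions, data.patient_labels.class_names)
            row[f"patient_pr_auc_{arm}"] = res.patient_metrics["pr_auc"]["disease"]
            row[f"cell_pr_auc_{arm}"] = res.cell_macro_pr_auc
            row[f"cell_assoc_err_{arm}"] = float(
                np.abs(association_error(assoc, data.expected)).mean())
        report[data.scenario] = row
    return AblationReport(report)


__all__ = [
    "pr_auc", "roc_auc", "per_class_aucs", "km_logrank_median_split",
    "association_error", "group_centroids", "deconvolve_least_squares",
    "embed_2d", "kmedoids", "silhouette_optimal_k", "CVResult",
    "cross_validate", "prepare_unit_inputs",
    "disease_association_from_impressions", "median_association_by_group",
    "top_association_groups", "prioritization_correct",
    "domain_adaptation_experiment", "unregularized",
    "AblationReport", "ablation_regularization",
]
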