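"""Cohort-level analysis: feature selection, SVM classification, BC contrasts.

The cohort stage consumes per-subject node-metric tables for one network
configuration and performs:

* **Feature selection** — per node, Welch two-sample t-tests between the two
  groups on degree, betweenness and clustering; Bonferroni calibration over
  the family of 3 x n_nodes tests; a node becomes a feature when at least two
  of its three calibrated p-values fall below alpha.
* **Classification** — RBF-kernel SVM with stratified k-fold (default 10)
  cross-validation.  Feature standardization, the inner hyperparameter grid
  search, and (by default) the feature selection itself are all refit inside
  each training fold, so no information leaks from test subjects.  Accuracy,
  specificity and sensitivity are computed from pooled out-of-fold
  predictions with the patient group as the positive class.
* **Group BC comparison** — per-node Welch t-tests on normalized betweenness
  with Bonferroni calibration, reporting the direction of significant
  changes.
* :func:`run_pipeline` — the end-to-end composition from 4-D volumes to the
  tables above, for both the highly-available and the conventional-mean
  representative signals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics as gm
from . import network as net
from . import voxel_nodes as vn
from .io import RunConfig, read_nifti, read_subject_table, write_manifest
from .synthetic import Parcellation

logger = logging.getLogger(__name__)

METRIC_NAMES = ("degree", "betweenness", "clustering")

#: Inner grid for the RBF SVM; log-spaced, searched with 3-fold CV inside
#: every training fold.
SVM_PARAM_GRID = {
    "svc__C": [0.1, 1.0, 10.0, 100.0],
    "svc__gamma": ["scale", 0.01, 0.1, 1.0],
}


@dataclass(frozen=True)
class CohortMetrics:
    """Node metrics of every subject for one shared network configuration."""

    subject_ids: tuple[str, ...]
    groups: np.ndarray
    node_names: tuple[str, ...]
    degree: np.ndarray = field(repr=False)
    betweenness: np.ndarray = field(repr=False)
    clustering: np.ndarray = field(repr=False)
    normalized_betweenness: np.ndarray = field(repr=False)
    graph_kind: str = "mst"
    sparsity: float | None = None

    def __post_init__(self) -> None:
        s, n = len(self.subject_ids), len(self.node_names)
        for name in ("degree", "betweenness", "clustering", "normalized_betweenness"):
            arr = getattr(self, name)
            if arr.shape != (s, n):
                raise ValueError(f"{name} must be {s} x {n}, got {arr.shape}")
        if len(self.groups) != s:
            raise ValueError("one group label per subject required")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def metric(self, name: str) -> np.ndarray:
        if name not in METRIC_NAMES + ("normalized_betweenness",):
            raise KeyError(name)
        return getattr(self, name)

    def subset(self, idx: np.ndarray) -> "CohortMetrics":
        return CohortMetrics(
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            groups=self.groups[idx],
            node_names=self.node_names,
            degree=self.degree[idx],
            betweenness=self.betweenness[idx],
            clustering=self.clustering[idx],
            normalized_betweenness=self.normalized_betweenness[idx],
            graph_kind=self.graph_kind,
            sparsity=self.sparsity,
        )

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise ValueError(
                f"no subjects in group {group!r}; present: "
                f"{sorted(set(self.groups.tolist()))}"
            )
        return idx


def cohort_from_tables(
    subject_ids: Sequence[str],
    groups: Sequence[str],
    tables: Sequence[gm.NodeMetricTable],
) -> CohortMetrics:
    """Stack per-subject :class:`NodeMetricTable`s into a cohort."""
    if not tables:
        raise ValueError("no metric tables given")
    names = tables[0].node_names
    kinds = {(t.graph_kind, t.sparsity) for t in tables}
    if len(kinds) > 1:
        raise ValueError(f"mixed graph configurations in one cohort: {kinds}")
    for t in tables:
        if t.node_names != names:
            raise ValueError("all subjects must share the node ordering")
    stack = {
        m: np.vstack([t.table[m].to_numpy(dtype=float) for t in tables])
        for m in METRIC_NAMES + ("normalized_betweenness",)
    }
    kind, sp = next(iter(kinds))
    return CohortMetrics(
        subject_ids=tuple(subject_ids),
        groups=np.asarray(list(groups)),
        node_names=names,
        degree=stack["degree"],
        betweenness=stack["betweenness"],
        clustering=stack["clustering"],
        normalized_betweenness=stack["normalized_betweenness"],
        graph_kind=kind,
        sparsity=sp,
    )


def _welch_columns(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Welch t-test; degenerate (zero-variance-both) columns get p=1."""
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # near-constant metric columns (e.g. tree degrees) trip scipy's
        # precision warning; they are handled below by setting p = 1
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.info("%d degenerate (zero-variance) tests set to p=1", int(bad.sum()))
        p[bad] = 1.0
        t[~np.isfinite(t)] = 0.0
    return t, p


@dataclass(frozen=True)
class FeatureSelection:
    """Per-node t-test p-values and the any-two-of-three node selection."""

    pvalues: pd.DataFrame  # roi_name + raw/calibrated p per metric
    selected_nodes: tuple[str, ...]
    selected_idx: np.ndarray
    alpha: float
    bonferroni_m: int

    @property
    def n_selected(self) -> int:
        return len(self.selected_nodes)


def select_features(
    cohort: CohortMetrics,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> FeatureSelection:
    """Any-two-of-three node selection with Bonferroni calibration.

    The Bonferroni family is the full set of 3 x n_nodes tests of one pairwise
    comparison; calibrated p-values are min(1, p * m).
    """
    ia = cohort.group_indices(group_a)
    ib = cohort.group_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need at least 2 subjects per group for a t-test")
    m = 3 * cohort.n_nodes
    cols: dict[str, np.ndarray] = {}
    n_sig = np.zeros(cohort.n_nodes, dtype=int)
    for metric in METRIC_NAMES:
        x = cohort.metric(metric)
        t, p = _welch_columns(x[ia], x[ib])
        p_cal = np.minimum(1.0, p * m)
        cols[f"t_{metric}"] = t
        cols[f"p_{metric}"] = p
        cols[f"p_{metric}_bonferroni"] = p_cal
        n_sig += (p_cal < alpha).astype(int)
    selected = np.flatnonzero(n_sig >= 2)
    df = pd.DataFrame({"roi_name": list(cohort.node_names), **cols})
    df["n_significant_metrics"] = n_sig
    df["selected"] = n_sig >= 2
    return FeatureSelection(
        pvalues=df,
        selected_nodes=tuple(cohort.node_names[i] for i in selected),
        selected_idx=selected,
        alpha=alpha,
        bonferroni_m=m,
    )


def feature_matrix(cohort: CohortMetrics, node_idx: np.ndarray) -> np.ndarray:
    """Per-subject feature vectors: the three metric values at chosen nodes."""
    node_idx = np.asarray(node_idx, dtype=int)
    return np.hstack([cohort.metric(m)[:, node_idx] for m in METRIC_NAMES])


@dataclass(frozen=True)
class ClassificationResult:
    """Pooled out-of-fold performance of the cross-validated RBF SVM."""

    accuracy: float  # percent
    specificity: float
    sensitivity: float
    positive_label: str
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_of_subject: np.ndarray
    n_folds: int
    seed: int
    selection_mode: str = "none"
    selected_per_fold: tuple[tuple[str, ...], ...] = ()
    best_params_per_fold: tuple[dict, ...] = ()


def _pooled_scores(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str
) -> tuple[float, float, float]:
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    acc = 100.0 * (tp + tn) / len(y_true)
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, spec, sens


def _make_svm() -> GridSearchCV:
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    return GridSearchCV(pipe, SVM_PARAM_GRID, cv=3, n_jobs=None)


def _check_folds(y: np.ndarray, k: int) -> None:
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"k={k} folds exceed the smallest group ({counts.min()} subjects); "
            f"use k <= {int(counts.min())}"
        )


def cross_validated_svm(
    features: np.ndarray,
    labels: Sequence[str],
    positive_label: str,
    k: int = 10,
    seed: int = 0,
) -> ClassificationResult:
    """Stratified k-fold RBF-SVM on fixed per-subject feature vectors.

    Standardization and the hyperparameter grid search are fit on each
    training fold only.  Deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(list(labels))
    if X.shape[0] != len(y):
        raise ValueError("one feature vector per subject required")
    _check_folds(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    best = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        clf = _make_svm()
        clf.fit(X[tr], y[tr])
        y_pred[te] = clf.predict(X[te])
        fold_of[te] = f
        best.append(dict(clf.best_params_))
    acc, spec, sens = _pooled_scores(y, y_pred, positive_label)
    return ClassificationResult(
        accuracy=acc,
        specificity=spec,
        sensitivity=sens,
        positive_label=positive_label,
        y_true=y,
        y_pred=y_pred,
        fold_of_subject=fold_of,
        n_folds=k,
        seed=seed,
        selection_mode="precomputed",
    )


def classify_groups(
    cohort: CohortMetrics,
    group_a: str,
    group_b: str,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    selection: str = "fold",
    positive_label: str | None = None,
) -> ClassificationResult:
    """Feature-selected, cross-validated classification of two groups.

    ``selection='fold'`` (default) refits the any-two-of-three node selection
    inside every training fold, so test subjects never influence the chosen
    features; ``'descriptive'`` selects once on the whole cohort (matches the
    hub-table analysis but leaks into the CV estimate); ``'none'`` uses all
    nodes.  A training fold that selects zero nodes falls back to all nodes.
    The positive class defaults to ``group_a`` (the patient group by the
    calling convention).
    """
    if selection not in ("fold", "descriptive", "none"):
        raise ValueError("selection must be 'fold', 'descriptive' or 'none'")
    idx = np.concatenate([cohort.group_indices(group_a), cohort.group_indices(group_b)])
    idx.sort()
    sub = cohort.subset(idx)
    y = sub.groups
    positive = positive_label or group_a
    _check_folds(y, k)

    all_nodes = np.arange(sub.n_nodes)
    if selection == "descriptive":
        fixed = select_features(sub, group_a, group_b, alpha).selected_idx
        if fixed.size == 0:
            fixed = all_nodes
    elif selection == "none":
        fixed = all_nodes
    else:
        fixed = None

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    selected_per_fold = []
    best = []
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if fixed is not None:
            nodes = fixed
        else:
            sel = select_features(sub.subset(tr), group_a, group_b, alpha)
            nodes = sel.selected_idx if sel.n_selected else all_nodes
        X = feature_matrix(sub, nodes)
        clf = _make_svm()
        clf.fit(X[tr], y[tr])
        y_pred[te] = clf.predict(X[te])
        fold_of[te] = f
        selected_per_fold.append(tuple(sub.node_names[i] for i in nodes))
        best.append(dict(clf.best_params_))
    acc, spec, sens = _pooled_scores(y, y_pred, positive)
    return ClassificationResult(
        accuracy=acc,
        specificity=spec,
        sensitivity=sens,
        positive_label=positive,
        y_true=y,
        y_pred=y_pred,
        fold_of_subject=fold_of,
        n_folds=k,
        seed=seed,
        selection_mode=selection,
        selected_per_fold=tuple(selected_per_fold),
        best_params_per_fold=tuple(best),
    )


def compare_group_bc(
    cohort: CohortMetrics,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-node normalized-betweenness contrast between two groups.

    Welch t-tests with Bonferroni calibration over the n_nodes family; rows
    with calibrated p < alpha are flagged with the direction of change in
    ``group_a`` relative to ``group_b``.
    """
    ia = cohort.group_indices(group_a)
    ib = cohort.group_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need at least 2 subjects per group for a t-test")
    xa = cohort.normalized_betweenness[ia]
    xb = cohort.normalized_betweenness[ib]
    t, p = _welch_columns(xa, xb)
    p_cal = np.minimum(1.0, p * cohort.n_nodes)
    sig = p_cal < alpha
    delta = xa.mean(axis=0) - xb.mean(axis=0)
    direction = np.where(sig, np.where(delta > 0, "increase", "decrease"), "")
    return pd.DataFrame(
        {
            "roi_name": list(cohort.node_names),
            f"mean_{group_a}": xa.mean(axis=0),
            f"mean_{group_b}": xb.mean(axis=0),
            "t": t,
            "p": p,
            "p_bonferroni": p_cal,
            "significant": sig,
            "direction": direction,
        }
    )


def group_hub_table(
    full_graphs: Mapping[str, Sequence[net.BrainGraph]],
    sparsity: float = 0.12,
    hub_cutoff: float = 1.7,
    length_transform: str = "inv",
    only_hubs: bool = True,
) -> pd.DataFrame:
    """Group-level hub table from group-averaged adjacency matrices.

    For each group, full-network weights are averaged across subjects, the
    average is thresholded at the given sparsity, and normalized betweenness
    is computed; rows are regions, columns the groups' b_i values plus hub
    flags.  With ``only_hubs`` the table keeps regions that are a hub
    (b_i > cutoff) in at least one group.
    """
    groups = list(full_graphs)
    names = None
    b_cols = {}
    hub_cols = {}
    for g in groups:
        graphs = list(full_graphs[g])
        if not graphs:
            raise ValueError(f"group {g!r} has no graphs")
        names = names or graphs[0].node_names
        mean_w = np.mean([gr.weights for gr in graphs], axis=0)
        np.fill_diagonal(mean_w, 0.0)
        avg = net.BrainGraph(mean_w, kind="full", node_names=names)
        thr = net.threshold_by_sparsity(avg, sparsity)
        b = gm.betweenness(thr, length_transform)
        bn = gm.normalized_betweenness(b)
        b_cols[g] = bn
        hub_cols[g] = bn > hub_cutoff
    df = pd.DataFrame({"roi_name": list(names)})
    for g in groups:
        df[f"b_{g}"] = b_cols[g]
        df[f"hub_{g}"] = hub_cols[g]
    if only_hubs:
        any_hub = np.column_stack([hub_cols[g] for g in groups]).any(axis=1)
        df = df.loc[any_hub].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# end-to-end composition


def subject_networks(
    volume: np.ndarray,
    parcellation: Parcellation,
    config: RunConfig,
    pair_seed: int | None = None,
) -> dict[str, net.BrainGraph]:
    """Volume -> representative signals -> full / mst / sparsity graphs."""
    vset = vn.extract_voxel_series(volume, parcellation)
    if config.method == "han":
        if config.pair_mode == "auto":
            pcs = vn.auto_pairs(
                vset,
                seed=pair_seed,
                pair_cap=config.pair_cap,
                pairs_per_voxel=config.pairs_per_voxel,
            )
        else:
            pcs = vn.enumerate_pairs(
                vset, mode=config.pair_mode, n_pairs=config.n_pairs, seed=pair_seed
            )
        thr = vn.find_threshold(pcs, vset.roi_labels, config.grid_step)
        if not thr.feasible:
            raise RuntimeError(
                "threshold search infeasible: no grid value keeps an effective "
                "voxel in every region"
            )
        signals = vn.representative_series(pcs, thr, vset)
    else:
        signals = vn.conventional_series(vset)

    full = net.full_network(signals)
    out = {"full": full, "mst": net.maximum_spanning_tree(full)}
    for s in config.sparsities:
        out[f"sparsity_{s:g}"] = net.threshold_by_sparsity(
            full, s, config.ensure_connected
        )
    return out


def run_pipeline(
    subject_table: pd.DataFrame | str | Path,
    parcellation: Parcellation,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    volumes: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """Full analysis over a cohort: networks, metrics, statistics, classifier.

    ``subject_table`` needs columns subject_id, group, path; ``volumes`` may
    supply in-memory arrays keyed by subject_id instead of paths.  Returns a
    bundle with per-network cohorts, descriptive feature selections,
    classification results, BC contrasts and group hub tables; writes TSV
    tables plus a manifest when ``out_dir`` is given.
    """
    config = config or RunConfig()
    if not isinstance(subject_table, pd.DataFrame):
        subject_table = read_subject_table(subject_table)
    subject_ids = subject_table["subject_id"].tolist()
    groups = subject_table["group"].tolist()

    per_network_tables: dict[str, list[gm.NodeMetricTable]] = {}
    full_by_group: dict[str, list[net.BrainGraph]] = {}
    seeds = np.random.SeedSequence(config.seed).generate_state(len(subject_ids))
    for i, (sid, grp) in enumerate(zip(subject_ids, groups)):
        if volumes is not None and sid in volumes:
            vol = np.asarray(volumes[sid])
        else:
            vol, _, _ = read_nifti(subject_table.iloc[i]["path"], expected_ndim=4)
        try:
            nets = subject_networks(vol, parcellation, config, int(seeds[i]))
        except Exception as exc:
            raise RuntimeError(f"subject {sid}: {exc}") from exc
        full_by_group.setdefault(grp, []).append(nets.pop("full"))
        for key, graph in nets.items():
            per_network_tables.setdefault(key, []).append(
                gm.node_metric_table(graph, config.length_transform, config.hub_cutoff)
            )
        logger.info("subject %s (%s): networks built", sid, grp)

    cohorts = {
        key: cohort_from_tables(subject_ids, groups, tables)
        for key, tables in per_network_tables.items()
    }

    unique_groups = list(dict.fromkeys(groups))
    pairs = list(itertools.combinations(unique_groups, 2))
    results: dict = {
        "cohorts": cohorts,
        "feature_selection": {},
        "classification": {},
        "bc_comparison": {},
        "hub_table": group_hub_table(
            full_by_group,
            sparsity=config.hub_sparsity,
            hub_cutoff=config.hub_cutoff,
            length_transform=config.length_transform,
        ),
        "config": config,
    }
    for ga, gb in pairs:
        positive = config.positive_group if config.positive_group in (ga, gb) else ga
        for key in config.classify_networks:
            if key not in cohorts:
                raise ValueError(
                    f"classify_networks entry {key!r} not among built networks "
                    f"{sorted(cohorts)}"
                )
            cohort = cohorts[key]
            results["feature_selection"][(ga, gb, key)] = select_features(
                cohort, ga, gb, config.alpha
            )
            results["classification"][(ga, gb, key)] = classify_groups(
                cohort,
                ga,
                gb,
                k=config.folds,
                seed=config.seed,
                alpha=config.alpha,
                positive_label=positive,
            )
            results["bc_comparison"][(ga, gb, key)] = compare_group_bc(
                cohort, ga, gb, config.alpha
            )

    if out_dir is not None:
        _write_results(Path(out_dir), results, config)
    return results


def _write_results(out: Path, results: dict, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results["hub_table"].to_csv(out / "hub_table.tsv", sep="\t", index=False)
    rows = []
    for (ga, gb, key), res in results["classification"].items():
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "network": key,
                "accuracy_pct": res.accuracy,
                "specificity_pct": res.specificity,
                "sensitivity_pct": res.sensitivity,
                "positive": res.positive_label,
                "folds": res.n_folds,
            }
        )
    pd.DataFrame(rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    for (ga, gb, key), sel in results["feature_selection"].items():
        sel.pvalues.to_csv(
            out / f"features_{ga}_vs_{gb}_{key}.tsv", sep="\t", index=False
        )
    for (ga, gb, key), df in results["bc_comparison"].items():
        df.to_csv(out / f"bc_{ga}_vs_{gb}_{key}.tsv", sep="\t", index=False)
    write_manifest(out / "manifest.txt", config, extra={"n_cohorts": len(results["cohorts"])})
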