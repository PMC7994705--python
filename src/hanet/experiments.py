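"""Simulation studies that characterise the pipeline's statistical behaviour.

These are the package's desk-scale study conditions: null calibration of the
any-two-of-three feature rule, power against a planted metric shift, hub
recovery through the full imaging pipeline, and the head-to-head comparison
of the highly-available-node representative against the conventional ROI
mean on cohorts with planted group covariance differences.

Problem sizes (20-region parcellations, T = 80 time points, 15 subjects per
group, 20 replicates) are the package's chosen desk scale: large enough for
the qualitative effects to be stable, small enough to re-run routinely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as gm
from . import network as net
from . import voxel_nodes as vn
from .pipeline import (
    CohortMetrics,
    classify_groups,
    select_features,
)
from .synthetic import (
    Parcellation,
    SimulationSpec,
    hub_covariance,
    make_parcellation,
    simulate_cohort,
)

METRICS = ("degree", "betweenness", "clustering")


def synthetic_cohort_metrics(
    rng: np.random.Generator,
    n_a: int = 30,
    n_b: int = 30,
    n_nodes: int = 90,
    shift_node: int | None = None,
    shift_sd: float = 0.0,
    shift_metrics: tuple[str, ...] = ("degree", "betweenness"),
) -> CohortMetrics:
    """Metric-level cohort with iid standard-normal node metrics.

    Used for calibration studies of the selection/classification stage in
    isolation: group B optionally receives a ``shift_sd``-pooled-SD shift at
    ``shift_node`` in the listed metrics.
    """
    s = n_a + n_b
    data = {m: rng.standard_normal((s, n_nodes)) for m in METRICS}
    if shift_node is not None and shift_sd:
        for m in shift_metrics:
            data[m][n_a:, shift_node] += shift_sd
    bc = data["betweenness"]
    bn = bc - bc.min() + 0.1  # positive surrogate so normalization is defined
    bn = bn / bn.mean(axis=1, keepdims=True)
    return CohortMetrics(
        subject_ids=tuple(f"s{i:03d}" for i in range(s)),
        groups=np.array(["A"] * n_a + ["B"] * n_b),
        node_names=tuple(f"ROI_{i+1}" for i in range(n_nodes)),
        degree=data["degree"],
        betweenness=data["betweenness"],
        clustering=data["clustering"],
        normalized_betweenness=bn,
        graph_kind="synthetic",
    )


def null_selection_rate(
    n_reps: int = 200,
    n_per_group: int = 30,
    n_nodes: int = 90,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise selection rate when both groups share one distribution."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cohort = synthetic_cohort_metrics(rng, n_per_group, n_per_group, n_nodes)
        sel = select_features(cohort, "A", "B", alpha)
        hits += sel.n_selected > 0
    return hits / n_reps


def planted_shift_selection_rate(
    n_reps: int = 50,
    n_per_group: int = 30,
    n_nodes: int = 90,
    shift_sd: float = 3.0,
    shift_node: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the planted node is selected."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cohort = synthetic_cohort_metrics(
            rng, n_per_group, n_per_group, n_nodes, shift_node, shift_sd
        )
        sel = select_features(cohort, "A", "B", alpha)
        hits += shift_node in sel.selected_idx
    return hits / n_reps


def null_cv_accuracy(
    n_reps: int = 20,
    n_per_group: int = 30,
    n_nodes: int = 90,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean pooled CV accuracy (percent) on pure-noise cohorts.

    With fold-contained feature selection this must sit at chance; a value
    systematically above 50% would indicate leakage.
    """
    rng = np.random.default_rng(seed)
    accs = []
    for rep in range(n_reps):
        cohort = synthetic_cohort_metrics(rng, n_per_group, n_per_group, n_nodes)
        res = classify_groups(
            cohort, "A", "B", k=k, seed=int(rng.integers(2**31)), selection="fold"
        )
        accs.append(res.accuracy)
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# imaging-level studies


@dataclass(frozen=True)
class TwoGroupDesign:
    """Planted group structure for the imaging-level studies.

    The patient group has globally weaker region covariance and weaker hub
    elevation than the control group — the qualitative signature of
    disconnection syndromes — while voxel noise and its heterogeneity are
    shared.
    """

    n_rois: int = 20
    shape: tuple[int, int, int] = (8, 8, 6)
    n_subjects: int = 15
    n_timepoints: int = 80
    hub_rois: tuple[int, ...] = (3, 7)
    control_base_r: float = 0.35
    control_hub_r: float = 0.7
    patient_base_r: float = 0.2
    patient_hub_r: float = 0.45
    voxel_noise_sd: float = 1.0
    within_roi_signal_fraction: float = 0.8
    voxel_noise_heterogeneity: float = 0.75

    def simulation_spec(self, seed: int) -> SimulationSpec:
        cov = {
            "patient": hub_covariance(
                self.n_rois, self.patient_base_r, self.hub_rois, self.patient_hub_r
            ),
            "control": hub_covariance(
                self.n_rois, self.control_base_r, self.hub_rois, self.control_hub_r
            ),
        }
        return SimulationSpec(
            n_subjects_per_group=self.n_subjects,
            groups=("patient", "control"),
            roi_covariance_per_group=cov,
            n_timepoints=self.n_timepoints,
            voxel_noise_sd=self.voxel_noise_sd,
            within_roi_signal_fraction=self.within_roi_signal_fraction,
            voxel_noise_heterogeneity=self.voxel_noise_heterogeneity,
            hub_rois=self.hub_rois,
            seed=seed,
        )


def _cohort_metrics_both_methods(
    design: TwoGroupDesign,
    seed: int,
    sparsity: float = 0.12,
) -> tuple[CohortMetrics, CohortMetrics]:
    """Simulate one cohort; return (han, conventional) metric cohorts."""
    parcellation = make_parcellation(design.shape, design.n_rois, seed=seed)
    spec = design.simulation_spec(seed)
    records = simulate_cohort(parcellation, spec)
    tables = {"han": [], "mean": []}
    ids, groups = [], []
    for rec in records:
        vset = vn.extract_voxel_series(rec.volume, parcellation)
        pcs = vn.enumerate_pairs(vset, mode="exhaustive")
        thr = vn.find_threshold(pcs, vset.roi_labels)
        signals = {
            "han": vn.representative_series(pcs, thr, vset),
            "mean": vn.conventional_series(vset),
        }
        for method, sig in signals.items():
            full = net.full_network(sig)
            graph = net.threshold_by_sparsity(full, sparsity)
            tables[method].append(gm.node_metric_table(graph))
        ids.append(rec.subject_id)
        groups.append(rec.group)
    from .pipeline import cohort_from_tables

    return (
        cohort_from_tables(ids, groups, tables["han"]),
        cohort_from_tables(ids, groups, tables["mean"]),
    )


def method_comparison(
    n_replicates: int = 20,
    seed: int = 0,
    design: TwoGroupDesign | None = None,
    sparsity: float = 0.12,
    k: int = 10,
) -> pd.DataFrame:
    """Accuracy of the highly-available vs conventional representative.

    Each replicate simulates an independent two-group cohort, runs both
    representative-signal methods through the identical downstream pipeline
    (sparsity-thresholded network, node metrics, fold-contained selection,
    RBF-SVM CV with matched folds), and records the two pooled accuracies.
    """
    design = design or TwoGroupDesign()
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    rows = []
    for rep, rs in enumerate(rep_seeds):
        han, mean = _cohort_metrics_both_methods(design, int(rs), sparsity)
        cv_seed = int(rs) % (2**31)
        res_han = classify_groups(han, "patient", "control", k=k, seed=cv_seed)
        res_mean = classify_groups(mean, "patient", "control", k=k, seed=cv_seed)
        rows.append(
            {
                "replicate": rep,
                "accuracy_han": res_han.accuracy,
                "accuracy_mean": res_mean.accuracy,
            }
        )
    df = pd.DataFrame(rows)
    df["han_ge_mean"] = df["accuracy_han"] >= df["accuracy_mean"]
    return df


def hub_recovery_rate(
    n_replicates: int = 20,
    seed: int = 0,
    hub_roi: int = 5,
    n_rois: int = 12,
    shape: tuple[int, int, int] = (7, 7, 6),
    n_timepoints: int = 120,
    base_r: float = 0.15,
    hub_r: float = 0.6,
) -> float:
    """Fraction of replicates where the planted hub tops MST betweenness.

    One subject per replicate is simulated with a single region elevated
    against all others, pushed through the full highly-available pipeline,
    and the planted region is checked to carry the highest spanning-tree
    betweenness centrality.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    hits = 0
    for rs in rep_seeds:
        parcellation = make_parcellation(shape, n_rois, seed=int(rs))
        cov = hub_covariance(n_rois, base_r, (hub_roi,), hub_r)
        spec = SimulationSpec(
            n_subjects_per_group=1,
            groups=("g",),
            roi_covariance_per_group={"g": cov},
            n_timepoints=n_timepoints,
            hub_rois=(hub_roi,),
            seed=int(rs),
        )
        rec = simulate_cohort(parcellation, spec)[0]
        vset = vn.extract_voxel_series(rec.volume, parcellation)
        pcs = vn.enumerate_pairs(vset, mode="exhaustive")
        thr = vn.find_threshold(pcs, vset.roi_labels)
        sig = vn.representative_series(pcs, thr, vset)
        mst = net.maximum_spanning_tree(net.full_network(sig))
        b = gm.betweenness(mst)
        hits += int(np.argmax(b)) == hub_roi - 1
    return hits / n_replicates
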