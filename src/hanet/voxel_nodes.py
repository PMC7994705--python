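"""Representative regional time series via the highly-available-node rule.

A parcellation region is usually summarised by the unweighted mean of its
voxels' time series (:func:`conventional_series`).  The highly-available-node
alternative summarises it instead as a *pair-count-weighted* average of its
"effective" voxels:

1. Pearson correlations are computed for voxel pairs whose endpoints lie in
   different regions; self-pairs and negative correlations are deemed zero, so
   every retained correlation lies in [0, 1] (:func:`pair_correlation`,
   :func:`enumerate_pairs`).
2. A correlation threshold r* is chosen on a grid as the largest value at
   which (I) a voxel is "effective" when at least one of its cross-region
   pairs has r >= r*, and (II) every region contains at least one effective
   voxel (:func:`find_threshold`).
3. Each region's representative series is sum_k (N_k / N) * A_k over its
   effective voxels, where N_k is the number of surviving pairs incident to
   voxel k and N = sum_k N_k (:func:`representative_series`).  Weights sum to
   one, so the representative is a convex combination of voxel series: voxels
   that correlate with many voxels elsewhere dominate, noisy voxels drop out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import Parcellation

logger = logging.getLogger(__name__)

#: Above this many cross-region pairs the auto policy switches to sampling.
DEFAULT_PAIR_CAP = 2_000_000
#: Pairs drawn per voxel when sampling.
DEFAULT_PAIRS_PER_VOXEL = 100


@dataclass(frozen=True)
class VoxelSeriesSet:
    """All labelled-voxel time series of one subject.

    ``series`` is V x T, ``roi_of_voxel`` maps each row to its region label
    (1..R), ``coords`` holds the original 3-D indices.  Constant rows are
    excluded at construction (their Pearson correlation is undefined);
    ``n_constant_excluded`` records how many were dropped.
    """

    series: np.ndarray = field(repr=False)
    roi_of_voxel: np.ndarray
    coords: np.ndarray
    roi_labels: np.ndarray
    n_constant_excluded: int = 0

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]

    def voxels_of_roi(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.roi_of_voxel == label)


@dataclass(frozen=True)
class PairCorrelationSet:
    """Cross-region voxel pairs with zero-ruled Pearson correlations.

    Each unordered pair appears once; ``r`` is already mapped through the
    zeroing rule (negatives -> 0), so all values lie in [0, 1].
    """

    voxel_a: np.ndarray
    voxel_b: np.ndarray
    roi_a: np.ndarray
    roi_b: np.ndarray
    r: np.ndarray
    sampling_mode: str = "exhaustive"
    n_requested: int | None = None
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class NodeThreshold:
    """Result of the criteria-I/II threshold search."""

    r_star: float | None
    grid_step: float
    feasible: bool
    effective_voxels: dict[int, int]

    def __post_init__(self) -> None:
        if self.feasible and self.r_star is None:
            raise ValueError("feasible threshold must carry r_star")


@dataclass(frozen=True)
class RoiSignalMatrix:
    """R x T representative signals, one row per region label."""

    signals: np.ndarray = field(repr=False)
    roi_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    method: str = "highly_available"
    r_star_used: float | None = None
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("representative signals must be finite")

    @property
    def n_rois(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


def extract_voxel_series(volume: np.ndarray, parcellation: Parcellation) -> VoxelSeriesSet:
    """Pull every labelled voxel's time course out of a 4-D volume.

    Rows follow the lexicographic order of voxel coordinates, so repeated
    extractions are identically ordered.  Background voxels are skipped and
    constant (zero-variance) voxels are excluded with a logged count.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {volume.shape}")
    if volume.shape[:3] != parcellation.shape:
        raise ValueError(
            f"volume spatial shape {volume.shape[:3]} does not match "
            f"parcellation shape {parcellation.shape}"
        )
    if volume.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    lv = parcellation.label_volume
    coords = np.argwhere(lv > 0)
    if len(coords) == 0:
        raise ValueError("parcellation labels no voxels (all background)")
    series = volume[coords[:, 0], coords[:, 1], coords[:, 2], :].astype(float)
    roi = lv[coords[:, 0], coords[:, 1], coords[:, 2]].astype(int)

    keep = series.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("excluded %d constant voxel series", n_dropped)
    return VoxelSeriesSet(
        series=series[keep],
        roi_of_voxel=roi[keep],
        coords=coords[keep],
        roi_labels=parcellation.labels.copy(),
        n_constant_excluded=n_dropped,
    )


def pair_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two voxel series under the zeroing rule.

    Self-pairs (identical object or identical values) and negative
    correlations are deemed zero, so the result lies in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0 or ssy == 0.0:
        raise ValueError("Pearson correlation undefined for a constant series")
    if x is y or np.array_equal(x, y):
        return 0.0  # auto-correlation deemed zero
    r = float(xc @ yc) / np.sqrt(ssx * ssy)
    return max(r, 0.0)


def _cross_roi_index_pairs(roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = np.triu_indices(len(roi), k=1)
    cross = roi[ia] != roi[ib]
    return ia[cross], ib[cross]


def n_cross_roi_pairs(vset: VoxelSeriesSet) -> int:
    """Number of unordered cross-region voxel pairs, sum_{r<s} |r|·|s|."""
    counts = np.bincount(vset.roi_of_voxel)
    v = int(counts.sum())
    return (v * (v - 1) - int((counts * (counts - 1)).sum())) // 2


def _pairwise_r(series: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    centred = series - series.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centred, centred)
    num = np.einsum("ij,ij->i", centred[ia], centred[ib])
    r = num / np.sqrt(ss[ia] * ss[ib])
    return np.clip(r, 0.0, 1.0)


def enumerate_pairs(
    vset: VoxelSeriesSet,
    mode: str = "exhaustive",
    n_pairs: int | None = None,
    seed: int | None = None,
) -> PairCorrelationSet:
    """Compose cross-region voxel pairs and score them.

    ``exhaustive`` emits every unordered cross-region pair; ``random`` draws
    ``n_pairs`` of them uniformly without replacement under ``seed``.
    Within-region pairs are never emitted.
    """
    if len(np.unique(vset.roi_of_voxel)) < 2:
        raise ValueError("need voxels from at least 2 regions to form cross pairs")
    ia, ib = _cross_roi_index_pairs(vset.roi_of_voxel)
    if mode == "exhaustive":
        pass
    elif mode == "random":
        if n_pairs is None:
            raise ValueError("random mode requires n_pairs")
        if n_pairs > len(ia):
            raise ValueError(
                f"requested {n_pairs} pairs but only {len(ia)} cross-region "
                f"pairs exist"
            )
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(ia), size=n_pairs, replace=False)
        pick.sort()
        ia, ib = ia[pick], ib[pick]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    r = _pairwise_r(vset.series, ia, ib)
    return PairCorrelationSet(
        voxel_a=ia,
        voxel_b=ib,
        roi_a=vset.roi_of_voxel[ia],
        roi_b=vset.roi_of_voxel[ib],
        r=r,
        sampling_mode=mode,
        n_requested=n_pairs,
        seed=seed,
    )


def auto_pairs(
    vset: VoxelSeriesSet,
    seed: int | None = None,
    pair_cap: int = DEFAULT_PAIR_CAP,
    pairs_per_voxel: int = DEFAULT_PAIRS_PER_VOXEL,
) -> PairCorrelationSet:
    """Default pairing policy: exhaustive when cheap, seeded sampling when not."""
    total = n_cross_roi_pairs(vset)
    if total <= pair_cap:
        return enumerate_pairs(vset, mode="exhaustive")
    n = min(pairs_per_voxel * vset.n_voxels, total)
    return enumerate_pairs(vset, mode="random", n_pairs=n, seed=seed)


def find_threshold(
    pcs: PairCorrelationSet,
    roi_labels: np.ndarray,
    grid_step: float = 0.01,
) -> NodeThreshold:
    """Largest grid threshold at which every region keeps an effective voxel.

    Scans the grid {grid_step, 2*grid_step, ..., 1 - grid_step} from high to
    low.  At threshold t, a voxel is effective iff it sits in >= 1 retained
    pair (r >= t, r > 0) whose partner lies in a different region
    (criterion I); t qualifies iff every region owns >= 1 effective voxel
    (criterion II).  Because the retained-pair set only grows as t falls, the
    answer is the per-region best pair correlation, minimised over regions and
    snapped down to the grid; infeasibility is reported, not raised.
    """
    if pcs.n_pairs == 0:
        raise ValueError("empty pair set")
    if not 0 < grid_step < 1:
        raise ValueError("grid_step must lie in (0, 1)")
    roi_labels = np.asarray(roi_labels)
    max_r = np.zeros(int(roi_labels.max()) + 1)
    pos = pcs.r > 0
    np.maximum.at(max_r, pcs.roi_a[pos], pcs.r[pos])
    np.maximum.at(max_r, pcs.roi_b[pos], pcs.r[pos])
    best_per_roi = max_r[roi_labels]
    m = float(best_per_roi.min())

    n_levels = int(round(1.0 / grid_step)) - 1  # top grid value = 1 - grid_step
    k = int(np.floor(m / grid_step + 1e-9))
    k = min(k, n_levels)
    if k < 1:
        return NodeThreshold(None, grid_step, False, {})
    r_star = round(k * grid_step, 12)

    keep = (pcs.r >= r_star - 1e-12) & pos
    vox = np.concatenate([pcs.voxel_a[keep], pcs.voxel_b[keep]])
    rois = np.concatenate([pcs.roi_a[keep], pcs.roi_b[keep]])
    _, first = np.unique(vox, return_index=True)
    eff_counts = np.bincount(rois[first], minlength=int(roi_labels.max()) + 1)
    eff = {int(label): int(eff_counts[label]) for label in roi_labels}
    return NodeThreshold(r_star, grid_step, True, eff)


def representative_series(
    pcs: PairCorrelationSet,
    threshold: NodeThreshold,
    vset: VoxelSeriesSet,
) -> RoiSignalMatrix:
    """Pair-count-weighted regional signals at the chosen threshold.

    For each region, N_k counts the surviving pairs incident to voxel k and
    the representative row is sum_k (N_k / N) A_k with N = sum_k N_k.  The
    weights sum to one; voxels with no surviving pair contribute nothing.
    """
    if not threshold.feasible or threshold.r_star is None:
        raise ValueError("threshold search was infeasible; no representative defined")
    keep = (pcs.r >= threshold.r_star - 1e-12) & (pcs.r > 0)
    counts = np.bincount(
        np.concatenate([pcs.voxel_a[keep], pcs.voxel_b[keep]]),
        minlength=vset.n_voxels,
    ).astype(float)

    labels = vset.roi_labels
    signals = np.empty((len(labels), vset.n_timepoints))
    for row, label in enumerate(labels):
        idx = vset.voxels_of_roi(int(label))
        nk = counts[idx]
        n_total = nk.sum()
        if n_total == 0:
            raise RuntimeError(
                f"region {label} has no surviving pair at r*={threshold.r_star}; "
                "criterion II should have guaranteed one"
            )
        signals[row] = (nk / n_total) @ vset.series[idx]
    return RoiSignalMatrix(
        signals=signals,
        roi_labels=np.asarray(labels),
        method="highly_available",
        r_star_used=threshold.r_star,
    )


def conventional_series(vset: VoxelSeriesSet) -> RoiSignalMatrix:
    """Baseline representative: unweighted mean over each region's voxels."""
    labels = vset.roi_labels
    signals = np.empty((len(labels), vset.n_timepoints))
    for row, label in enumerate(labels):
        idx = vset.voxels_of_roi(int(label))
        if len(idx) == 0:
            raise ValueError(f"region {label} has no voxels")
        signals[row] = vset.series[idx].mean(axis=0)
    return RoiSignalMatrix(
        signals=signals,
        roi_labels=np.asarray(labels),
        method="conventional",
        r_star_used=None,
    )
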