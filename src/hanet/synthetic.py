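"""Synthetic resting-state BOLD cohorts with known regional structure.

Real resting-state data arrive as a preprocessed 4-D volume per subject plus a
3-D integer parcellation assigning every brain voxel to one of R regions
(90 in the AAL-style default, 45 per hemisphere).  This module emulates that
shape so the whole analysis chain is testable without any download:

* :func:`make_parcellation` grows R connected, near-equal-sized regions over an
  ellipsoidal foreground mask on a voxel grid.
* :func:`simulate_subject` draws one latent time series per region from a
  stationary Gaussian AR(1) process whose innovation covariance is the group's
  R x R region covariance, then renders each voxel as
  ``fraction * latent + noise``.  Per-voxel noise scales are log-normally
  dispersed so that regions are internally heterogeneous — some voxels carry
  the regional signal cleanly, others are dominated by noise — which is the
  regime the pair-count-weighted representative-signal method is designed for.
* :func:`simulate_cohort` derives per-subject seeds from one master seed and
  optionally writes NIfTI volumes plus a subject table.

Group differences are planted through the region covariance: per-group base
correlation levels and "hub" regions whose correlation to every other region
is elevated (see :func:`hub_covariance`).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: 6-connectivity offsets used for region growth.
_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class Parcellation:
    """A 3-D integer label volume: 0 = background, 1..R = regions."""

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vol = np.asarray(self.label_volume)
        if vol.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {vol.shape}")
        labels = np.unique(vol)
        nonzero = labels[labels > 0]
        n = int(nonzero.max()) if nonzero.size else 0
        if not np.array_equal(nonzero, np.arange(1, n + 1)):
            raise ValueError("labels must be exactly {0} ∪ {1..R} with no gaps")
        counts = np.bincount(vol.ravel(), minlength=n + 1)
        small = np.flatnonzero(counts[1:] < 2) + 1
        if small.size:
            raise ValueError(f"every region needs >= 2 voxels; too small: {small.tolist()}")
        names = self.roi_names or tuple(default_roi_names(n))
        if len(names) != n:
            raise ValueError(f"{len(names)} names for {n} regions")
        object.__setattr__(self, "roi_names", tuple(names))

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.label_volume.shape)  # type: ignore[return-value]

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_rois + 1)

    def voxel_counts(self) -> np.ndarray:
        """Number of voxels per region, indexed ``[label - 1]``."""
        return np.bincount(self.label_volume.ravel(), minlength=self.n_rois + 1)[1:]


def default_roi_names(n_rois: int) -> list[str]:
    """Left/right-paired region names, mirroring a bilateral atlas."""
    names = []
    for i in range(n_rois):
        pair = i // 2 + 1
        side = "L" if i % 2 == 0 else "R"
        if i == n_rois - 1 and n_rois % 2 == 1:
            side = "M"  # unpaired midline region for odd R
        names.append(f"Region{pair:02d}{side}")
    return names


@dataclass(frozen=True)
class SimulationSpec:
    """Everything that determines a simulated cohort.

    Parameters
    ----------
    n_subjects_per_group:
        Cohort size per group.
    groups:
        Ordered group names (e.g. ``("AD", "MCI", "NC")``).
    n_timepoints:
        Length T of every time series.  Default 130 — the order implied by a
        140-volume acquisition with the first 10 volumes discarded.
    roi_covariance_per_group:
        Group name -> R x R symmetric PSD latent covariance.
    voxel_noise_sd:
        Baseline standard deviation of the additive voxel noise.
    within_roi_signal_fraction:
        Coefficient on the regional latent signal in every voxel, in [0, 1].
    voxel_noise_heterogeneity:
        Log-normal sigma of per-voxel noise scales.  0 makes every voxel
        equally noisy; the default 0.75 gives a realistic several-fold spread
        of voxel quality within a region.
    hub_rois:
        Labels of regions given elevated covariance (metadata; the covariance
        matrices themselves carry the structure — see :func:`hub_covariance`).
    seed:
        Master seed; fully determines the cohort.
    ar_coeff:
        Lag-1 autocorrelation of the latent signals.  0.3 mimics the temporal
        smoothness of band-passed (0.01–0.08 Hz) BOLD without implementing a
        filter; the stationary cross-region correlation is unaffected.
    """

    n_subjects_per_group: int
    groups: tuple[str, ...]
    roi_covariance_per_group: Mapping[str, np.ndarray]
    n_timepoints: int = 130
    voxel_noise_sd: float = 1.0
    within_roi_signal_fraction: float = 0.8
    voxel_noise_heterogeneity: float = 0.75
    hub_rois: tuple[int, ...] = ()
    seed: int = 0
    ar_coeff: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if not 0.0 <= self.within_roi_signal_fraction <= 1.0:
            raise ValueError("within_roi_signal_fraction must lie in [0, 1]")
        if self.voxel_noise_sd < 0 or self.voxel_noise_heterogeneity < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        for g, cov in self.roi_covariance_per_group.items():
            cov = np.asarray(cov, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValueError(f"covariance for group {g!r} is not square")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance for group {g!r} is not symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError(f"covariance for group {g!r} is not PSD")

    @property
    def n_rois(self) -> int:
        first = next(iter(self.roi_covariance_per_group.values()))
        return np.asarray(first).shape[0]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    volume: np.ndarray = field(repr=False)
    path: Path | None = None


def _ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    """Brain-like connected foreground: the ellipsoid inscribed in the grid."""
    grids = np.indices(shape).astype(float)
    centred = [
        (g - (s - 1) / 2.0) / max(s / 2.0, 0.5) for g, s in zip(grids, shape)
    ]
    return sum(c**2 for c in centred) <= 1.0 + 1e-9


def make_parcellation(
    shape: Sequence[int],
    n_rois: int = 90,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Parcellation:
    """Partition an ellipsoidal foreground into ``n_rois`` connected regions.

    Seeds are placed by farthest-point sampling (so regions spread evenly) and
    grown by round-robin breadth-first search, which keeps every region
    connected and of near-equal size.  Deterministic for a fixed seed.
    """
    shape = tuple(int(s) for s in shape)
    minimum = 2 * n_rois
    if int(np.prod(shape)) < minimum:
        raise ValueError(
            f"grid of {int(np.prod(shape))} voxels cannot host {n_rois} regions; "
            f"need at least {minimum} voxels"
        )
    mask = _ellipsoid_mask(shape)
    coords = np.argwhere(mask)  # lexicographic order
    if len(coords) < minimum:
        raise ValueError(
            f"foreground mask has {len(coords)} voxels; need at least {minimum} "
            f"for {n_rois} regions — use a larger grid"
        )
    rng = np.random.default_rng(seed)

    # farthest-point seed placement
    start = int(rng.integers(len(coords)))
    seed_idx = [start]
    d = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(n_rois - 1):
        nxt = int(np.argmax(d))
        seed_idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))

    labels = np.zeros(shape, dtype=np.int16)
    queues = []
    for r, si in enumerate(seed_idx, start=1):
        labels[tuple(coords[si])] = r
        queues.append(deque([coords[si]]))

    # round-robin BFS growth: one voxel per region per sweep
    grew = True
    while grew:
        grew = False
        for r, q in enumerate(queues, start=1):
            while q:
                v = q.popleft()
                placed = False
                for off in _NEIGHBOURS:
                    w = v + off
                    if np.any(w < 0) or np.any(w >= shape):
                        continue
                    t = tuple(w)
                    if mask[t] and labels[t] == 0:
                        labels[t] = r
                        q.append(v)  # revisit: v may have more free neighbours
                        q.append(w)
                        placed = True
                        grew = True
                        break
                if placed:
                    break

    assert int((labels > 0).sum()) == len(coords), "mask not fully labelled"
    _repair_small_regions(labels, mask, n_rois)
    return Parcellation(labels, voxel_size, tuple(default_roi_names(n_rois)))


def _repair_small_regions(labels: np.ndarray, mask: np.ndarray, n_rois: int) -> None:
    """Reassign boundary voxels so every region owns at least 2 voxels."""
    for _ in range(4 * n_rois):
        counts = np.bincount(labels.ravel(), minlength=n_rois + 1)
        small = np.flatnonzero(counts[1:] < 2) + 1
        if not small.size:
            return
        target = int(small[0])
        moved = False
        for v in np.argwhere(labels == target):
            for off in _NEIGHBOURS:
                w = v + off
                if np.any(w < 0) or np.any(w >= labels.shape):
                    continue
                donor = labels[tuple(w)]
                if donor > 0 and donor != target and counts[donor] >= 3:
                    labels[tuple(w)] = target
                    moved = True
                    break
            if moved:
                break
        if not moved:  # pragma: no cover - only with pathological masks
            raise RuntimeError(f"could not grow region {target} to 2 voxels")
    raise RuntimeError("region repair failed to converge")  # pragma: no cover


def latent_signals(
    cov: np.ndarray, n_timepoints: int, ar_coeff: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian AR(1) draw, shape (T, R).

    Innovations share covariance ``cov``; the stationary marginal covariance of
    the process equals ``cov`` exactly (innovations are scaled by
    sqrt(1 - phi^2)), so planted cross-region correlations are preserved.
    """
    cov = np.asarray(cov, dtype=float)
    n_rois = cov.shape[0]
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_rois))
    innov = rng.standard_normal((n_timepoints, n_rois)) @ chol.T
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - ar_coeff**2)
    for t in range(1, n_timepoints):
        out[t] = ar_coeff * out[t - 1] + scale * innov[t]
    return out


def simulate_subject(
    parcellation: Parcellation,
    spec: SimulationSpec,
    group: str,
    subject_seed: int,
) -> np.ndarray:
    """Render one subject's 4-D volume (X, Y, Z, T) for the given group."""
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}; valid groups: {list(spec.groups)}")
    if spec.n_rois != parcellation.n_rois:
        raise ValueError(
            f"covariance is {spec.n_rois} x {spec.n_rois} but parcellation has "
            f"{parcellation.n_rois} regions"
        )
    rng = np.random.default_rng(subject_seed)
    latent = latent_signals(
        np.asarray(spec.roi_covariance_per_group[group], dtype=float),
        spec.n_timepoints,
        spec.ar_coeff,
        rng,
    )  # (T, R)

    lv = parcellation.label_volume
    coords = np.argwhere(lv > 0)
    roi = lv[lv > 0]
    n_vox = len(coords)
    if spec.voxel_noise_heterogeneity > 0:
        scales = np.exp(rng.normal(0.0, spec.voxel_noise_heterogeneity, n_vox))
    else:
        scales = np.ones(n_vox)
    noise = rng.standard_normal((n_vox, spec.n_timepoints))
    noise *= (spec.voxel_noise_sd * scales)[:, None]
    series = spec.within_roi_signal_fraction * latent[:, roi - 1].T + noise

    volume = np.zeros(parcellation.shape + (spec.n_timepoints,), dtype=np.float64)
    volume[coords[:, 0], coords[:, 1], coords[:, 2], :] = series
    return volume


def simulate_cohort(
    parcellation: Parcellation,
    spec: SimulationSpec,
    out_dir: str | Path | None = None,
) -> list[SubjectRecord]:
    """Simulate every subject of every group; optionally write NIfTI + table.

    Per-subject seeds are derived deterministically from ``spec.seed``, so the
    same spec always yields the same cohort (and byte-identical files).
    """
    n_total = spec.n_subjects_per_group * len(spec.groups)
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_total)
    records: list[SubjectRecord] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        from .io import write_nifti  # local import: io depends on nibabel only

        write_nifti(
            parcellation.label_volume.astype(np.int16),
            out_path / "parcellation.nii.gz",
            parcellation.voxel_size,
        )

    idx = 0
    rows = []
    for group in spec.groups:
        for s in range(spec.n_subjects_per_group):
            subject_id = f"sub_{group}_{s:03d}"
            vol = simulate_subject(parcellation, spec, group, int(seeds[idx]))
            path = None
            if out_path is not None:
                from .io import write_nifti

                path = out_path / f"{subject_id}.nii.gz"
                write_nifti(vol.astype(np.float32), path, parcellation.voxel_size)
            records.append(SubjectRecord(subject_id, group, vol, path))
            # table stores filenames, not absolute paths, so identical specs
            # give byte-identical tables regardless of the output location
            rows.append((subject_id, group, path.name if path else ""))
            idx += 1

    if out_path is not None:
        lines = ["subject_id\tgroup\tpath"]
        lines += ["\t".join(r) for r in rows]
        (out_path / "subjects.tsv").write_text("\n".join(lines) + "\n")
        logger.info("wrote %d subjects to %s", n_total, out_path)
    return records


def hub_covariance(
    n_rois: int,
    base_r: float = 0.2,
    hub_rois: Sequence[int] = (),
    hub_r: float = 0.6,
) -> np.ndarray:
    """Unit-diagonal covariance with constant base correlation and hub rows.

    Every pair correlates at ``base_r`` except pairs involving a hub region,
    which correlate at ``hub_r``.  The result is projected to the nearest PSD
    matrix (eigenvalue clipping) and rescaled to unit diagonal, so it is always
    a valid correlation matrix.
    """
    if not 0 <= base_r < 1 or not 0 <= hub_r < 1:
        raise ValueError("correlations must lie in [0, 1)")
    cov = np.full((n_rois, n_rois), base_r)
    for h in hub_rois:
        if not 1 <= h <= n_rois:
            raise ValueError(f"hub label {h} outside 1..{n_rois}")
        cov[h - 1, :] = hub_r
        cov[:, h - 1] = hub_r
    np.fill_diagonal(cov, 1.0)
    w, v = np.linalg.eigh(cov)
    if w.min() < 1e-8:
        cov = (v * np.maximum(w, 1e-8)) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
    return cov
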