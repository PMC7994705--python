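"""NIfTI and TSV readers/writers, run configuration, manifests.

All spatial processing happens in voxel space; affines are carried through
untouched.  Matrices and tables are exchanged as tab-separated text (10
significant digits), which keeps every intermediate diff-able.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


def read_nifti(path: str | Path, expected_ndim: int | None = None):
    """Load a NIfTI-1 volume; returns (data, affine, voxel_size_mm).

    Plain ``.nii`` and gzipped ``.nii.gz`` are both accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed header / not NIfTI
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj)
    if expected_ndim is not None and data.ndim != expected_ndim:
        raise ValueError(
            f"{path} is {data.ndim}-D but a {expected_ndim}-D volume was expected"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, voxel_size


def write_nifti(
    data: np.ndarray,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
    return path


def write_matrix_tsv(
    matrix: np.ndarray,
    path: str | Path,
    labels: list[str] | tuple[str, ...] | None = None,
) -> Path:
    """Write a labelled numeric matrix as TSV with 10 significant digits."""
    matrix = np.asarray(matrix)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels is None:
        labels = [f"c{i}" for i in range(matrix.shape[1])]
    if len(labels) != matrix.shape[1]:
        raise ValueError("one label per column required")
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_matrix_tsv(
    path: str | Path, require_symmetric: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Read a header-labelled numeric TSV; returns (matrix, column labels).

    Ragged rows and non-numeric cells raise a parse error naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty file")
    labels = lines[0].rstrip("\n").split("\t")
    width = len(labels)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != width:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} cells, expected {width}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    matrix = np.array(rows)
    if require_symmetric:
        if matrix.shape[0] != matrix.shape[1] or not np.allclose(
            matrix, matrix.T, atol=1e-9
        ):
            raise ValueError(f"{path}: matrix is not symmetric")
    return matrix, labels


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Subject table TSV with columns subject_id, group, path.

    Relative volume paths are resolved against the table's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"subject_id", "group", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["path"] = [
        p if (not p or Path(p).is_absolute()) else str(path.parent / p)
        for p in df["path"].fillna("")
    ]
    return df


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with validated defaults."""

    method: str = "han"  # han | mean
    pair_mode: str = "auto"  # auto | exhaustive | random
    n_pairs: int | None = None
    pair_cap: int = 2_000_000
    pairs_per_voxel: int = 100
    grid_step: float = 0.01
    sparsities: tuple[float, ...] = (0.06, 0.12, 0.18, 0.24, 0.30, 0.36)
    length_transform: str = "inv"  # inv | sub
    hub_cutoff: float = 1.7
    hub_sparsity: float = 0.12
    alpha: float = 0.05
    folds: int = 10
    seed: int = 0
    ensure_connected: bool = False
    classify_networks: tuple[str, ...] = ("mst", "sparsity_0.12")
    positive_group: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("han", "mean"):
            raise ValueError("method must be 'han' or 'mean'")
        if self.pair_mode not in ("auto", "exhaustive", "random"):
            raise ValueError("pair_mode must be auto, exhaustive or random")
        if self.pair_mode == "random" and not self.n_pairs:
            raise ValueError("random pair_mode requires n_pairs")
        if not 0 < self.grid_step < 1:
            raise ValueError("grid_step must lie in (0, 1)")
        if not all(0 < s <= 1 for s in self.sparsities):
            raise ValueError("sparsities must lie in (0, 1]")
        if self.length_transform not in ("inv", "sub"):
            raise ValueError("length_transform must be 'inv' or 'sub'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.hub_cutoff <= 0 or self.hub_sparsity <= 0:
            raise ValueError("hub parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("sparsities", "classify_networks"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def as_flat_dict(self) -> dict[str, str]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            out[f.name] = "" if v is None else str(v)
        return out


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: RunConfig,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, object] | None = None,
) -> Path:
    """Flat key=value manifest: config, seeds, package version, input digests."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"hanet_version={__version__}"]
    for k, v in config.as_flat_dict().items():
        lines.append(f"config.{k}={v}")
    for name, p in (inputs or {}).items():
        p = Path(p)
        digest = sha256_of(p) if p.exists() else "missing"
        lines.append(f"input.{name}={p}")
        lines.append(f"input.{name}.sha256={digest}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    path.write_text("\n".join(lines) + "\n")
    return path
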