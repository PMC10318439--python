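"""Voxel encoding of residue features on a 36³ grid of 2 Å voxels.

Each residue's feature vector is written into the voxel containing its Cβ
(half-open cells, floor indexing).  Voxels without a Cβ stay zero.  The box
spans 72 Å per side; proteins that do not fit are partitioned into several
grids along their principal axes so that every residue lands in exactly one
grid.  Two residues falling into the same voxel (possible at 2 Å resolution)
have their feature vectors averaged; the voxel label is positive if any
co-resident residue is positive — conservative for recall.

Rotation augmentation follows the training recipe: a random angle uniform on
[-180°, 180°] about the axis through a uniformly chosen residue's Cβ and the
protein center of mass, applied to protein and carbohydrate coordinates
alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .features import FeatureTable
from .structure import ProteinStructure

GRID_SIZE = 36
VOXEL_EDGE = 2.0  # Å
BOX_EDGE = GRID_SIZE * VOXEL_EDGE  # 72 Å


# ---------------------------------------------------------------------------
# Rotation augmentation


@dataclass
class RotationRecord:
    """A rigid rotation about an axis through two points."""

    angle_deg: float
    axis_point: np.ndarray          # point on the axis (center of mass)
    axis_dir: np.ndarray            # unit direction
    residue_index: int              # residue whose Cβ defined the axis

    @property
    def matrix(self) -> np.ndarray:
        u = self.axis_dir
        t = np.deg2rad(self.angle_deg)
        c, s = np.cos(t), np.sin(t)
        ux, uy, uz = u
        K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
        return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, float) - self.axis_point
        return x @ self.matrix.T + self.axis_point


def random_rotation(cb_coords: np.ndarray, center_of_mass: np.ndarray,
                    rng: np.random.Generator) -> RotationRecord:
    """Sample the augmentation rotation: angle uniform on [-180°, 180°],
    axis through a uniformly chosen residue's Cβ and the center of mass.
    A residue whose Cβ coincides with the center of mass (degenerate axis)
    is resampled."""
    cb_coords = np.asarray(cb_coords, float)
    if len(cb_coords) < 1:
        raise ValueError("need at least one residue")
    com = np.asarray(center_of_mass, float)
    for _ in range(64):
        idx = int(rng.integers(0, len(cb_coords)))
        axis = cb_coords[idx] - com
        norm = np.linalg.norm(axis)
        if norm > 1e-6:
            break
    else:
        raise ValueError("all residue anchors coincide with the center of mass")
    angle = float(rng.uniform(-180.0, 180.0))
    return RotationRecord(angle, com, axis / norm, idx)


def rotate_structure(structure: ProteinStructure,
                     rng: np.random.Generator) -> tuple[ProteinStructure, RotationRecord]:
    """Apply one fresh augmentation rotation to protein and carbohydrates."""
    com = structure.all_protein_atoms().mean(axis=0)
    rec = random_rotation(structure.cb_coords, com, rng)
    R = rec.matrix
    t = rec.axis_point - rec.axis_point @ R.T  # x -> R(x - p) + p
    return structure.transformed(R, t), rec


# ---------------------------------------------------------------------------
# Voxelization


@dataclass
class VoxelGrid:
    """One 36³ feature grid with its residue bookkeeping."""

    channels: np.ndarray                # (n_features, 36, 36, 36)
    labels: np.ndarray                  # (36, 36, 36) binary
    origin: np.ndarray                  # (3,) Å, low corner of voxel (0,0,0)
    voxel_edge: float = VOXEL_EDGE
    residue_map: dict = field(default_factory=dict)   # (ix,iy,iz) -> [residue idx]

    @property
    def residue_indices(self) -> list:
        return sorted(i for idxs in self.residue_map.values() for i in idxs)


def _assign(table: FeatureTable, indices: np.ndarray, origin: np.ndarray) -> VoxelGrid:
    """Fill one grid with the residues listed in `indices`."""
    n_feat = table.vectors.shape[1]
    channels = np.zeros((n_feat, GRID_SIZE, GRID_SIZE, GRID_SIZE))
    labels = np.zeros((GRID_SIZE, GRID_SIZE, GRID_SIZE), dtype=int)
    residue_map: dict = {}
    voxel_of = np.floor((table.coords_cb[indices] - origin) / VOXEL_EDGE).astype(int)
    for row, res_idx in enumerate(indices):
        key = tuple(voxel_of[row])
        if not all(0 <= k < GRID_SIZE for k in key):
            raise AssertionError(f"residue {res_idx} fell outside its grid at {key}")
        residue_map.setdefault(key, []).append(int(res_idx))
    for key, members in residue_map.items():
        channels[(slice(None),) + key] = table.vectors[members].mean(axis=0)
        labels[key] = int(table.labels[members].max())
    return VoxelGrid(channels, labels, np.asarray(origin, float), VOXEL_EDGE, residue_map)


def voxelize(table: FeatureTable) -> list[VoxelGrid]:
    """Encode a voxel-scheme feature table into one or more grids.

    A protein whose Cβ extent fits in the 72 Å box yields a single grid with
    the Cβ centroid at the box center.  Larger proteins are partitioned into
    non-overlapping 72 Å windows along their principal axes (PCA of the Cβ
    cloud); each occupied window becomes one grid, so every residue is
    covered exactly once.
    """
    if table.scheme != "voxel":
        raise ValueError("voxelize requires a voxel-scheme FeatureTable")
    if len(table) == 0:
        raise ValueError("empty feature table")

    cb = table.coords_cb
    centroid = cb.mean(axis=0)
    extent = cb.max(axis=0) - cb.min(axis=0)
    all_idx = np.arange(len(table))

    if np.all(extent < BOX_EDGE - VOXEL_EDGE):
        origin = centroid - BOX_EDGE / 2.0
        return [_assign(table, all_idx, origin)]

    # split: rotate into the principal frame, tile with 72 Å windows
    centered = cb - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pca = centered @ vt.T
    low = pca.min(axis=0) - VOXEL_EDGE / 2.0
    window = np.floor((pca - low) / BOX_EDGE).astype(int)

    # rebuild a table in the principal frame so grid indexing stays axis-aligned
    rotated = FeatureTable(
        scheme=table.scheme,
        vectors=_rotate_orientation(table.vectors, vt),
        labels=table.labels,
        coords_cb=pca,
        coords_ca=(table.coords_ca - centroid) @ vt.T,
        chain=table.chain,
        author_index=table.author_index,
    )

    grids = []
    for key in sorted({tuple(w) for w in window}):
        members = all_idx[np.all(window == np.array(key), axis=1)]
        origin = low + np.array(key, float) * BOX_EDGE
        grids.append(_assign(rotated, members, origin))
    return grids


def _rotate_orientation(vectors: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Co-rotate the orientation block (last 3 columns of the voxel scheme)."""
    out = vectors.copy()
    out[:, 25:28] = vectors[:, 25:28] @ rot.T
    return out


def devoxelize(voxel_probs: np.ndarray, residue_map: dict,
               out: np.ndarray | None = None) -> dict:
    """Map per-voxel probabilities back to residues.

    Each residue receives the probability of the voxel it was assigned to;
    residues sharing a voxel share a probability.  Returns a dict
    residue index -> probability (and also writes into `out` if given).
    """
    voxel_probs = np.asarray(voxel_probs)
    if voxel_probs.shape != (GRID_SIZE,) * 3:
        raise ValueError(f"expected a {GRID_SIZE}^3 probability array")
    result = {}
    for key, members in residue_map.items():
        p = float(voxel_probs[key])
        for idx in members:
            result[idx] = p
            if out is not None:
                out[idx] = p
    return result


def devoxelize_all(grids: list[VoxelGrid], probs: list[np.ndarray],
                   n_residues: int) -> np.ndarray:
    """Assemble per-residue probabilities from all grids of one protein."""
    out = np.full(n_residues, np.nan)
    for grid, p in zip(grids, probs):
        devoxelize(p, grid.residue_map, out)
    if np.isnan(out).any():
        missing = np.flatnonzero(np.isnan(out))
        raise ValueError(f"residues missing from every grid: {missing.tolist()}")
    return out


# ---------------------------------------------------------------------------
# Serialization


def save_grids(path, grids: list[VoxelGrid]) -> None:
    """Write grids to a compressed array container plus a JSON sidecar."""
    arrays = {}
    meta = []
    for g_i, g in enumerate(grids):
        arrays[f"channels_{g_i}"] = g.channels.astype(np.float32)
        arrays[f"labels_{g_i}"] = g.labels.astype(np.int8)
        meta.append({
            "origin": g.origin.tolist(),
            "voxel_edge": g.voxel_edge,
            "residue_map": {",".join(map(str, k)): v for k, v in g.residue_map.items()},
        })
    np.savez_compressed(path, **arrays)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
        else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)


def load_grids(path) -> list[VoxelGrid]:
    data = np.load(path)
    sidecar = str(path)[:-4] + ".json" if str(path).endswith(".npz") \
        else str(path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    grids = []
    for g_i, m in enumerate(meta):
        grids.append(VoxelGrid(
            channels=data[f"channels_{g_i}"].astype(float),
            labels=data[f"labels_{g_i}"].astype(int),
            origin=np.array(m["origin"]),
            voxel_edge=float(m["voxel_edge"]),
            residue_map={tuple(map(int, k.split(","))): v
                         for k, v in m["residue_map"].items()},
        ))
    return grids
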