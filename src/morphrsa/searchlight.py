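"""Whole-volume searchlight RSA on a masked voxel grid.

A sphere of configurable world-space radius (default 6 mm, at most 90 voxels,
at least 10% of the geometric sphere in-mask) is centered on every in-mask
voxel; within each sphere a neural RDM is computed and correlated (tau-a)
against the hypothesis RDMs, yielding one map per model. Maps are Fisher
z-transformed before group-level one-sample t-tests with sign-flip
permutation max-T (or Bonferroni) familywise control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import stats

from .rdm import (
    RDM,
    correlation_distance_matrix,
    kendall_tau_a,
    neutral_by_partial_cells,
    rank01,
)

__all__ = [
    "VoxelGrid",
    "Neighborhoods",
    "sphere_neighborhoods",
    "run_searchlight",
    "fisher_z",
    "group_maps",
    "save_map",
    "load_mask",
]


@dataclass
class VoxelGrid:
    """A 3-D voxel grid with a boolean mask and a grid-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape must equal grid shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size_mm: float = 2.0,
                  mask: np.ndarray | None = None) -> "VoxelGrid":
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return cls(tuple(shape), aff, mask)


@dataclass
class Neighborhoods:
    """Per-center voxel memberships of a searchlight run."""

    grid: VoxelGrid
    centers: np.ndarray          # (n_centers, 3) integer grid coords of in-mask centers
    members: list[np.ndarray]    # flat in-mask indices per center, distance-ordered
    valid: np.ndarray            # bool per center


def _sphere_offsets(affine: np.ndarray, radius_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer grid offsets within radius_mm world distance, sorted by
    (distance, lexicographic offset) for a deterministic truncation order."""
    lin = affine[:3, :3]
    # bounding box of the sphere in grid units
    step = np.sqrt((lin ** 2).sum(axis=0))
    bound = np.maximum(np.floor(radius_mm / np.where(step > 0, step, np.inf)).astype(int), 0)
    ax = [np.arange(-b, b + 1) for b in bound]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid @ lin.T, axis=1)
    keep = dist <= radius_mm + 1e-9
    offs, dist = grid[keep], dist[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], dist))
    return offs[order], dist[order]


def sphere_neighborhoods(
    grid: VoxelGrid,
    radius_mm: float = 6.0,
    max_voxels: int = 90,
    min_valid_fraction: float = 0.1,
) -> Neighborhoods:
    """Build spherical neighborhoods around every in-mask voxel.

    World distances are measured through the affine, so anisotropic voxels are
    handled. Each neighborhood is truncated to ``max_voxels`` by ascending
    distance (lexicographic tie-break); centers whose in-mask fraction of the
    geometric sphere falls below ``min_valid_fraction`` are flagged invalid.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    offsets, _ = _sphere_offsets(grid.affine, radius_mm)
    n_sphere = len(offsets)
    centers = np.argwhere(grid.mask)
    shape = np.asarray(grid.shape)
    members: list[np.ndarray] = []
    valid = np.zeros(len(centers), dtype=bool)
    for ci, c in enumerate(centers):
        pts = c[None, :] + offsets
        inside = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inside]
        in_mask = grid.mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[in_mask]
        valid[ci] = (len(pts) / n_sphere) >= min_valid_fraction
        pts = pts[:max_voxels]
        members.append(np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]),
                                            tuple(grid.shape)))
    return Neighborhoods(grid=grid, centers=centers, members=members, valid=valid)


def run_searchlight(
    pattern_volume: np.ndarray,
    neighborhoods: Neighborhoods,
    hypothesis_rdms: list[RDM],
    comparison_cells: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Tau-a map per hypothesis model over all valid searchlight centers.

    ``pattern_volume`` is conditions × x × y × z with condition order matching
    the hypothesis RDM labels. Invalid centers and centers with fewer than two
    usable voxels are NaN in every returned map.
    """
    labels = hypothesis_rdms[0].labels
    for r in hypothesis_rdms[1:]:
        if r.labels != labels:
            raise ValueError("hypothesis RDMs have mismatched condition labels")
    if pattern_volume.shape[0] != len(labels):
        raise ValueError("pattern volume condition axis does not match RDM labels")
    if comparison_cells is None:
        comparison_cells = neutral_by_partial_cells(labels)
    flat = pattern_volume.reshape(pattern_volume.shape[0], -1)
    hyp_vecs = {r.source: r.cells(comparison_cells) for r in hypothesis_rdms}
    maps = {name: np.full(neighborhoods.grid.shape, np.nan) for name in hyp_vecs}
    for ci, (center, idx) in enumerate(zip(neighborhoods.centers,
                                           neighborhoods.members)):
        if not neighborhoods.valid[ci] or idx.size < 2:
            continue
        patch = flat[:, idx]
        if np.any(patch.std(axis=1) == 0):
            continue
        d = rank01(correlation_distance_matrix(patch))
        neural_vec = d[comparison_cells[0], comparison_cells[1]]
        cx, cy, cz = center
        for name, hv in hyp_vecs.items():
            maps[name][cx, cy, cz] = kendall_tau_a(neural_vec, hv)
    return maps


def fisher_z(map_values: np.ndarray) -> np.ndarray:
    """Fisher z-transform (atanh) of a correlation map; NaNs preserved."""
    arr = np.asarray(map_values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (np.any(finite <= -1) or np.any(finite >= 1)):
        raise ValueError("fisher_z requires values strictly inside (-1, 1)")
    return np.arctanh(arr)


def group_maps(
    subject_maps: list[np.ndarray],
    correction: str = "max_t",
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t-test over subjects with FWE control.

    Contrast maps (e.g. model A minus model B per subject) are passed directly
    as ``subject_maps``. Familywise correction is sign-flip permutation max-T
    by default, Bonferroni over in-analysis voxels as fallback. Voxels missing
    (NaN) in any subject, or with zero variance, are NaN in both outputs.
    Returns (t_map, corrected_p_map).
    """
    if len(subject_maps) < 5:
        raise ValueError("group map needs at least 5 subjects")
    data = np.stack(subject_maps)
    shape = data.shape[1:]
    for m in subject_maps[1:]:
        if m.shape != subject_maps[0].shape:
            raise ValueError("subject maps have mismatched grids")
    flat = data.reshape(len(subject_maps), -1)
    usable = np.all(np.isfinite(flat), axis=0) & (flat.std(axis=0) > 0)
    t_map = np.full(flat.shape[1], np.nan)
    p_map = np.full(flat.shape[1], np.nan)
    if not usable.any():
        return t_map.reshape(shape), p_map.reshape(shape)
    x = flat[:, usable]
    n = x.shape[0]
    t_obs = x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n))
    t_map[usable] = t_obs
    if correction == "bonferroni":
        p = 2 * stats.t.sf(np.abs(t_obs), df=n - 1)
        p_map[usable] = np.minimum(1.0, p * usable.sum())
    elif correction == "max_t":
        rng = np.random.default_rng(seed)
        exceed = np.ones(t_obs.size)  # include the observed permutation
        for _ in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=(n, 1))
            xp = x * signs
            tp = xp.mean(axis=0) / (xp.std(axis=0, ddof=1) / np.sqrt(n))
            exceed += (np.max(np.abs(tp)) >= np.abs(t_obs))
        p_map[usable] = exceed / (n_permutations + 1)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return t_map.reshape(shape), p_map.reshape(shape)


def save_map(map_values: np.ndarray, grid: VoxelGrid, path: str | Path,
             meta: dict | None = None) -> None:
    """Write a map as NIfTI with a JSON sidecar of metadata."""
    img = nib.Nifti1Image(np.asarray(map_values, dtype=np.float32), grid.affine)
    if meta:
        img.header["descrip"] = json.dumps(meta)[:79].encode()
    nib.save(img, str(path))
    if meta:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_mask(path: str | Path) -> VoxelGrid:
    """Read a binary mask NIfTI into a VoxelGrid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    return VoxelGrid(tuple(data.shape), img.affine, data)
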