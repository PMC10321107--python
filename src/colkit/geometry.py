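"""Synthetic cortical-patch geometries and benchmark preference maps.

Real laminar-fMRI pipelines obtain a local cortical coordinate frame from
segmentation-derived tools: U and V are geodesic surface coordinates (mm)
imposed on a flattened disc of cortex, and D is the normalized equi-volume
depth (0 at the white-matter border, 1 at the CSF border).  This module
produces the same (U, V, D) parametrization analytically, for flat and
sinusoidally folded ribbon phantoms, so that every downstream stage — the
cylindrical searchlight in particular — can be exercised and unit-tested
without any acquired data.

It also builds the two benchmark preference maps used to bracket empirical
columnarity distributions: a voxel-wise ``random`` map (pure-noise lower
bound) and an ``ideal`` hexagonal-bin map of full-depth columns (upper
bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PatchGeometry",
    "PreferenceMap",
    "make_flat_slab",
    "make_curved_patch",
    "hexbin_ideal_map",
    "random_preference_map",
]


@dataclass
class PatchGeometry:
    """A voxelized cortical patch with local UVD coordinates.

    Coordinate arrays are full-grid float volumes holding NaN outside the
    gray-matter mask; ``depth_d`` is the normalized equi-volume depth in
    [0, 1] with 0 at the white-matter border and 1 at the CSF border.
    """

    voxel_size: tuple[float, float, float]
    gm_mask: np.ndarray
    coord_u: np.ndarray
    coord_v: np.ndarray
    depth_d: np.ndarray
    thickness: np.ndarray

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.gm_mask.shape)

    @property
    def n_gm(self) -> int:
        return int(self.gm_mask.sum())

    def uv(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 2) array of U, V coordinates for ``mask`` voxels (default GM)."""
        m = self.gm_mask if mask is None else mask
        return np.column_stack([self.coord_u[m], self.coord_v[m]])

    def validate(self) -> None:
        m = self.gm_mask
        for name in ("coord_u", "coord_v", "depth_d", "thickness"):
            arr = getattr(self, name)
            if arr.shape != m.shape:
                raise ValueError(f"{name} shape {arr.shape} != mask shape {m.shape}")
            if not np.all(np.isfinite(arr[m])):
                raise ValueError(f"{name} has non-finite values inside the GM mask")
        if m.any():
            d = self.depth_d[m]
            if d.min() < 0 or d.max() > 1:
                raise ValueError("depth_d outside [0, 1] on GM voxels")
            if self.thickness[m].min() <= 0:
                raise ValueError("thickness must be positive on GM voxels")


@dataclass
class PreferenceMap:
    """Per-voxel winning-condition labels: 0 outside the domain, 1..K inside."""

    labels: np.ndarray
    n_conditions: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        inside = self.labels > 0
        if inside.any() and self.labels[inside].max() > self.n_conditions:
            raise ValueError("labels exceed n_conditions")

    @property
    def domain(self) -> np.ndarray:
        return self.labels > 0


def _nan_volume(dims: tuple[int, int, int]) -> np.ndarray:
    out = np.full(dims, np.nan)
    return out


def make_flat_slab(n_u: int, n_v: int, n_d: int, voxel_size: float) -> PatchGeometry:
    """A rectangular slab phantom with trivially flat UVD coordinates.

    U runs along axis 0 and V along axis 1 in steps of ``voxel_size``; depth
    D samples axis 2 at voxel centers, (k + 0.5) / n_d.  Thickness is the
    constant n_d * voxel_size and every voxel is gray matter.
    """
    if n_u < 1 or n_v < 1 or n_d < 1:
        raise ValueError("slab dimensions must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    dims = (n_u, n_v, n_d)
    i, j, k = np.meshgrid(
        np.arange(n_u), np.arange(n_v), np.arange(n_d), indexing="ij"
    )
    return PatchGeometry(
        voxel_size=(voxel_size,) * 3,
        gm_mask=np.ones(dims, dtype=bool),
        coord_u=i * voxel_size,
        coord_v=j * voxel_size,
        depth_d=(k + 0.5) / n_d,
        thickness=np.full(dims, n_d * voxel_size),
    )


def make_curved_patch(
    n_u: int,
    n_v: int,
    n_d: int,
    voxel_size: float,
    fold_amplitude: float,
    fold_period: float,
) -> PatchGeometry:
    """A folded ribbon phantom: the mid-surface follows a sinusoid.

    The mid-surface height above the base plane is
    ``z(x) = fold_amplitude * sin(2*pi*x / fold_period)``, where x runs along
    volume axis 0.  U is the arc length along the mid-surface (the honest
    geodesic coordinate on this geometry), V is the straight coordinate along
    axis 1, and D is the normalized signed-normal offset across the constant
    thickness ``n_d * voxel_size``.  The ribbon is voxelized back onto a
    regular grid; voxels whose center lies within half a thickness of the
    mid-surface form the gray-matter mask.

    With ``fold_amplitude == 0`` this reduces exactly to
    :func:`make_flat_slab` on matched dimensions.
    """
    if n_u < 1 or n_v < 1 or n_d < 1:
        raise ValueError("patch dimensions must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if fold_period <= 0:
        raise ValueError("fold_period must be positive")
    thickness = n_d * voxel_size
    if fold_amplitude > 0:
        # min radius of curvature of A*sin(2*pi*x/P) is P^2 / (4*pi^2*A);
        # the inner surface self-intersects once that drops below T/2.
        r_min = fold_period**2 / (4 * np.pi**2 * fold_amplitude)
        if r_min <= thickness / 2:
            raise ValueError(
                "fold_amplitude/fold_period fold the ribbon onto itself "
                f"(min curvature radius {r_min:.3f} mm <= half thickness "
                f"{thickness / 2:.3f} mm)"
            )

    # Dense sampling of the mid-surface curve in the (x, z) plane.
    x_extent = n_u * voxel_size
    xs = np.linspace(-voxel_size, x_extent + voxel_size, max(256, 64 * n_u))
    zs = fold_amplitude * np.sin(2 * np.pi * xs / fold_period)
    dz = 2 * np.pi * fold_amplitude / fold_period * np.cos(2 * np.pi * xs / fold_period)
    seg = np.hypot(np.diff(xs), np.diff(zs))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    # Arc length measured from x=0 so that U matches the flat slab there.
    arc -= np.interp(0.0, xs, arc)
    norm = np.hypot(1.0, dz)
    tangents = np.column_stack([1.0 / norm, dz / norm])
    normals = np.column_stack([-dz / norm, 1.0 / norm])
    curve = np.column_stack([xs, zs])

    # Volume grid: axis 2 must span the folded ribbon; centers symmetric
    # about z=0 so the zero-fold ribbon occupies exactly n_d voxels.
    n_z = n_d + int(np.ceil(2 * fold_amplitude / voxel_size)) + 2
    dims = (n_u, n_v, n_z)
    i, j, k = np.meshgrid(
        np.arange(n_u), np.arange(n_v), np.arange(n_z), indexing="ij"
    )
    px = i * voxel_size
    pz = (k + 0.5 - n_z / 2) * voxel_size

    tree = cKDTree(curve)
    pts = np.column_stack([px.ravel(), pz.ravel()])
    _, nearest = tree.query(pts)
    # First-order foot-point refinement: project onto the local tangent line.
    rel = pts - curve[nearest]
    along = np.einsum("ij,ij->i", rel, tangents[nearest])
    d_signed = np.einsum("ij,ij->i", rel, normals[nearest])
    u_arc = arc[nearest] + along

    u_max = np.interp((n_u - 1) * voxel_size, xs, arc)
    inside = (
        (np.abs(d_signed) <= thickness / 2)
        & (u_arc >= -voxel_size / 2)
        & (u_arc <= u_max + voxel_size / 2)
    )

    gm = inside.reshape(dims)
    coord_u = _nan_volume(dims)
    coord_v = _nan_volume(dims)
    depth_d = _nan_volume(dims)
    thick = _nan_volume(dims)
    coord_u[gm] = u_arc.reshape(dims)[gm]
    coord_v[gm] = (j * voxel_size)[gm]
    depth_d[gm] = np.clip(
        (d_signed.reshape(dims)[gm] + thickness / 2) / thickness, 0.0, 1.0
    )
    thick[gm] = thickness
    if not gm.any():
        raise ValueError("voxelization produced an empty gray-matter mask")
    return PatchGeometry(
        voxel_size=(voxel_size,) * 3,
        gm_mask=gm,
        coord_u=coord_u,
        coord_v=coord_v,
        depth_d=depth_d,
        thickness=thick,
    )


def _hex_bin_ids(u: np.ndarray, v: np.ndarray, spacing: float) -> np.ndarray:
    """Assign each (u, v) point to its nearest triangular-lattice center.

    The Voronoi cells of a triangular lattice with nearest-neighbor distance
    ``spacing`` are regular hexagons of flat-to-flat width ``spacing``.
    Returns an (N, 2) integer array of lattice coordinates (col, row).
    """
    row_h = spacing * np.sqrt(3) / 2
    # Candidate rows/cols around each point; nearest over a 3x3 neighborhood.
    r0 = np.floor(v / row_h).astype(int)
    best_d = np.full(u.shape, np.inf)
    best = np.zeros((u.size, 2), dtype=int)
    for dr in (-1, 0, 1, 2):
        r = r0 + dr
        cy = r * row_h
        off = np.where(r % 2 == 0, 0.0, spacing / 2)
        c0 = np.floor((u - off) / spacing).astype(int)
        for dc in (-1, 0, 1, 2):
            c = c0 + dc
            cx = c * spacing + off
            d = (u - cx) ** 2 + (v - cy) ** 2
            better = d < best_d
            best_d[better] = d[better]
            best[better, 0] = c[better]
            best[better, 1] = r[better]
    return best


def hexbin_ideal_map(
    geom: PatchGeometry,
    bin_diameter: float,
    n_conditions: int,
    seed: int,
) -> PreferenceMap:
    """Ideal columnar benchmark: hexagonal full-depth bins in the UV plane.

    The UV plane is tiled by regular hexagons of the given flat-to-flat
    diameter; each bin receives one label drawn uniformly from 1..K.  Depth
    is ignored, so every bin is a geometrically perfect column spanning the
    whole cortical thickness — the upper-bound benchmark for the
    columnarity index.
    """
    if bin_diameter <= 0:
        raise ValueError("bin_diameter must be positive")
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    if not geom.gm_mask.any():
        raise ValueError("geometry has no gray-matter voxels")
    uv = geom.uv()
    # Center the lattice on the UV centroid so small patches sit inside one bin.
    center = uv.mean(axis=0)
    ids = _hex_bin_ids(uv[:, 0] - center[0], uv[:, 1] - center[1], bin_diameter)
    uniq, inverse = np.unique(ids, axis=0, return_inverse=True)
    rng = np.random.default_rng(seed)
    bin_labels = rng.integers(1, n_conditions + 1, size=len(uniq))
    labels = np.zeros(geom.dims, dtype=np.int32)
    labels[geom.gm_mask] = bin_labels[inverse]
    return PreferenceMap(labels=labels, n_conditions=n_conditions)


def random_preference_map(
    geom: PatchGeometry,
    n_conditions: int,
    seed: int,
    upsample_factor: int = 4,
) -> PreferenceMap:
    """Pure-noise benchmark: i.i.d. uniform labels on a coarse native grid.

    Labels are drawn uniformly on 1..K on a grid ``upsample_factor`` times
    coarser than the patch, then block-replicated (nearest-neighbor) back to
    the patch grid — mirroring how empirical maps acquired at native
    resolution are upsampled before the searchlight.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    dims = geom.dims
    coarse = tuple(-(-d // upsample_factor) for d in dims)
    rng = np.random.default_rng(seed)
    coarse_labels = rng.integers(1, n_conditions + 1, size=coarse).astype(np.int32)
    labels = coarse_labels
    for axis in range(3):
        labels = np.repeat(labels, upsample_factor, axis=axis)
    labels = labels[: dims[0], : dims[1], : dims[2]].copy()
    labels[~geom.gm_mask] = 0
    return PreferenceMap(labels=labels, n_conditions=n_conditions)
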