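"""NIfTI volume I/O, run manifests, and the end-to-end pipeline.

All volumes are NIfTI-1/2 via nibabel.  The affine is the sole authority
on physical units: voxel sizes are read from it, every output volume
carries the input affine unchanged, and no implicit resampling ever
happens — mismatched grids are a hard error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import columnarity as col
from . import geometry as geo
from . import metrics as met
from . import selection as sel
from . import simulate as sim

__all__ = [
    "read_volume",
    "write_volume",
    "load_geometry",
    "save_geometry",
    "load_runs",
    "RunManifest",
    "run_pipeline",
]


def read_volume(path: str | Path):
    """Load a NIfTI volume: (data, affine, voxel_size)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    # The affine is the authority on physical units (header zooms are float32).
    voxel_size = tuple(
        float(v) for v in np.sqrt((img.affine[:3, :3] ** 2).sum(axis=0))
    )
    return data, img.affine, voxel_size


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write a volume, preserving the given affine; parent dirs are created."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _check_grid(name: str, shape, ref_shape) -> None:
    if tuple(shape[:3]) != tuple(ref_shape[:3]):
        raise ValueError(
            f"{name}: grid {tuple(shape[:3])} does not match {tuple(ref_shape[:3])}; "
            "volumes are never resampled implicitly"
        )


def load_geometry(
    u_path, v_path, d_path, mask_path, thickness_path=None
) -> tuple[geo.PatchGeometry, np.ndarray]:
    """Assemble a PatchGeometry from coordinate volumes; returns (geom, affine).

    Coordinates outside the mask are set to NaN.  Without a thickness
    volume a unit placeholder is stored; nothing in the full-depth
    searchlight consumes it.
    """
    mask, affine, voxel_size = read_volume(mask_path)
    mask = mask.astype(bool)
    arrays = {}
    for name, p in (("u", u_path), ("v", v_path), ("d", d_path)):
        data, aff, _ = read_volume(p)
        _check_grid(name, data.shape, mask.shape)
        if not np.allclose(aff, affine, atol=1e-4):
            raise ValueError(f"{name}: affine differs from mask affine")
        out = np.full(mask.shape, np.nan)
        out[mask] = data[mask]
        arrays[name] = out
    if thickness_path is not None:
        thick, _, _ = read_volume(thickness_path)
        _check_grid("thickness", thick.shape, mask.shape)
        thickness = np.full(mask.shape, np.nan)
        thickness[mask] = thick[mask]
    else:
        thickness = np.full(mask.shape, np.nan)
        thickness[mask] = 1.0
    geom = geo.PatchGeometry(
        voxel_size=voxel_size,
        gm_mask=mask,
        coord_u=arrays["u"],
        coord_v=arrays["v"],
        depth_d=arrays["d"],
        thickness=thickness,
    )
    geom.validate()
    return geom, affine


def save_geometry(geom: geo.PatchGeometry, out_dir: str | Path) -> dict[str, Path]:
    """Write u/v/d/mask (+thickness) volumes; background voxels are 0."""
    out_dir = Path(out_dir)
    affine = np.diag(list(geom.voxel_size) + [1.0])
    paths = {}
    for name, data in (
        ("u", geom.coord_u),
        ("v", geom.coord_v),
        ("d", geom.depth_d),
        ("thickness", geom.thickness),
    ):
        p = out_dir / f"{name}.nii.gz"
        write_volume(p, np.nan_to_num(data, nan=0.0), affine)
        paths[name] = p
    p = out_dir / "mask.nii.gz"
    write_volume(p, geom.gm_mask, affine)
    paths["mask"] = p
    return paths


def load_runs(paths, ref_shape=None) -> list[sim.ResponseMap]:
    """Load per-run 4D response volumes; K is the 4th dimension."""
    runs = []
    for i, p in enumerate(paths):
        data, _, _ = read_volume(p)
        if data.ndim != 4:
            raise ValueError(f"{p}: expected a 4D (x, y, z, condition) volume")
        if ref_shape is not None:
            _check_grid(str(p), data.shape, ref_shape)
        runs.append(sim.ResponseMap(values=data.astype(float), run_id=i))
    shapes = {r.values.shape for r in runs}
    if len(shapes) > 1:
        raise ValueError(f"run shape mismatch: {sorted(shapes)}")
    return runs


def _sha1(path: str | Path) -> str:
    h = hashlib.sha1()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:12]


@dataclass
class RunManifest:
    """Inputs and parameters of a full pipeline run.

    Stored on disk as a flat ``key = value`` file; ``runs`` is a
    comma-separated list of paths.  Every field can be overridden by CLI
    flags (CLI wins).
    """

    u: str
    v: str
    d: str
    mask: str
    runs: list[str]
    out_prefix: str
    domain: str | None = None
    p_values: str | None = None
    t_stats: str | None = None
    dof: int | None = None
    q: float = 0.05
    min_cluster: int = 4
    connectivity: int = 26
    min_folds: int | None = None
    radius: float = 0.6
    height: float | str = col.FULL
    hexbin_diameter: float = 1.0
    upsample_factor: int = 4
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"manifest line without '=': {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        required = ["u", "v", "d", "mask", "runs", "out_prefix"]
        missing = [k for k in required if k not in kv]
        if missing:
            raise ValueError(f"manifest missing keys: {missing}")
        def num(key, cast, default):
            return cast(kv[key]) if key in kv else default
        height = kv.get("height", col.FULL)
        if height != col.FULL:
            height = float(height)
        known = {
            "u", "v", "d", "mask", "runs", "out_prefix", "domain", "p_values",
            "t_stats", "dof", "q", "min_cluster", "connectivity", "min_folds",
            "radius", "height", "hexbin_diameter", "upsample_factor", "seed",
        }
        return cls(
            u=kv["u"], v=kv["v"], d=kv["d"], mask=kv["mask"],
            runs=[s.strip() for s in kv["runs"].split(",") if s.strip()],
            out_prefix=kv["out_prefix"],
            domain=kv.get("domain"),
            p_values=kv.get("p_values"),
            t_stats=kv.get("t_stats"),
            dof=num("dof", int, None),
            q=num("q", float, 0.05),
            min_cluster=num("min_cluster", int, 4),
            connectivity=num("connectivity", int, 26),
            min_folds=num("min_folds", int, None),
            radius=num("radius", float, 0.6),
            height=height,
            hexbin_diameter=num("hexbin_diameter", float, 1.0),
            upsample_factor=num("upsample_factor", int, 4),
            seed=num("seed", int, 0),
            extras={k: v for k, v in kv.items() if k not in known},
        )


def run_pipeline(manifest: RunManifest, log=print) -> dict:
    """Execute selection -> metrics -> columnarity -> benchmarks.

    Writes all output volumes and tables under ``manifest.out_prefix`` and
    returns (and writes) a machine-readable JSON report.  Any stage
    failure raises with the stage named.
    """
    report: dict = {"parameters": {
        "q": manifest.q, "min_cluster": manifest.min_cluster,
        "connectivity": manifest.connectivity, "min_folds": manifest.min_folds,
        "radius": manifest.radius, "height": manifest.height,
        "hexbin_diameter": manifest.hexbin_diameter,
        "upsample_factor": manifest.upsample_factor, "seed": manifest.seed,
    }}
    prefix = Path(manifest.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log(f"[colkit] stage: {name}")

    try:
        stage("load")
        geom, affine = load_geometry(manifest.u, manifest.v, manifest.d, manifest.mask)
        runs = load_runs(manifest.runs, ref_shape=geom.dims)
        k = runs[0].n_conditions
        inputs = {"mask": manifest.mask, "u": manifest.u, "v": manifest.v,
                  "d": manifest.d, **{f"run{i}": p for i, p in enumerate(manifest.runs)}}
        report["inputs"] = {name: _sha1(p) for name, p in inputs.items()}
        report["n_conditions"] = k
        if manifest.domain:
            dom_data, _, _ = read_volume(manifest.domain)
            _check_grid("domain", dom_data.shape, geom.dims)
            domain = dom_data.astype(bool) & geom.gm_mask
        else:
            domain = geom.gm_mask.copy()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    try:
        stage("selection")
        if manifest.p_values or manifest.t_stats:
            if manifest.p_values:
                p, _, _ = read_volume(manifest.p_values)
            else:
                if manifest.dof is None:
                    raise ValueError("t_stats given without dof")
                t, _, _ = read_volume(manifest.t_stats)
                p = sel.p_from_t(t, manifest.dof)
            fdr = sel.fdr_select(p, manifest.q, domain)
            fdr_mask = sel.cluster_filter(
                fdr.mask, manifest.min_cluster, manifest.connectivity
            )
            report["n_fdr"] = int(fdr_mask.sum())
            seed_domain = fdr.mask  # cluster filter applies last, CV seeds raw FDR
        else:
            seed_domain = domain
            report["n_fdr"] = None
        if not seed_domain.any():
            raise ValueError("selection seeding domain is empty")
        selections = sel.select_from_runs(
            runs, seed_domain,
            min_folds=manifest.min_folds,
            min_cluster=manifest.min_cluster,
            connectivity=manifest.connectivity,
        )
        cv_mask = selections["CV"].mask
        cvp_mask = selections["CV+"].mask
        report["n_domain"] = int(domain.sum())
        report["n_cv"] = int(cv_mask.sum())
        report["n_cv_plus"] = int(cvp_mask.sum())
        write_volume(f"{prefix}_cv_mask.nii.gz", cv_mask, affine)
        write_volume(f"{prefix}_cvplus_mask.nii.gz", cvp_mask, affine)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'selection' failed: {exc}") from exc

    try:
        stage("metrics")
        avg = sim.average_runs(runs)
        pref = met.preference_map(avg, domain)
        write_volume(f"{prefix}_pref.nii.gz", pref.labels, affine)
        sens_map, spec_map, table, n_degen = met.sensitivity_specificity_maps(
            avg, domain, zero_negatives=True, pref=pref
        )
        write_volume(f"{prefix}_sensitivity.nii.gz",
                     np.nan_to_num(sens_map, nan=0.0), affine)
        write_volume(f"{prefix}_specificity.nii.gz",
                     np.nan_to_num(spec_map, nan=0.0), affine)
        table.to_csv(f"{prefix}_metrics.tsv", sep="\t", index=False)
        curves = met.tuning_curves(avg, pref, cv_mask)
        report["n_degenerate"] = n_degen
        report["selectivity_index"] = [
            None if not np.isfinite(s) else float(s)
            for s in curves.selectivity_index
        ]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {exc}") from exc

    try:
        stage("columnarity")
        cyl = col.CylinderSpec(radius=manifest.radius, height=manifest.height)
        extended = col.extend_domain(geom, cv_mask if cv_mask.any() else domain, cyl)
        pref_ext = met.preference_map(avg, extended)
        colmap = col.columnarity_map(geom, pref_ext, extended, cyl)
        write_volume(f"{prefix}_columnarity.nii.gz",
                     np.nan_to_num(colmap.index, nan=0.0), affine)
        summary = col.summarize_by_columnarity(
            colmap, np.nan_to_num(sens_map, nan=0.0),
            np.nan_to_num(spec_map, nan=0.0), extended
        )
        summary.to_csv(f"{prefix}_columnarity_summary.tsv", sep="\t", index=False)
        report["n_extended_domain"] = int(extended.sum())
        report["columnarity_median"] = float(np.median(colmap.values()))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'columnarity' failed: {exc}") from exc

    try:
        stage("benchmarks")
        rand = geo.random_preference_map(
            geom, k, seed=manifest.seed, upsample_factor=manifest.upsample_factor
        )
        ideal = geo.hexbin_ideal_map(
            geom, manifest.hexbin_diameter, k, seed=manifest.seed + 1
        )
        colmap_rand = col.columnarity_map(geom, rand, extended, cyl)
        colmap_ideal = col.columnarity_map(geom, ideal, extended, cyl)
        bench = col.benchmark_compare(colmap, colmap_rand, colmap_ideal)
        report["benchmark"] = bench
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'benchmarks' failed: {exc}") from exc

    report_path = Path(f"{prefix}_report.json")
    report_path.write_text(json.dumps(report, indent=2))
    log(f"[colkit] report written to {report_path}")
    return report
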