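"""NIfTI / manifest / archive I/O and the end-to-end pipeline runner.

All time points of a subject must already be co-registered and resampled to
one voxel grid; the tool refuses mismatched grids rather than resampling,
because silent resampling is exactly the kind of asymmetric preprocessing a
longitudinal pipeline must avoid.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import intensity as inten
from . import lesion as lesionmod
from . import metrics as metricsmod
from .cross_sectional import FitOptions, fit_cross_sectional, segment
from .longitudinal import LongHyperparams, fit_longitudinal
from .mesh import SimplexAtlas, load_atlas, make_toy_atlas

__all__ = [
    "read_volume",
    "write_volume",
    "read_manifest",
    "load_images",
    "save_model",
    "load_model",
    "RunConfig",
    "run_pipeline",
]


def read_volume(path):
    """Read a NIfTI volume; returns ``(data, affine, voxel_size)``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, img.affine, voxel_size


def write_volume(path, volume, affine=None):
    """Write a NIfTI volume, preserving integer dtypes (label maps)."""
    volume = np.asarray(volume)
    if affine is None:
        affine = np.eye(4)
    if np.issubdtype(volume.dtype, np.integer):
        volume = volume.astype(np.int32)
    img = nib.Nifti1Image(volume, affine)
    img.to_filename(str(path))


def read_manifest(path):
    """Load a longitudinal manifest (YAML).

    Expected layout::

        contrasts: [t1w, flair]
        timepoints:
          - id: tp0
            time_years: 0.0        # or time_days
            volumes: {t1w: scan0_t1w.nii.gz, flair: scan0_flair.nii.gz}

    Times given in days are converted to years via 365.25.  Relative paths
    resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    contrasts = doc.get("contrasts")
    if not contrasts:
        raise ValueError("manifest must list contrasts")
    entries = []
    for tp in doc.get("timepoints", []):
        if "time_years" in tp:
            t = float(tp["time_years"])
        elif "time_days" in tp:
            t = float(tp["time_days"]) / 365.25
        else:
            raise ValueError(f"timepoint {tp.get('id')} lacks a time")
        vols = {}
        for c in contrasts:
            if c not in tp.get("volumes", {}):
                raise ValueError(
                    f"timepoint {tp.get('id')} lacks contrast {c!r}")
            p = Path(tp["volumes"][c])
            vols[c] = p if p.is_absolute() else path.parent / p
        entries.append(dict(id=tp.get("id"), time_years=t, volumes=vols))
    if not entries:
        raise ValueError("manifest lists no timepoints")
    entries.sort(key=lambda e: e["time_years"])
    return contrasts, entries


def load_images(contrasts, entries, log_floor=None):
    """Read each time point's contrasts into an :class:`ImageData` list.

    Raw intensities are log-transformed; the analysis mask is the set of
    voxels that are strictly positive in every contrast at every time point
    (so all time points share one mask).
    """
    raws, shapes, voxel_size = [], set(), None
    for e in entries:
        vols = []
        for c in contrasts:
            data, affine, vs = read_volume(e["volumes"][c])
            vols.append(np.asarray(data, dtype=float))
            shapes.add(data.shape)
            voxel_size = voxel_size or vs
        raws.append(np.stack(vols, axis=-1))
    if len(shapes) != 1:
        raise ValueError(
            f"time points are on different grids: {sorted(shapes)}; "
            "co-register and resample them first")
    mask = np.all(np.stack(raws) > 0, axis=(0, -1))
    images = []
    for e, raw in zip(entries, raws):
        data = inten.log_transform(raw, mask, floor=log_floor)
        data.voxel_size = voxel_size
        data.timepoint_time = e["time_years"]
        images.append(data)
    return images


def save_model(path, model: inten.IntensityModel, basis_order):
    np.savez_compressed(
        path, means=model.means, covariances=model.covariances,
        bias_coeffs=model.bias_coeffs, basis_order=np.asarray(basis_order),
        class_names=np.array(model.class_names or []))


def load_model(path):
    with np.load(path, allow_pickle=False) as z:
        model = inten.IntensityModel(
            means=z["means"], covariances=z["covariances"],
            bias_coeffs=z["bias_coeffs"],
            class_names=[str(c) for c in z["class_names"]] or None)
        return model, tuple(int(o) for o in z["basis_order"])


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    manifest: str
    output_dir: str
    atlas: str = None  # atlas archive path; None -> toy atlas on the grid
    k_classes: int = 4
    stiffness: float = 0.1
    seed: int = 0
    hyper_k0: float = None  # None -> auto (20 K)
    hyper_p0_scale: float = None  # None -> auto (0.5 N_k)
    n_global: int = 5
    n_em: int = 2
    max_outer: int = 30
    tol: float = 1e-5
    bias_order: int = 2
    lesion: bool = False
    lesion_contrast: int = -1
    lesion_mixing: float = 0.05
    compute_metrics: bool = True

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self):
        return dataclasses.asdict(self)


def _resolve_atlas(config: RunConfig, grid_shape) -> SimplexAtlas:
    if config.atlas:
        atlas = load_atlas(config.atlas)
        if atlas.grid_shape != tuple(grid_shape):
            raise ValueError(
                f"atlas grid {atlas.grid_shape} does not match image grid "
                f"{tuple(grid_shape)}")
        return atlas
    return make_toy_atlas(grid_shape, config.k_classes,
                          stiffness=config.stiffness)


def run_pipeline(config: RunConfig) -> dict:
    """Template construction, longitudinal fit, per-time-point segmentation
    and volumetry; returns (and writes) a JSON-serializable run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config": config.to_dict(), "stages": {}}
    t_start = _time.time()

    contrasts, entries = read_manifest(config.manifest)
    images = load_images(contrasts, entries)
    atlas = _resolve_atlas(config, images[0].grid_shape)
    times = [im.timepoint_time for im in images]
    report["stages"]["load"] = {
        "n_timepoints": len(images), "contrasts": contrasts,
        "grid_shape": list(images[0].grid_shape), "times_years": times}
    if len(images) == 1:
        report["mode"] = "cross-sectional (single time point)"
    else:
        report["mode"] = "longitudinal"

    opts = FitOptions(n_em=config.n_em, max_outer=config.max_outer,
                      tol=config.tol,
                      bias_order=(config.bias_order,) * len(atlas.grid_shape))
    hyper = "auto"
    if config.hyper_k0 is not None or config.hyper_p0_scale is not None:
        from .longitudinal import build_template, derive_hyperparameters
        template = build_template(images)
        tf = fit_cross_sectional(template, atlas, opts)
        labels = segment(template, atlas, tf.mesh, tf.intensity, tf.basis)
        auto = derive_hyperparameters(labels, atlas)
        k0 = config.hyper_k0 if config.hyper_k0 is not None else auto.K0
        p0 = auto.P0 if config.hyper_p0_scale is None else \
            auto.P0 * (config.hyper_p0_scale / 0.5)
        hyper = LongHyperparams(K0=k0, P0=p0)

    t0 = _time.time()
    lesion_masks = None
    if config.lesion:
        lesion_opts = lesionmod.LesionOptions(
            contrast=config.lesion_contrast, mixing=config.lesion_mixing)
        result, lesion_masks, _ = lesionmod.fit_with_lesion(
            images, atlas, hyper=hyper, lesion_opts=lesion_opts, opts=opts)
    else:
        result = fit_longitudinal(images, atlas, hyper=hyper, opts=opts,
                                  n_global=config.n_global,
                                  n_em_per_sweep=config.n_em)
    report["stages"]["fit"] = {
        "seconds": _time.time() - t0,
        "objective_trace": [float(v) for v in result.objective_trace],
        "K0": float(result.hyper.K0),
        "P0": [float(p) for p in result.hyper.P0]}

    # outputs
    for t, lm in enumerate(result.label_maps):
        write_volume(out / f"labels_tp{t}.nii.gz", lm.labels)
    with open(out / "class_names.json", "w") as fh:
        json.dump(result.label_maps[0].class_names, fh)
    vols = result.volumes.copy()
    vols.columns = [e["id"] or f"tp{t}" for t, e in enumerate(entries)]
    vols.to_csv(out / "volumes.csv")
    np.savez_compressed(out / "latents.npz", x0=result.latents.x0,
                        proto_means=result.latents.proto_means,
                        proto_covs=result.latents.proto_covs)
    if lesion_masks is not None:
        for t, m in enumerate(lesion_masks):
            write_volume(out / f"lesion_tp{t}.nii.gz",
                         m.astype(np.int32))

    if config.compute_metrics and len(images) >= 2:
        rows = []
        for name in vols.index:
            v = vols.loc[name].to_numpy()
            row = {"structure": name,
                   "aspc_first_last": metricsmod.aspc(v[0], v[-1]),
                   "spc_first_last": metricsmod.spc(v[0], v[-1])}
            if len(images) >= 2 and v[0] > 0:
                row["apc"] = metricsmod.apc(
                    metricsmod.VolumeSeries(name, v, np.asarray(times)))
            rows.append(row)
        mdf = pd.DataFrame(rows).set_index("structure")
        mdf.to_csv(out / "metrics.csv")
        report["stages"]["metrics"] = {"structures": list(mdf.index)}
        if lesion_masks is not None:
            rates = metricsmod.lesion_change_rates(
                lesion_masks, times, images[0].voxel_size)
            report["stages"]["metrics"]["lesion_rates"] = dataclasses.asdict(
                rates)

    report["volumes_ml"] = {
        name: [float(v) for v in vols.loc[name]] for name in vols.index}
    report["elapsed_seconds"] = _time.time() - t_start
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
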