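"""File I/O: complex k-space containers (HDF5), magnitude NIfTI, JSON reports.

The k-space container is a small documented HDF5 layout:

* dataset ``kspace`` — complex (Nx, Ny, Nt)
* root attrs ``readout_axis`` (int) and ``center_index`` (two ints)
* optional dataset ``frame_labels`` (floats or strings)

Datasets are written with ``track_times=False`` so identical content
yields byte-identical files.  Magnitude images go to uncompressed
NIfTI-1 for the same reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .kspace import DespikeDiagnostics, KSpaceSeries, reconstruct_images

__all__ = [
    "KSpaceFormatError",
    "read_kspace",
    "write_kspace",
    "report_from_diagnostics",
    "write_outputs",
]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class KSpaceFormatError(ValueError):
    """Raised when a k-space container violates the documented layout."""


def write_kspace(path, series: KSpaceSeries) -> None:
    """Write a series to the documented HDF5 layout (deterministic bytes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=series.data.astype(np.complex128),
                         track_times=False)
        f.attrs["readout_axis"] = int(series.readout_axis)
        f.attrs["center_index"] = np.asarray(series.center_index, dtype=np.int64)
        if series.frame_labels is not None:
            labels = np.asarray(series.frame_labels)
            if labels.dtype.kind in "iuf":
                f.create_dataset("frame_labels", data=labels.astype(float),
                                 track_times=False)
            else:
                f.create_dataset(
                    "frame_labels",
                    data=labels.astype(h5py.string_dtype()),
                    track_times=False,
                )


def read_kspace(path) -> KSpaceSeries:
    """Read a k-space series, applying documented defaults for missing
    metadata (center = grid center, readout axis = 0, each logged)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise KSpaceFormatError(f"{path}: missing dataset 'kspace'")
        dset = f["kspace"]
        if dset.dtype.kind != "c":
            raise KSpaceFormatError(
                f"{path}: dataset 'kspace' is not complex — the despiking "
                "algorithm requires complex raw k-space, not magnitude images"
            )
        data = dset[()]
        if data.ndim == 2:
            data = data[:, :, None]
        if data.ndim != 3:
            raise KSpaceFormatError(
                f"{path}: dataset 'kspace' must be (Nx, Ny, Nt), got shape "
                f"{data.shape}")

        if "readout_axis" in f.attrs:
            readout_axis = int(f.attrs["readout_axis"])
        else:
            readout_axis = 0
            log.warning("%s: no 'readout_axis' attribute; defaulting to 0", path)
        if "center_index" in f.attrs:
            ci = tuple(int(v) for v in np.asarray(f.attrs["center_index"]))
            if len(ci) != 2:
                raise KSpaceFormatError(
                    f"{path}: attribute 'center_index' must hold two integers")
        else:
            ci = (data.shape[0] // 2, data.shape[1] // 2)
            log.warning("%s: no 'center_index' attribute; defaulting to grid "
                        "center %s", path, ci)

        labels = None
        if "frame_labels" in f:
            raw = f["frame_labels"][()]
            if len(raw) != data.shape[2]:
                raise KSpaceFormatError(
                    f"{path}: 'frame_labels' length {len(raw)} != Nt "
                    f"{data.shape[2]}")
            labels = tuple(
                v.decode() if isinstance(v, bytes) else float(v) for v in raw)

    try:
        return KSpaceSeries(data, readout_axis, ci, labels)
    except ValueError as exc:
        raise KSpaceFormatError(f"{path}: {exc}") from exc


def report_from_diagnostics(diag: DespikeDiagnostics) -> dict:
    """JSON-serializable run report (frozen schema, version 1)."""
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "kappa": diag.kappa,
        "lambda_eff": diag.lambda_eff,
        "mode": diag.mode,
        "converged": bool(diag.converged),
        "n_iter": [r.n_iter for r in diag.rpca],
        "final_residual": [r.final_residual for r in diag.rpca],
        "rank_L": diag.rank_L,
        "refilled_pixels": (
            None if diag.refill_reports is None
            else [r.n_refilled_pixels for r in diag.refill_reports]
        ),
    }


def _save_nifti(path, volume: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4))
    nib.save(img, str(path))


def write_outputs(
    clean: KSpaceSeries,
    spikes: KSpaceSeries,
    images_before: np.ndarray,
    images_after: np.ndarray,
    report: dict,
    outdir,
) -> dict[str, Path]:
    """Write the full despiking output set to ``outdir``.

    Emits the despiked and sparse-component k-space containers, the
    before/after/difference magnitude NIfTI volumes, and the JSON run
    report.  Returns the mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "despiked_kspace": outdir / "despiked_kspace.h5",
        "sparse_component": outdir / "sparse_component.h5",
        "before": outdir / "before.nii",
        "after": outdir / "after.nii",
        "difference": outdir / "difference.nii",
        "report": outdir / "report.json",
    }
    write_kspace(paths["despiked_kspace"], clean)
    write_kspace(paths["sparse_component"], spikes)
    _save_nifti(paths["before"], images_before)
    _save_nifti(paths["after"], images_after)
    _save_nifti(paths["difference"], images_before - images_after)
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
    return paths
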