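"""File-format adapters: FSL gradient tables, NIfTI volumes, sidecars.

b-values on disk follow the FSL convention (s/mm^2, one whitespace-
separated row); internally everything is ms/um^2 (1000 s/mm^2 == 1.0).
Volumes are NIfTI-1 via nibabel.  Every pipeline output can carry a JSON
sidecar recording the config, seed and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .forward_model import AcquisitionScheme, ValidationError
from .estimator import FractionMaps

__all__ = [
    "read_gradient_table",
    "write_gradient_table",
    "load_volume",
    "save_volume",
    "save_fraction_maps",
    "load_fraction_maps",
    "write_sidecar",
]

_BVAL_SCALE = 1000.0  # s/mm^2 per ms/um^2


def _read_rows(path) -> list[np.ndarray]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append(np.array([float(tok) for tok in line.split()]))
        except ValueError as exc:
            raise ValidationError(f"non-numeric token in {path}: {exc}") from None
    return rows


def read_gradient_table(bval_path, bvec_path, shell_tolerance: float = 0.1) -> AcquisitionScheme:
    """Read an FSL bval/bvec pair into an :class:`AcquisitionScheme`.

    bvals are converted s/mm^2 -> ms/um^2.  Direction vectors within 1e-3
    of unit norm are renormalized; anything further off is rejected.
    """
    bval_rows = _read_rows(bval_path)
    if len(bval_rows) != 1:
        raise ValidationError(f"{bval_path} must contain exactly one row of b-values")
    bvals = bval_rows[0] / _BVAL_SCALE
    bvec_rows = _read_rows(bvec_path)
    if len(bvec_rows) != 3:
        raise ValidationError(f"{bvec_path} must contain exactly 3 rows (x, y, z)")
    lengths = {len(r) for r in bvec_rows}
    if len(lengths) != 1:
        raise ValidationError(f"bvec rows have unequal lengths {sorted(lengths)}")
    n_vec = lengths.pop()
    if n_vec != len(bvals):
        raise ValidationError(
            f"bval has {len(bvals)} entries but bvec has {n_vec} columns"
        )
    g = np.vstack(bvec_rows).T
    norms = np.linalg.norm(g, axis=1)
    dw = bvals > 0
    bad = dw & (np.abs(norms - 1.0) > 1e-3)
    if bad.any():
        raise ValidationError(
            f"direction {int(np.flatnonzero(bad)[0])} has norm "
            f"{norms[bad][0]:.4f}, too far from unit to renormalize"
        )
    fix = dw & (norms > 0)
    g[fix] /= norms[fix, None]
    return AcquisitionScheme(bvals, g, shell_tolerance=shell_tolerance)


def write_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path):
    """Write a scheme as an FSL bval/bvec pair (s/mm^2)."""
    bvals = scheme.bvalues * _BVAL_SCALE
    Path(bval_path).write_text(" ".join(f"{b:.6g}" for b in bvals) + "\n")
    lines = [
        " ".join(f"{v:.9f}" for v in scheme.directions[:, ax])
        for ax in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def load_volume(path):
    """Load a NIfTI-1 volume; returns (data, affine, voxel_size)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception:
        magic = path.read_bytes()[:4] if path.exists() else b""
        raise ValidationError(
            f"{path} is not a readable NIfTI file (magic bytes {magic!r})"
        ) from None
    data = np.asarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, voxel_size


def save_volume(data, path, affine=None, voxel_size=None, dtype=None):
    """Save an array as NIfTI-1; masks should pass ``dtype=np.uint8``."""
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    aff = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(data, aff)
    if voxel_size is not None:
        img.header.set_zooms(tuple(voxel_size) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return Path(path)


def save_fraction_maps(maps: FractionMaps, prefix):
    """Serialize fraction maps as three NIfTI volumes (suffix _vintra /
    _vextra / _vcsf)."""
    prefix = Path(prefix)
    out = {}
    for suffix, arr in (
        ("vintra", maps.v_intra),
        ("vextra", maps.v_extra),
        ("vcsf", maps.v_csf),
    ):
        p = prefix.parent / f"{prefix.name}_{suffix}.nii.gz"
        save_volume(arr, p, affine=maps.affine, voxel_size=maps.voxel_size)
        out[suffix] = p
    return out


def load_fraction_maps(prefix) -> FractionMaps:
    prefix = Path(prefix)
    arrays = {}
    affine = voxel_size = None
    for suffix in ("vintra", "vextra", "vcsf"):
        data, affine, voxel_size = load_volume(
            prefix.parent / f"{prefix.name}_{suffix}.nii.gz"
        )
        arrays[suffix] = np.asarray(data, dtype=float)
    return FractionMaps(
        v_intra=arrays["vintra"],
        v_extra=arrays["vextra"],
        v_csf=arrays["vcsf"],
        voxel_size=voxel_size,
        affine=affine,
    )


def write_sidecar(path, config: dict, seed: int):
    """JSON provenance sidecar: config, its hash, seed, package version."""
    payload = json.dumps(config, sort_keys=True, default=str)
    sidecar = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }
    Path(path).write_text(json.dumps(sidecar, indent=2, default=str) + "\n")
    return Path(path)
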