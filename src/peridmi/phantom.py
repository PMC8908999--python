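"""Volumetric synthetic "patients" for the perilesional-edema analysis.

A phantom is a concentric spherical geometry on a desk-scale grid: a
contrast-enhancing tumor core, a surrounding perilesional T2-hyperintense
rim, the remaining brain as normal-appearing white matter (NAWM), and
background.  Each zone carries its own distribution of compartment
fractions; the rim differs between "GBM" mode (edema plus tumor
infiltration: moderate free water) and "metastasis" mode (predominantly
vasogenic edema: high free water).  Multi-shell DWI is rendered per voxel
from the stick-zeppelin-ball model with Rician noise, alongside the
ground-truth fraction maps and the masks the ROI pipeline consumes.

The absolute zone fractions are declared synthetic stand-ins: the
clinical reference reports only NAWM-normalized ratios, so the defaults
are chosen to reproduce the *direction* of those ratio contrasts, not
measured absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward_model import (
    CANONICAL_DIFFUSIVITIES,
    AcquisitionScheme,
    ValidationError,
)
from .estimator import FractionMaps

__all__ = [
    "PhantomConfig",
    "ZONE_LABELS",
    "DEFAULT_ZONE_FRACTIONS",
    "make_labels",
    "render_dwi",
    "export_masks",
]

#: Label conventions for the phantom volume.
ZONE_LABELS = {"background": 0, "nawm": 1, "perilesional": 2, "core": 3}

#: Mean (v_i, v_e, v_f) per zone and mode — synthetic stand-ins chosen so
#: NAWM-normalized ratios have the clinically reported directions
#: (metastasis rim: more free water, fewer cellular compartments than GBM rim).
DEFAULT_ZONE_FRACTIONS = {
    "nawm": (0.45, 0.45, 0.10),
    "perilesional_gbm": (0.25, 0.40, 0.35),
    "perilesional_metastasis": (0.15, 0.30, 0.55),
    "core": (0.10, 0.50, 0.40),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, zone microstructure, noise and seed of one phantom.

    ``mode`` selects the perilesional-rim fraction means ("GBM" or
    "metastasis").  ``snr`` is the b=0 signal-to-noise ratio (sigma =
    s0/snr); ``snr=inf`` renders noise-free.  ``jitter_concentration`` is
    the symmetric scale of the per-voxel Dirichlet jitter around the zone
    means (larger = tighter).
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    core_radius: float = 8.0  # mm
    rim_thickness: float = 10.0  # mm
    brain_radius: float | None = None  # mm; default 0.45 * min grid extent
    mode: str = "GBM"
    zone_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_FRACTIONS))
    jitter_concentration: float = 100.0
    snr: float = 30.0
    s0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("GBM", "metastasis"):
            raise ValidationError(f"mode must be 'GBM' or 'metastasis', got {self.mode!r}")
        if self.rim_thickness <= 0:
            raise ValidationError("rim_thickness must be positive")
        if self.core_radius < 0:
            raise ValidationError("core_radius must be non-negative")
        for zone, fr in self.zone_fractions.items():
            fr = np.asarray(fr, float)
            if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
                raise ValidationError(f"zone {zone!r} fractions must lie on the simplex")
        gbm_vf = self.zone_fractions["perilesional_gbm"][2]
        met_vf = self.zone_fractions["perilesional_metastasis"][2]
        if not met_vf > gbm_vf:
            raise ValidationError(
                "configured contrast requires metastasis perilesional v_f "
                f"> GBM's ({met_vf} <= {gbm_vf})"
            )
        if self.snr <= 0:
            raise ValidationError("snr must be positive (use inf for noise-free)")

    @property
    def effective_brain_radius(self) -> float:
        if self.brain_radius is not None:
            return self.brain_radius
        extent = min(n * v for n, v in zip(self.grid_shape, self.voxel_size))
        return 0.45 * extent

    @property
    def rim_fraction_means(self) -> tuple:
        key = "perilesional_gbm" if self.mode == "GBM" else "perilesional_metastasis"
        return self.zone_fractions[key]


def make_labels(config: PhantomConfig) -> np.ndarray:
    """Concentric label volume: 0=background, 1=NAWM, 2=rim, 3=core."""
    brain_r = config.effective_brain_radius
    if config.core_radius + config.rim_thickness >= brain_r:
        raise ValidationError(
            f"core_radius + rim_thickness ({config.core_radius + config.rim_thickness}"
            f" mm) must fit inside the brain radius ({brain_r:.1f} mm)"
        )
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(config.grid_shape, config.voxel_size)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    labels = np.zeros(config.grid_shape, dtype=np.uint8)
    labels[r <= brain_r] = ZONE_LABELS["nawm"]
    labels[r <= config.core_radius + config.rim_thickness] = ZONE_LABELS["perilesional"]
    if config.core_radius > 0:
        labels[r <= config.core_radius] = ZONE_LABELS["core"]
    return labels


def _zone_mean_fractions(config: PhantomConfig, zone: int):
    if zone == ZONE_LABELS["nawm"]:
        return config.zone_fractions["nawm"]
    if zone == ZONE_LABELS["perilesional"]:
        return config.rim_fraction_means
    if zone == ZONE_LABELS["core"]:
        return config.zone_fractions["core"]
    raise ValidationError(f"no microstructure defined for zone {zone}")


def render_dwi(labels: np.ndarray, config: PhantomConfig, scheme: AcquisitionScheme):
    """Render the multi-shell DWI volume and its ground-truth fraction maps.

    Per brain voxel, fractions are drawn from a Dirichlet jitter around the
    zone mean, the orientation uniformly on the sphere, diffusivities at
    the canonical values; the signal follows the three-compartment model
    with Rician noise at ``config.snr``.  Deterministic given
    ``config.seed``.  Returns ``(dwi, truth)`` with ``dwi`` of shape
    ``grid_shape + (n_volumes,)`` and ``truth`` a :class:`FractionMaps`.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    dwi = np.zeros(labels.shape + (scheme.n_volumes,))
    truth = np.zeros(labels.shape + (3,))
    b = scheme.bvalues[None, :]
    D = CANONICAL_DIFFUSIVITIES
    for zone in (ZONE_LABELS["nawm"], ZONE_LABELS["perilesional"], ZONE_LABELS["core"]):
        sel = labels == zone
        n = int(sel.sum())
        if n == 0:
            continue
        mean = np.asarray(_zone_mean_fractions(config, zone), float)
        fr = rng.dirichlet(config.jitter_concentration * 3 * mean, size=n)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cos2 = (u @ scheme.directions.T) ** 2
        intra = np.exp(-b * D["D_i"] * cos2)
        extra = np.exp(-b * (D["D_e_perp"] + (D["D_e_par"] - D["D_e_perp"]) * cos2))
        free = np.exp(-b * D["D_f"]) * np.ones_like(intra)
        sig = config.s0 * (
            fr[:, 0:1] * intra + fr[:, 1:2] * extra + fr[:, 2:3] * free
        )
        if np.isfinite(config.snr):
            sigma = config.s0 / config.snr
            e1 = rng.normal(0.0, sigma, sig.shape)
            e2 = rng.normal(0.0, sigma, sig.shape)
            sig = np.sqrt((sig + e1) ** 2 + e2**2)
        dwi[sel] = sig
        truth[sel] = fr
    gt = FractionMaps(
        v_intra=truth[..., 0],
        v_extra=truth[..., 1],
        v_csf=truth[..., 2],
        voxel_size=tuple(config.voxel_size),
    )
    return dwi, gt


def export_masks(labels: np.ndarray):
    """Binary masks for the ROI pipeline.

    Returns ``(roi_mask, wm_mask, core_mask)``: the perilesional rim, the
    white matter (NAWM plus rim), and the enhancing core.  The ROI and
    core masks are disjoint by construction.
    """
    labels = np.asarray(labels)
    roi = (labels == ZONE_LABELS["perilesional"]).astype(np.uint8)
    wm = np.isin(labels, (ZONE_LABELS["nawm"], ZONE_LABELS["perilesional"])).astype(np.uint8)
    core = (labels == ZONE_LABELS["core"]).astype(np.uint8)
    if roi.sum() == 0:
        warnings.warn("perilesional zone is empty; ROI mask has no voxels", stacklevel=2)
    return roi, wm, core
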