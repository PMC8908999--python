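"""Bayesian volume-fraction estimation by simulated regression.

The per-voxel compartment fractions (v_i, v_e, v_f) are estimated with a
posterior-mean surrogate: draw microstructure parameters from a prior,
simulate noisy signals under the acquisition scheme, reduce each signal to
rotation-invariant features (per-shell powder averages normalized by the
b=0 mean), and fit a polynomial least-squares regression from features to
the generating fractions.  On new data the regression evaluates (an
approximation of) the posterior mean of the fractions given the features,
marginalized over the diffusivity and noise priors.  Outputs are clipped
to [0, 1] and renormalized so they always satisfy the simplex constraint.

An independent exhaustive grid search over the fraction simplex at fixed
canonical diffusivities (`grid_oracle_fit`) serves as verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .forward_model import (
    CANONICAL_DIFFUSIVITIES,
    FREE_WATER_DIFFUSIVITY,
    AcquisitionScheme,
    MicrostructureParams,
    ValidationError,
    add_rician_noise,
    spherical_mean,
    voxel_signal,
)

__all__ = [
    "PriorSpec",
    "FractionMaps",
    "PolynomialFractionEstimator",
    "sample_prior",
    "features",
    "train_estimator",
    "fit_volume",
    "grid_oracle_fit",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior over microstructure parameters for estimator training.

    Fractions are uniform on the 2-simplex; diffusivities uniform on the
    stated intervals (um^2/ms); D_e_perp = ratio * D_e_par with the ratio
    uniform on ``perp_ratio_range``; the training-noise SNR (defined at
    b=0) uniform on ``snr_range``.  D_f is fixed at 3.0 um^2/ms.
    """

    D_i_range: tuple = (1.5, 2.5)
    D_e_par_range: tuple = (1.0, 2.0)
    perp_ratio_range: tuple = (0.2, 0.6)
    snr_range: tuple = (20.0, 50.0)
    n_samples: int = 20000
    seed: int = 0

    def __post_init__(self):
        for name in ("D_i_range", "D_e_par_range", "perp_ratio_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi <= 3.5):
                raise ValidationError(
                    f"{name} must satisfy 0 < lo <= hi <= 3.5, got ({lo}, {hi})"
                )
        lo, hi = self.snr_range
        if not (0 < lo <= hi):
            raise ValidationError(f"snr_range must be positive, got ({lo}, {hi})")
        if self.n_samples < 1000:
            raise ValidationError("n_samples must be at least 1000")


@dataclass
class FractionMaps:
    """Volumetric V-intra / V-extra / V-CSF maps with spatial metadata.

    Inside the brain mask the three maps sum to 1 voxelwise; outside they
    are zero.
    """

    v_intra: np.ndarray
    v_extra: np.ndarray
    v_csf: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        shapes = {self.v_intra.shape, self.v_extra.shape, self.v_csf.shape}
        if len(shapes) != 1:
            raise ValidationError(f"map shapes differ: {shapes}")
        for name in ("v_intra", "v_extra", "v_csf"):
            m = getattr(self, name)
            if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
                raise ValidationError(f"{name} has values outside [0, 1]")

    @property
    def shape(self):
        return self.v_intra.shape

    def stacked(self) -> np.ndarray:
        """(..., 3) array of (v_intra, v_extra, v_csf)."""
        return np.stack([self.v_intra, self.v_extra, self.v_csf], axis=-1)


def sample_prior(prior: PriorSpec) -> dict:
    """Draw ``n_samples`` parameter sets from the prior.

    Returns a dict of arrays: fractions (n, 3) uniform on the simplex,
    D_i, D_e_par, D_e_perp, snr (n,), orientations (n, 3) uniform on the
    sphere.  Deterministic given ``prior.seed``.
    """
    rng = np.random.default_rng(prior.seed)
    n = prior.n_samples
    fractions = rng.dirichlet(np.ones(3), size=n)
    D_i = rng.uniform(*prior.D_i_range, n)
    D_e_par = rng.uniform(*prior.D_e_par_range, n)
    D_e_perp = D_e_par * rng.uniform(*prior.perp_ratio_range, n)
    snr = rng.uniform(*prior.snr_range, n)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return {
        "fractions": fractions,
        "D_i": D_i,
        "D_e_par": D_e_par,
        "D_e_perp": D_e_perp,
        "D_f": np.full(n, FREE_WATER_DIFFUSIVITY),
        "snr": snr,
        "orientations": u,
    }


def features(signal, scheme: AcquisitionScheme) -> np.ndarray:
    """Rotation-invariant features: per-shell powder means over the b=0 mean.

    ``signal`` may be a single vector (n_volumes,) or a stack
    (n_voxels, n_volumes).  Returns one feature per nonzero shell,
    ascending in b.  Invariant to permutations of same-shell volumes and
    to overall signal scale.
    """
    signal = np.asarray(signal, dtype=float)
    single = signal.ndim == 1
    sig = signal[None, :] if single else signal
    if sig.shape[-1] != scheme.n_volumes:
        raise ValidationError(
            f"signal has {sig.shape[-1]} volumes, scheme expects {scheme.n_volumes}"
        )
    b0 = scheme.b0_mask
    if not b0.any():
        raise ValidationError("scheme has no b=0 volume to normalize by")
    s0 = sig[:, b0].mean(axis=1)
    feats = np.stack(
        [sig[:, m].mean(axis=1) / s0 for m in scheme.shell_masks()], axis=-1
    )
    return feats[0] if single else feats


def _poly_design(feats: np.ndarray, degree: int) -> np.ndarray:
    """Full polynomial expansion (with interactions) up to ``degree``."""
    feats = np.atleast_2d(feats)
    cols = [np.ones(feats.shape[0])]
    k = feats.shape[1]
    for d in range(1, degree + 1):
        for idx in combinations_with_replacement(range(k), d):
            cols.append(np.prod(feats[:, idx], axis=1))
    return np.column_stack(cols)


@dataclass
class PolynomialFractionEstimator:
    """Least-squares polynomial map from shell features to fractions."""

    coef: np.ndarray  # (n_terms, 3)
    degree: int
    n_shells: int
    shells: np.ndarray

    def check_scheme(self, scheme: AcquisitionScheme):
        if len(scheme.shells) != self.n_shells or not np.allclose(
            scheme.shells, self.shells, atol=scheme.shell_tolerance
        ):
            raise ValidationError(
                f"estimator was trained on shells {self.shells}, "
                f"scheme has {scheme.shells}"
            )

    def predict(self, feats: np.ndarray) -> np.ndarray:
        """Map features to simplex-valued fractions (n, 3) or (3,)."""
        single = np.asarray(feats).ndim == 1
        X = _poly_design(feats, self.degree)
        raw = X @ self.coef
        clipped = np.clip(raw, 0.0, 1.0)
        tot = clipped.sum(axis=1, keepdims=True)
        # an all-zero clip is only possible for unphysical inputs;
        # fall back to the uninformative center of the simplex
        out = np.where(tot > 0, clipped / np.maximum(tot, 1e-300), 1.0 / 3.0)
        return out[0] if single else out


def _simulate_prior_signals(prior: PriorSpec, scheme: AcquisitionScheme):
    """Noise-free prior signals (n, n_volumes) plus the prior draws."""
    draws = sample_prior(prior)
    b = scheme.bvalues[None, :]
    cos2 = (draws["orientations"] @ scheme.directions.T) ** 2
    intra = np.exp(-b * draws["D_i"][:, None] * cos2)
    delta = (draws["D_e_par"] - draws["D_e_perp"])[:, None]
    extra = np.exp(-b * (draws["D_e_perp"][:, None] + delta * cos2))
    free = np.exp(-b * draws["D_f"][:, None])
    fr = draws["fractions"]
    sig = fr[:, 0:1] * intra + fr[:, 1:2] * extra + fr[:, 2:3] * free
    return sig, draws


def train_estimator(
    prior: PriorSpec, scheme: AcquisitionScheme, degree: int = 3
) -> PolynomialFractionEstimator:
    """Train the posterior-mean regression estimator.

    Simulates ``prior.n_samples`` voxels (signals with Rician noise at an
    SNR drawn from the prior), computes shell features, and solves one
    least-squares problem mapping degree-``degree`` polynomial feature
    expansions to the generating fractions.  Deterministic given the
    prior seed.
    """
    signals, draws = _simulate_prior_signals(prior, scheme)
    rng = np.random.default_rng(prior.seed + 1)
    sigma = 1.0 / draws["snr"]  # s0 == 1 in training
    e1 = rng.normal(size=signals.shape) * sigma[:, None]
    e2 = rng.normal(size=signals.shape) * sigma[:, None]
    noisy = np.sqrt((signals + e1) ** 2 + e2**2)
    feats = features(noisy, scheme)
    X = _poly_design(feats, degree)
    coef, _, rank, _ = np.linalg.lstsq(X, draws["fractions"], rcond=None)
    if rank < X.shape[1]:
        raise ValidationError(
            f"rank-deficient polynomial design (rank {rank} < {X.shape[1]}); "
            "increase n_samples or lower the degree"
        )
    return PolynomialFractionEstimator(
        coef=coef, degree=degree, n_shells=len(scheme.shells), shells=scheme.shells
    )


def fit_volume(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    estimator: PolynomialFractionEstimator,
    voxel_size=(2.0, 2.0, 2.0),
    affine=None,
) -> FractionMaps:
    """Estimate fraction maps for every voxel inside ``mask``.

    ``dwi`` is 4-D (x, y, z, volume); ``mask`` 3-D binary.  Voxels outside
    the mask are zero in all three maps.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if dwi.ndim != 4:
        raise ValidationError(f"dwi must be 4-D, got {dwi.ndim}-D")
    if dwi.shape[:3] != mask.shape:
        raise ValidationError(
            f"dwi spatial shape {dwi.shape[:3]} != mask shape {mask.shape}"
        )
    if dwi.shape[3] != scheme.n_volumes:
        raise ValidationError(
            f"dwi has {dwi.shape[3]} volumes, scheme expects {scheme.n_volumes}"
        )
    estimator.check_scheme(scheme)
    maps = np.zeros(mask.shape + (3,))
    if mask.any():
        feats = features(dwi[mask], scheme)
        maps[mask] = estimator.predict(feats)
    return FractionMaps(
        v_intra=maps[..., 0],
        v_extra=maps[..., 1],
        v_csf=maps[..., 2],
        voxel_size=tuple(voxel_size),
        affine=np.eye(4) if affine is None else affine,
    )


def _simplex_grid(step: float) -> np.ndarray:
    k = int(round(1.0 / step))
    pts = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            pts.append((i * step, j * step, 1.0 - i * step - j * step))
    return np.asarray(pts)


def grid_oracle_fit(signal, scheme: AcquisitionScheme, step: float = 0.02):
    """Exhaustive-search fraction estimate at canonical diffusivities.

    Minimizes the sum of squared differences between the observed shell
    features and the fraction-weighted spherical-mean attenuations over a
    simplex grid of resolution ``step``.  Independent of the regression
    estimator; intended for noise-free or low-noise verification.
    """
    obs = features(signal, scheme)
    params = MicrostructureParams(v_i=1 / 3, v_e=1 / 3, v_f=1 / 3,
                                  **CANONICAL_DIFFUSIVITIES)
    comp = np.array([spherical_mean(params, b) for b in scheme.shells])  # (S, 3)
    grid = _simplex_grid(step)  # (G, 3)
    pred = grid @ comp.T  # (G, S)
    sse = np.sum((pred - obs[None, :]) ** 2, axis=1)
    return tuple(grid[int(np.argmin(sse))])
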