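"""Three-compartment white-matter diffusion signal model.

The voxel signal is a volume-fraction-weighted sum of three canonical
compartments:

* **stick** — intra-axonal water, one-dimensional diffusion along the axon
  direction ``u`` with diffusivity ``D_i``;
* **zeppelin** — extra-axonal cellular water, an axially symmetric tensor
  with parallel/perpendicular diffusivities ``D_e_par >= D_e_perp``;
* **ball** — free water / CSF, isotropic with diffusivity ``D_f``
  (fixed by convention at 3.0 um^2/ms, body-temperature free water).

All b-values are in ms/um^2 (1.0 ms/um^2 == 1000 s/mm^2), diffusivities in
um^2/ms, so b*D is dimensionless.  Closed-form orientation averages
(spherical means / powder averages) are provided for every compartment;
they are the rotation-invariant features the estimator works with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "AcquisitionScheme",
    "MicrostructureParams",
    "FREE_WATER_DIFFUSIVITY",
    "CANONICAL_DIFFUSIVITIES",
    "compartment_signal",
    "voxel_signal",
    "spherical_mean",
    "add_rician_noise",
    "default_scheme",
    "repulsion_directions",
]

#: Free-water diffusivity at body temperature, um^2/ms.
FREE_WATER_DIFFUSIVITY = 3.0

#: Reference diffusivities used by the grid-search oracle and the phantom.
CANONICAL_DIFFUSIVITIES = {
    "D_i": 2.0,
    "D_e_par": 1.5,
    "D_e_perp": 0.5,
    "D_f": FREE_WATER_DIFFUSIVITY,
}


class ValidationError(ValueError):
    """Raised when a physical precondition on model inputs is violated."""


def _as_unit(v, name: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise ValidationError(f"{name} must have unit norm, got |{name}| = {n:.6g}")
    return v


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: per-volume b-values and gradient directions.

    Parameters
    ----------
    bvalues
        b-value per acquired volume, ms/um^2.
    directions
        Unit gradient direction per volume, shape (n_volumes, 3).  The
        direction of b=0 volumes is ignored.
    shell_tolerance
        b-values closer than this are treated as one shell (ms/um^2).
    """

    bvalues: np.ndarray
    directions: np.ndarray
    shell_tolerance: float = 0.1

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValidationError(f"directions must have shape (n, 3), got {g.shape}")
        if len(b) != len(g):
            raise ValidationError(
                f"bvalues ({len(b)}) and directions ({len(g)}) count mismatch"
            )
        if np.any(b < 0):
            raise ValidationError("negative b-values are not physical")
        dw = b > 0
        if dw.any():
            norms = np.linalg.norm(g[dw], axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                bad = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
                raise ValidationError(
                    f"diffusion-weighted direction {bad} is not unit norm"
                )
        if not (b == 0).any():
            raise ValidationError("scheme must contain at least one b=0 volume")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)
        if len(self.shells) < 2:
            raise ValidationError(
                "at least 2 distinct nonzero shells are required to identify "
                f"a three-compartment model (found {len(self.shells)})"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def shells(self) -> np.ndarray:
        """Mean b-value of each nonzero shell, ascending."""
        nz = np.sort(self.bvalues[self.bvalues > 0])
        if nz.size == 0:
            return np.array([])
        groups = [[nz[0]]]
        for v in nz[1:]:
            if v - groups[-1][0] <= self.shell_tolerance:
                groups[-1].append(v)
            else:
                groups.append([v])
        return np.array([float(np.mean(gr)) for gr in groups])

    def shell_masks(self) -> list[np.ndarray]:
        """Boolean volume masks, one per nonzero shell (ascending b)."""
        return [
            np.abs(self.bvalues - s) <= self.shell_tolerance
            for s in self.shells
        ]


@dataclass(frozen=True)
class MicrostructureParams:
    """Single-voxel parameters of the stick-zeppelin-ball model.

    Volume fractions ``v_i`` (intra-axonal), ``v_e`` (extra-axonal) and
    ``v_f`` (free water) live on the unit simplex.  Diffusivities in
    um^2/ms; ``orientation`` is the axon direction; ``s0`` the
    non-diffusion-weighted amplitude.
    """

    v_i: float
    v_e: float
    v_f: float
    D_i: float = CANONICAL_DIFFUSIVITIES["D_i"]
    D_e_par: float = CANONICAL_DIFFUSIVITIES["D_e_par"]
    D_e_perp: float = CANONICAL_DIFFUSIVITIES["D_e_perp"]
    D_f: float = FREE_WATER_DIFFUSIVITY
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    s0: float = 1.0

    def __post_init__(self):
        fr = np.array([self.v_i, self.v_e, self.v_f], dtype=float)
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValidationError(f"volume fractions must lie in [0, 1], got {fr}")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"volume fractions must sum to 1, got {fr.sum():.12g}"
            )
        if not (0 <= self.D_e_perp <= self.D_e_par):
            raise ValidationError(
                f"need 0 <= D_e_perp <= D_e_par, got {self.D_e_perp}, {self.D_e_par}"
            )
        if self.D_i <= 0 or self.D_f <= 0:
            raise ValidationError("D_i and D_f must be positive")
        if self.s0 <= 0:
            raise ValidationError("s0 must be positive")
        object.__setattr__(self, "orientation", _as_unit(self.orientation, "orientation"))

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.v_i, self.v_e, self.v_f])


def compartment_signal(params: MicrostructureParams, b, g):
    """Per-compartment attenuations ``(intra, extra, free)`` at (b, g).

    ``b`` may be a scalar or array; ``g`` a 3-vector or an (n, 3) array of
    unit directions.  Returns attenuations in (0, 1]:

    * stick:    exp(-b * D_i * (g.u)^2)
    * zeppelin: exp(-b * (D_e_perp + (D_e_par - D_e_perp) * (g.u)^2))
    * ball:     exp(-b * D_f)
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b-value must be non-negative")
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    g2 = g[None, :] if single else g
    if g2.shape[-1] != 3:
        raise ValidationError(f"gradient direction must be a 3-vector, got {g.shape}")
    norms = np.linalg.norm(g2, axis=-1)
    dw = np.broadcast_to(b, norms.shape) > 0
    if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
        raise ValidationError("gradient direction must have unit norm where b > 0")
    cos2 = (g2 @ params.orientation) ** 2
    if single:
        cos2 = cos2[0]
    intra = np.exp(-b * params.D_i * cos2)
    extra = np.exp(-b * (params.D_e_perp + (params.D_e_par - params.D_e_perp) * cos2))
    free = np.exp(-b * params.D_f) * np.ones_like(intra)
    return intra, extra, free


def voxel_signal(params: MicrostructureParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signal S(b, g) = s0 * (v_i*E_i + v_e*E_e + v_f*E_f)."""
    intra, extra, free = compartment_signal(params, scheme.bvalues, scheme.directions)
    return params.s0 * (params.v_i * intra + params.v_e * extra + params.v_f * free)


def _stick_mean(bD) -> np.ndarray:
    """Orientation average of exp(-bD cos^2 theta) over the uniform sphere.

    Equals sqrt(pi/(4 bD)) * erf(sqrt(bD)); series expansion below bD=1e-6.
    """
    bD = np.asarray(bD, dtype=float)
    out = np.empty_like(bD)
    small = bD < 1e-6
    out[small] = 1.0 - bD[small] / 3.0
    x = bD[~small]
    out[~small] = np.sqrt(np.pi / (4.0 * x)) * erf(np.sqrt(x))
    return out


def spherical_mean(params: MicrostructureParams, b):
    """Per-compartment spherical-mean (powder-average) attenuations at b > 0.

    stick:    sqrt(pi/(4 b D_i)) erf(sqrt(b D_i))
    zeppelin: exp(-b D_e_perp) * stick-mean of (D_e_par - D_e_perp)
    ball:     exp(-b D_f)

    The zeppelin form degenerates continuously to exp(-b D_e_par) as the
    anisotropy D_e_par - D_e_perp vanishes.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValidationError("spherical mean requires b > 0")
    stick = _stick_mean(b * params.D_i)
    delta = params.D_e_par - params.D_e_perp
    extra = np.exp(-b * params.D_e_perp) * _stick_mean(b * delta)
    free = np.exp(-b * params.D_f) * np.ones_like(stick)
    if b.ndim == 0:
        return float(stick), float(extra), float(free)
    return stick, extra, free


def add_rician_noise(signal, sigma: float, seed) -> np.ndarray:
    """Corrupt a magnitude-MR signal with Rician noise.

    Each value S becomes sqrt((S + e1)^2 + e2^2) with e1, e2 independent
    N(0, sigma).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise ValidationError("noise scale sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def repulsion_directions(n: int, seed: int = 42, n_iter: int = 300) -> np.ndarray:
    """Approximately uniform unit directions by electrostatic repulsion.

    Points repel their neighbours and the antipodes of their neighbours
    (gradient directions are sign-invariant), by projected gradient descent
    from a seeded random start.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            d = x[:, None, :] - sign * x[None, :, :]
            r2 = np.sum(d * d, axis=-1)
            np.fill_diagonal(r2, np.inf)
            r2 = np.maximum(r2, 1e-12)
            force += np.sum(d / r2[..., None] ** 1.5, axis=1)
        # project onto the tangent plane, step, renormalize
        force -= x * np.sum(force * x, axis=1, keepdims=True)
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def default_scheme(
    n_per_shell: int = 30,
    shell_bvalues=(1.0, 2.0),
    n_b0: int = 1,
    seed: int = 42,
) -> AcquisitionScheme:
    """Default synthetic protocol: n_b0 b=0 volumes plus two 30-direction
    shells at b = 1.0 and 2.0 ms/um^2 with repulsion-optimized directions."""
    bvals = [0.0] * n_b0
    dirs = [np.array([0.0, 0.0, 0.0])] * n_b0
    for i, b in enumerate(shell_bvalues):
        pts = repulsion_directions(n_per_shell, seed=seed + i)
        bvals.extend([float(b)] * n_per_shell)
        dirs.extend(pts)
    return AcquisitionScheme(np.array(bvals), np.array(dirs))
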