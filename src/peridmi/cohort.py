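"""Patient-level synthetic cohorts for the group-statistics layer.

Each simulated patient carries age, sex, a steroid flag, the perilesional
T2-lesion volume (ml) and the three NAWM-normalized microstructure ratios
(V-intra, V-extra, V-CSF).  Marginals are log-normal for the positive
quantities, parameterized so the *population* median and IQR equal the
configured targets (median = exp(mu); the IQR pins sigma through the
25/75-quantile spread), and normal for age.  Cross-variable dependence is
imposed through a Gaussian copula whose latent correlations are
moment-matched: given a target Pearson correlation on the observed scale,
the latent correlation is solved in closed form from the bivariate
(log-)normal moment identities, so large-sample observed correlations hit
the targets rather than a copula-distorted version of them.

Default targets are the published group summaries of the
GBM-versus-metastasis perilesional cohort (n = 19 / 17).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .forward_model import ValidationError

__all__ = [
    "GroupTargets",
    "CohortConfig",
    "PatientRecord",
    "COHORT_COLUMNS",
    "lognormal_from_median_iqr",
    "simulate_cohort",
    "default_config",
]

#: Fixed column order of the cohort table (CSV exchange schema).
COHORT_COLUMNS = [
    "id",
    "group",
    "age",
    "sex",
    "steroid",
    "t2_volume_ml",
    "v_intra_norm",
    "v_extra_norm",
    "v_csf_norm",
]

_METRICS = ["v_intra_norm", "v_extra_norm", "v_csf_norm"]
_Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: demographics, lesion volume and normalized metrics."""

    id: str
    group: str
    age: float
    sex: str
    steroid: bool
    t2_volume_ml: float
    v_intra_norm: float
    v_extra_norm: float
    v_csf_norm: float


@dataclass(frozen=True)
class GroupTargets:
    """Population targets for one diagnostic group.

    ``(median, iqr)`` pairs for the lesion volume and the three normalized
    metrics; Pearson correlation targets on the observed scale for
    (V-CSF, T2 volume) and (age, V-CSF); a steroid fraction and a female
    count for bookkeeping.
    """

    n: int
    age_mean: float
    age_sd: float
    t2_volume: tuple  # (median ml, IQR ml)
    v_intra: tuple
    v_extra: tuple
    v_csf: tuple
    r_vcsf_volume: float
    r_age_vcsf: float
    steroid_fraction: float
    n_female: int

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("group size must be at least 2")
        for name in ("t2_volume", "v_intra", "v_extra", "v_csf"):
            med, iqr = getattr(self, name)
            if med <= 0 or iqr <= 0:
                raise ValidationError(f"{name} median and IQR must be positive")
        for name in ("r_vcsf_volume", "r_age_vcsf"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValidationError(f"{name} must lie in (-1, 1), got {r}")


@dataclass(frozen=True)
class CohortConfig:
    gbm: GroupTargets
    metastasis: GroupTargets
    seed: int = 0


def lognormal_from_median_iqr(median: float, iqr: float):
    """(mu, sigma) of the log-normal with the given median and IQR.

    median = exp(mu); IQR = 2 * median * sinh(z75 * sigma) with z75 the
    0.75 standard-normal quantile, hence sigma = asinh(IQR/(2 median))/z75.
    """
    mu = np.log(median)
    sigma = np.arcsinh(iqr / (2.0 * median)) / _Z75
    return float(mu), float(sigma)


def _latent_rho_lnln(r: float, s1: float, s2: float) -> float:
    """Latent Gaussian correlation giving Pearson ``r`` between two
    log-normals with log-scale sigmas s1, s2 (exact bivariate moments)."""
    spread = np.sqrt(np.expm1(s1**2) * np.expm1(s2**2))
    arg = 1.0 + r * spread
    if arg <= 0:
        raise ValidationError(f"target correlation {r} infeasible for log-normal pair")
    rho = np.log(arg) / (s1 * s2)
    if not -1 < rho < 1:
        raise ValidationError(
            f"target correlation {r} maps to latent rho {rho:.3f} outside (-1, 1)"
        )
    return float(rho)


def _latent_rho_nln(r: float, s: float) -> float:
    """Latent correlation for a normal variable against a log-normal with
    log-scale sigma s (corr(X, e^{sZ}) = rho * s / sqrt(e^{s^2} - 1))."""
    rho = r * np.sqrt(np.expm1(s**2)) / s
    if not -1 < rho < 1:
        raise ValidationError(
            f"target correlation {r} maps to latent rho {rho:.3f} outside (-1, 1)"
        )
    return float(rho)


def _group_correlation_matrix(t: GroupTargets) -> np.ndarray:
    """Latent 5x5 correlation over (age, volume, v_intra, v_extra, v_csf)."""
    _, s_vol = lognormal_from_median_iqr(*t.t2_volume)
    _, s_csf = lognormal_from_median_iqr(*t.v_csf)
    R = np.eye(5)
    R[1, 4] = R[4, 1] = _latent_rho_lnln(t.r_vcsf_volume, s_vol, s_csf)
    R[0, 4] = R[4, 0] = _latent_rho_nln(t.r_age_vcsf, s_csf)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "latent correlation matrix is not positive definite; the "
            "(v_csf, t2_volume) and (age, v_csf) targets "
            f"({t.r_vcsf_volume}, {t.r_age_vcsf}) are jointly infeasible"
        ) from None
    return R


def _simulate_group(
    t: GroupTargets, group: str, rng: np.random.Generator, n: int | None
) -> pd.DataFrame:
    n = t.n if n is None else n
    R = _group_correlation_matrix(t)
    z = rng.multivariate_normal(np.zeros(5), R, size=n, method="cholesky")
    age = t.age_mean + t.age_sd * z[:, 0]
    cols = {"age": age}
    for j, (name, tgt) in enumerate(
        [("t2_volume_ml", t.t2_volume), ("v_intra_norm", t.v_intra),
         ("v_extra_norm", t.v_extra), ("v_csf_norm", t.v_csf)], start=1
    ):
        mu, sigma = lognormal_from_median_iqr(*tgt)
        cols[name] = np.exp(mu + sigma * z[:, j])
    n_steroid = int(round(t.steroid_fraction * n))
    steroid = np.zeros(n, dtype=bool)
    steroid[rng.choice(n, size=n_steroid, replace=False)] = True
    n_female = t.n_female if n == t.n else int(round(t.n_female / t.n * n))
    sex = np.array(["M"] * n)
    sex[rng.choice(n, size=min(n_female, n), replace=False)] = "F"
    frame = pd.DataFrame(cols)
    frame["group"] = group
    frame["sex"] = sex
    frame["steroid"] = steroid
    return frame


def simulate_cohort(config: CohortConfig, n_per_group: int | None = None) -> pd.DataFrame:
    """Simulate one cohort table (one row per patient).

    ``n_per_group`` overrides both group sizes (used for large-sample
    fidelity checks); by default the configured sizes are used.
    Deterministic given ``config.seed``.  Columns follow
    :data:`COHORT_COLUMNS`.
    """
    rng = np.random.default_rng(config.seed)
    frames = [
        _simulate_group(config.gbm, "GBM", rng, n_per_group),
        _simulate_group(config.metastasis, "metastasis", rng, n_per_group),
    ]
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"P{i:05d}" for i in range(len(out))])
    return out[COHORT_COLUMNS]


def records(frame: pd.DataFrame) -> list[PatientRecord]:
    """View a cohort table as a list of typed patient records."""
    return [PatientRecord(**row) for row in frame.to_dict("records")]


def default_config(seed: int = 0) -> CohortConfig:
    """Published group summaries of the perilesional cohort (n = 19 / 17).

    Medians (IQR) of the NAWM-normalized metrics and T2 volumes, age
    mean/SD, and the reported (V-CSF, T2-volume) and (age, V-CSF)
    Pearson correlations, per group.
    """
    gbm = GroupTargets(
        n=19,
        age_mean=66.4,
        age_sd=14.1,
        t2_volume=(20.7, 22.1),
        v_intra=(0.25, 0.13),
        v_extra=(0.88, 0.30),
        v_csf=(3.17, 1.26),
        r_vcsf_volume=0.33,
        r_age_vcsf=-0.67,
        steroid_fraction=7 / 19,
        n_female=9,
    )
    met = GroupTargets(
        n=17,
        age_mean=63.5,
        age_sd=11.8,
        t2_volume=(19.5, 35.1),
        v_intra=(0.20, 0.03),
        v_extra=(0.81, 0.18),
        v_csf=(4.52, 0.86),
        r_vcsf_volume=0.51,
        r_age_vcsf=-0.62,
        steroid_fraction=6 / 17,
        n_female=8,
    )
    return CohortConfig(gbm=gbm, metastasis=met, seed=seed)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
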