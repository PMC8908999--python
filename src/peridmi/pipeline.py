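"""End-to-end drivers chaining phantom -> fit -> ROI -> statistics.

Two arms share the seed:

* the **imaging arm** renders synthetic GBM- and metastasis-mode
  phantoms, estimates fraction maps, and reduces them to NAWM-normalized
  ROI metrics — demonstrating the voxel-level chain on known ground truth;
* the **cohort arm** simulates a patient table at the published group
  summaries and runs the ANCOVA / ROC / correlation battery.

All randomness descends from one top-level seed, split deterministically
per module, so a full run is reproducible from a single integer.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import default_config, simulate_cohort
from .estimator import PriorSpec, fit_volume, train_estimator
from .forward_model import default_scheme
from .phantom import PhantomConfig, export_masks, make_labels, render_dwi
from .roi import build_nawm_mask, patient_metrics
from .stats import analyze_cohort

__all__ = ["split_seed", "phantom_patient_metrics", "imaging_run", "full_run"]


def split_seed(seed: int, stream: str) -> int:
    """Deterministic per-module child seed below 2**31."""
    digest = hashlib.sha256(stream.encode()).digest()
    ss = np.random.SeedSequence([int(seed), int.from_bytes(digest[:4], "big")])
    return int(ss.generate_state(1)[0] % (2**31))


def phantom_patient_metrics(config: PhantomConfig, scheme, estimator):
    """Render one phantom, fit it, and reduce to normalized ROI metrics.

    Returns ``(metrics_row, truth_row)``: dicts with the estimated and the
    ground-truth normalized metrics plus the ROI volume.
    """
    labels = make_labels(config)
    dwi, truth = render_dwi(labels, config, scheme)
    roi_mask, wm_mask, core_mask = export_masks(labels)
    brain = wm_mask.astype(bool) | core_mask.astype(bool)
    maps = fit_volume(dwi, scheme, brain, estimator, voxel_size=config.voxel_size)
    nawm = build_nawm_mask(wm_mask, roi_mask, core_mask)
    est = patient_metrics(maps, roi_mask, nawm)
    gt = patient_metrics(truth, roi_mask, nawm)

    def row(m):
        return {
            "mode": config.mode,
            "snr": config.snr,
            "seed": config.seed,
            "t2_volume_ml": m.roi_volume_ml,
            "v_intra_norm": m.normalized["v_intra"],
            "v_extra_norm": m.normalized["v_extra"],
            "v_csf_norm": m.normalized["v_csf"],
        }

    return row(est), row(gt)


def imaging_run(seed: int = 0, snr: float = 30.0, n_per_mode: int = 1,
                grid_shape=(32, 32, 32)) -> pd.DataFrame:
    """Phantom pair(s) through the full voxel-level chain.

    Returns one row per phantom and source ("estimated" ground-truth
    "truth"), with the normalized ROI metrics.
    """
    scheme = default_scheme()
    estimator = train_estimator(PriorSpec(seed=split_seed(seed, "prior")), scheme)
    rows = []
    for mode in ("GBM", "metastasis"):
        for i in range(n_per_mode):
            cfg = PhantomConfig(
                mode=mode,
                snr=snr,
                grid_shape=tuple(grid_shape),
                seed=split_seed(seed, f"phantom-{mode}-{i}"),
            )
            est, gt = phantom_patient_metrics(cfg, scheme, estimator)
            rows.append({**est, "source": "estimated"})
            rows.append({**gt, "source": "truth"})
    return pd.DataFrame(rows)


def full_run(outdir, seed: int = 0, snr: float = 30.0, n_per_mode: int = 1) -> dict:
    """Run both arms and write all tables under ``outdir``.

    Writes ``imaging_metrics.csv`` (phantom chain), ``cohort.csv``
    (simulated patient table at the published summaries) and
    ``group_results.csv`` (ANCOVA / ROC battery).  Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    imaging = imaging_run(seed=seed, snr=snr, n_per_mode=n_per_mode)
    imaging_path = outdir / "imaging_metrics.csv"
    imaging.to_csv(imaging_path, index=False)

    config = default_config(seed=split_seed(seed, "cohort"))
    cohort = simulate_cohort(config)
    cohort_path = outdir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    results = analyze_cohort(cohort)
    results_path = outdir / "group_results.csv"
    results.to_csv(results_path, index=False)

    from .io import write_sidecar

    sidecar = write_sidecar(
        outdir / "run_sidecar.json",
        {
            "seed": seed,
            "snr": snr,
            "n_per_mode": n_per_mode,
            "cohort_config": {
                "gbm": asdict(config.gbm),
                "metastasis": asdict(config.metastasis),
            },
        },
        seed,
    )
    return {
        "imaging_metrics": imaging_path,
        "cohort": cohort_path,
        "group_results": results_path,
        "sidecar": sidecar,
    }
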