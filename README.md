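# peridmi

Diffusion-microstructure analysis of perilesional T2 hyperintensities,
rebuilt end to end on synthetic data.

Glioblastoma (GBM) and solitary brain metastasis often look alike on
conventional MRI, but the T2-hyperintense zone around the enhancing tumor
differs biologically: around metastases it is predominantly vasogenic
edema (excess free water), around GBM it also contains infiltrating
tumor. Multi-shell diffusion MRI can quantify this via a three-compartment
white-matter model,

S(b,g) = S₀·[ v_i·e^{−b D_i (g·u)²} + v_e·e^{−b(D_e⊥+(D_e∥−D_e⊥)(g·u)²)} + v_f·e^{−b D_f} ],

whose volume fractions — V-intra (intra-axonal, stick), V-extra
(extra-axonal cellular, zeppelin) and V-CSF (free water, ball) — are
estimated per voxel, averaged over the perilesional ROI, normalized to
each patient's normal-appearing white matter (NAWM), and compared between
groups with an ANCOVA (controlling for lesion volume), Pearson
correlations, and ROC analysis with an equally-weighted
sensitivity/specificity cutpoint.

The package is for methods developers and students who want the full
chain — signal simulation, Bayesian fraction estimation, ROI
normalization, group statistics — as tested, reproducible code without
access to patient data. Everything runs on synthetic phantoms and
simulated cohorts whose group summaries match the published ones;
see `docs/methods.md` for the model, priors and declared stand-ins.

## Worked example

```python
from peridmi.pipeline import full_run

paths = full_run("out", seed=0, snr=30.0)
```

or, equivalently, `peridmi full-run --out out --seed 0`. This renders a
GBM-mode and a metastasis-mode phantom (32³ voxels, SNR 30), estimates
fraction maps, reduces them to NAWM-normalized ROI metrics
(`out/imaging_metrics.csv`):

```
      mode    source  t2_volume_ml  v_intra_norm  v_extra_norm  v_csf_norm
       GBM estimated        22.656         0.669         0.851       2.716
metastasis estimated        22.656         0.439         0.614       4.416
```

— the metastasis phantom's normalized V-CSF (4.42) exceeds the GBM
phantom's (2.72): the configured free-water excess of perimetastatic
edema survives estimation and normalization. It then simulates a
19 GBM / 17 metastasis cohort at the published group summaries and runs
the statistical battery (`out/group_results.csv`):

```
      metric      F  p_raw  p_bonferroni   auc  cutpoint direction  sens  spec
v_intra_norm 13.271  0.001         0.003 0.789     0.273        >= 0.579 1.000
v_extra_norm  0.077  0.783         1.000 0.588     0.809        >= 0.684 0.588
  v_csf_norm 26.678  0.000         0.000 0.876     3.811        <= 0.789 0.941
```

Read: the ANCOVA (lesion volume as covariate) flags V-CSF and V-intra as
group-different after Bonferroni correction; normalized V-CSF is the best
GBM-vs-metastasis discriminator (AUC 0.876 on this draw, "V-CSF ≤ 3.81
predicts GBM"), V-extra the worst — the ordering reported for the real
cohort.

The numbered scripts under `analysis/` run the same two arms stepwise
(01 phantoms → 02 fit → 03 ROI metrics; 04 cohort → 05 statistics) and
write their tables under `results/`; volumes go to `scratch/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at the given seed — phantom
pair through fraction estimation and ROI normalization, simulated cohort
through the statistical battery — and writes the JSON report.

## Layout

```
src/peridmi/        forward_model, estimator, phantom, cohort, roi,
                    stats, pipeline, io, cli
analysis/           numbered narrative drivers
tests/              pytest suite incl. property-based acceptance checks
docs/methods.md     model, priors, design choices, limitations
```
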