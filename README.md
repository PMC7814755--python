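# paintract

White-matter tract analysis for pain research, on synthetic diffusion MRI:
global tractography by simulated annealing, ROI-combination bundle selection,
fiber-density mapping with group aggregation and threshold masks,
three-compartment microstructure estimation, and covariate-adjusted
nonparametric statistics relating tract integrity to self-reported pain.

The scientific question the pipeline addresses: do the white-matter tracts of
a pain-signaling network carry a microstructural correlate of recent pain
experience? The proxy for functional fiber integrity is the intra-axonal
signal fraction v_intra of the stick-zeppelin-ball "standard model"

    A(b, g) = v_intra e^{-b d_a (g·n)^2}
            + v_extra e^{-b [d_⊥ + (d_∥ - d_⊥)(g·n)^2]}
            + v_csf  e^{-b d_csf},

estimated per voxel from rotation-invariant spherical-mean (powder-average)
signals by a supervised posterior-mean regressor, averaged within tract-core
masks, and tested against a 0-10 pain score by rank regression with age and
sex as covariates, Freedman-Lane permutation inference, and Bonferroni /
Benjamini-Hochberg FDR < 5% control.

Everything runs on synthetic data with known ground truth: a voxel phantom
with tubular bundles (including a 90° crossing and a negative-control ROI
pair) and a calibrated 100-subject cohort (age 29 ± 3.7, 64 F / 36 M, pain
1.63 on the NTPIS 0-10 scale) in which designated tracts carry a configurable
pain→v_intra coupling and control tracts carry none. The package is used from
Python (see `examples/`); a thin `paintract` CLI wraps the pipeline stages
(`simulate`, `track`, `select`, `density`, `mask`, `microstructure`, `stats`,
`run-all`).

## Worked example

`python examples/full_pipeline.py` runs the whole study at a reduced
annealing schedule (about half a minute on one CPU) and prints:

```
tractogram: 245 streamlines
kept tracts: ['AP', 'CS', 'DP', 'PN'] (dropped: ['NC'])
FACT visualization tract: 482 streamlines

tract  coefficient  p_perm  p_param  sig_bonferroni  sig_fdr  n_subjects
   AP     0.432709   0.001 0.000008            True     True         100
   CS     0.361275   0.001 0.000265            True     True         100
   DP     0.425482   0.001 0.000013            True     True         100
   PN    -0.121749   0.219 0.230713           False    False         100

FDR log10 threshold: -3.000
significant under FDR<5%: ['AP', 'CS', 'DP']
significant under Bonferroni: ['AP', 'CS', 'DP']
```

Reading the output: global tractography recovered 245 streamlines from the
phantom DWI; every true bundle (AP, DP, CS, PN) yielded a connected ROI
combination and survived the 40% group-occurrence retention rule, while the
negative-control pair NC — two ROIs joined by no bundle — was dropped. The
`coefficient` column is the standardized rank-regression slope of tract
v_intra on pain (age and sex adjusted); `p_perm` is its Freedman-Lane
permutation p-value (B = 999 here). The three pain-coupled tracts are flagged
by both corrections; the uncoupled control tract PN is not. The FDR decision
boundary is reported as log10 of the largest BH-rejected p-value.

Each capability also has a focused example: `forward_model.py`,
`phantom_and_cohort.py`, `global_tracking_demo.py`, `density_maps_demo.py`,
`fact_tracking_demo.py`, `microstructure_demo.py`, `pain_statistics_demo.py`.

## Documentation

`docs/methods.md` describes the models, the energy functional and annealing
schedule of the global tracker, the estimator's prior and features, the
statistical procedures, all defaults with units, and the limitations of the
synthetic data.
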