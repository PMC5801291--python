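# ppmcompare

Classical versus Bayesian second-level inference for fMRI group analysis,
in one tested pipeline.

Group ("second-level") fMRI analysis asks, per voxel, whether a contrast
of interest is nonzero across subjects.  The classical route runs a
one-sample t-test at every voxel and controls the familywise error rate
with random field theory (RFT) — either a voxelwise height threshold
`P(max T > t*) ≤ α`, or cluster-extent inference above a cluster-forming
threshold.  The Bayesian route places a global shrinkage prior
`β_v ~ N(0, c_B)` on the per-voxel effect, forms the conjugate Gaussian
posterior, and declares a voxel active when the log posterior odds that
the effect exceeds an effect-size threshold γ beat a cut τ:

    ln [ P(β_v > γ | D) / P(β_v ≤ γ | D) ] > τ,      γ = d · √c_B

Under equal prior odds the left side is the log Bayes factor ("logBF":
3 ≈ strong, 5 ≈ very strong evidence), and √c_B plays the role of a
Cohen's d of 1.0, so d picks the effect size in conventional units
(0.2 / 0.5 / 0.8).  The package implements both routes, a synthetic-data
generator that stands in for first-level outputs, and the evaluation
protocols used to compare the methods: survived-voxel counts,
noise-injection false-alarm/hit rates, and incremental sample-size
sweeps.  It is aimed at methodologists studying thresholding behavior and
at practitioners who want a transparent, scriptable re-implementation of
the joint effect-size + logBF thresholding rule.

## Worked example

Create `config.yaml`:

```yaml
input:
  synthetic:
    grid_shape: [40, 48, 34]
    voxel_size_mm: 2.0
    n_subjects: 16
    sigma_between: 1.0
    smooth_fwhm_voxels: 3.0
    blobs:
      - {center: [18, 44, 18], radius: 8.0, d_true: 1.2}
    mask_shape: ellipsoid
    seed: 7
methods:
  - {kind: clusterwise}          # CDT p < 0.001, cluster FWE p < 0.05
  - {kind: voxelwise_fwe}        # voxel FWE p < 0.05
  - {kind: bayes, d: 0.5, tau: 5}
output_dir: out
```

then run:

```sh
ppmcompare compare --config config.yaml
```

which prints the survived-voxel report

```
          clusterwise  voxelwise_fwe  bayes_d0.5_tau5
contrast
dataset          1311            117             1034
```

and writes `out/report.csv`, a binary activation mask and cluster table
per method, the t and posterior maps, and `out/run_log.jsonl` with every
estimated quantity: here the residual-field smoothness came out at FWHM
≈ (3.02, 3.02, 3.03) voxels (the generator used 3.0), the voxelwise FWE
threshold at t* = 7.23 (df = 15, ~34k-voxel ellipsoid mask), and the
shrinkage prior at c_B = 0.066, so the medium-effect threshold resolved
to γ = 0.5·√c_B = 0.128 in contrast units.  The counts show the
qualitative pattern this comparison is about: cluster-extent inference is
the most liberal, voxelwise FWE by far the most conservative, and the
Bayesian rule at d = 0.5, τ = 5 sits between them.

The evaluation protocols run the same way:

```sh
ppmcompare evaluate-noise --config config.yaml   # 10 x 25%-noise replicates
ppmcompare evaluate-sweep --config config.yaml   # n = 2..N, 10 subject orders
```

producing tidy `noise_eval.csv` (replicate, method, false_alarm, hit,
seed) and `sweep.csv` / `orders.csv` tables.  Real data work too: point
`input.nifti_dir` at a directory of per-subject contrast NIfTIs plus a
mask, e.g. first-level maps downloaded from a public repository.

Everything is also available as a library — see `ppmcompare.classical`
(GLM, smoothness/resels, expected Euler characteristic, FWE thresholds),
`ppmcompare.bayesian` (shrinkage prior, posterior, log-odds
thresholding), `ppmcompare.synthetic` and `ppmcompare.evaluation`.

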