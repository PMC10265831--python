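# glymkin

Quantitative analysis of solute clearance from the brain, built around
dynamic contrast-enhanced (DCE) MRI time-signal curves (TSCs):

- **`glymkin.io_core`** — NIfTI label/dynamic volumes, TSC tables (TSV),
  baseline normalization and region-wise TSC extraction.
- **`glymkin.synth`** — synthetic cohorts and voxelized shell phantoms with
  planted kinetic ground truth (gamma-variate inputs, RK4 integration of the
  exchange ODE, per-condition presets, seeded noise).
- **`glymkin.tsc`** — TSC parameterization: arrival time (three successive
  rises), time-to-maximum, maximum, trapezoidal AUC over 0–6 h, and a
  mono-exponential decay fit restricted to ≥ 90 min after the maximum with
  the corresponding discard rules.
- **`glymkin.geometry`** — splitting a labeled region into a closed outer
  envelope of uniform voxel thickness (6-connected erosion) and an inner
  core, with summed compartment curves.
- **`glymkin.kinetics`** — the two-compartment exchange model: an exact
  piecewise-linear convolution forward model, profiled least-squares
  estimation of the exchange rates (k1, k2), curve volumes, exchanged
  volumes, the net exchange ratio (NER = k2·V_in / (k1·V_out)), the shell
  thickness search and a volume-based QC gate.
- **`glymkin.calcium`** — calcium-trace band power: zero-phase lowpass
  (20 Hz passband / 40 Hz stopband) with resampling to 60 Hz, 2-min
  segments every 12 min (30 per 6 h), periodogram band sums for
  0.1–1 / 1–4 / 1–20 Hz and per-animal averaging.
- **`glymkin.adc`** — mono-exponential ADC fitting over multi-b diffusion
  series, a single-shell pseudo-ADC flow surrogate and ROI percent-change.
- **`glymkin.stats`** — the group-comparison decision tree: Lilliefors
  normality gate, ANOVA/Kruskal–Wallis omnibus, t-test/Mann–Whitney
  post-hocs, boxplot summaries (median/mean, quartile box, 5–95 whiskers).
- **`glymkin.pipeline`** / **`glymkin.cli`** — end-to-end orchestration
  from a YAML config with provenance manifests and a `glymkin` CLI.

## CLI

```sh
glymkin simulate --out sim/ --seed 1 --condition MED --n-animals 8
glymkin tsc params --in sim/curves.tsv --out params.tsv
glymkin exchange fit --curves pair.tsv --out fit.json
glymkin exchange search --dyn dce.nii.gz --labels atlas.nii.gz \
    --region 1 --smin 1 --smax 17 --out search.json
glymkin calcium bands --in trace.csv --rate 2000 --out bands.tsv
glymkin adc fit --in series.tsv --out adc.tsv
glymkin stats compare --in fits.tsv --param ner --group condition --out cmp.json
glymkin run --config run.yaml --out results/ --seed 1
```

A pipeline config is a small YAML file:

```yaml
conditions:
  MED: {n_animals: 7}
  ISO+MED: {n_animals: 8}
n_frames: 40
duration_min: 360.0
seed: 1
```

## Notes on conventions

- Percent change is `100·(S − BL)/BL`; the baseline frame maps to 0.
- The model's compartment curves are voxel *sums* of percent-change values;
  region TSCs are means.
- The calcium lowpass description in the source material is internally
  inconsistent; it is implemented as a 20→40 Hz transition designed at the
  native rate followed by resampling to 60 Hz (see `glymkin.calcium`).
- Synthetic condition presets are illustrative phenomenology, not measured
  values.
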