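# pneumotex

Rule-based plus neural-network texture classification of
pneumoconiosis-like opacities in chest-radiograph regions of interest
(ROIs), built around power-spectrum features of three enhancement methods.

Pneumoconiosis (silicosis, asbestosis and related occupational dust
diseases) shows on chest radiographs as small rounded (p/q/r) or irregular
(s/t) opacities whose *profusion* is graded on the ILO subcategory scale
0/0 … 3/3. Distinguishing early disease from normal parenchymal texture in
a 32 × 32-pixel ROI (0.175 mm/pixel) is hard even for experienced readers;
this package implements a classical computer-aided detection scheme for
that task and a synthetic texture generator to exercise it end to end.

## Method

For each ROI:

1. **Trend correction** — subtract the least-squares second-order
   polynomial surface f(x,y) = c₀₀ + c₁₀x + c₀₁y + c₂₀x² + c₁₁xy + c₀₂y².
2. **Enhancement** along three branches: radial **window functions**
   (Hanning H(n) = 0.5 + 0.5 cos 2πn/(N−1), Hamming
   h(n) = 0.54 + 0.46 cos 2πn/(N−1), Blackman
   B(n) = 0.42 + 0.5 cos 2πn/(N−1) + 0.08 cos 4πn/(N−1), with
   n = √(x²+y²)); the morphological **top-hat transform** (image minus its
   opening with a flat square structuring element, 13–25 px); and the
   **gray-level co-occurrence feature image** (joint probability matrix of
   6-bit gray-level pairs at displacement d along 45°/225°).
3. **Power-spectrum features** — |DFT|², centred; the two radial
   directions with maximal aggregate energy (main and second axes) are
   sampled at radial bins 1 … N/2 and jointly normalized: 32 features per
   image-domain branch, 64 for the co-occurrence branch, 128 combined.
4. **Classification** — a rule stage on the main-axis values at 0.179 and
   0.357 cycles/mm (the nodular-pattern frequencies) forces "obviously"
   abnormal/normal decisions learned from training extrema, OR-fused
   across branches; undecided ROIs are scored by a three-layer sigmoid
   perceptron (32-17-1 / 64-33-1 / 128-65-1) trained to targets 0.1/0.9.
5. **Evaluation** — ten stratified random train/test halvings, empirical
   AUC per split (Mann–Whitney equivalent), vertically averaged ROC,
   mean ± SD AUC, and two-tailed paired t-tests between methods.

## Worked example

```python
import pneumotex as px

cfgs = px.default_study_configs()            # 0/0 plus five abnormal conditions
normals, _ = px.gen_dataset(cfgs[:1], 150, seed=7)
abnormals, _ = px.gen_dataset(cfgs[1:], 30, seed=7)

result = px.run_experiment(
    normals + abnormals,
    methods=("trend_only", "combined"),
    n_splits=10,
    seed=7,
)
print(result.summary().to_string(index=False))
print(result.pairwise.to_string(index=False))
```

prints

```
    method  mean_auc   sd_auc
trend_only  0.711253 0.036050
  combined  0.746364 0.044569
  method_a method_b         t        p
trend_only combined -3.761753 0.004473
```

Read: on 150 synthetic ROIs per class, plain trend correction separates
normal from abnormal texture with a split-averaged AUC of 0.71; adding the
three enhancement branches and the combined rule-plus-network classifier
raises it to 0.75, and the paired t-test over the ten shared splits calls
the difference significant (p ≈ 0.004). Absolute AUCs are a property of
the synthetic generator's difficulty setting; the ordering is the result.

The same pipeline is scriptable from the shell:

```sh
pneumotex simulate --n 20 --seed 1 --out rois/
pneumotex extract  --in rois/ --out features.csv
pneumotex train    --features features.csv --arch combined --seed 1 --model model.json
pneumotex score    --model model.json --features features.csv --out scores.csv
pneumotex evaluate --in rois/ --methods trend_only,combined --splits 10 --seed 1 --out results.csv
pneumotex run      --config my.cfg --out out/        # everything at once
```

## Layout

- `src/pneumotex/synthetic.py` — labelled ROI generator (the study data)
- `src/pneumotex/preprocess.py` — polynomial trend correction
- `src/pneumotex/enhance.py` — window / top-hat / co-occurrence branches
- `src/pneumotex/spectrum.py` — power spectra, axis profiles, features
- `src/pneumotex/classify.py` — rules, perceptron, fusion
- `src/pneumotex/evaluate.py` — split protocol, ROC/AUC, paired t-tests
- `src/pneumotex/cli.py`, `io.py` — command-line stages and file plumbing
- `docs/methods.md` — model assumptions, parameter rationale, limitations
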