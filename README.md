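# mcsv — Multiresolution Critical Spectral Verge seizure prediction

`mcsv` is a research pipeline for predicting epileptic seizures from
multichannel scalp EEG. It classifies short windows into **pre-ictal**
(the minutes before a seizure onset) versus **inter-ictal** (baseline)
states and turns window probabilities into alarms scored under standard
SPH/SOP semantics. It is aimed at researchers who want a tested,
end-to-end reference implementation of spectral-verge features — with a
synthetic EEG generator standing in for clinical corpora such as TUH-EEG.

The core method, per 4-s segment and channel:

1. **MRAF preprocessing** — DWT (`db4`) soft-threshold denoising with the
   universal threshold `Z = σ√(2 ln P)`, then one adaptive (normalised
   LMS) band stream per EEG band: δ (0.5–4 Hz), θ (4–8), α (8–13),
   β (13–30), γ (30–100) and the full band *fb*.
2. **CSV features** — per band, a ≤ 0.1 Hz-resolution periodogram; the
   *spectral verge* `SV = max{ m : P(m) > P̄ }` (the highest in-band
   frequency with above-mean power) is refined by a flower-pollination
   optimiser (Lévy-flight global steps, uniform local mixing) into the
   *critical spectral verge*, one value per band × segment × channel.
3. **CNN classification** — a compact six-layer CNN (3×3×8/1×1 →
   5×5×16/1×3 → 3×3×32/1×3 convolutions with 2×2 pooling, dense
   256/128/2, dropout 0.5, Adam 0.001, batch 100, early stopping on
   validation error) over feature-map windows, with ROS / RUS /
   borderline-SMOTE rebalancing of the ~15:1 inter-ictal : pre-ictal
   imbalance.
4. **Alarm scoring** — sensitivity `TP/(TP+FN)`, accuracy
   `(TP+TN)/total`, false predictions per inter-ictal hour, and AUC,
   with an alarm counted correct only if the onset falls inside
   `[t + SPH, t + SPH + SOP]`.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from mcsv import (SimulationConfig, simulate_record, segment,
                  decompose_bands, build_feature_map, FPMConfig)

cfg = SimulationConfig.balanced(pil_minutes=1.25, iil_pil_ratio=15,
                                n_channels=4, preictal_gamma_gain=4.0, seed=7)
record, truth = simulate_record(cfg)
print(truth.state_seconds())

grid = segment(record, window_s=4.0)
filtered = decompose_bands(record, grid)
fmap = build_feature_map(filtered, FPMConfig(seed=1))
gamma = fmap.band_names.index("gamma")
pil = truth.labels[::grid.window_samples][: grid.k] == 1
print("gamma-row CSV  IIL %.1f Hz   PIL %.1f Hz"
      % (fmap.values[:, gamma, ~pil].mean(), fmap.values[:, gamma, pil].mean()))
```

prints

```
{'interictal': 1125.0, 'preictal': 75.0, 'ictal': 30.0}
gamma-row CSV  IIL 66.4 Hz   PIL 81.7 Hz
```

— the record's inter-ictal : pre-ictal time is exactly 15:1, and the
γ-band critical spectral verge climbs from ~66 Hz at baseline to ~82 Hz in
the pre-ictal span: the planted high-γ signature the classifier learns.

The same pipeline is scriptable from the shell:

```bash
mcsv run-all --config config.yaml --seed 1 --out results/
mcsv ablate  --config config.yaml --out results/   # ablation variants
```

`run-all` emits a JSON report with `sensitivity`, `window_accuracy`,
`fpr_per_hour` and `auc`, plus a manifest recording the config hash and
seed of every artifact.

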