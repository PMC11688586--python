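# echogan

Cycle-consistent adversarial enhancement of B-mode ultrasound images.

Portable handheld ultrasound probes produce noticeably worse images than
cart-based systems — more speckle, less resolution, compressed dynamic range.
`echogan` trains a translator between the two quality domains from pairs of
images that show the same anatomy but are **not** pixel-registered (the two
acquisitions happen at different times and orientations), and ships the full
loop: synthetic paired data, model, training, enhancement, and evaluation.

## Model

Two UNet generators map between the low-quality domain *L* and the
high-quality domain *H* (G_H : L→H enhances; G_L : H→L degrades), opposed by
two spectrally normalized PatchGAN discriminators D_H, D_L that judge
overlapping patches via a spatial score map (30×30 for 256-px inputs). The
generators minimize

    L(G_H, G_L) = λ_adv·L_adv + λ_cycle·L_cycle + λ_L1·L_L1 + λ_per·L_per

with λ = (1, 10, 2, 10): a least-squares adversarial term against all-ones
score targets, the cycle-consistency term |G_L(G_H(L)) − L|₁ + |G_H(G_L(H)) − H|₁,
a paired L1 term, and a perceptual feature distance (channel-normalized deep
features, squared differences summed over stages) that compares images the
way registration-free pairs must be compared. Discriminators train on a
least-squares objective with conditional label smoothing: the real-image
target drops from 1.0 to 0.9 once the batch-mean scores reach 0.9.

Evaluation uses four full-reference metrics — SSI, LNCC, PSNR and the
perceptual distance (LPIPS-style) — plus one-sided Wilcoxon signed-rank
comparisons on per-pair scores.

Everything runs on a NumPy reverse-mode autodiff core written for this
package; no GPU or deep-learning framework is required.

## Worked example

The desk-scale benchmark generates 200 synthetic 64-px speckle-phantom pairs
(blur σ=2, ×2 downsampling, speckle 4→2 looks, 1 px warp), trains depth-6
generators for 10 epochs, and compares the trained enhancer against the
unenhanced "reference low" baseline on the 40-pair held-out split:

```python
from echogan import desk_scale_experiment  # ~8 min on one CPU
res = desk_scale_experiment(seed=1, out_dir="runs/desk")
print(res["baseline"], res["trained"], res["p_values"], sep="\n")
```

prints (seed 1):

```
{'ssi': 0.0597, 'lncc': 0.0736, 'psnr': 11.1964, 'lpips': 3.1143}   # baseline
{'ssi': 0.0713, 'lncc': 0.0963, 'psnr': 14.2400, 'lpips': 2.5791}   # trained
{'ssi': 5.77e-05, 'lncc': 6.00e-09, 'psnr': 9.09e-13, 'lpips': 9.09e-13}
```

The trained enhancer beats the raw low-quality images on every metric:
+3.0 dB PSNR, higher structural similarity and local correlation, and a
lower perceptual distance, each significant at p < 10⁻⁴ (one-sided
signed-rank, n = 40). Desk-scale numbers demonstrate the learning signal;
they are not clinical image-quality claims (see `docs/methods.md`).

## Command line

```sh
echogan synth    --config cfg.yaml --n-pairs 200 --out data/
echogan split    --config cfg.yaml --root data/
echogan train    --config cfg.yaml --root data/ --out run/
echogan enhance  --checkpoint run/checkpoint_best.npz --input data/low --out out/
echogan evaluate --config cfg.yaml --root data/ --split test \
                 --checkpoint run/checkpoint_best.npz --out report
echogan compare  --report-a report.csv --report-b baseline.csv
```

Datasets live as 8-bit grayscale PNGs (16-bit TIFF supported) under
`<root>/low/`, `<root>/high/` with a `manifest.csv` (id, registered, split,
paths). Every run writes an effective-config snapshot for reproducibility.

## Layout

- `src/echogan/phantom.py` — synthetic speckle phantoms and degradations
- `src/echogan/models.py` — UNet generators, PatchGAN discriminators,
  spectral normalization
- `src/echogan/losses.py` — perceptual/adversarial/cycle/L1 losses, label rule
- `src/echogan/metrics.py` — SSI, LNCC, PSNR, perceptual metric, Wilcoxon
- `src/echogan/training.py` — splits, lr schedule, training loop, checkpoints
- `src/echogan/benchmark.py` — the desk-scale experiment
- `src/echogan/nn/` — the NumPy autodiff core
- `src/echogan/{cli,io,config}.py` — CLI, image/manifest I/O, run configs
- `docs/methods.md` — models, assumptions, parameter choices, limitations
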