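# vnetpp

A tested library + CLI implementing a 4-stage 2D V-Net++ brain-tumor
segmentation pipeline: a residual encoder-decoder with a context-boosting
bottleneck (max-pool → 500-filter convolution → learned upsampling) trained
with the composite **Log-Cosh-Focal-Tversky (LCFT)** loss
(`0.6·log(cosh(1−Dice)) + 0.2·(1−Tversky)^0.75 + 0.2·(1−Jaccard)`),
plus a six-variant ablation harness and a synthetic multi-modal phantom
generator so everything runs offline on CPU.

The network, reverse-mode autodiff, and the Nadam optimizer are implemented
in pure NumPy (no deep-learning framework required); gradients are verified
against finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `vnetpp.losses` | soft/hard confusion counts, Dice/Jaccard/Tversky metrics, LCFT loss |
| `vnetpp.architecture` | `ArchitectureSpec`, the segmentation model, CBF block, six ablation variants |
| `vnetpp.brats_io` | NIfTI case reading, normalization, slice-window extraction, 240→192 crop, label remap, 80/20 split |
| `vnetpp.synthetic` | seeded BraTS-like phantom cohorts (4 modalities + nested tumor labels {0,1,2,4}) |
| `vnetpp.training` | Nadam training loop, per-epoch history, checkpointing |
| `vnetpp.evaluation` | pooled metric reports, ablation harness, one-way ANOVA, montages |
| `vnetpp.cli` / `vnetpp.config` | `vnetpp` command with a strict YAML run config |

## CLI

```bash
vnetpp init-config --out run.yaml                 # commented defaults
vnetpp synth --cases 2 --shape test --out data/   # phantom cohort
vnetpp preprocess --data-dir data --out slices.npz
vnetpp train --data-dir data --config run.yaml --checkpoint-dir ckpt
vnetpp predict --checkpoint ckpt/final.npz --case-dir data/phantom_000 --out pred.nii.gz
vnetpp evaluate --checkpoint ckpt/final.npz --data-dir data --out report.tsv
vnetpp ablate --data-dir data --scale test --out ablation.tsv --seed 0
```

Defaults encode the pipeline's standard values: learning rate 0.0002, Nadam,
30 epochs, loss weights 0.6/0.2/0.2, focal exponent 0.75, 500 CBF filters,
axial slice window [30, 120), 240→192 centered crop, 80/20 split.

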