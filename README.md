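# mvtomo

Multi-view, graph-guided transformer segmentation of cryo-electron
tomography (cryo-ET) volumes — a complete, CPU-friendly implementation
with a synthetic tomogram generator, so every stage of the pipeline can be
trained, evaluated and tested without any external data.

## Who this is for

Cryo-ET produces 3D grayscale voxel volumes (tomograms) in which
macromolecular particles must be localized and classified — a multi-class
voxel segmentation problem at very low signal-to-noise.  `mvtomo` is for
researchers who want a transparent, fully-tested reference implementation
of a transformer-based approach to this problem: every component, from the
MRC reader to the attention layers, is plain numpy/scipy and unit-tested
against independent oracles.

## The model

A volume `x ∈ R^{H×W×D}` is observed along three orthogonal perspectives
(XY canonical, YZ with axes `(H, D, W)`, XZ with `(D, W, H)`), cut into 4³
voxel patches, and embedded as token sequences

&nbsp;&nbsp;&nbsp;&nbsp;`I_v = [ proj(p_1) + e_1^v, …, proj(p_L) + e_L^v ]`,&nbsp;&nbsp; v ∈ {XY, XZ, YZ},

with one shared linear projection and a separate learnable position table
`e^v` per view.  A parallel context encoder (three stride-2 conv–BN–ReLU
blocks) produces a feature grid that k-means clusters into K graph nodes
`g_1..g_K` (cluster means); these act as the queries of the first
transformer layer, whose node summaries are redistributed back onto the
tokens through the renormalized transpose of the attention map.  The
remaining `Ln−1` layers are standard pre-norm self-attention blocks.  Two
decoder heads map token features to per-class scores: **MF** fuses
`n_tap` intermediate encoder layers through conv/upsample branches;
**P3DA** applies four parallel atrous convolutions (dilation 1, 6, 12, 18)
at full resolution.  Per-view predictions `ŷ_v` are realigned to the
canonical grid and fused by summation, `ŷ = ŷ_XY + ŷ_XZ' + ŷ_YZ'`, and the
training loss is

&nbsp;&nbsp;&nbsp;&nbsp;`L = CE(y, ŷ_XY) + CE(y, ŷ_YZ') + CE(y, ŷ_XZ') + CE(y, ŷ) + L_recon`,

where `L_recon` is the masked-view reconstruction MSE: each step masks
half of one view's tokens and a lightweight transformer decoder
reconstructs their voxel contents from all three views.  See
`docs/methods.md` for the full account.

## Worked example

Simulate a small dataset, train the desk-scale model, and evaluate:

```python
import numpy as np
from mvtomo.experiments import run_toy_segmentation

res = run_toy_segmentation(seed=1)
print(f"fused foreground Dice : {res['dice_fused']:.4f}")
print(f"best single-view Dice : {res['dice_best_view']:.4f}")
print(f"fused mIoU            : {res['miou_fused']:.4f}")
p = res["picking"]
print(f"picking P/R/F1        : {p['precision']:.3f} {p['recall']:.3f} {p['f1']:.3f}")
```

This generates 200 training and 32 held-out synthetic patches (16³, one
particle class, variance-ratio SNR 0.05), trains the toy profile (2
encoder layers, 32 channels, 4 heads, 4 graph nodes) for 300 Adam steps,
and prints:

```
fused foreground Dice : 0.8396
best single-view Dice : 0.8388
fused mIoU            : 0.8559
picking P/R/F1        : 0.946 0.761 0.843
```

The fused prediction beats every single view (the multi-view gain),
nearly every particle the model reports is real (precision 0.95), and the
Dice value sits at the boundary-noise ceiling these small, heavily noised
particles admit — a matched-filter oracle tuned on the ground truth
reaches only 0.83 on the same data; see the methods note.  The
command-line interface exposes the same pipeline on MRC files on disk:

```bash
mvtomo simulate --config sim.yaml --out data/
mvtomo train    --data data/ --out run/ --toy --seed 1
mvtomo predict  --checkpoint run/checkpoint.npz --volume data/volume_0000.mrc --out pred/
mvtomo evaluate --pred pred/labels.mrc --gt data/labels_0000.mrc \
                --particles data/particles_0000.tsv --n-classes 1 --out report.json
```

Ablation switches: `--decoder {mf,p3da}`, `--views {xy,xz,yz,all}`,
`--no-graph` (disable graph-guided attention), `--no-vsl` (disable the
reconstruction objective).

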