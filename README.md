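# cortexfuse

Weakly supervised cortical-surface and vessel segmentation for
intraoperative hyperspectral imaging (HSI), with probabilistic fusion that
corrects the tumor/vessel confusions of pixel-wise tissue classifiers.

During brain-tumor surgery, HSI tissue classifiers label every pixel of
the exposed surgical field as healthy, tumor, blood vessel, or dura. In
practice they confuse blood vessels with tumor remarkably often — an error
with serious consequences if the map guides resection. `cortexfuse`
implements a two-part remedy:

1. **Surface segmentation.** A dual-input encoder–decoder (`CortexNet`)
   segments the exposed cortex and its superficial vessels. It is trained
   in three steps — contrastive pre-training, RGB training on
   automatically *refined pseudo-labels* grown from quick square patch
   annotations, and HSI fine-tuning in which only a small spectral stem
   trains at full learning rate (the trunk's rate is divided by 1e3).
   Shape priors (concave-hull and excess losses) keep predictions compact
   and vessels inside the cortex.
2. **Probability fusion.** The classifier's 4-class probabilities are
   reduced to healthy-vs-rest and recombined with the cortex probability
   P_ctx and vessel probability P_vsl as
   `[Q_h·(1−P_vsl)·P_ctx, Q_nh·(1−P_vsl)·P_ctx, P_vsl·P_ctx, 1−P_ctx]`.
   The output is a proper per-pixel distribution (channels sum to 1
   exactly; the vessel channel is exactly P_vsl·P_ctx), so a confidently
   detected vessel can never be relabeled tumor, and everything outside
   the cortex becomes background.

Clinical HSI data is access-restricted, so the package ships a synthetic
craniotomy scene generator (RGB image + 25-band snapshot-mosaic cube +
sparse annotations + dense truth) and a controllable "flawed classifier"
that injects a known vessel→tumor confusion. Every claim below is
reproducible offline on one CPU. See [docs/methods.md](docs/methods.md)
for the full method description.

## Worked example

The end-to-end demo generates 12 synthetic scenes, preprocesses the raw
mosaic frames, grows pseudo-labels, runs the three-step training at desk
scale (reduced network and schedules; ~5 minutes on one CPU), then fuses a
deliberately flawed classifier (80 % vessel→tumor confusion) on the two
held-out scenes:

```text
$ cortexfuse demo --out runs/demo
{
  "metrics": "runs/demo/metrics.json",
  "raw_tumor_f1": 37.524990003998404,
  "fused_tumor_f1": 0.0,
  "oracle_fused_tumor_f1": 100.0,
  "raw_vessel_f1": 30.5,
  "fused_vessel_f1": 19.744937565151815,
  "oracle_fused_vessel_f1": 100.0,
  "cortex_dsc_mean": 70.59107281763983
}
```

Reading the numbers: the flawed classifier's tumor F1 is 37.5 because
vessels bleed into the tumor class. Fusing with **oracle** surface masks
(`oracle_fused_*`) repairs both classes completely (F1 = 100) — that is
the fusion-algebra property, isolated from network quality. Fusing with
the **learned** desk-scale masks is honest but rough: the tiny network
(base_channels 8, ~5 % of the full schedule) reaches cortex DSC ≈ 71 on
held-out HSI cubes, and its vessel head over-fires inside the cortex, so
learned-mask fusion does not yet beat the raw classifier at this scale.
The full-scale configuration (the package default when you pass a config
with no overrides) uses base_channels 32 and the complete
400/1000/700-epoch schedule.

The run directory contains `metrics.json` (per-scene F1 and DSC),
`manifest.json` (config hash, seeds, library versions, stage timings),
JSON-lines training logs, the checkpoint, and rendered PNGs of the scene,
pseudo-labels and fused map.

Individual stages are scriptable too, e.g.:

```bash
cortexfuse synth --out runs/s --seed 3 --n-scenes 2
cortexfuse preproc --raw runs/s/scene000_raw.npz --out runs/s/cube000.npz \
    --prgb runs/s/prgb000.png
cortexfuse fuse --tissue clf.npz --cortex pctx.png --vessel pvsl.png \
    --out fused.npz --render fused.png
```

## Package layout

| Module | Contents |
| --- | --- |
| `cortexfuse.preproc` | demosaicking, reflectance calibration, pseudo-RGB band selection |
| `cortexfuse.pseudolabel` | cortex refinement, contour/vessel pseudo-labels, adjusted GT |
| `cortexfuse.network` | `CortexNet` dual-input encoder–decoder, checkpoints |
| `cortexfuse.nn` | NumPy autograd engine, layers, AdamW, cosine schedule |
| `cortexfuse.losses` | Dice/BCE, hull and excess shape losses, SupCon, masked BCEs |
| `cortexfuse.training` | splits, augmentation, the three training steps, ablation presets |
| `cortexfuse.fusion` | probability reduction + fusion, reference tissue classifier |
| `cortexfuse.evaluation` | DSC, ASSD, VHR/VER, F1, AUC, confusion matrices, aggregation |
| `cortexfuse.synthetic` | synthetic scene generator, flawed-classifier sampler |
| `cortexfuse.pipeline` / `cortexfuse.cli` | end-to-end demo and the `cortexfuse` CLI |
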