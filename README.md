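# svpnet

Autonomous classification of spontaneous retinal venous pulsations (SVPs)
in fundus videos. The pipeline has two stages: an attention-gated,
recurrent-residual U-Net built from depthwise-separable convolutions
localizes the optic disc in every frame; a stabilized disc-centered crop
(30 frames, 64x64, grayscale) is then classified as SVP *present* or
*absent* by one of five video classifiers — 3D Inception, 3D Dense-ResNet,
3D ResNet, LRCN or ConvLSTM.

A synthetic phantom generator produces fundus-like images with exact disc
masks and videos with a vein whose caliber pulses at a cardiac-like
frequency (or not), so the whole pipeline is trainable and testable at desk
scale without any dataset downloads.

All networks run on a small numpy-based reverse-mode autodiff engine
(`svpnet.nn`) — no deep-learning framework is required. Training defaults
to float32; the functional building blocks default to float64 so they can
be compared against scalar-loop reference implementations at 1e-6.

## Layout

- `svpnet.phantom` — synthetic images/clips with ground truth (`PhantomSpec`,
  `make_disc_image`, `make_svp_clip`, `make_dataset`)
- `svpnet.localizer` — depthwise-separable conv, attention gate,
  recurrent-residual block, U-Net model, Dice loss, RMSprop training,
  per-frame mask prediction
- `svpnet.cropper` — largest-component bounding boxes, median aggregation
  across frames, the 30x64x64x1 crop contract
- `svpnet.classifiers` — the five architectures (with "small" desk-scale
  and "full" presets), the ConvLSTM cell, Adam training, prediction
- `svpnet.evaluation` — confusion counts, sensitivity/specificity/precision/
  accuracy/F1/NPV, Dice/IoU, trapezoidal ROC-AUC, 180-degree rotation
  augmentation, k-fold cross-validation with mean +/- sd reporting
- `svpnet.cli` — the `svpnet` command group and the end-to-end pipeline
- `svpnet.nn` — the autograd engine (tensors, layers, optimizers)

## CLI

```bash
# synthetic data
svpnet generate --kind images --n 40 --seed 1 --out data/images
svpnet generate --kind clips  --n 20 --seed 1 --out data/clips

# localizer
svpnet train-localizer --data data/images --config cfg.yaml --out ckpt/
svpnet localize --model ckpt/localizer.npz --frames video_dir --out masks/

# crop + classifier
svpnet crop --video video_dir --masks masks/ --out clip.npz
svpnet train-classifier --arch convlstm --data data/clips --out ckpt/
svpnet evaluate --arch convlstm --data data/clips --folds 5 --out report/

# full chain on one video
svpnet predict --video video_dir --localizer ckpt/localizer.npz \
    --model ckpt/convlstm.npz --artifacts out/

# versioned test fixtures
svpnet fixtures --out fixtures/ --seed 0
```

Videos are directories of per-frame PNGs (`frame_0000.png`, ...) with a
JSON manifest, or any single-file container imageio can read. Configs are
YAML; checkpoints are `.npz` parameter archives with a JSON config snapshot
alongside. Exit codes: 0 success, 2 data error, 3 contract error.

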