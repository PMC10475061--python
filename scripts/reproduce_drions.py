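#!/usr/bin/env python
"""Full-scale optic-disc localizer reproduction on DRIONS-DB.

Not a test: requires the DRIONS-DB download (110 fundus images plus expert
contour annotations) and several CPU-hours. Expected outcome at full scale
is a held-out Dice around 0.95 and IoU around 0.91.

Expected layout (adjust --images / --contours if yours differs):
    <root>/images/image_001.jpg ...
    <root>/experts_anotation/anotExpert1_001.txt ...

Usage:
    python scripts/reproduce_drions.py --root /path/to/DRIONS-DB --out ckpt/
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from svpnet import evaluation, io, localizer  # noqa: E402
from svpnet.phantom import LabeledImage       # noqa: E402


def load_drions(images_dir: Path, contours_dir: Path) -> list[LabeledImage]:
    pairs = []
    for img_path in sorted(images_dir.iterdir()):
        if img_path.suffix.lower() not in (".jpg", ".png", ".jpeg", ".bmp"):
            continue
        number = "".join(ch for ch in img_path.stem if ch.isdigit())
        matches = sorted(contours_dir.glob(f"*{number}.txt"))
        if matches:
            pairs.append((img_path, matches[0]))
    if not pairs:
        raise SystemExit(f"no image/contour pairs under {images_dir}")
    data = []
    for img_path, contour_path in pairs:
        frame = io.rgb_to_gray(io.read_image(img_path))
        contour = io.read_contour_file(contour_path)
        mask = io.contour_to_mask(contour, frame.shape)
        data.append(LabeledImage(frame=frame, mask=mask))
    return data


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--root", type=Path, required=True)
    parser.add_argument("--images", type=Path, default=None)
    parser.add_argument("--contours", type=Path, default=None)
    parser.add_argument("--epochs", type=int, default=100)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("ckpt_drions"))
    args = parser.parse_args()

    images_dir = args.images or args.root / "images"
    contours_dir = args.contours or args.root / "experts_anotation"
    data = load_drions(images_dir, contours_dir)
    print(f"loaded {len(data)} image/mask pairs")

    config = localizer.LocalizerConfig(
        depth=4, base_filters=16, recurrence_steps=1, input_size=256,
        learning_rate=0.003, batch_size=6, epochs=args.epochs, seed=args.seed)
    model, history = localizer.train_localizer(data, config, verbose=True)
    localizer.save_localizer(args.out / "localizer.npz", model)

    dices, ious = [], []
    for i in history["split"]["test"]:
        pred = localizer.predict_mask(model, data[i].frame)
        dice, iou = evaluation.dice_iou(pred, data[i].mask)
        dices.append(dice)
        ious.append(iou)
    print(f"test Dice {np.mean(dices):.3f}  IoU {np.mean(ious):.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
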