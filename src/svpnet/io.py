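"""Reading and writing of frames, masks, clips and model checkpoints.

Images and masks travel as 8-bit PNG. A clip is a directory of zero-padded
per-frame PNGs (``frame_0000.png`` ...) plus a ``manifest.json`` sidecar
holding the label, spec and frame rate. Checkpoints are ``.npz`` parameter
archives with a JSON config snapshot next to them.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DataError
from .phantom import LabeledClip, LabeledImage, PhantomSpec, VideoClip

LUMA = (0.299, 0.587, 0.114)


def to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(arr) * 255.0), 0, 255).astype(np.uint8)


def from_uint8(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=np.float64) / 255.0


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance; identity for already-grayscale input."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        r, g, b = LUMA
        return r * frame[..., 0] + g * frame[..., 1] + b * frame[..., 2]
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[..., 0]
    raise DataError(f"cannot interpret frame of shape {frame.shape} as an image")


def write_image(path: str | Path, frame: np.ndarray) -> None:
    iio.imwrite(Path(path), to_uint8(frame))


def read_image(path: str | Path) -> np.ndarray:
    return from_uint8(iio.imread(Path(path)))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return (iio.imread(Path(path)) > 127).astype(np.uint8)


def write_labeled_image(out_dir: str | Path, stem: str, item: LabeledImage) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(out_dir / f"{stem}.png", item.frame)
    write_mask(out_dir / f"{stem}_mask.png", item.mask)


def read_labeled_image(image_path: str | Path,
                       mask_path: str | Path) -> LabeledImage:
    frame = rgb_to_gray(read_image(image_path))
    mask = read_mask(mask_path)
    if frame.shape != mask.shape:
        raise DataError(f"frame {frame.shape} and mask {mask.shape} shapes differ")
    return LabeledImage(frame=frame, mask=mask)


def write_clip(out_dir: str | Path, item: LabeledClip) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in range(item.clip.n_frames):
        write_image(out_dir / f"frame_{t:04d}.png", item.clip.frames[t])
    manifest = {
        "label": item.label,
        "frame_rate": item.clip.frame_rate,
        "n_frames": item.clip.n_frames,
        "spec": item.spec.to_dict() if item.spec is not None else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_clip(clip_dir: str | Path) -> LabeledClip:
    clip_dir = Path(clip_dir)
    manifest_path = clip_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {clip_dir}")
    manifest = json.loads(manifest_path.read_text())
    frames = read_frames(clip_dir)
    spec = (PhantomSpec.from_dict(manifest["spec"])
            if manifest.get("spec") else PhantomSpec())
    return LabeledClip(
        clip=VideoClip(frames=frames, frame_rate=manifest.get("frame_rate", 30.0)),
        label=manifest.get("label", "absent"), spec=spec)


def read_frames(source: str | Path) -> np.ndarray:
    """Load a video as (T, H, W[, C]) floats in [0,1].

    `source` may be a directory of per-frame PNGs or a single video file
    readable by imageio.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("frame_*.png")) or sorted(source.glob("*.png"))
        if not paths:
            raise DataError(f"no PNG frames found in {source}")
        return np.stack([read_image(p) for p in paths])
    if not source.exists():
        raise DataError(f"video source {source} does not exist")
    return from_uint8(np.asarray(iio.imread(source)))


def contour_to_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed contour (given as (x, y) i.e. (col, row) pairs, the
    convention of expert-annotated disc contour files) into a binary mask."""
    from skimage.draw import polygon
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise DataError(f"need >= 3 (x, y) contour points, got {points.shape}")
    rr, cc = polygon(points[:, 1], points[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def read_contour_file(path: str | Path) -> np.ndarray:
    """Read one comma- or whitespace-separated contour point list."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().replace(",", " ")
        if not line:
            continue
        parts = line.split()
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise DataError(f"no contour points in {path}")
    return np.array(rows)


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray],
                    config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **state)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(config, fh, indent=2)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    if not path.exists():
        raise DataError(f"checkpoint {path} does not exist")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    config_path = path.with_suffix(".json")
    config = json.loads(config_path.read_text()) if config_path.exists() else {}
    return state, config
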