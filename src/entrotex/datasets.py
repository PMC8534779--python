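"""Labeled image datasets in the class-per-directory layout.

A dataset root contains one subdirectory per class; class order is
lexicographic by directory name so confusion matrices are deterministic.
An optional filename regex with a ``tag`` group extracts the acquisition
sample tag needed by the leave-one-sample-out protocol (KTH-TIPS-2b
style, where each class splits into 4 acquisition samples).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


@dataclass
class Sample:
    image: np.ndarray | None
    label: str
    tag: str | None = None
    path: Path | None = None

    def load(self) -> np.ndarray:
        if self.image is None:
            self.image = read_image(self.path)
        return self.image


@dataclass
class LabeledDataset:
    samples: list[Sample] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        return sorted({s.label for s in self.samples})

    @property
    def tags(self) -> list[str] | None:
        tags = {s.tag for s in self.samples}
        if tags == {None}:
            return None
        return sorted(t for t in tags if t is not None)

    def images(self) -> list[np.ndarray]:
        return [s.load() for s in self.samples]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices])


def read_image(path) -> np.ndarray:
    """Read an 8-bit raster as a 2-D gray or HxWx3 RGB integer array.

    16-bit inputs are rescaled to [0, 255] with a warning; palette/alpha
    images are converted to RGB.  No ICC transforms are applied.
    """
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L"):
            arr = np.asarray(im, dtype=np.float64)
            warnings.warn(f"{path}: 16-bit input rescaled to [0, 255]", stacklevel=2)
            arr = arr / 65535.0 * 255.0
            return np.round(arr).astype(np.int64)
        if im.mode == "L":
            return np.asarray(im, dtype=np.int64)
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.int64)


def write_image(path, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8)).save(path)


def load_dataset(root, tag_pattern: str | None = None) -> LabeledDataset:
    """Load a class-per-directory dataset.

    ``tag_pattern`` is a regex applied to each filename; its ``tag`` group
    (or first group) becomes the acquisition-sample tag.  Unreadable files
    are skipped with a warning count; an empty class directory is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"dataset root {root} must contain >= 2 class subdirectories")
    pattern = re.compile(tag_pattern) if tag_pattern else None
    samples: list[Sample] = []
    skipped = 0
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"class directory {cdir.name!r} contains no images")
        for p in files:
            tag = None
            if pattern is not None:
                m = pattern.search(p.name)
                if m:
                    tag = m.groupdict().get("tag") or m.group(1)
            try:
                img = read_image(p)
            except Exception as exc:  # unreadable file: report and skip
                logger.warning("skipping unreadable image %s: %s", p, exc)
                skipped += 1
                continue
            samples.append(Sample(image=img, label=cdir.name, tag=tag, path=p))
    if skipped:
        logger.warning("skipped %d unreadable image(s) under %s", skipped, root)
    return LabeledDataset(samples)
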