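"""Black-box feature extraction and dual-stream fusion.

A texture image is described twice: once as-is (the "original" stream) and
once through its local-entropy map (the "entropy" stream).  Each stream is
pushed through a feature extractor — canonically the 4096-unit penultimate
fully connected layer of an ImageNet-pretrained VGG19, but any
deterministic image -> fixed-length-vector map satisfying the extractor
contract can be registered — and the two descriptors are concatenated.

The bundled ``pooled-stats`` extractor (per-channel means, variances and a
fixed-seed Gaussian random projection of the resized image) satisfies the
contract with no pretrained weights and makes the whole pipeline runnable
offline at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .entropy import (
    EntropyMap,
    EntropySpec,
    HistogramSpec,
    WindowSpec,
    entropy_transform,
    validate_gray_image,
)

__all__ = [
    "BackboneSpec",
    "FeatureVector",
    "ConfigurationError",
    "PooledStatsExtractor",
    "get_extractor",
    "register_extractor",
    "to_grayscale",
    "entropy_to_input",
    "extract_features",
    "fuse",
    "DualStreamFeaturizer",
    "FeatureCache",
]

# ITU-R BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class ConfigurationError(RuntimeError):
    """An extractor is unavailable in the current environment."""


@dataclass(frozen=True)
class BackboneSpec:
    """Contract of a feature extractor: square input side, output length, preprocessing tag."""

    name: str
    input_side: int
    output_dim: int
    preprocessing: str = "none"

    def __post_init__(self) -> None:
        if self.input_side < 1 or self.output_dim < 1:
            raise ValueError("input_side and output_dim must be >= 1")


@dataclass
class FeatureVector:
    """Descriptor with provenance: which stream produced it and at which q."""

    values: np.ndarray
    stream: str  # original | entropy | fused
    backbone: str
    q: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("feature vector must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")
        if self.stream not in ("original", "entropy", "fused"):
            raise ValueError(f"unknown stream tag {self.stream!r}")

    def __len__(self) -> int:
        return self.values.size


def to_grayscale(img) -> np.ndarray:
    """BT.601 luminance of an RGB image, rounded to integers in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        return validate_gray_image(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 color image, got shape {arr.shape}")
    lum = arr.astype(np.float64) @ _LUMA
    return np.clip(np.round(lum), 0, 255).astype(np.int64)


def as_color(img) -> np.ndarray:
    """Return an HxWx3 uint8 view of a gray or color image (gray is channel-replicated)."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a 2-D or HxWx3 image, got shape {arr.shape}")
    return np.clip(arr, 0, 255).astype(np.uint8)


def entropy_to_input(emap: EntropyMap, spec: BackboneSpec) -> np.ndarray:
    """Adapt an entropy map to a backbone input.

    Min–max rescale to [0, 255] (a constant map becomes mid-gray 128),
    round-half-even quantisation, replication to three channels and
    bilinear resize to the backbone's square input side.
    """
    vals = np.asarray(emap.values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("entropy map must be finite")
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scaled = (vals - lo) * (255.0 / (hi - lo))
    else:
        scaled = np.full_like(vals, 128.0)
    gray = np.rint(scaled).astype(np.uint8)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    if rgb.shape[:2] != (spec.input_side, spec.input_side):
        resized = resize(
            rgb.astype(np.float64),
            (spec.input_side, spec.input_side, 3),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        rgb = np.rint(resized).astype(np.uint8)
    return rgb


class PooledStatsExtractor:
    """Weight-free stand-in extractor.

    Descriptor = per-channel mean and variance of the resized image (scaled
    to [0, 1]) followed by ``n_projections`` fixed-seed Gaussian random
    projections of the flattened pixels.  Deterministic by construction:
    the projection matrix is drawn once from a seed derived from the
    extractor name, so identical inputs always give identical outputs.
    """

    def __init__(self, input_side: int = 32, n_projections: int = 10, seed: int = 12345):
        self.spec = BackboneSpec(
            name="pooled-stats",
            input_side=input_side,
            output_dim=6 + n_projections,
            preprocessing="unit-scale",
        )
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((n_projections, input_side * input_side * 3))
        self._proj /= np.sqrt(self._proj.shape[1])
        self.calls = 0  # instrumentation for cache tests

    def __call__(self, img: np.ndarray) -> np.ndarray:
        self.calls += 1
        rgb = as_color(img)
        side = self.spec.input_side
        if rgb.shape[:2] != (side, side):
            rgb = resize(
                rgb.astype(np.float64),
                (side, side, 3),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
        x = rgb.astype(np.float64) / 255.0
        means = x.mean(axis=(0, 1))
        variances = x.var(axis=(0, 1))
        proj = self._proj @ x.ravel()
        return np.concatenate([means, variances, proj])


def _make_vgg19():
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            "the 'vgg19-penultimate' backbone needs torch/torchvision with "
            "pretrained weights, which are not available here; use the "
            "'pooled-stats' stand-in extractor instead (flag --backbone "
            "pooled-stats, or --offline)"
        ) from exc
    from torchvision.models import VGG19_Weights, vgg19

    model = vgg19(weights=VGG19_Weights.IMAGENET1K_V1).eval()

    class _VGG19Penultimate:
        spec = BackboneSpec(
            name="vgg19-penultimate", input_side=224, output_dim=4096,
            preprocessing="imagenet",
        )

        def __init__(self):
            self.calls = 0

        def __call__(self, img):
            import torch

            self.calls += 1
            rgb = as_color(img).astype(np.float32) / 255.0
            rgb = resize(rgb, (224, 224, 3), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
            mean = np.array([0.485, 0.456, 0.406], dtype=np.float32)
            std = np.array([0.229, 0.224, 0.225], dtype=np.float32)
            t = torch.from_numpy(((rgb - mean) / std).transpose(2, 0, 1)[None])
            with torch.no_grad():
                feats = model.features(t)
                feats = model.avgpool(feats).flatten(1)
                # stop one layer short of the classifier head
                for layer in list(model.classifier)[:-1]:
                    feats = layer(feats)
            return feats.numpy().ravel().astype(np.float64)

    return _VGG19Penultimate()


_REGISTRY = {
    "pooled-stats": PooledStatsExtractor,
    "vgg19-penultimate": _make_vgg19,
}

#: Declared output dimensionality of registered backbones (VGG19's 4096-unit
#: penultimate fully connected layer; the stand-in's 16 pooled statistics).
BACKBONE_OUTPUT_DIMS = {"pooled-stats": 16, "vgg19-penultimate": 4096}


def register_extractor(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_extractor(name: str = "pooled-stats", **kwargs):
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown backbone {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def extract_features(img, extractor, stream: str = "original", q: float | None = None) -> FeatureVector:
    """Run an image through an extractor, tagging the result with its provenance."""
    values = extractor(img)
    spec = getattr(extractor, "spec", None)
    if spec is not None and values.size != spec.output_dim:
        raise RuntimeError(
            f"extractor {spec.name!r} returned {values.size} values, declared {spec.output_dim}"
        )
    return FeatureVector(values=values, stream=stream,
                         backbone=spec.name if spec else "custom", q=q)


def fuse(original_fv: FeatureVector, entropy_fv: FeatureVector) -> FeatureVector:
    """Concatenate the two stream descriptors, original stream first."""
    if original_fv.stream != "original" or entropy_fv.stream != "entropy":
        raise ValueError(
            "fuse expects an 'original' and an 'entropy' stream vector, got "
            f"{original_fv.stream!r} and {entropy_fv.stream!r}"
        )
    if original_fv.backbone != entropy_fv.backbone:
        raise ValueError(
            f"streams come from different backbones: {original_fv.backbone!r} "
            f"vs {entropy_fv.backbone!r}"
        )
    return FeatureVector(
        values=np.concatenate([original_fv.values, entropy_fv.values]),
        stream="fused",
        backbone=original_fv.backbone,
        q=entropy_fv.q,
    )


class FeatureCache:
    """Descriptor cache keyed by image content, stream, q and backbone.

    The original-image stream does not depend on q, so its key carries
    q = None and a sweep over many q values recomputes it only once.
    With ``directory`` set, entries are also persisted as one ``.npy``
    file per key (named by the key's content hash), so a second run over
    the same images skips the extractor entirely; a corrupt entry is
    recomputed with a warning.
    """

    def __init__(self, directory=None):
        from pathlib import Path

        self._store: dict[tuple, np.ndarray] = {}
        self.directory = Path(directory) if directory else None
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
        self.hits = 0
        self.misses = 0

    @staticmethod
    def image_key(img: np.ndarray) -> bytes:
        import hashlib

        arr = np.ascontiguousarray(img)
        h = hashlib.sha1()
        h.update(str(arr.shape).encode())
        h.update(str(arr.dtype).encode())
        h.update(arr.tobytes())
        return h.digest()

    def _disk_path(self, key: tuple):
        import hashlib

        digest = hashlib.sha1(repr(key).encode()).hexdigest()
        return self.directory / f"{digest}.npy"

    def get_or_compute(self, key: tuple, compute):
        import warnings

        if key in self._store:
            self.hits += 1
            return self._store[key]
        if self.directory is not None:
            path = self._disk_path(key)
            if path.exists():
                try:
                    value = np.load(path)
                    if not (value.ndim == 1 and np.all(np.isfinite(value))):
                        raise ValueError("malformed cached descriptor")
                    self.hits += 1
                    self._store[key] = value
                    return value
                except Exception as exc:
                    warnings.warn(
                        f"corrupt feature-cache entry {path.name}: {exc}; recomputing",
                        stacklevel=2,
                    )
        self.misses += 1
        value = compute()
        self._store[key] = value
        if self.directory is not None:
            np.save(self._disk_path(key), value)
        return value

    def __len__(self) -> int:
        return len(self._store)


class DualStreamFeaturizer(BaseEstimator, TransformerMixin):
    """Images -> descriptor matrix for one or both streams.

    Parameters
    ----------
    q, radius, bin_width, normalize, border_mode, q1_mode
        Local-entropy transform parameters (see :mod:`entrotex.entropy`).
    backbone
        Registered extractor name; ``pooled-stats`` needs no weights.
    stream
        ``"fused"`` (default, concatenated original+entropy), ``"original"``
        or ``"entropy"``.
    cache
        Optional shared :class:`FeatureCache`; extractor invocations are
        skipped on cache hits.
    """

    def __init__(
        self,
        q: float = 1.5,
        radius: int = 2,
        bin_width: int = 32,
        normalize: bool = True,
        border_mode: str = "reflect",
        q1_mode: str = "bgs_limit",
        backbone: str = "pooled-stats",
        stream: str = "fused",
        cache: FeatureCache | None = None,
    ):
        self.q = q
        self.radius = radius
        self.bin_width = bin_width
        self.normalize = normalize
        self.border_mode = border_mode
        self.q1_mode = q1_mode
        self.backbone = backbone
        self.stream = stream
        self.cache = cache

    def fit(self, X=None, y=None):
        if self.stream not in ("fused", "original", "entropy"):
            raise ValueError(f"unknown stream {self.stream!r}")
        self._extractor = get_extractor(self.backbone)
        return self

    def _ensure_extractor(self):
        if not hasattr(self, "_extractor"):
            self.fit()
        return self._extractor

    def _entropy_input(self, img: np.ndarray) -> np.ndarray:
        gray = to_grayscale(img)
        emap = entropy_transform(
            gray,
            WindowSpec(radius=self.radius, border_mode=self.border_mode),
            HistogramSpec(bin_width=self.bin_width, normalize=self.normalize),
            EntropySpec(q=self.q, q1_mode=self.q1_mode),
        )
        return entropy_to_input(emap, self._extractor.spec)

    def transform_one(self, img) -> FeatureVector:
        extractor = self._ensure_extractor()
        img = np.asarray(img)
        cache = self.cache
        parts = {}
        if self.stream in ("fused", "original"):
            key = None
            if cache is not None:
                key = (cache.image_key(img), "original", None, self.backbone)
                values = cache.get_or_compute(key, lambda: extractor(as_color(img)))
            else:
                values = extractor(as_color(img))
            parts["original"] = FeatureVector(values, "original", extractor.spec.name)
        if self.stream in ("fused", "entropy"):
            ent_params = (self.q, self.radius, self.bin_width, self.normalize,
                          self.border_mode, self.q1_mode)
            if cache is not None:
                key = (cache.image_key(img), "entropy", ent_params, self.backbone)
                values = cache.get_or_compute(
                    key, lambda: extractor(self._entropy_input(img))
                )
            else:
                values = extractor(self._entropy_input(img))
            parts["entropy"] = FeatureVector(values, "entropy", extractor.spec.name, q=self.q)
        if self.stream == "fused":
            return fuse(parts["original"], parts["entropy"])
        return parts[self.stream]

    def transform(self, X) -> np.ndarray:
        return np.vstack([self.transform_one(img).values for img in X])

    def __sklearn_is_fitted__(self) -> bool:
        return True
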