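"""Local non-additive entropy of image neighbourhoods.

The central primitive of the package: every pixel of an 8-bit grayscale
image is replaced by the reduced Tsallis entropy

    S'_q = sum_k p_k^q

of the intensity histogram of the square (2r+1)x(2r+1) window centred on
it, where ``p`` is the window histogram binned with width ``h_b`` (and
normalised to a probability vector by default).  The resulting real-valued
field ("entropy map") is an alternative representation of the texture in
which local disorder, rather than raw intensity, carries the signal.

The full Tsallis entropy S_q = k/(q-1) * (1 - sum p^q) and its q -> 1
Boltzmann-Gibbs-Shannon limit -k * sum p log p are provided as validation
oracles, together with a deliberately naive per-pixel reference
implementation of the transform against which the vectorised one is tested
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpecError",
    "WindowSpec",
    "HistogramSpec",
    "EntropySpec",
    "LocalHistogram",
    "EntropyMap",
    "validate_gray_image",
    "local_histogram",
    "tsallis_entropy",
    "bgs_entropy",
    "reduced_entropy",
    "entropy_transform",
    "entropy_transform_naive",
    "LocalEntropyTransformer",
]


class SpecError(ValueError):
    """Invalid window/histogram/entropy specification."""


#: np.pad modes backing the two supported border conventions.  "reflect"
#: mirrors without repeating the edge pixel; "clamp" repeats it.
_BORDER_TO_PAD = {"reflect": "reflect", "clamp": "edge"}


@dataclass(frozen=True)
class WindowSpec:
    """Square neighbourhood of side 2*radius+1 around each pixel."""

    radius: int = 2
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if not (isinstance(self.radius, (int, np.integer)) and self.radius >= 1):
            raise SpecError(f"window radius must be a positive integer, got {self.radius!r}")
        if self.border_mode not in _BORDER_TO_PAD:
            raise SpecError(
                f"border_mode must be one of {sorted(_BORDER_TO_PAD)}, got {self.border_mode!r}"
            )

    @property
    def side(self) -> int:
        return 2 * self.radius + 1

    @property
    def n_pixels(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class HistogramSpec:
    """Intensity binning of a window: ``n_bins = n_levels / bin_width``.

    Bins are half-open ``[(k)*bin_width, (k+1)*bin_width)`` so that every
    integer intensity in [0, n_levels-1] lands in exactly one bin; the top
    intensity n_levels-1 belongs to the last bin.  With ``normalize`` the
    histogram is scaled to a probability vector, otherwise raw counts are
    kept (strict-letter mode; entropy then carries a window-size factor).
    """

    bin_width: int = 32
    n_levels: int = 256
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.bin_width, (int, np.integer)) and self.bin_width >= 1):
            raise SpecError(f"bin_width must be a positive integer, got {self.bin_width!r}")
        if self.n_levels % self.bin_width != 0:
            raise SpecError(
                f"bin_width ({self.bin_width}) must divide the number of gray "
                f"levels ({self.n_levels})"
            )

    @property
    def n_bins(self) -> int:
        return self.n_levels // self.bin_width


@dataclass(frozen=True)
class EntropySpec:
    """Entropic index q (> 0), prefactor k_B and the behaviour at q = 1.

    ``S'_q`` at q = 1 over a normalised histogram is identically 1, so by
    default (``q1_mode="bgs_limit"``) the Shannon/BGS limit -sum p log p is
    substituted there; ``q1_mode="raw"`` keeps the literal (constant) sum.
    """

    q: float = 1.5
    k_B: float = 1.0
    q1_mode: str = "bgs_limit"

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise SpecError(f"entropic index q must be > 0, got {self.q!r}")
        if self.q1_mode not in ("bgs_limit", "raw"):
            raise SpecError(f"q1_mode must be 'bgs_limit' or 'raw', got {self.q1_mode!r}")


@dataclass
class LocalHistogram:
    """Binned window histogram: per-bin mass and the pixel count it aggregates."""

    mass: np.ndarray
    count_total: int
    normalized: bool = True


@dataclass
class EntropyMap:
    """Per-pixel S'_q field with the parameters that produced it."""

    values: np.ndarray
    q: float
    radius: int
    bin_width: int
    normalized: bool = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def validate_gray_image(image, n_levels: int = 256) -> np.ndarray:
    """Check a 2-D integer intensity grid in [0, n_levels-1]; return it as int array."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"grayscale image must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("grayscale image must hold integer intensities")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > n_levels - 1:
        raise ValueError(
            f"intensities must lie in [0, {n_levels - 1}], "
            f"found range [{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.int64, copy=False)


def _pad(arr: np.ndarray, radius: int, border_mode: str) -> np.ndarray:
    return np.pad(arr, radius, mode=_BORDER_TO_PAD[border_mode])


def local_histogram(image, center, win: WindowSpec, hist: HistogramSpec) -> LocalHistogram:
    """Histogram of the window centred at ``center`` = (row, col).

    Border windows are filled according to ``win.border_mode``.
    """
    arr = validate_gray_image(image, hist.n_levels)
    y, x = int(center[0]), int(center[1])
    if not (0 <= y < arr.shape[0] and 0 <= x < arr.shape[1]):
        raise IndexError(f"window center {center} outside image of shape {arr.shape}")
    r = win.radius
    padded = _pad(arr, r, win.border_mode)
    window = padded[y : y + 2 * r + 1, x : x + 2 * r + 1]
    bins = window // hist.bin_width
    counts = np.bincount(bins.ravel(), minlength=hist.n_bins).astype(np.float64)
    total = int(counts.sum())
    if hist.normalize:
        mass = counts / total
    else:
        mass = counts
    return LocalHistogram(mass=mass, count_total=total, normalized=hist.normalize)


def _check_probability(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probability masses must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
    return p


def tsallis_entropy(p, spec: EntropySpec = EntropySpec()) -> float:
    """Tsallis entropy S_q(p) = k_B/(q-1) * (1 - sum_i p_i^q), q != 1."""
    if spec.q == 1:
        raise ValueError("Tsallis entropy is undefined at q = 1; use bgs_entropy (the limit)")
    p = _check_probability(p)
    return spec.k_B / (spec.q - 1.0) * (1.0 - float(np.sum(p**spec.q)))


def bgs_entropy(p, k_B: float = 1.0) -> float:
    """Boltzmann-Gibbs-Shannon entropy -k_B * sum p log p, with 0 log 0 = 0."""
    p = _check_probability(p)
    nz = p[p > 0]
    return -k_B * float(np.sum(nz * np.log(nz)))


def reduced_entropy(h: LocalHistogram, spec: EntropySpec = EntropySpec()) -> float:
    """Reduced entropy S'_q = sum_k mass_k^q of a window histogram.

    At q = 1 the default mode substitutes the Shannon entropy of the
    normalised masses (the Tsallis -> BGS limit); ``raw`` mode returns the
    literal sum of masses, which is constant across windows.
    """
    mass = np.asarray(h.mass, dtype=np.float64)
    if spec.q == 1:
        if spec.q1_mode == "raw":
            return float(np.sum(mass))
        p = mass / mass.sum() if not h.normalized else mass
        return _shannon_sum(p)
    return float(np.sum(mass**spec.q))


def _shannon_sum(p: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -float(np.sum(terms))


def _bin_counts_map(image: np.ndarray, win: WindowSpec, hist: HistogramSpec) -> np.ndarray:
    """(H, W, n_bins) integer window-bin counts for every pixel, via summed-area tables."""
    r = win.radius
    bins = _pad(image // hist.bin_width, r, win.border_mode)
    h, w = image.shape
    counts = np.empty((h, w, hist.n_bins), dtype=np.int64)
    side = 2 * r + 1
    for k in range(hist.n_bins):
        ind = (bins == k).astype(np.int64)
        # summed-area table with a zero top row / left column
        sat = np.zeros((ind.shape[0] + 1, ind.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(ind, axis=0), axis=1, out=sat[1:, 1:])
        counts[:, :, k] = (
            sat[side : side + h, side : side + w]
            - sat[:h, side : side + w]
            - sat[side : side + h, :w]
            + sat[:h, :w]
        )
    return counts


def entropy_transform(
    image,
    win: WindowSpec = WindowSpec(),
    hist: HistogramSpec = HistogramSpec(),
    spec: EntropySpec = EntropySpec(),
) -> EntropyMap:
    """Replace each pixel by the reduced entropy of its window histogram.

    Vectorised with per-bin summed-area tables; agrees bit for bit with
    :func:`entropy_transform_naive` because both divide the same integer
    counts and sum bin contributions in the same order.
    """
    arr = validate_gray_image(image, hist.n_levels)
    counts = _bin_counts_map(arr, win, hist)
    total = float(win.n_pixels)
    if hist.normalize:
        mass = counts / total
    else:
        mass = counts.astype(np.float64)
    if spec.q == 1:
        if spec.q1_mode == "raw":
            values = mass.sum(axis=-1)
        else:
            p = mass if hist.normalize else mass / total
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(p > 0, p * np.log(p), 0.0)
            values = -terms.sum(axis=-1)
    else:
        values = (mass**spec.q).sum(axis=-1)
    return EntropyMap(
        values=values,
        q=spec.q,
        radius=win.radius,
        bin_width=hist.bin_width,
        normalized=hist.normalize,
    )


def entropy_transform_naive(
    image,
    win: WindowSpec = WindowSpec(),
    hist: HistogramSpec = HistogramSpec(),
    spec: EntropySpec = EntropySpec(),
) -> EntropyMap:
    """Reference double-loop implementation (oracle for the vectorised path)."""
    arr = validate_gray_image(image, hist.n_levels)
    out = np.empty(arr.shape, dtype=np.float64)
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            out[y, x] = reduced_entropy(local_histogram(arr, (y, x), win, hist), spec)
    return EntropyMap(
        values=out,
        q=spec.q,
        radius=win.radius,
        bin_width=hist.bin_width,
        normalized=hist.normalize,
    )


class LocalEntropyTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping grayscale images to entropy maps.

    Parameters mirror the window/histogram/entropy specifications; ``fit``
    is a no-op (the transform has nothing to learn) and ``transform``
    accepts a single 2-D image or a sequence of them, returning
    :class:`EntropyMap` objects of matching arity.
    """

    def __init__(
        self,
        q: float = 1.5,
        radius: int = 2,
        bin_width: int = 32,
        normalize: bool = True,
        border_mode: str = "reflect",
        q1_mode: str = "bgs_limit",
    ):
        self.q = q
        self.radius = radius
        self.bin_width = bin_width
        self.normalize = normalize
        self.border_mode = border_mode
        self.q1_mode = q1_mode

    def _specs(self):
        return (
            WindowSpec(radius=self.radius, border_mode=self.border_mode),
            HistogramSpec(bin_width=self.bin_width, normalize=self.normalize),
            EntropySpec(q=self.q, q1_mode=self.q1_mode),
        )

    def fit(self, X=None, y=None):
        self._specs()  # validate parameters eagerly
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        win, hist, spec = self._specs()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return entropy_transform(X, win, hist, spec)
        return [entropy_transform(img, win, hist, spec) for img in X]

    def __sklearn_is_fitted__(self) -> bool:
        return True
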