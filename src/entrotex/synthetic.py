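"""Synthetic textures and the perturbed-distribution experiment.

Two generators make every stage of the package testable offline:

* multi-class texture images built from smoothed Gaussian noise, where a
  class is defined by its mean intensity (what the original-image stream
  sees) and by the amplitude of its local intensity fluctuations (what
  the entropy stream sees);
* a Monte-Carlo experiment measuring how the Tsallis entropy of a random
  discrete distribution responds to additive noise at different entropic
  indices q — the mechanism that makes q worth tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .datasets import LabeledDataset, Sample
from .entropy import EntropySpec, bgs_entropy, tsallis_entropy

__all__ = [
    "TextureClassSpec",
    "generate_texture_image",
    "generate_texture_dataset",
    "default_class_specs",
    "split_information_specs",
    "rare_bin_specs",
    "write_dataset_dir",
    "PerturbationExperiment",
    "PerturbationResult",
    "run_perturbation_experiment",
]


@dataclass(frozen=True)
class TextureClassSpec:
    """One synthetic texture class.

    ``base_mean`` sets the intensity level, ``noise_amplitude`` the pixel
    standard deviation of the smoothed-noise field (local disorder),
    ``correlation_length`` the Gaussian smoothing sigma in pixels, and
    ``gradient`` adds a left-to-right illumination ramp.  ``salt`` paints
    rare outlier pixels: a (probability, [intensities]) pair, each salted
    pixel taking one of the listed intensities uniformly at random.
    """

    name: str
    base_mean: float = 128.0
    noise_amplitude: float = 20.0
    correlation_length: float = 1.5
    gradient: bool = False
    salt: tuple | None = None


def default_class_specs() -> list[TextureClassSpec]:
    """Four classes separated by local disorder (entropy-stream signal)."""
    return [
        TextureClassSpec("smooth", base_mean=128, noise_amplitude=5),
        TextureClassSpec("mild", base_mean=128, noise_amplitude=25),
        TextureClassSpec("rough", base_mean=128, noise_amplitude=50),
        TextureClassSpec("chaotic", base_mean=128, noise_amplitude=75),
    ]


def split_information_specs() -> list[TextureClassSpec]:
    """Four classes on a 2x2 grid of (mean intensity) x (local disorder).

    Mean intensity alone or disorder alone each separate only two pairs;
    telling all four apart needs both streams, which is the designed
    setting for the fusion-dominance check.
    """
    return [
        TextureClassSpec("dark-calm", base_mean=90, noise_amplitude=8),
        TextureClassSpec("dark-rough", base_mean=90, noise_amplitude=55),
        TextureClassSpec("light-calm", base_mean=165, noise_amplitude=8),
        TextureClassSpec("light-rough", base_mean=165, noise_amplitude=55),
    ]


def rare_bin_specs(eps: float = 0.5) -> list[TextureClassSpec]:
    """Two classes that differ only in how rare-pixel mass splits across bins.

    Both classes sprinkle outlier pixels with the same total probability
    ``eps`` over a quiet base texture; one puts all outliers at a single
    intensity (one histogram bin), the other splits them between two bins.
    The reduced-entropy gap between a (2e) bin and an (e, e) pair scales
    like e^q (2 - 2^q) relative to the common-bin term, so small q
    amplifies the distinction — a construction where a small entropic
    index demonstrably dominates a sweep run on the entropy stream.
    """
    return [
        TextureClassSpec("onebin", base_mean=110, noise_amplitude=5,
                         correlation_length=0.0, salt=(eps, (230,))),
        TextureClassSpec("twobin", base_mean=110, noise_amplitude=5,
                         correlation_length=0.0, salt=(eps, (200, 250))),
    ]


def generate_texture_image(spec: TextureClassSpec, side: int, rng: np.random.Generator) -> np.ndarray:
    """One synthetic texture image (2-D int64 in [0, 255])."""
    noise = rng.standard_normal((side, side))
    if spec.correlation_length > 0:
        noise = gaussian_filter(noise, sigma=spec.correlation_length, mode="reflect")
        sd = noise.std()
        if sd > 0:  # restore unit variance so amplitude means pixel std
            noise = noise / sd
    img = spec.base_mean + spec.noise_amplitude * noise
    if spec.gradient:
        img = img + np.linspace(-20, 20, side)[None, :]
    if spec.salt is not None:
        prob, intensities = spec.salt
        mask = rng.random((side, side)) < prob
        values = rng.choice(np.asarray(intensities), size=int(mask.sum()))
        img[mask] = values
    return np.clip(np.round(img), 0, 255).astype(np.int64)


def generate_texture_dataset(
    specs: list[TextureClassSpec] | None = None,
    n_per_class: int = 20,
    side: int = 64,
    seed: int = 0,
    radius: int = 2,
) -> LabeledDataset:
    """Deterministic labeled dataset of synthetic textures.

    ``radius`` is the entropy-window radius the dataset is meant to feed;
    images must be large enough for at least one full window.
    """
    if specs is None:
        specs = default_class_specs()
    if len(specs) < 2:
        raise ValueError("need at least 2 texture classes")
    if side < 2 * radius + 1:
        raise ValueError(
            f"side {side} too small for an entropy window of radius {radius}"
        )
    samples: list[Sample] = []
    for ci, spec in enumerate(specs):
        rng = np.random.default_rng((seed * 1009 + ci) % (2**31 - 1))
        for _ in range(n_per_class):
            samples.append(Sample(image=generate_texture_image(spec, side, rng),
                                  label=spec.name))
    return LabeledDataset(samples)


def write_dataset_dir(ds: LabeledDataset, root) -> None:
    """Materialise a dataset as PNG files in the class-per-directory layout."""
    from pathlib import Path

    from .datasets import write_image

    root = Path(root)
    counters: dict[str, int] = {}
    for s in ds.samples:
        cdir = root / s.label
        cdir.mkdir(parents=True, exist_ok=True)
        i = counters.get(s.label, 0)
        counters[s.label] = i + 1
        write_image(cdir / f"{s.label}_{i:03d}.png", s.load())


@dataclass
class PerturbationExperiment:
    """Monte-Carlo design: entropy change of a noised discrete distribution.

    Each trial draws raw bin masses v uniformly from [0, 1] over
    ``n_bins`` bins; the base distribution is p0 = v / sum(v).  For each
    perturbation level n, i.i.d. uniform noise in [0, 0.1 n] is added to
    the raw masses and the result renormalised, so the noise scale is
    commensurate with the masses it perturbs (added to the already
    normalised vector it would swamp them and the entropy difference
    would shrink with n instead of growing).  The Tsallis entropy (k = 1)
    of both vectors is taken at every q in ``q_grid`` (BGS entropy at
    q = 1) and the difference S_n - S_0 averaged over trials.
    """

    n_bins: int = 50
    n_levels: tuple = (1, 2, 3, 4, 5)
    trials: int = 200
    q_grid: tuple = tuple(np.round(np.arange(0.05, 2.01, 0.05), 2))
    seed: int = 0


@dataclass
class PerturbationResult:
    experiment: PerturbationExperiment
    mean_diff: np.ndarray  # (len(n_levels), len(q_grid)) mean of S_n - S_0
    se_diff: np.ndarray  # Monte-Carlo standard error of the mean

    def as_table(self) -> str:
        lines = ["n\tq\tmean_diff\tse"]
        for i, n in enumerate(self.experiment.n_levels):
            for j, q in enumerate(self.experiment.q_grid):
                lines.append(f"{n}\t{q:g}\t{self.mean_diff[i, j]:.8f}\t{self.se_diff[i, j]:.8f}")
        return "\n".join(lines)


def _entropy_at(p: np.ndarray, q: float) -> float:
    if q == 1:
        return bgs_entropy(p)
    return tsallis_entropy(p, EntropySpec(q=q))


def run_perturbation_experiment(exp: PerturbationExperiment) -> PerturbationResult:
    """Run the experiment; degenerate level n = 0 yields exactly zero difference."""
    if exp.trials < 1:
        raise ValueError("trials must be >= 1")
    qs = [float(q) for q in exp.q_grid]
    if any(q <= 0 for q in qs):
        raise ValueError("q grid must be positive")
    rng = np.random.default_rng(exp.seed)
    diffs = np.empty((exp.trials, len(exp.n_levels), len(qs)))
    for t in range(exp.trials):
        raw = rng.random(exp.n_bins)
        p0 = raw / raw.sum()
        s0 = np.array([_entropy_at(p0, q) for q in qs])
        for i, n in enumerate(exp.n_levels):
            if n == 0:
                diffs[t, i] = 0.0
                continue
            pn = raw + rng.uniform(0.0, 0.1 * n, size=exp.n_bins)
            pn /= pn.sum()
            sn = np.array([_entropy_at(pn, q) for q in qs])
            diffs[t, i] = sn - s0
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(exp.trials) if exp.trials > 1 else np.zeros_like(mean)
    return PerturbationResult(experiment=exp, mean_diff=mean, se_diff=se)
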