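"""Synthetic study inputs: labeled feature tables with known ground truth,
and toy grayscale "mass" images for the extractor smoke test.

The table generator stands in for deep features extracted from mammogram
patches: a block of informative columns whose class-conditional means differ
by ``class_separation`` standard deviations, noisy copies of those columns
(redundant), and label-independent Gaussian noise columns.  Ground truth is
returned alongside so selection quality is scoreable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tabular import LabeledTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_table", "generate_blob_images"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic labeled table.

    ``class_separation`` is the gap between the two class means of every
    informative column, in units of the within-class SD (1).  Redundant
    column ``i`` is informative column ``i mod n_informative`` plus Gaussian
    noise of SD ``redundancy_noise_sd``.
    """

    n_samples: int = 200
    n_informative: int = 4
    n_redundant: int = 2
    n_noise: int = 10
    class_separation: float = 3.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature-block sizes must be non-negative")
        if self.class_separation < 0 or self.redundancy_noise_sd < 0:
            raise ValueError("separations and noise SDs must be >= 0")

    @property
    def d(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    """Which generated columns carry signal, echo it, or are pure noise."""

    informative_indices: list[int]
    redundant_map: dict[int, int]
    noise_indices: list[int]

    def __post_init__(self) -> None:
        groups = (
            set(self.informative_indices)
            | set(self.redundant_map)
            | set(self.noise_indices)
        )
        total = (
            len(self.informative_indices)
            + len(self.redundant_map)
            + len(self.noise_indices)
        )
        if len(groups) != total or groups != set(range(total)):
            raise ValueError("index groups must partition 0..d-1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "informative_indices": self.informative_indices,
                    "redundant_map": {str(k): v for k, v in self.redundant_map.items()},
                    "noise_indices": self.noise_indices,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            obj["informative_indices"],
            {int(k): v for k, v in obj["redundant_map"].items()},
            obj["noise_indices"],
        )


def generate_table(spec: SyntheticSpec) -> tuple[LabeledTable, GroundTruth]:
    """Draw one labeled table per ``spec``; same seed -> identical table.

    Labels are balanced exactly (ceil/floor) and row order is a seeded
    permutation, so stratified splits stay stable at small n.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.d
    n_pos = n // 2
    labels = np.concatenate([np.zeros(n - n_pos, dtype=int), np.ones(n_pos, dtype=int)])
    labels = labels[rng.permutation(n)]

    X = np.empty((n, d))
    k_inf, k_red = spec.n_informative, spec.n_redundant
    X[:, :k_inf] = rng.standard_normal((n, k_inf))
    X[labels == 1, :k_inf] += spec.class_separation

    redundant_map: dict[int, int] = {}
    for i in range(k_red):
        src = i % k_inf
        col = k_inf + i
        redundant_map[col] = src
        X[:, col] = X[:, src] + spec.redundancy_noise_sd * rng.standard_normal(n)

    X[:, k_inf + k_red:] = rng.standard_normal((n, spec.n_noise))

    names = (
        [f"inf_{j}" for j in range(k_inf)]
        + [f"red_{i}_of_inf_{i % k_inf}" for i in range(k_red)]
        + [f"noise_{j}" for j in range(spec.n_noise)]
    )
    truth = GroundTruth(
        informative_indices=list(range(k_inf)),
        redundant_map=redundant_map,
        noise_indices=list(range(k_inf + k_red, d)),
    )
    return LabeledTable(X, labels, names), truth


def generate_blob_images(
    n_images: int,
    size: int = 64,
    with_mass_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy grayscale patches: positives contain one bright Gaussian blob.

    Returns ``(images, labels)`` with images in ``[0, 1]`` of shape
    ``(n_images, size, size)``.  The background is smoothed Gaussian texture on
    both classes; only positives get the blob, mimicking mass vs. no-mass
    mammogram patches at cartoon fidelity.
    """
    if size < 32:
        raise ValueError("size must be >= 32 pixels")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    n_pos = int(round(n_images * with_mass_fraction))
    labels = np.zeros(n_images, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n_images)]

    yy, xx = np.mgrid[0:size, 0:size]
    images = np.empty((n_images, size, size))
    for i in range(n_images):
        bg = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16)
        bg = bg - bg.min()
        bg = 0.3 * bg / max(bg.max(), 1e-12)
        img = bg
        if labels[i] == 1:
            cy, cx = rng.uniform(size * 0.25, size * 0.75, size=2)
            sigma = rng.uniform(size / 12, size / 6)
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            img = img + 0.7 * blob
        images[i] = np.clip(img, 0.0, 1.0)
    return images, labels


def save_images_png(images: np.ndarray, labels: np.ndarray, directory) -> list[str]:
    """Write each image as an 8-bit grayscale PNG named ``img_<i>_y<label>.png``."""
    from pathlib import Path

    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (img, y) in enumerate(zip(images, labels)):
        arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        p = directory / f"img_{i:04d}_y{int(y)}.png"
        Image.fromarray(arr, mode="L").save(p)
        paths.append(str(p))
    return paths
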