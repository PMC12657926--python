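"""Synthetic inputs: class-structured grayscale images and graph fixtures.

The image generator emulates the structure that matters for
pixel-similarity graphs. A key property of the construction those graphs
come from: the min-max-normalized Brightness Distance Matrix is invariant
to affine intensity maps and blind to pixel positions, so a thresholded
pixel graph is determined entirely by the *shape of the intensity
histogram* (it is the interval graph of the pixel intensities). Class
structure must therefore live in histogram shape, not in spatial texture.

Each image is a smooth mid-gray parenchyma field (white noise convolved
with a Gaussian kernel of length ``smooth_len``, scaled to a narrow
intensity band) in which a class-dependent fraction of pixels --
contiguous "atrophy" regions selected by a second correlated field -- is
displaced to a broad dark intensity band. As the stage label grows, the
displaced fraction grows and the correlation length shrinks (more, smaller
lesions): the histogram develops a heavier, more diffuse tail, so the
pixel graph acquires a long sparse intensity chain hanging off the dense
bulk. Path-based statistics (average path length, Wiener index, and with
them the whole six-index vector) increase monotonically across stages,
which is the separable class signal the classifier consumes. Local
clustering, by contrast, is structurally pinned near 0.75-0.8 for interval
graphs of this kind and is deliberately not relied on as the class
covariate.

Graph fixtures cover the families used by the index oracles: paths, cycles,
complete graphs, ring lattices, random trees, and random connected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter

from . import ws_model

__all__ = [
    "SynthImageSpec",
    "GraphFixtureSpec",
    "DEFAULT_CLASS_SPECS",
    "make_image",
    "make_dataset",
    "make_graph",
]


@dataclass(frozen=True)
class SynthImageSpec:
    """Recipe for one synthetic grayscale image.

    smooth_len : spatial correlation length in pixels (Gaussian sigma) of
        both the parenchyma texture and the lesion field; larger -> fewer,
        larger contiguous regions.
    contrast : overall intensity scale in gray levels; the parenchyma band
        has sd 0.22*contrast, the lesion band is centered 1.2*contrast
        below mid-gray with sd 0.65*contrast.
    noise_sd : additive white pixel noise, gray levels.
    lesion_frac : fraction of pixels displaced into the broad dark band;
        the monotone stage covariate.
    """

    label: int
    size: tuple = (32, 32)
    smooth_len: float = 4.0
    contrast: float = 55.0
    noise_sd: float = 3.0
    lesion_frac: float = 0.1

    def __post_init__(self):
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be in 0..3, got {self.label}")
        if self.smooth_len <= 0:
            raise ValueError("smooth_len must be positive")
        if not 0.0 <= self.lesion_frac < 1.0:
            raise ValueError("lesion_frac must lie in [0, 1)")


#: Default per-class recipes: the displaced-pixel fraction grows and the
#: correlation length shrinks with the stage label, so pixel graphs get
#: progressively longer-pathed and more fragmented from class 0 to class 3.
DEFAULT_CLASS_SPECS = {
    0: SynthImageSpec(label=0, smooth_len=6.0, lesion_frac=0.03),
    1: SynthImageSpec(label=1, smooth_len=4.0, lesion_frac=0.09),
    2: SynthImageSpec(label=2, smooth_len=2.6, lesion_frac=0.18),
    3: SynthImageSpec(label=3, smooth_len=1.6, lesion_frac=0.30),
}


@dataclass(frozen=True)
class GraphFixtureSpec:
    """Recipe for one fixture graph."""

    family: str
    size: int
    seed: int | None = None
    edge_prob: float = 0.3
    delta: int = 4  # ring_lattice only


def _filter_gain(sigma: float) -> float:
    """Output sd of the 2-D Gaussian filter applied to unit white noise.

    Exact for the discrete truncated kernel scipy uses: the per-axis kernel
    a_i ~ exp(-i^2 / (2 sigma^2)) gives output variance (sum a_i^2)^2.
    """
    radius = int(4.0 * sigma + 0.5)
    i = np.arange(-radius, radius + 1)
    a = np.exp(-(i**2) / (2.0 * sigma**2))
    a /= a.sum()
    return float((a**2).sum())


def _smooth_field(rng, size, sigma):
    """Correlated Gaussian field, unit sd in the well-resolved regime.

    Normalized by the theoretical filter gain, not the sample sd, so a
    smoothing length far above the image size degenerates to a near-zero
    (near-constant) field instead of being re-amplified.
    """
    f = gaussian_filter(rng.standard_normal(size), sigma=sigma, mode="wrap")
    f = f / _filter_gain(sigma)
    return f - f.mean()


def make_image(spec: SynthImageSpec, rng=None) -> np.ndarray:
    """Generate one image from a spec; deterministic given the rng state.

    parenchyma: ``127.5 + 0.22*c * field``; lesion pixels (top
    ``lesion_frac`` quantile of a second correlated field) are displaced to
    ``127.5 - 1.2*c + 0.65*c * field``; plus white noise, clipped to
    [0, 255]. With ``contrast = noise_sd = 0`` the image is constant.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, m = spec.size
    c = spec.contrast
    f1 = _smooth_field(rng, (n, m), spec.smooth_len)
    f2 = _smooth_field(rng, (n, m), spec.smooth_len)
    img = 127.5 + 0.22 * c * f1
    if spec.lesion_frac > 0:
        mask = f2 > np.quantile(f2, 1.0 - spec.lesion_frac)
        img[mask] = 127.5 - 1.2 * c + 0.65 * c * f1[mask]
    img = img + rng.standard_normal((n, m)) * spec.noise_sd
    return np.clip(img, 0.0, 255.0)


def make_dataset(
    n_per_class: int,
    class_specs: dict | None = None,
    seed=None,
    imbalance=None,
):
    """Labeled image set: ``n_per_class`` images per class (scaled by ``imbalance``).

    ``imbalance`` is an optional per-class factor tuple, e.g.
    ``(1.0, 0.5, 0.5, 0.1)``; counts are ``max(1, round(f * n_per_class))``.
    Returns ``(images, labels)`` where images is a list of 2-D arrays. All
    randomness flows from ``seed`` through one spawned stream per image, so
    the dataset is reproducible and insensitive to generation order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    specs = dict(DEFAULT_CLASS_SPECS)
    if class_specs:
        specs.update(class_specs)
    factors = imbalance if imbalance is not None else (1.0,) * 4
    counts = [max(1, int(round(f * n_per_class))) for f in factors]
    root = np.random.SeedSequence(seed)
    total = sum(counts)
    streams = root.spawn(total)
    images, labels = [], []
    k = 0
    for label in range(4):
        for _ in range(counts[label]):
            images.append(make_image(specs[label], rng=np.random.default_rng(streams[k])))
            labels.append(label)
            k += 1
    return images, np.asarray(labels)


def make_graph(spec: GraphFixtureSpec) -> nx.Graph:
    """Generate a simple graph from the named family.

    Families: ``path``, ``cycle``, ``complete``, ``ring_lattice`` (delegates
    to :func:`braingraph.ws_model.ring_lattice`), ``random_tree``,
    ``random_connected`` (G(n, p) resampled until connected, bounded retries).
    """
    n = spec.size
    if spec.family == "path":
        return nx.path_graph(n)
    if spec.family == "cycle":
        return nx.cycle_graph(n)
    if spec.family == "complete":
        return nx.complete_graph(n)
    if spec.family == "ring_lattice":
        return ws_model.ring_lattice(n, spec.delta)
    rng = np.random.default_rng(spec.seed)
    if spec.family == "random_tree":
        # random Pruefer sequence -> uniform labeled tree
        if n < 2:
            raise ValueError("random_tree needs size >= 2")
        if n == 2:
            return nx.path_graph(2)
        seq = rng.integers(0, n, size=n - 2)
        return nx.from_prufer_sequence(seq.tolist())
    if spec.family == "random_connected":
        for _ in range(200):
            g = nx.gnp_random_graph(n, spec.edge_prob, seed=int(rng.integers(2**31)))
            if n >= 2 and nx.is_connected(g):
                return g
        raise RuntimeError(
            "could not sample a connected graph in 200 tries; raise edge_prob"
        )
    raise ValueError(f"unknown graph family {spec.family!r}")
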