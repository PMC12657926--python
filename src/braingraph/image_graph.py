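"""Grayscale image -> pixel-similarity graph.

A grayscale image is turned into an undirected simple graph in three steps:

1. **Brightness Distance Matrix (BDM)** -- for an image with ``mn`` pixels
   (row-major, 0-based), the ``mn x mn`` matrix of absolute luminance
   differences ``L(p, q) = |Lum(p) - Lum(q)|``.
2. **Min-max normalization** -- ``L_n(p, q) = (L - min L) / (max L - min L)``,
   mapping entries to [0, 1].
3. **Thresholding** -- pixels ``p != q`` are joined by an edge whenever their
   brightness similarity ``1 - L_n(p, q)`` is at least a threshold ``tau``;
   self-loops are never created.

Higher ``tau`` gives a sparser graph. Distance-based graph invariants are
defined only on connected graphs, so :func:`largest_component` extracts the
dominant component before index computation.

Images are plain 2-D ``float64`` numpy arrays with intensities in [0, 255];
graphs are :class:`networkx.Graph` objects whose nodes are row-major pixel
indices.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights for RGB -> grayscale conversion.
DEFAULT_LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {img.shape}")
    if img.size < 2:
        raise ValueError(f"image must have at least 2 pixels, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img


def load_grayscale(path, luma_weights=DEFAULT_LUMA_WEIGHTS) -> np.ndarray:
    """Read a PNG/JPEG as a float grayscale array in [0, 255].

    Color images are reduced with the weighted luma combination
    ``w_R*R + w_G*G + w_B*B``; the weights must sum to 1. Grayscale inputs
    pass through unchanged (up to float conversion).
    """
    w = np.asarray(luma_weights, dtype=float)
    if w.shape != (3,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("luma_weights must be three reals summing to 1")
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("L", "I;16", "I", "F"):
                arr = np.asarray(im.convert("F"), dtype=float)
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=float)
                arr = rgb @ w
    except FileNotFoundError:
        raise
    except OSError as exc:  # unreadable / truncated file
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    return _validate_image(np.clip(arr, 0.0, 255.0))


def downsample(img: np.ndarray, target_m: int, target_n: int) -> np.ndarray:
    """Area-averaged resize of ``img`` to ``target_m`` rows x ``target_n`` cols.

    Uses a box filter (exact block averaging for integer ratios). A no-op
    when the target equals the source shape. The target may not exceed the
    source in either dimension.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if target_m < 1 or target_n < 1:
        raise ValueError("target dimensions must be >= 1")
    if target_m > img.shape[0] or target_n > img.shape[1]:
        raise ValueError(
            f"target {target_m}x{target_n} exceeds source {img.shape[0]}x{img.shape[1]}"
        )
    if (target_m, target_n) == img.shape:
        return img.copy()
    im = Image.fromarray(img.astype(np.float32), mode="F")
    out = im.resize((target_n, target_m), resample=Image.BOX)
    return np.clip(np.asarray(out, dtype=float), 0.0, 255.0)


def compute_bdm(img: np.ndarray) -> np.ndarray:
    """Brightness Distance Matrix: ``L(p, q) = |Lum(p) - Lum(q)|``.

    Pixels are ordered row-major, so pixel (i, j) of an m-row, n-col image
    has index ``i*n + j``. The result is symmetric with a zero diagonal.
    """
    img = _validate_image(img)
    flat = img.ravel(order="C")
    return np.abs(flat[:, None] - flat[None, :])


def normalize_bdm(bdm: np.ndarray) -> np.ndarray:
    """Min-max normalize a BDM to [0, 1].

    The diagonal guarantees ``min L = 0`` for any valid BDM. For a constant
    image (``max L = min L``) the normalization is undefined; all entries are
    then defined as 0 and a warning is logged.
    """
    bdm = np.asarray(bdm, dtype=float)
    lo, hi = bdm.min(), bdm.max()
    if hi == lo:
        logger.warning("constant image: BDM normalization degenerate, using all zeros")
        return np.zeros_like(bdm)
    return (bdm - lo) / (hi - lo)


def threshold_adjacency(nbdm: np.ndarray, tau: float) -> nx.Graph:
    """Build the pixel graph: edge ``pq`` iff ``1 - L_n(p, q) >= tau``, p != q.

    ``tau`` must lie in [0, 1]. The result is a simple graph (no self-loops,
    no parallel edges) on nodes ``0 .. mn-1``; the threshold is stored in
    ``g.graph["tau"]``. Edge count is non-increasing in ``tau``.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    A = adjacency_matrix(nbdm, tau)
    g = nx.from_numpy_array(A)
    for _, _, d in g.edges(data=True):
        d.clear()
    g.graph["tau"] = tau
    return g


def adjacency_matrix(nbdm: np.ndarray, tau: float) -> np.ndarray:
    """Boolean adjacency for the thresholding rule, zero diagonal."""
    nbdm = np.asarray(nbdm, dtype=float)
    A = (1.0 - nbdm) >= tau
    np.fill_diagonal(A, False)
    return A


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken toward the component
    containing the smallest vertex index. Node labels are preserved.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no components")
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        logger.info("graph has %d components; keeping the largest", len(comps))
    best = max(comps, key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(best).copy()
    sub.graph.update(g.graph)
    return sub


def pixel_index(row: int, col: int, n_cols: int) -> int:
    """Row-major pixel index of (row, col) in an image with ``n_cols`` columns."""
    return row * n_cols + col


def pixel_coords(index: int, n_cols: int) -> tuple[int, int]:
    """Inverse of :func:`pixel_index`."""
    return divmod(index, n_cols)


def image_to_graph(
    img: np.ndarray,
    tau: float = 0.95,
    resize: tuple[int, int] | None = (32, 32),
    keep_all_components: bool = False,
) -> nx.Graph:
    """Full chain: (resize) -> BDM -> normalize -> threshold (-> largest component)."""
    img = _validate_image(img)
    if resize is not None:
        tm = min(resize[0], img.shape[0])
        tn = min(resize[1], img.shape[1])
        img = downsample(img, tm, tn)
    g = threshold_adjacency(normalize_bdm(compute_bdm(img)), tau)
    if not keep_all_components:
        g = largest_component(g)
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    """Write one ``u v`` pair per line, 0-based vertex labels."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path) -> nx.Graph:
    """Read a whitespace-delimited edge list with integer vertex labels."""
    return nx.read_edgelist(path, nodetype=int, data=False)
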