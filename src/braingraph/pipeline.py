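"""End-to-end orchestration: images -> graphs -> indices -> normalized
features -> classification report.

The pipeline mirrors the package's module chain. `extract_features` maps
each labeled image through grayscale loading, area-averaged resizing, the
Brightness Distance Matrix, min-max normalization, threshold adjacency,
largest-component extraction, the six topological indices, and WS-ensemble
normalization, producing one feature row per image. `run_full` feeds the
feature table into stratified cross-validation of the configured model and
writes a JSON report carrying full reproducibility metadata (config hash,
seeds, package version).

WS normalization references are cached per (v, delta) within a run: images
whose pixel graphs have the same size and matched degree share one ensemble.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import FEATURE_NAMES, cross_validate
from .image_graph import (
    adjacency_matrix,
    compute_bdm,
    downsample,
    load_grayscale,
    normalize_bdm,
)
from .invariants import (
    IndexVector,
    largest_component_adjacency,
    stats_from_adjacency,
)
from .ws_model import WSParams, ensemble_indices, _matched_delta, normalize_index_vector

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "extract_features", "run_extract", "run_full"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    input_dir: str | None = None
    tau: float = 0.95
    resize: tuple | None = (32, 32)
    p_ref: float = 0.25
    ws_reps: int = 100
    model: str = "nn4"
    folds: int = 5
    epochs: int = 150
    seed: int = 0
    out_dir: str = "braingraph_out"
    keep_all_components: bool = False
    normalize: bool = True

    def to_dict(self, with_out_dir: bool = True) -> dict:
        d = asdict(self)
        if d["resize"] is not None:
            d["resize"] = list(d["resize"])
        if not with_out_dir:
            d.pop("out_dir")
        return d

    def param_dict(self) -> dict:
        """Parameters that determine the results (output location excluded)."""
        return self.to_dict(with_out_dir=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("resize") is not None:
            d["resize"] = tuple(d["resize"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.param_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _features_one_image(img, config: RunConfig, ref_cache: dict) -> dict:
    """Array-level fast path of the per-image chain (no networkx objects)."""
    if config.resize is not None:
        tm = min(config.resize[0], img.shape[0])
        tn = min(config.resize[1], img.shape[1])
        img = downsample(img, tm, tn)
    A = adjacency_matrix(normalize_bdm(compute_bdm(img)), config.tau)
    if not config.keep_all_components:
        A = largest_component_adjacency(A)
    stats = stats_from_adjacency(A)
    v = A.shape[0]
    n_edges = int(A.sum()) // 2
    raw = IndexVector(sz=stats["Sz"], abc=stats["ABC"], pi=stats["PI"],
                      mo=stats["MO"], ngg=stats["NGG"], w=stats["W"])
    vec = raw
    if config.normalize:
        delta = _matched_delta(2.0 * n_edges / v, v)
        key = (v, delta)
        if key not in ref_cache:
            # one deterministic stream per (v, delta) reference
            ref_seed = np.random.SeedSequence([config.seed, v, delta])
            ref_cache[key] = ensemble_indices(
                WSParams(v=v, delta=delta, p=config.p_ref),
                config.ws_reps,
                rng=np.random.default_rng(ref_seed),
            )
        vec = normalize_index_vector(raw, ref_cache[key])
    row = dict(zip(FEATURE_NAMES, vec.to_array().tolist()))
    row.update(v=v, edges=n_edges, C_cc=stats["C_cc"], L_apl=stats["L_apl"])
    return row


def extract_features(images, labels, config: RunConfig, image_ids=None) -> pd.DataFrame:
    """One feature row per image: six (normalized) indices plus graph stats.

    Per-image failures are logged and skipped; the run aborts if more than
    10% of images fail. The returned frame carries the run parameters in
    ``df.attrs["meta"]``.
    """
    if image_ids is None:
        image_ids = [f"img{i:05d}" for i in range(len(images))]
    ref_cache: dict = {}
    rows, failed = [], 0
    for img_id, img, label in zip(image_ids, images, labels):
        try:
            row = _features_one_image(np.asarray(img, dtype=float), config, ref_cache)
            row["image_id"] = img_id
            row["label"] = int(label)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the contract
            failed += 1
            logger.warning("image %s failed: %s", img_id, exc)
    total = len(images)
    if total == 0:
        raise ValueError("no input images")
    if failed > 0.1 * total:
        raise RuntimeError(f"{failed}/{total} images failed feature extraction")
    cols = ["image_id", *FEATURE_NAMES, "label", "v", "edges", "C_cc", "L_apl"]
    df = pd.DataFrame(rows)[cols]
    df.attrs["meta"] = {
        "tau": config.tau,
        "resize": list(config.resize) if config.resize else None,
        "p_ref": config.p_ref,
        "ws_reps": config.ws_reps,
        "normalize": config.normalize,
        "seed": config.seed,
        "version": __version__,
    }
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    """CSV with '# key: value' metadata header lines, 6-decimal rounding."""
    meta = df.attrs.get("meta", {})
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}: {meta[k]}\n")
        df.round(6).to_csv(fh, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _load_labeled_dir(input_dir) -> tuple:
    """Read images listed in ``labels.csv`` (columns filename, label)."""
    input_dir = Path(input_dir)
    manifest = input_dir / "labels.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no labels.csv manifest in {input_dir}")
    table = pd.read_csv(manifest)
    if table.empty:
        raise ValueError(f"empty manifest {manifest}")
    images, labels, ids = [], [], []
    for _, rec in table.iterrows():
        images.append(load_grayscale(input_dir / rec["filename"]))
        labels.append(int(rec["label"]))
        ids.append(str(rec["filename"]))
    return images, labels, ids


def run_extract(config: RunConfig, images=None, labels=None, image_ids=None):
    """Extract the feature table, writing ``features.csv`` to the output dir."""
    if images is None:
        images, labels, image_ids = _load_labeled_dir(config.input_dir)
    df = extract_features(images, labels, config, image_ids=image_ids)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_feature_csv(df, out_dir / "features.csv")
    return df


def run_full(config: RunConfig, images=None, labels=None, image_ids=None) -> dict:
    """Extract features, cross-validate the configured model, write a report.

    The report contains per-fold metrics and confusion matrices, the metric
    means, and enough metadata (config, hash, seeds, version) to re-run the
    pipeline exactly. Written to ``<out_dir>/report.json``.
    """
    df = run_extract(config, images=images, labels=labels, image_ids=image_ids)
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy()
    hyper = {"epochs": config.epochs} if config.model in ("nn2", "nn4") else None
    cv = cross_validate(
        X, y, model_kind=config.model, folds=config.folds, hyper=hyper, seed=config.seed
    )
    report = {
        "config": config.param_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_images": int(len(df)),
        "cv": cv.to_dict(),
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
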