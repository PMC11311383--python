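"""Domain datasets, YOLO-format label I/O, and image feature extraction.

A *domain* is one acquisition condition: a set of annotated images sharing an
origin, a cleaning status (washed / unwashed) and an acquisition mode (static
light box vs. dynamic production line).  Domains are compared with a kernel
two-sample distance (see :mod:`domainmatch.nsfe_mmd`), which operates on
per-image feature vectors.  This module owns the data model, the on-disk
dataset convention (``images/`` + ``labels/`` with YOLO text annotations) and
the feature map that turns a domain into an ``n x d`` matrix.

The kernel used downstream is the quadratic kernel ``k(x, y) = (x . y)^2``,
which compares the second-moment structure of the feature vectors.  The
default feature map is therefore a 32x32 grayscale pixel flattening with
joint z-scoring across all domains entering one comparison, so that the
kernel sees intensity *patterns* on a common scale rather than raw 8-bit
magnitudes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("domainmatch")

#: ITU-R 601 luma weights for RGB -> grayscale conversion.
LUMA_601 = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    """One labelled object: class index plus a normalized YOLO box.

    ``bbox`` is ``(cx, cy, w, h)`` as fractions of image width/height;
    ``class_id`` indexes the owning dataset's label space
    (0 = intact, 1 = cracked by default).
    """

    class_id: int
    bbox: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        # coerce numpy scalars so serialization round-trips cleanly
        object.__setattr__(self, "class_id", int(self.class_id))
        object.__setattr__(self, "bbox", tuple(float(v) for v in self.bbox))
        cx, cy, w, h = self.bbox
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError(f"box center out of [0,1]: {self.bbox}")
        if not (0.0 < w <= 1.0 and 0.0 < h <= 1.0):
            raise ValueError(f"box size out of (0,1]: {self.bbox}")
        if self.class_id < 0:
            raise ValueError(f"negative class_id {self.class_id}")

    def to_xyxy(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Denormalize to pixel-space corners, clipped to the image bounds."""
        cx, cy, w, h = self.bbox
        x0 = max((cx - w / 2) * width, 0.0)
        y0 = max((cy - h / 2) * height, 0.0)
        x1 = min((cx + w / 2) * width, float(width))
        y1 = min((cy + h / 2) * height, float(height))
        return x0, y0, x1, y1


@dataclass
class ImageRecord:
    """One image with its annotations.

    ``pixels`` is either an ``H x W`` / ``H x W x 3`` uint8 array or a path
    resolvable at access time through :func:`record_pixels`.
    """

    image_id: str
    pixels: np.ndarray | Path
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class DomainMetadata:
    """Acquisition metadata mirrored from the study design; "unknown" allowed."""

    origin: str = "unknown"
    washed: str = "unknown"       # "washed" | "unwashed" | "unknown"
    acquisition: str = "unknown"  # "static" | "dynamic" | "unknown"


@dataclass
class DomainDataset:
    """All images of one acquisition domain plus its label space and metadata."""

    domain_id: str
    records: list[ImageRecord]
    label_space: tuple[str, ...] = ("intact", "cracked")
    metadata: DomainMetadata = field(default_factory=DomainMetadata)

    def __post_init__(self) -> None:
        self.label_space = tuple(self.label_space)
        n_classes = len(self.label_space)
        for rec in self.records:
            for ann in rec.annotations:
                if ann.class_id >= n_classes:
                    raise ValueError(
                        f"record {rec.image_id}: class_id {ann.class_id} outside "
                        f"label space of size {n_classes}"
                    )

    @property
    def n_images(self) -> int:
        return len(self.records)

    @property
    def n_annotations(self) -> int:
        return sum(len(r.annotations) for r in self.records)


def record_pixels(record: ImageRecord) -> np.ndarray:
    """Return the pixel array for a record, loading from disk if needed."""
    if isinstance(record.pixels, np.ndarray):
        return record.pixels
    with Image.open(record.pixels) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


# ---------------------------------------------------------------------------
# YOLO-format dataset I/O
# ---------------------------------------------------------------------------

def _parse_label_line(line: str, n_classes: int) -> Annotation | None:
    """Parse one YOLO label line; return None (with a warning) if malformed."""
    fields = line.split()
    if len(fields) != 5:
        logger.warning("rejecting label line (need 5 fields): %r", line)
        return None
    try:
        class_id = int(fields[0])
        cx, cy, w, h = (float(v) for v in fields[1:])
    except ValueError:
        logger.warning("rejecting label line (non-numeric): %r", line)
        return None
    if class_id < 0 or class_id >= n_classes:
        logger.warning("rejecting label line (class %d out of range): %r", class_id, line)
        return None
    if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0 and 0.0 < w <= 1.0 and 0.0 < h <= 1.0):
        logger.warning("rejecting label line (box out of range): %r", line)
        return None
    return Annotation(class_id=class_id, bbox=(cx, cy, w, h))


def load_domain(
    root: str | Path,
    domain_id: str,
    label_space: Sequence[str] = ("intact", "cracked"),
    metadata: DomainMetadata | None = None,
    load_pixels: bool = False,
) -> DomainDataset:
    """Load a YOLO-layout dataset directory as one domain.

    ``root`` must contain an ``images/`` directory; labels are looked up in a
    sibling ``labels/`` directory by filename stem.  Images with no label file
    get an empty annotation list.  Malformed label lines are rejected with a
    warning; the record is kept.  Record order is lexicographic by filename.
    """
    root = Path(root)
    images_dir = root / "images"
    labels_dir = root / "labels"
    if not images_dir.is_dir():
        raise FileNotFoundError(f"{root}: no images/ directory")

    n_classes = len(label_space)
    records: list[ImageRecord] = []
    for img_path in sorted(images_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        annotations: list[Annotation] = []
        label_path = labels_dir / (img_path.stem + ".txt")
        if label_path.is_file():
            for line in label_path.read_text().splitlines():
                if not line.strip():
                    continue
                ann = _parse_label_line(line, n_classes)
                if ann is not None:
                    annotations.append(ann)
        pixels: np.ndarray | Path = img_path
        if load_pixels:
            with Image.open(img_path) as im:
                if im.mode not in ("L", "RGB"):
                    im = im.convert("RGB")
                pixels = np.asarray(im)
        records.append(ImageRecord(image_id=img_path.stem, pixels=pixels,
                                   annotations=annotations))
    return DomainDataset(
        domain_id=domain_id,
        records=records,
        label_space=tuple(label_space),
        metadata=metadata or DomainMetadata(),
    )


def load_domains_from_manifest(path: str | Path) -> list[DomainDataset]:
    """Load several domains from a YAML study manifest.

    Layout::

        label_space: [intact, cracked]
        domains:
          - {domain_id: d1, path: data/d1, origin: wuhan,
             washed: washed, acquisition: static}
          - ...

    Domain paths are resolved relative to the manifest file.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    label_space = tuple(cfg.get("label_space", ("intact", "cracked")))
    out = []
    for entry in cfg["domains"]:
        meta = DomainMetadata(
            origin=str(entry.get("origin", "unknown")),
            washed=str(entry.get("washed", "unknown")),
            acquisition=str(entry.get("acquisition", "unknown")),
        )
        root = Path(entry["path"])
        if not root.is_absolute():
            root = path.parent / root
        out.append(load_domain(root, entry["domain_id"], label_space, meta))
    return out


def save_domain(dataset: DomainDataset, out_dir: str | Path) -> Path:
    """Write a domain to disk in YOLO layout (``images/*.png`` + ``labels/*.txt``).

    Box coordinates are written with ``repr`` precision so that reloading
    reproduces the annotations bit-for-bit.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    labels_dir = out_dir / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    for rec in dataset.records:
        px = record_pixels(rec)
        Image.fromarray(px).save(images_dir / f"{rec.image_id}.png")
        lines = [
            f"{a.class_id} {a.bbox[0]!r} {a.bbox[1]!r} {a.bbox[2]!r} {a.bbox[3]!r}"
            for a in rec.annotations
        ]
        (labels_dir / f"{rec.image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    return out_dir


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

_FEATURE_HOOKS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_feature_hook(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a custom per-image feature function for ``custom_hook`` mode.

    ``fn`` maps an image array (uint8, grayscale or RGB) to a 1-D float vector
    of fixed length.
    """
    _FEATURE_HOOKS[name] = fn


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature map applied to every image of a domain.

    mode
        ``gray_pixels`` — grayscale, bilinear resize to ``resize``, row-major
        flatten (d = H' * W').  ``color_histogram`` — per-channel 32-bin
        normalized intensity histograms, concatenated (d = 96).
        ``custom_hook`` — a function registered via
        :func:`register_feature_hook` under ``hook_name``.
    standardize
        ``joint_scale`` (default) divides each feature by its std pooled over
        all domains entering one comparison — this makes quadratic-kernel
        magnitudes comparable across feature spaces while keeping the mean
        structure the kernel needs (see :func:`joint_scale`).
        ``joint_zscore`` additionally centers (see :func:`joint_standardize`);
        note that centering discards first-moment shift, to which the
        quadratic kernel is otherwise sensitive.  ``none`` leaves raw values.
    max_samples_per_domain
        Cap on images per domain (sampling without replacement, seeded);
        bounds the O(n^2) kernel sums.  ``None`` = unlimited.
    """

    mode: str = "gray_pixels"
    resize: tuple[int, int] = (32, 32)
    standardize: str = "joint_scale"
    max_samples_per_domain: int | None = 200
    seed: int = 0
    hook_name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gray_pixels", "color_histogram", "custom_hook"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.standardize not in ("joint_zscore", "joint_scale", "none"):
            raise ValueError(f"unknown standardize {self.standardize!r}")
        if min(self.resize) < 4:
            raise ValueError("resize dims must be >= 4")
        if self.max_samples_per_domain is not None and self.max_samples_per_domain < 1:
            raise ValueError("max_samples_per_domain must be positive or None")

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "mode": self.mode,
                "resize": list(self.resize),
                "standardize": self.standardize,
                "max_samples_per_domain": self.max_samples_per_domain,
                "seed": self.seed,
                "hook_name": self.hook_name,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """``n x d`` feature matrix for one domain; rows are sampled images."""

    domain_id: str
    values: np.ndarray
    config_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature matrix must be 2-D with n >= 1 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> grayscale via ITU-R 601 luma weights; pass grayscale through."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ LUMA_601
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    raise ValueError(f"unsupported image shape {arr.shape}")


def _gray_pixel_vector(image: np.ndarray, resize: tuple[int, int]) -> np.ndarray:
    gray = to_grayscale(image)
    if gray.shape != resize:
        gray = _sk_resize(gray, resize, order=1, anti_aliasing=False,
                          preserve_range=True)
    return gray.ravel(order="C")


def _color_histogram_vector(image: np.ndarray, bins: int = 32) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    chunks = []
    n_px = arr.shape[0] * arr.shape[1]
    for c in range(3):
        hist, _ = np.histogram(arr[:, :, c], bins=bins, range=(0, 256))
        chunks.append(hist / n_px)
    return np.concatenate(chunks)


def extract_features(
    dataset: DomainDataset,
    config: FeatureConfig,
    rng_seed: int | None = None,
) -> FeatureMatrix:
    """Turn a domain into an ``n x d`` feature matrix.

    Deterministic given (dataset content, config, seed).  When the dataset
    exceeds ``config.max_samples_per_domain``, images are subsampled without
    replacement using ``rng_seed`` (falls back to ``config.seed``); the
    sampled subset is kept in original record order.
    """
    if dataset.n_images == 0:
        raise ValueError(f"domain {dataset.domain_id!r} is empty")
    seed = config.seed if rng_seed is None else rng_seed

    records = dataset.records
    cap = config.max_samples_per_domain
    if cap is not None and len(records) > cap:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(records), size=cap, replace=False))
        records = [records[i] for i in idx]

    if config.mode == "custom_hook":
        if config.hook_name is None or config.hook_name not in _FEATURE_HOOKS:
            raise ValueError(
                f"custom_hook mode needs a registered hook (got {config.hook_name!r})"
            )
        fn = _FEATURE_HOOKS[config.hook_name]
        rows = [np.asarray(fn(record_pixels(r)), dtype=float).ravel() for r in records]
    elif config.mode == "gray_pixels":
        rows = [_gray_pixel_vector(record_pixels(r), config.resize) for r in records]
    else:
        rows = [_color_histogram_vector(record_pixels(r)) for r in records]

    return FeatureMatrix(
        domain_id=dataset.domain_id,
        values=np.vstack(rows),
        config_hash=config.content_hash(),
    )


def joint_standardize(matrices: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
    """Per-feature z-scoring with mean/std pooled over *all* input matrices.

    Uses the population standard deviation (``ddof=0``), matching the plug-in
    moment view of the quadratic kernel.  Features with pooled std 0 are set
    to 0.  All inputs must share a config hash and dimensionality; the hash is
    suffixed to record that standardization happened.
    """
    if not matrices:
        raise ValueError("no matrices to standardize")
    hashes = {m.config_hash for m in matrices}
    if len(hashes) != 1:
        raise ValueError(f"mixed feature config hashes: {sorted(hashes)}")
    dims = {m.d for m in matrices}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions: {sorted(dims)}")

    pooled = np.concatenate([m.values for m in matrices], axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0, ddof=0)
    nonzero = std > 0
    new_hash = matrices[0].config_hash + "+jz"

    out = []
    for m in matrices:
        vals = np.zeros_like(m.values)
        vals[:, nonzero] = (m.values[:, nonzero] - mean[nonzero]) / std[nonzero]
        out.append(FeatureMatrix(domain_id=m.domain_id, values=vals,
                                 config_hash=new_hash))
    return out


def joint_scale(matrices: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
    """Per-feature scaling by the std pooled over all input matrices, without
    centering.

    The quadratic kernel compares uncentered second moments; dividing by the
    pooled std equalizes feature magnitudes across feature spaces while
    preserving the mean structure that carries most of the domain shift
    (centering would make same-side shifts indistinguishable to a sign-blind
    kernel).  Features with pooled std 0 are set to 0.
    """
    if not matrices:
        raise ValueError("no matrices to standardize")
    hashes = {m.config_hash for m in matrices}
    if len(hashes) != 1:
        raise ValueError(f"mixed feature config hashes: {sorted(hashes)}")
    dims = {m.d for m in matrices}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions: {sorted(dims)}")

    pooled = np.concatenate([m.values for m in matrices], axis=0)
    std = pooled.std(axis=0, ddof=0)
    nonzero = std > 0
    new_hash = matrices[0].config_hash + "+js"

    out = []
    for m in matrices:
        vals = np.zeros_like(m.values)
        vals[:, nonzero] = m.values[:, nonzero] / std[nonzero]
        out.append(FeatureMatrix(domain_id=m.domain_id, values=vals,
                                 config_hash=new_hash))
    return out


def domain_feature_matrices(
    datasets: Sequence[DomainDataset],
    config: FeatureConfig | None = None,
    rng_seed: int | None = None,
) -> list[FeatureMatrix]:
    """Extract features for several domains under one config, then jointly
    standardize when the config asks for it.  This is the canonical entry
    point for preparing inputs to the pairwise domain-distance computation."""
    config = config or FeatureConfig()
    mats = [extract_features(ds, config, rng_seed=rng_seed) for ds in datasets]
    if config.standardize == "joint_zscore":
        mats = joint_standardize(mats)
    elif config.standardize == "joint_scale":
        mats = joint_scale(mats)
    return mats
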