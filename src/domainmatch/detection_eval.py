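"""Detection metrics, a lightweight proxy detector, and the multi-domain
training benchmark on an unknown test domain.

Metrics follow the standard object-detection recipe: predictions are greedily
matched to ground truth per class in descending confidence order (a match
needs IoU >= 0.5 and each ground-truth box is used at most once); the
precision-recall curve is integrated with all-point interpolation to give
per-class average precision (AP); mAP is the mean AP over classes with

    precision = TP / (TP + FP),   recall = TP / (TP + FN).

The proxy detector stands in for a full deep detector at desk scale: a
threshold-based egg-candidate segmentation (Otsu + connected components)
proposes boxes, and a logistic regression on intensity / gradient-magnitude
histograms of each candidate crop scores cracked vs. intact.  It is fully
deterministic and deliberately simple — its purpose is to expose the
*relative* ordering of training-set choices (single-domain vs. selected-pair
vs. all-domain training), not to approach deep-detector accuracy.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, binary_fill_holes
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops
from skimage.transform import resize as _sk_resize
from sklearn.ensemble import HistGradientBoostingClassifier

from .domain_matching import (SelectionResult, TrainingManifest,
                              emit_training_manifest, select_training_pair)
from .imageio_features import (Annotation, DomainDataset, FeatureConfig,
                               ImageRecord, _parse_label_line,
                               domain_feature_matrices, record_pixels,
                               to_grayscale)
from .nsfe_mmd import DistanceMatrix, pairwise_nsfe_mmd

logger = logging.getLogger("domainmatch")


# ---------------------------------------------------------------------------
# boxes and matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """One predicted box: normalized (cx, cy, w, h) + class + confidence."""

    image_id: str
    class_id: int
    bbox: tuple[float, float, float, float]
    confidence: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.confidence):
            raise ValueError("non-finite confidence")


def _to_corners(bbox: tuple[float, float, float, float]) -> tuple[float, float, float, float]:
    cx, cy, w, h = bbox
    return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2


def iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """Intersection over union of two (cx, cy, w, h) boxes, in [0, 1]."""
    ax0, ay0, ax1, ay1 = _to_corners(a)
    bx0, by0, bx1, by1 = _to_corners(b)
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


@dataclass
class PRCurve:
    """Precision-recall points ordered by descending confidence threshold."""

    confidences: np.ndarray  # descending
    tp_cum: np.ndarray
    fp_cum: np.ndarray
    n_pos: int

    @property
    def precision(self) -> np.ndarray:
        denom = self.tp_cum + self.fp_cum
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.tp_cum / denom, 0.0)

    @property
    def recall(self) -> np.ndarray:
        if self.n_pos == 0:
            return np.zeros_like(self.tp_cum, dtype=float)
        return self.tp_cum / self.n_pos

    @property
    def fn_at_end(self) -> int:
        matched = int(self.tp_cum[-1]) if len(self.tp_cum) else 0
        return self.n_pos - matched


def match_detections(
    detections: Sequence[Detection],
    truths: Mapping[str, Sequence[Annotation]],
    iou_threshold: float = 0.5,
    class_id: int | None = None,
) -> PRCurve:
    """Greedy confidence-ordered matching of detections to ground truth.

    A detection is a true positive if it attains IoU >= ``iou_threshold``
    with a not-yet-matched ground-truth box of the same class in its image
    (best IoU wins); otherwise a false positive.  Each ground truth is
    matched at most once; leftover truths are false negatives.  When
    ``class_id`` is given, both sides are restricted to that class first.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must be in (0, 1)")
    if class_id is not None:
        detections = [d for d in detections if d.class_id == class_id]
        truths = {
            img: [t for t in anns if t.class_id == class_id]
            for img, anns in truths.items()
        }
    n_pos = sum(len(anns) for anns in truths.values())

    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence,
                                  detections[i].image_id, i))
    matched: dict[str, set[int]] = {img: set() for img in truths}
    tp = np.zeros(len(order))
    fp = np.zeros(len(order))
    for rank, i in enumerate(order):
        det = detections[i]
        anns = truths.get(det.image_id, [])
        best_iou, best_j = 0.0, -1
        for j, ann in enumerate(anns):
            if ann.class_id != det.class_id:
                continue
            if j in matched.get(det.image_id, set()):
                continue
            v = iou(det.bbox, ann.bbox)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[rank] = 1
            matched.setdefault(det.image_id, set()).add(best_j)
        else:
            fp[rank] = 1
    return PRCurve(
        confidences=np.array([detections[i].confidence for i in order]),
        tp_cum=np.cumsum(tp),
        fp_cum=np.cumsum(fp),
        n_pos=n_pos,
    )


def average_precision(curve: PRCurve) -> float:
    """Area under the monotone precision envelope (all-point interpolation).

    Raises on a curve with zero ground-truth positives — AP is undefined
    there and the class must be excluded from mAP by the caller.
    """
    if curve.n_pos == 0:
        raise ValueError("AP undefined: no ground-truth positives")
    if len(curve.tp_cum) == 0:
        return 0.0
    recall = np.concatenate([[0.0], curve.recall])
    precision = np.concatenate([[0.0], curve.precision])
    # monotone nonincreasing envelope from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for k in range(1, len(recall)):
        ap += (recall[k] - recall[k - 1]) * envelope[k]
    return float(ap)


@dataclass
class MetricsReport:
    """Per-class AP at IoU 0.5 plus the headline operating-point numbers."""

    per_class_ap: dict[str, float]
    map50: float
    precision: float
    recall: float
    n_classes: int
    skipped_classes: list[str] = field(default_factory=list)


def evaluate(
    detections: Sequence[Detection],
    truths: Mapping[str, Sequence[Annotation]],
    label_space: Sequence[str] = ("intact", "cracked"),
    iou_threshold: float = 0.5,
) -> MetricsReport:
    """Full detector evaluation on one test set.

    mAP is the mean per-class AP at the given IoU threshold; classes with no
    ground truth are excluded with a logged notice.  Precision and recall are
    reported at the confidence-0 operating point (every detection counted).
    Zero-denominator cases (no detections) report precision 0, logged.
    """
    aps: dict[str, float] = {}
    skipped: list[str] = []
    for c, name in enumerate(label_space):
        curve = match_detections(detections, truths, iou_threshold, class_id=c)
        if curve.n_pos == 0:
            logger.info("class %r has no ground truth; excluded from mAP", name)
            skipped.append(name)
            continue
        aps[name] = average_precision(curve)
    map50 = float(np.mean(list(aps.values()))) if aps else 0.0

    pooled = match_detections(detections, truths, iou_threshold)
    tp = float(pooled.tp_cum[-1]) if len(pooled.tp_cum) else 0.0
    fp = float(pooled.fp_cum[-1]) if len(pooled.fp_cum) else 0.0
    fn = pooled.n_pos - tp
    if tp + fp == 0:
        logger.info("no detections: precision reported as 0 by convention")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / pooled.n_pos if pooled.n_pos > 0 else 0.0
    return MetricsReport(per_class_ap=aps, map50=map50, precision=precision,
                         recall=recall, n_classes=len(aps), skipped_classes=skipped)


# ---------------------------------------------------------------------------
# proxy detector
# ---------------------------------------------------------------------------

_PATCH = 40          # candidate crops resized to _PATCH x _PATCH
_HIST_BINS = 16
_MIN_REGION_AREA = 250
_MAX_REGION_FRAC = 0.55
_ERODE_ITERS = 4


def segment_candidates(gray: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Propose egg-candidate boxes (x0, y0, x1, y1) by intensity segmentation.

    Otsu threshold on grayscale -> fill holes (cracks punch holes in the
    foreground) -> erosion (splits thin blur bridges between adjacent
    objects) -> connected components -> area-filtered bounding boxes, padded
    to undo the erosion.  A near-uniform image yields no candidates.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.max() - gray.min() < 30:
        return []
    t = threshold_otsu(gray)
    fg = binary_fill_holes(gray > t)
    if fg.mean() > _MAX_REGION_FRAC + 0.2:
        return []
    fg = binary_erosion(fg, iterations=_ERODE_ITERS)
    boxes = []
    h, w = gray.shape
    min_area = max(_MIN_REGION_AREA - 12 * _ERODE_ITERS, 50)
    for region in regionprops(_cc_label(fg)):
        if region.area < min_area or region.area > _MAX_REGION_FRAC * h * w:
            continue
        y0, x0, y1, x1 = region.bbox
        pad = _ERODE_ITERS
        boxes.append((max(int(x0) - pad, 0), max(int(y0) - pad, 0),
                      min(int(x1) + pad, w), min(int(y1) + pad, h)))
    boxes.sort()
    return boxes


def _candidate_features(gray: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Fixed patch descriptor: intensity and gradient-magnitude histograms.

    Deliberately *not* contrast-normalized: the descriptor responds to the
    same appearance axes (shell brightness, background level, edge
    sharpness, dirt texture) that the domain distance measures, so
    training-set coverage of those axes is what decides test performance.
    """
    x0, y0, x1, y1 = box
    crop = gray[y0:y1, x0:x1] / 255.0
    crop = _sk_resize(crop, (_PATCH, _PATCH), order=1, anti_aliasing=True,
                      preserve_range=True)
    ih, _ = np.histogram(crop, bins=_HIST_BINS, range=(0.0, 1.0))
    grad = sobel(crop)
    gh, _ = np.histogram(grad, bins=_HIST_BINS, range=(0.0, 0.5))
    n = crop.size
    return np.concatenate([ih / n, gh / n])


def _box_to_norm(box: tuple[int, int, int, int], w: int, h: int) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = box
    return ((x0 + x1) / 2 / w, (y0 + y1) / 2 / h, (x1 - x0) / w, (y1 - y0) / h)


@dataclass
class ProxyDetector:
    """Segmentation + boosted-tree crack/intact classifier; deterministic.

    The classifier is a small depth-limited gradient-boosted tree ensemble:
    enough capacity to hold per-regime decision rules for each training
    domain simultaneously (the property that makes multi-domain training
    data useful), while remaining fully deterministic and desk-fast.
    """

    classifier: HistGradientBoostingClassifier | None
    constant_class: int | None = None  # set when training saw one class only
    iou_match: float = 0.5

    def detect_image(self, record: ImageRecord) -> list[Detection]:
        px = record_pixels(record)
        gray = to_grayscale(px)
        h, w = gray.shape
        dets = []
        for box in segment_candidates(gray):
            if self.constant_class is not None:
                cls, conf = self.constant_class, 0.95
            else:
                feats = _candidate_features(gray, box).reshape(1, -1)
                proba = self.classifier.predict_proba(feats)[0]
                k = int(np.argmax(proba))
                cls = int(self.classifier.classes_[k])
                conf = float(proba[k])
            dets.append(Detection(image_id=record.image_id, class_id=cls,
                                  bbox=_box_to_norm(box, w, h), confidence=conf))
        return dets

    def detect(self, records: Iterable[ImageRecord]) -> list[Detection]:
        out: list[Detection] = []
        for rec in records:
            out.extend(self.detect_image(rec))
        return out


def _manifest_records(manifest: TrainingManifest) -> list[ImageRecord]:
    """Reload a training manifest's images + labels as in-memory records."""
    n_classes = len(manifest.class_names)
    records = []
    for img_path, lbl_path in zip(manifest.train_image_paths, manifest.train_label_paths):
        annotations = []
        for line in Path(lbl_path).read_text().splitlines():
            if line.strip():
                ann = _parse_label_line(line, n_classes)
                if ann is not None:
                    annotations.append(ann)
        records.append(ImageRecord(image_id=Path(img_path).stem,
                                   pixels=Path(img_path), annotations=annotations))
    return records


def train_proxy_detector(
    manifest: TrainingManifest | Sequence[ImageRecord],
    seed: int = 0,
) -> ProxyDetector:
    """Fit the proxy detector on a merged training set.

    Candidate boxes are matched to ground-truth boxes (IoU >= 0.5); matched
    candidates become classifier training patches labelled with the matched
    class.  Deterministic given (manifest content, seed).
    """
    records = _manifest_records(manifest) if isinstance(manifest, TrainingManifest) else list(manifest)
    if not records:
        raise ValueError("empty training manifest")

    feats: list[np.ndarray] = []
    labels: list[int] = []
    n_candidates = 0
    for rec in records:
        gray = to_grayscale(record_pixels(rec))
        h, w = gray.shape
        for box in segment_candidates(gray):
            n_candidates += 1
            nbox = _box_to_norm(box, w, h)
            best_iou, best_cls = 0.0, None
            for ann in rec.annotations:
                v = iou(nbox, ann.bbox)
                if v > best_iou:
                    best_iou, best_cls = v, ann.class_id
            if best_cls is not None and best_iou >= 0.5:
                feats.append(_candidate_features(gray, box))
                labels.append(best_cls)
    if n_candidates == 0:
        raise RuntimeError(
            "no egg candidates found in training data: segmentation produced "
            f"nothing across {len(records)} images"
        )
    if not feats:
        raise RuntimeError("candidates found but none matched ground truth")

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        logger.info("training labels contain a single class %d; constant classifier", y[0])
        return ProxyDetector(classifier=None, constant_class=int(y[0]))

    X = np.vstack(feats)
    clf = HistGradientBoostingClassifier(
        max_iter=60, max_depth=3, learning_rate=0.2, random_state=seed,
    )
    clf.fit(X, y)
    return ProxyDetector(classifier=clf)


# ---------------------------------------------------------------------------
# SDT / MDT / ADT benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """One benchmark run: per-row metrics plus the selection provenance."""

    table: pd.DataFrame
    domain_ids: list[str]
    selected_pair: tuple[str, str] | None
    distance_matrix: DistanceMatrix | None

    def to_text_table(self) -> str:
        """Rendered comparison table: method, domain flags, P, R, mAP.5."""
        rows = []
        header = ["Method"] + self.domain_ids + ["Precision", "Recall", "mAP.5"]
        for _, r in self.table.iterrows():
            flags = ["x" if d in r["domains"] else " " for d in self.domain_ids]
            rows.append([r["method"], *flags,
                         f"{r['precision']:.3f}", f"{r['recall']:.3f}", f"{r['map50']:.3f}"])
        widths = [max(len(str(v)) for v in col) for col in zip(header, *rows)]
        fmt = "  ".join("{:<%d}" % w for w in widths)
        return "\n".join([fmt.format(*header)] + [fmt.format(*r) for r in rows])

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["domains"] = df["domains"].map(lambda ds: "+".join(ds))
        df.to_csv(path, index=False)

    def write_provenance(self, path: str | Path) -> None:
        payload = {
            "domain_ids": self.domain_ids,
            "selected_pair": list(self.selected_pair) if self.selected_pair else None,
            "rows": int(len(self.table)),
            "seeds": sorted(self.table["seed"].unique().tolist()),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_benchmark(
    known: Sequence[DomainDataset],
    unknown: DomainDataset,
    modes: Sequence[str] = ("SDT", "MDT_all_pairs", "ADT"),
    seeds: Sequence[int] = (0,),
    feature_config: FeatureConfig | None = None,
    estimator: str = "unbiased",
    workdir: str | Path | None = None,
) -> BenchmarkResult:
    """Compare training-set strategies on a withheld unknown domain.

    Modes: ``SDT`` (one row per known domain), ``MDT_all_pairs`` (one row per
    pair), ``MDT_selected`` (the NSFE-MMD maximum-distance pair), ``ADT``
    (all known domains).  For each row and seed the proxy detector is trained
    on the corresponding merged manifest and evaluated on the unknown domain.
    The unknown domain must not share an id with any training domain.
    """
    known_ids = [ds.domain_id for ds in known]
    if unknown.domain_id in known_ids:
        raise ValueError(
            f"contamination guard: unknown domain {unknown.domain_id!r} is a training domain"
        )
    if len(known) < 2:
        raise ValueError("benchmark needs at least 2 known domains")

    selected: SelectionResult | None = None
    dist: DistanceMatrix | None = None
    if "MDT_selected" in modes:
        mats = domain_feature_matrices(list(known), feature_config)
        dist = pairwise_nsfe_mmd(mats, estimator=estimator)
        selected = select_training_pair(dist, known)

    plans: list[tuple[str, tuple[str, ...]]] = []
    for mode in modes:
        if mode == "SDT":
            plans += [("SDT", (did,)) for did in known_ids]
        elif mode == "MDT_all_pairs":
            plans += [
                ("MDT", (known_ids[i], known_ids[j]))
                for i in range(len(known_ids))
                for j in range(i + 1, len(known_ids))
            ]
        elif mode == "MDT_selected":
            plans.append(("MDT_selected", selected.pair))
        elif mode == "ADT":
            plans.append(("ADT", tuple(known_ids)))
        else:
            raise ValueError(f"unknown benchmark mode {mode!r}")
    # drop duplicate domain sets, keeping the most specific label
    seen: dict[tuple[str, ...], str] = {}
    for method, domains in plans:
        key = tuple(sorted(domains))
        if key not in seen or method == "MDT_selected":
            seen[key] = method
    plans = [(m, k) for k, m in seen.items()]

    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(tmp_ctx.name) if tmp_ctx else Path(workdir)
    truths = {rec.image_id: rec.annotations for rec in unknown.records}

    rows = []
    try:
        for method, domains in plans:
            mode_tag = "SDT" if len(domains) == 1 else ("ADT" if len(domains) == len(known_ids) and len(known_ids) > 2 else "MDT")
            out_dir = base / ("_".join(domains))
            manifest = emit_training_manifest(list(domains), known, out_dir, mode=mode_tag)
            for seed in seeds:
                detector = train_proxy_detector(manifest, seed=seed)
                dets = detector.detect(unknown.records)
                report = evaluate(dets, truths, label_space=unknown.label_space)
                rows.append({
                    "method": method,
                    "domains": tuple(sorted(domains)),
                    "seed": seed,
                    "precision": report.precision,
                    "recall": report.recall,
                    "map50": report.map50,
                })
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()

    order = {"SDT": 0, "MDT": 1, "MDT_selected": 2, "ADT": 3}
    table = pd.DataFrame(rows).sort_values(
        by=["method", "domains", "seed"],
        key=lambda col: col.map(order) if col.name == "method" else col,
    ).reset_index(drop=True)
    return BenchmarkResult(
        table=table,
        domain_ids=known_ids,
        selected_pair=selected.pair if selected else None,
        distance_matrix=dist,
    )
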