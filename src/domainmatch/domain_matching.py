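"""Training-domain selection: pick the maximally distant, semantically
consistent domain pair and emit a merged YOLO training manifest.

The selection rule is the heart of the multi-domain training strategy:
training an off-the-shelf detector on the *most dissimilar* pair of known
domains (largest NSFE-MMD distance) pushes it toward domain-invariant
features and improves performance on acquisition domains never seen during
training.  Semantic consistency — all merged domains annotate the same
ordered class set — is a precondition: distance is only meaningful between
datasets labelling the same things.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

from .imageio_features import DomainDataset, save_domain
from .nsfe_mmd import DistanceMatrix

logger = logging.getLogger("domainmatch")

TrainingMode = Literal["SDT", "MDT", "ADT"]


@dataclass
class ConsistencyReport:
    """Per-domain label spaces and whether they all agree (ordered equality)."""

    passed: bool
    label_spaces: dict[str, tuple[str, ...]]
    mismatches: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"semantic consistency: {'PASS' if self.passed else 'FAIL'}"]
        for did, space in self.label_spaces.items():
            flag = " (mismatch)" if did in self.mismatches else ""
            lines.append(f"  {did}: {list(space)}{flag}")
        return "\n".join(lines)


def check_semantic_consistency(datasets: Sequence[DomainDataset]) -> ConsistencyReport:
    """Report whether all datasets share an identical *ordered* label space.

    The first dataset's label space is the reference; any domain deviating
    from it is listed as a mismatch.  Report-only — callers decide whether a
    failure is fatal.
    """
    if len(datasets) < 2:
        raise ValueError("semantic consistency needs at least 2 datasets")
    reference = datasets[0].label_space
    spaces = {ds.domain_id: ds.label_space for ds in datasets}
    mismatches = [did for did, space in spaces.items() if space != reference]
    return ConsistencyReport(passed=not mismatches, label_spaces=spaces,
                             mismatches=mismatches)


@dataclass
class SelectionResult:
    """The chosen maximum-distance training pair."""

    pair: tuple[str, str]
    distance: float  # normalized NSFE-MMD of the pair
    matrix_ref: DistanceMatrix
    consistency_report: ConsistencyReport


def select_training_pair(
    dist: DistanceMatrix,
    datasets: Sequence[DomainDataset],
) -> SelectionResult:
    """Select the domain pair with the largest normalized NSFE-MMD distance.

    All candidate domains must pass the semantic consistency check.  Ties are
    broken by the lexicographically smallest (id_i, id_j) pair.  Ranking is
    identical under raw and normalized distances (normalization is a positive
    scaling); normalized values are reported because they are comparable
    across feature spaces.
    """
    by_id = {ds.domain_id: ds for ds in datasets}
    missing = [did for did in dist.domain_ids if did not in by_id]
    if missing:
        raise ValueError(f"distance matrix covers unknown domains: {missing}")
    candidates = [by_id[did] for did in dist.domain_ids]

    report = check_semantic_consistency(candidates)
    if not report.passed:
        raise ValueError(f"semantic consistency failed:\n{report}")

    best: tuple[str, str] | None = None
    best_dist = -1.0
    for i, id_i in enumerate(dist.domain_ids):
        for j in range(i + 1, len(dist.domain_ids)):
            id_j = dist.domain_ids[j]
            pair = tuple(sorted((id_i, id_j)))
            d = float(dist.normalized[i, j])
            if d > best_dist or (d == best_dist and pair < best):
                best, best_dist = pair, d
    assert best is not None
    logger.info("selected training pair %s at normalized distance %.4f", best, best_dist)
    return SelectionResult(pair=best, distance=best_dist, matrix_ref=dist,
                           consistency_report=report)


@dataclass
class TrainingManifest:
    """A merged training set emitted on disk in YOLO dataset layout."""

    train_image_paths: list[Path]
    train_label_paths: list[Path]
    class_names: tuple[str, ...]
    source_domains: list[str]
    mode: TrainingMode
    config_path: Path | None = None

    @property
    def n_images(self) -> int:
        return len(self.train_image_paths)


def emit_training_manifest(
    selection: SelectionResult | Sequence[str],
    datasets: Sequence[DomainDataset],
    out_dir: str | Path,
    mode: TrainingMode | None = None,
) -> TrainingManifest:
    """Write the merged training set for the chosen domains to ``out_dir``.

    ``selection`` is either a :class:`SelectionResult` (MDT over the selected
    pair) or an explicit list of domain ids; ``mode`` tags the manifest as
    single-domain (SDT), pair (MDT) or all-domain (ADT) training.  Images and
    labels land in YOLO layout with filenames prefixed by their source domain
    (deterministic, lexicographic ordering); a ``dataset.yaml`` lists paths
    and class names.
    """
    by_id = {ds.domain_id: ds for ds in datasets}
    if isinstance(selection, SelectionResult):
        source_ids = list(selection.pair)
        mode = mode or "MDT"
    else:
        source_ids = list(selection)
        if mode is None:
            mode = "SDT" if len(source_ids) == 1 else ("ADT" if len(source_ids) == len(datasets) and len(source_ids) > 2 else "MDT")
    missing = [did for did in source_ids if did not in by_id]
    if missing:
        raise ValueError(f"domains not loaded: {missing}")

    chosen = [by_id[did] for did in sorted(source_ids)]
    report = check_semantic_consistency(chosen) if len(chosen) > 1 else None
    if report is not None and not report.passed:
        raise ValueError(f"cannot merge inconsistent domains:\n{report}")
    class_names = chosen[0].label_space

    out_dir = Path(out_dir)
    image_paths: list[Path] = []
    label_paths: list[Path] = []
    for ds in chosen:
        # prefix each record with its domain id to avoid stem collisions
        renamed = DomainDataset(
            domain_id=ds.domain_id,
            records=[
                type(rec)(image_id=f"{ds.domain_id}_{rec.image_id}",
                          pixels=rec.pixels, annotations=rec.annotations)
                for rec in ds.records
            ],
            label_space=ds.label_space,
            metadata=ds.metadata,
        )
        save_domain(renamed, out_dir)
        for rec in renamed.records:
            image_paths.append(out_dir / "images" / f"{rec.image_id}.png")
            label_paths.append(out_dir / "labels" / f"{rec.image_id}.txt")

    config_path = out_dir / "dataset.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "mode": mode,
                "source_domains": sorted(source_ids),
                "names": list(class_names),
                "train": [str(p) for p in image_paths],
            },
            fh,
            sort_keys=False,
        )
    missing_files = [p for p in image_paths + label_paths if not p.exists()]
    if missing_files:
        raise RuntimeError(f"manifest emission incomplete: {missing_files[:3]}")
    return TrainingManifest(
        train_image_paths=image_paths,
        train_label_paths=label_paths,
        class_names=class_names,
        source_domains=sorted(source_ids),
        mode=mode,
        config_path=config_path,
    )
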