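"""Synthetic multi-domain egg imagery with controllable domain-shift factors.

Real multi-domain egg data come from distinct origins and two acquisition
setups: a static light box photographing a single washed egg per frame, and
a dynamic multi-channel conveyor whose frames show 9-12 eggs with motion
blur and, for unwashed eggs, dirt on the shells.  This module renders a
stylized stand-in for those conditions: shaded elliptical eggs on a uniform
background, dark jagged crack polylines, dirt speckles, and directional
blur.  Every shift factor (egg color, background level, blur strength,
speckle rate, eggs per frame) is an explicit preset parameter, so domain
distance and training-set selection can be exercised end to end without any
real data.

Randomness is split into two seeded streams per image: a *geometry* stream
(egg count, placement, axes, orientation, crack occurrence and path, shell
color deviation) and a *texture* stream (background noise, dirt speckles).
Changing a continuous shift factor such as blur sigma or background level
therefore leaves the egg geometry of a given seed untouched — shifted
variants of one domain are pixel-aligned, which makes distance monotonicity
in the shift factor a testable property.

Cracks are drawn before blur is applied, so dynamic domains genuinely
degrade crack visibility, as motion blur does on a real conveyor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line

from .imageio_features import Annotation, DomainDataset, DomainMetadata, ImageRecord

LABEL_SPACE = ("intact", "cracked")
INTACT, CRACKED = 0, 1


@dataclass(frozen=True)
class DomainPreset:
    """All shift factors of one synthetic acquisition domain.

    eggs_per_image
        Inclusive (lo, hi) range; (1, 1) emulates the static single-egg box,
        (9, 12) the dynamic conveyor frames.
    washed
        Unwashed shells get dark dirt speckles at ``shell_speckle_rate``
        expected blobs per egg.
    motion_blur_sigma / motion_blur_jitter
        Sigma (pixels) of directional blur along the conveyor travel axis;
        0 = static acquisition.  ``jitter`` adds per-frame speed variation:
        each image's sigma is drawn uniformly from
        [max(0, sigma - jitter), sigma + jitter] (texture stream).
    background_level / background_jitter
        8-bit intensity of the (slightly noisy) background; ``jitter`` draws
        a per-frame uniform offset in [-jitter, +jitter] (texture stream),
        emulating exposure/illumination variation within one site.
    egg_color_mean / egg_color_std / egg_color_jitter
        Per-channel RGB shell color distribution — the main "origin" factor.
        ``jitter`` adds one per-frame uniform offset to all channels
        (batch-to-batch variety variation).
    crack_probability
        Each egg is independently cracked with this probability.
    """

    name: str
    eggs_per_image: tuple[int, int] = (1, 1)
    washed: bool = True
    motion_blur_sigma: float = 0.0
    motion_blur_jitter: float = 0.0
    background_level: int = 60
    background_jitter: float = 0.0
    egg_color_mean: tuple[float, float, float] = (182.0, 168.0, 140.0)
    egg_color_std: tuple[float, float, float] = (6.0, 6.0, 6.0)
    egg_color_jitter: float = 0.0
    crack_probability: float = 0.35
    shell_speckle_rate: float = 0.0
    image_size: tuple[int, int] = (320, 320)
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        lo, hi = self.eggs_per_image
        if lo < 1 or hi < lo:
            raise ValueError(f"bad eggs_per_image range {self.eggs_per_image}")
        if not (0.0 <= self.crack_probability <= 1.0):
            raise ValueError("crack_probability must be in [0, 1]")
        if self.motion_blur_sigma < 0 or self.motion_blur_jitter < 0:
            raise ValueError("motion blur sigma/jitter must be >= 0")

    @property
    def acquisition(self) -> str:
        return "static" if self.motion_blur_sigma == 0 else "dynamic"


@dataclass(frozen=True)
class MixturePreset:
    """An unknown-origin domain whose frames alternate between acquisition
    regimes.

    A previously unseen production site does not operate at a single point
    of the (background, shell color, blur) space: its lines run at
    different speeds and illumination.  Each frame is rendered from one of
    the component presets, chosen by a dedicated seeded stream, so the test
    domain *spans a range of conditions* rather than sitting at one point —
    which is what makes training-set coverage (rather than proximity of a
    single training domain) the deciding factor.
    """

    name: str
    components: tuple[DomainPreset, ...]
    weights: tuple[float, ...] | None = None
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        if self.weights is not None and len(self.weights) != len(self.components):
            raise ValueError("weights/components length mismatch")


# Catalog emulating the five-domain study design: three known training
# domains from one origin (static/washed single-egg; dynamic/unwashed;
# dynamic/washed) plus two withheld unknown-origin domains whose shell
# color, background and blur span a range of conditions unseen in training.
PRESETS: dict[str, "DomainPreset | MixturePreset"] = {
    "d1": DomainPreset(
        name="d1", origin="origin-a", eggs_per_image=(1, 1), washed=True,
        motion_blur_sigma=0.0, background_level=60,
        egg_color_mean=(182.0, 168.0, 140.0),
    ),
    "d2": DomainPreset(
        name="d2", origin="origin-a", eggs_per_image=(9, 12), washed=False,
        motion_blur_sigma=1.0, background_level=78,
        egg_color_mean=(176.0, 162.0, 136.0), shell_speckle_rate=5.0,
    ),
    "d3": DomainPreset(
        name="d3", origin="origin-a", eggs_per_image=(9, 12), washed=True,
        motion_blur_sigma=2.4, background_level=108,
        egg_color_mean=(198.0, 186.0, 162.0),
    ),
    "d4": MixturePreset(
        name="d4", origin="origin-b",
        components=(
            DomainPreset(
                name="d4", origin="origin-b", eggs_per_image=(9, 12),
                washed=True, motion_blur_sigma=0.5, motion_blur_jitter=0.3,
                background_level=64, background_jitter=6.0,
                egg_color_mean=(184.0, 172.0, 146.0), egg_color_jitter=6.0,
            ),
            DomainPreset(
                name="d4", origin="origin-b", eggs_per_image=(9, 12),
                washed=True, motion_blur_sigma=2.0, motion_blur_jitter=0.3,
                background_level=104, background_jitter=6.0,
                egg_color_mean=(196.0, 184.0, 158.0), egg_color_jitter=6.0,
            ),
        ),
    ),
    "d5": MixturePreset(
        name="d5", origin="origin-c",
        components=(
            DomainPreset(
                name="d5", origin="origin-c", eggs_per_image=(9, 12),
                washed=False, shell_speckle_rate=1.0,
                motion_blur_sigma=0.6, motion_blur_jitter=0.3,
                background_level=58, background_jitter=6.0,
                egg_color_mean=(156.0, 128.0, 102.0), egg_color_jitter=6.0,
            ),
            DomainPreset(
                name="d5", origin="origin-c", eggs_per_image=(9, 12),
                washed=False, shell_speckle_rate=1.0,
                motion_blur_sigma=1.9, motion_blur_jitter=0.3,
                background_level=96, background_jitter=6.0,
                egg_color_mean=(164.0, 136.0, 108.0), egg_color_jitter=6.0,
            ),
        ),
    ),
}

_MAX_PLACEMENT_ATTEMPTS = 300
_MAX_PLACEMENT_RESTARTS = 25


def _egg_axes(preset: DomainPreset, rng: np.random.Generator) -> tuple[float, float]:
    # semi-axes as a fraction of the short image side; conveyor eggs are small
    short = min(preset.image_size)
    if preset.eggs_per_image[1] > 1:
        a = rng.uniform(0.072, 0.088) * short
    else:
        a = rng.uniform(0.22, 0.27) * short
    b = a * rng.uniform(0.68, 0.76)
    return a, b


def _place_eggs(
    preset: DomainPreset, n_eggs: int, rng: np.random.Generator
) -> list[tuple[float, float, float, float, float]]:
    """Rejection-sample non-overlapping (cx, cy, a, b, theta) placements.

    Larger eggs are placed first; if a configuration deadlocks the whole
    image is re-sampled, up to a fixed restart cap.
    """
    h, w = preset.image_size
    axes = sorted((_egg_axes(preset, rng) for _ in range(n_eggs)), reverse=True)
    if any(min(h, w) - 2 * a - 5 <= 0 for a, _ in axes):
        raise ValueError(
            f"image {preset.image_size} too small for egg semi-axis {axes[0][0]:.0f}"
        )
    for _restart in range(_MAX_PLACEMENT_RESTARTS):
        placed: list[tuple[float, float, float, float, float]] = []
        for a, b in axes:
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                cx = rng.uniform(a + 2, w - a - 3)
                cy = rng.uniform(a + 2, h - a - 3)
                if all(
                    (cx - px) ** 2 + (cy - py) ** 2 > (a + pa + 4.0) ** 2
                    for px, py, pa, _, _ in placed
                ):
                    theta = rng.uniform(0, np.pi)
                    placed.append((cx, cy, a, b, theta))
                    break
            else:
                break
        if len(placed) == n_eggs:
            return placed
    raise ValueError(
        f"could not place {n_eggs} eggs of this size in {preset.image_size}"
    )


def _draw_crack(
    img: np.ndarray,
    mask: np.ndarray,
    cx: float, cy: float, a: float, b: float, theta: float,
    rng: np.random.Generator,
) -> None:
    """Dark jagged polyline across the shell; geometry-stream randomness."""
    h, w = img.shape[:2]
    # chord through the egg at a random orientation, inset from the rim
    phi = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    ends = []
    # endpoints stay well inside the rim so a thresholded egg remains one
    # connected region (the crack is a fillable interior hole, not a cut)
    for s in (-0.62, 0.62):
        ex = s * a * np.cos(phi)
        ey = s * b * np.sin(phi)
        ends.append((cx + ex * ct - ey * st, cy + ex * st + ey * ct))
    (x0, y0), (x1, y1) = ends
    n_seg = 6
    ts = np.linspace(0, 1, n_seg + 1)
    jitter = rng.normal(0, 0.06 * min(a, b) + 0.4, size=(n_seg + 1, 2))
    jitter[0] = jitter[-1] = 0
    pts = np.stack([
        np.clip(x0 + ts * (x1 - x0) + jitter[:, 0], 0, w - 1),
        np.clip(y0 + ts * (y1 - y0) + jitter[:, 1], 0, h - 1),
    ], axis=1)
    # stroke width scales with egg size so cracks stay visible when large
    # static-acquisition eggs are later downsampled to fixed patches
    width = max(3, int(round(0.12 * min(a, b))))
    offsets = [(dr, dc) for dr in range(width) for dc in range(width)]
    for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(int(round(ay)), int(round(ax)), int(round(by)), int(round(bx)))
        for dr, dc in offsets:
            r2 = np.clip(rr + dr - width // 2, 0, h - 1)
            c2 = np.clip(cc + dc - width // 2, 0, w - 1)
            keep = mask[r2, c2]
            img[r2[keep], c2[keep]] *= 0.30


def _draw_speckles(
    img: np.ndarray,
    mask: np.ndarray,
    cx: float, cy: float, a: float, b: float,
    rate: float,
    rng: np.random.Generator,
) -> None:
    """Dirt blobs on an unwashed shell; texture-stream randomness."""
    h, w = img.shape[:2]
    n = rng.poisson(rate)
    for _ in range(n):
        # sample a point well inside the ellipse's bounding circle
        r = np.sqrt(rng.uniform(0, 0.8))
        ang = rng.uniform(0, 2 * np.pi)
        sx = cx + r * a * np.cos(ang)
        sy = cy + r * b * np.sin(ang)
        radius = rng.uniform(1.0, 0.10 * min(a, b) + 1.5)
        rr, cc = _draw_disk((sy, sx), radius, shape=(h, w))
        keep = mask[rr, cc]
        img[rr[keep], cc[keep]] *= rng.uniform(0.35, 0.55)


def generate_egg_image(
    preset: DomainPreset,
    rng: np.random.Generator,
    rng_texture: np.random.Generator | None = None,
    image_id: str = "synthetic",
) -> ImageRecord:
    """Render one annotated frame under a preset.

    ``rng`` drives egg geometry (count, placement, shape, cracks, shell
    color); ``rng_texture`` (defaults to a stream spawned from ``rng``)
    drives background noise and dirt so that changing texture-only factors
    never perturbs geometry.  Annotation boxes are tight to each rendered
    ellipse *before* blur; class is cracked/intact.
    """
    if rng_texture is None:
        rng_texture = np.random.default_rng(rng.integers(2**31))
    h, w = preset.image_size
    lo, hi = preset.eggs_per_image
    n_eggs = int(rng.integers(lo, hi + 1))

    placements = _place_eggs(preset, n_eggs, rng)

    bg = float(preset.background_level)
    if preset.background_jitter > 0:
        bg += rng_texture.uniform(-preset.background_jitter, preset.background_jitter)
    color_offset = 0.0
    if preset.egg_color_jitter > 0:
        color_offset = rng_texture.uniform(-preset.egg_color_jitter,
                                           preset.egg_color_jitter)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = bg
    img += rng_texture.normal(0, 2.0, size=(h, w, 1))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    annotations: list[Annotation] = []
    mean = np.asarray(preset.egg_color_mean)
    std = np.asarray(preset.egg_color_std)

    for cx, cy, a, b, theta in placements:
        color = mean + std * rng.normal(size=3) + color_offset
        cracked = rng.uniform() < preset.crack_probability

        ct, st = np.cos(theta), np.sin(theta)
        dx, dy = xx - cx, yy - cy
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        r2 = u**2 + v**2
        mask = r2 <= 1.0
        shade = 0.70 + 0.30 * np.sqrt(np.clip(1.0 - r2, 0.0, 1.0))
        for c in range(3):
            img[:, :, c][mask] = color[c] * shade[mask]

        if cracked:
            _draw_crack(img, mask, cx, cy, a, b, theta, rng)
        if not preset.washed and preset.shell_speckle_rate > 0:
            _draw_speckles(img, mask, cx, cy, a, b,
                           preset.shell_speckle_rate, rng_texture)

        rows, cols = np.nonzero(mask)
        x0, x1 = cols.min(), cols.max() + 1
        y0, y1 = rows.min(), rows.max() + 1
        annotations.append(Annotation(
            class_id=CRACKED if cracked else INTACT,
            bbox=((x0 + x1) / 2 / w, (y0 + y1) / 2 / h, (x1 - x0) / w, (y1 - y0) / h),
        ))

    sigma = preset.motion_blur_sigma
    if preset.motion_blur_jitter > 0:
        lo = max(0.0, sigma - preset.motion_blur_jitter)
        sigma = rng_texture.uniform(lo, sigma + preset.motion_blur_jitter)
    if sigma > 0:
        img = gaussian_filter1d(img, sigma=sigma, axis=1)

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return ImageRecord(image_id=image_id, pixels=pixels, annotations=annotations)


def generate_domain(
    preset: "DomainPreset | MixturePreset", n_images: int, seed: int
) -> DomainDataset:
    """Generate a full synthetic domain; bit-identical for identical calls.

    Each image gets its own geometry and texture streams derived from
    (seed, image index), so images are independent and per-image geometry is
    invariant to texture-only preset changes.  For a :class:`MixturePreset`
    each frame's component is drawn from a third, dedicated stream, so the
    frame's geometry does not depend on which component was chosen.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    records = []
    for i in range(n_images):
        if isinstance(preset, MixturePreset):
            pick = np.random.default_rng([seed, i, 2])
            p = preset.components[pick.choice(len(preset.components),
                                              p=preset.weights)]
        else:
            p = preset
        rng_geom = np.random.default_rng([seed, i, 0])
        rng_tex = np.random.default_rng([seed, i, 1])
        records.append(
            generate_egg_image(p, rng_geom, rng_tex,
                               image_id=f"{preset.name}_{i:04d}")
        )
    if isinstance(preset, MixturePreset):
        washed_vals = {c.washed for c in preset.components}
        meta = DomainMetadata(
            origin=preset.origin,
            washed=("washed" if washed_vals == {True}
                    else "unwashed" if washed_vals == {False} else "mixed"),
            acquisition="dynamic" if any(c.motion_blur_sigma > 0 for c in preset.components) else "static",
        )
    else:
        meta = DomainMetadata(
            origin=preset.origin,
            washed="washed" if preset.washed else "unwashed",
            acquisition=preset.acquisition,
        )
    return DomainDataset(
        domain_id=preset.name,
        records=records,
        label_space=LABEL_SPACE,
        metadata=meta,
    )


def shifted_variants(
    base: DomainPreset, factor: str, values: Iterable[float]
) -> list[DomainPreset]:
    """Presets identical to ``base`` except for one shift factor.

    For additive factors, ``values`` are offsets applied to the base value
    (``background_level`` offsets the level, ``egg_color_mean`` offsets all
    channels); for ``motion_blur_sigma`` and ``shell_speckle_rate`` they are
    absolute.  Combined with the fixed-geometry seeding of
    :func:`generate_domain`, this yields pixel-aligned domain variants whose
    only difference is the stated factor.
    """
    out = []
    for i, val in enumerate(values):
        if factor == "motion_blur_sigma":
            p = replace(base, name=f"{base.name}_blur{i}", motion_blur_sigma=float(val))
        elif factor == "background_level":
            p = replace(base, name=f"{base.name}_bg{i}",
                        background_level=int(base.background_level + val))
        elif factor == "egg_color_mean":
            p = replace(base, name=f"{base.name}_col{i}",
                        egg_color_mean=tuple(c + float(val) for c in base.egg_color_mean))
        elif factor == "shell_speckle_rate":
            p = replace(base, name=f"{base.name}_spk{i}", washed=False,
                        shell_speckle_rate=float(val))
        else:
            raise ValueError(f"unknown shift factor {factor!r}")
        out.append(p)
    return out
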