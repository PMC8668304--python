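"""Synthetic brain-phantom generator.

Produces seeded 2-D MR-like slices with pixel-level ground truth so that
every downstream stage (filtering, skull stripping, segmentation, and
classification) can be exercised without any external dataset.  A phantom
consists of a dark background, a bright thin skull ring, a textured brain
disk separated from the ring by a dark CSF-like gap, an optional
hyperintense tumor blob strictly inside the brain, and additive Gaussian or
Rician noise.  All intensities live in [0, 1].

The generator is a pure function of (spec, seed): identical inputs give
bit-identical arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PlacementError, TumorsegError

MODALITIES = ("T1", "T2", "T1CE", "FLAIR")

# Per-modality multiplicative gain applied jointly to brain tissue and
# tumor intensity, emulating contrast differences (FLAIR/T1CE-style brighter
# lesions) without changing the tumor/tissue ordering.
_MODALITY_GAIN = {"T1": 0.92, "T2": 1.00, "T1CE": 1.05, "FLAIR": 1.08}

# Width in pixels of the dark CSF-like gap separating brain disk from skull
# ring; it is what lets intensity-based stripping detach the ring.
_CSF_GAP_PX = 3.0


@dataclass
class SkullRingSpec:
    inner_radius_frac: float = 0.82  # ring inner radius / (min(H,W)/2)
    thickness_px: float = 6.0
    intensity: float = 0.95


@dataclass
class BrainTissueSpec:
    mean_intensity: float = 0.45
    texture_sd: float = 0.04


@dataclass
class TumorSpec:
    present: bool = False
    center: tuple[float, float] | None = None  # (row, col); None = auto offset
    radius_px: float = 20.0
    intensity: float = 0.85
    softness_px: float = 1.5


@dataclass
class NoiseSpec:
    model: str = "gaussian"  # "gaussian" | "rician"
    sigma: float = 0.02


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic slice."""

    height: int = 240
    width: int = 240
    skull_ring: SkullRingSpec = field(default_factory=SkullRingSpec)
    brain_tissue: BrainTissueSpec = field(default_factory=BrainTissueSpec)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    modality_tag: str = "FLAIR"
    subject_id: str = "S000"
    seed: int = 0

    def brain_radius(self) -> float:
        """Radius of the brain disk (inner ring radius minus the CSF gap)."""
        half = min(self.height, self.width) / 2.0
        return self.skull_ring.inner_radius_frac * half - _CSF_GAP_PX

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomDataset:
    """Parallel lists of images, masks, image-level labels and metadata."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: list[str]  # "tumor" | "normal"
    subject_ids: list[str]
    modality_tags: list[str]
    specs: list[PhantomSpec] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.images)
        for name in ("masks", "labels", "subject_ids", "modality_tags"):
            if len(getattr(self, name)) != n:
                raise TumorsegError(f"parallel list {name!r} has wrong length")

    def __len__(self) -> int:
        return len(self.images)


def _disk_mask(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return d2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one phantom.

    Returns ``(image, mask, label)`` where ``image`` is float64 in [0, 1],
    ``mask`` is uint8 with 1 on tumor pixels, and ``label`` is ``"tumor"``
    iff the mask contains at least one tumor pixel.

    Raises
    ------
    TumorsegError
        If dimensions are below 32x32 or parameters are out of range.
    PlacementError
        If the requested tumor does not fit strictly inside the brain disk.
    """
    h, w = spec.height, spec.width
    if h < 32 or w < 32:
        raise TumorsegError(f"phantom dimensions must be >= 32x32, got {h}x{w}")
    if spec.modality_tag not in MODALITIES:
        raise TumorsegError(f"unknown modality {spec.modality_tag!r}; expected one of {MODALITIES}")
    if spec.tumor.present and spec.tumor.radius_px >= min(h, w) / 2:
        raise PlacementError("tumor radius must be < min(height, width)/2")

    rng = np.random.default_rng(spec.seed)
    gain = _MODALITY_GAIN[spec.modality_tag]
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    half = min(h, w) / 2.0
    r_ring_in = spec.skull_ring.inner_radius_frac * half
    r_brain = spec.brain_radius()

    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)

    image = np.zeros((h, w), dtype=np.float64)

    # Brain disk: mean intensity plus smooth random texture.
    brain = dist <= r_brain
    tissue = np.clip(spec.brain_tissue.mean_intensity * gain, 0.0, 1.0)
    image[brain] = tissue
    if spec.brain_tissue.texture_sd > 0:
        texture = rng.normal(0.0, 1.0, size=(h, w))
        texture = ndimage.gaussian_filter(texture, sigma=2.0)
        # renormalize so the smoothed field has the requested sd
        sd = texture.std()
        if sd > 0:
            texture *= spec.brain_tissue.texture_sd / sd
        image[brain] += texture[brain]

    # Skull ring: annulus outside the CSF gap.
    ring = (dist >= r_ring_in) & (dist <= r_ring_in + spec.skull_ring.thickness_px)
    image[ring] = spec.skull_ring.intensity

    # Tumor blob.
    mask = np.zeros((h, w), dtype=np.uint8)
    if spec.tumor.present:
        t = spec.tumor
        t_center = t.center
        if t_center is None:
            # default placement: offset toward upper-left, inside the brain
            off = max(2.0, 0.25 * r_brain)
            t_center = (center[0] - off * 0.6, center[1] - off)
        d_off = np.hypot(t_center[0] - center[0], t_center[1] - center[1])
        if d_off + t.radius_px >= r_brain:
            raise PlacementError(
                f"tumor (center offset {d_off:.1f}px, radius {t.radius_px:.1f}px) "
                f"does not fit strictly inside brain disk of radius {r_brain:.1f}px"
            )
        d_t = np.sqrt((rr - t_center[0]) ** 2 + (cc - t_center[1]) ** 2)
        mask[d_t <= t.radius_px] = 1
        t_int = np.clip(t.intensity * gain, 0.0, 1.0)
        if t.softness_px > 0:
            # smooth radial falloff at the rim; the mask stays a hard disk
            profile = np.clip((t.radius_px + t.softness_px - d_t) / t.softness_px, 0.0, 1.0)
        else:
            profile = (d_t <= t.radius_px).astype(np.float64)
        image = image * (1.0 - profile) + t_int * profile

    # Noise.
    sigma = spec.noise.sigma
    if sigma > 0:
        if spec.noise.model == "gaussian":
            image = image + rng.normal(0.0, sigma, size=(h, w))
        elif spec.noise.model == "rician":
            g1 = rng.normal(0.0, sigma, size=(h, w))
            g2 = rng.normal(0.0, sigma, size=(h, w))
            image = np.sqrt((image + g1) ** 2 + g2**2)
        else:
            raise TumorsegError(f"unknown noise model {spec.noise.model!r}")

    image = np.clip(image, 0.0, 1.0)
    label = "tumor" if mask.any() else "normal"
    return image, mask, label


def generate_dataset(
    n_images: int,
    tumor_fraction: float = 0.5,
    n_subjects: int = 4,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> PhantomDataset:
    """Generate a seeded dataset of phantoms with subject structure.

    Exactly ``round(n_images * tumor_fraction)`` images carry a tumor.
    Subjects are assigned round-robin so every subject owns at least one
    image when ``n_subjects <= n_images``; per-image tumor geometry and
    noise are jittered deterministically from ``seed``.
    """
    if n_images <= 0:
        raise TumorsegError(f"n_images must be positive, got {n_images}")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise TumorsegError(f"tumor_fraction must be in [0, 1], got {tumor_fraction}")
    if not 1 <= n_subjects <= n_images:
        raise TumorsegError("need 1 <= n_subjects <= n_images")
    base = base_spec if base_spec is not None else PhantomSpec()

    n_tumor = int(np.floor(n_images * tumor_fraction + 0.5))
    rng = np.random.default_rng(seed)
    # interleave tumor/normal deterministically, then shuffle once
    tumor_flags = np.zeros(n_images, dtype=bool)
    tumor_flags[:n_tumor] = True
    rng.shuffle(tumor_flags)

    r_brain = base.brain_radius()
    images, masks, labels, subjects, mods, specs = [], [], [], [], [], []
    for i in range(n_images):
        subject = f"sub-{i % n_subjects:03d}"
        modality = MODALITIES[int(rng.integers(len(MODALITIES)))]
        item_seed = int(rng.integers(0, 2**31 - 1))
        if tumor_flags[i]:
            radius = base.tumor.radius_px * float(rng.uniform(0.7, 1.3))
            radius = min(radius, 0.45 * r_brain)
            max_off = max(0.0, r_brain - radius - 2.0)
            ang = float(rng.uniform(0, 2 * np.pi))
            off = float(rng.uniform(0, max_off))
            cy = (base.height - 1) / 2.0 + off * np.sin(ang)
            cx = (base.width - 1) / 2.0 + off * np.cos(ang)
            tumor = dataclasses.replace(
                base.tumor, present=True, center=(cy, cx), radius_px=radius
            )
        else:
            tumor = dataclasses.replace(base.tumor, present=False)
        spec_i = base.replace(
            tumor=tumor, modality_tag=modality, subject_id=subject, seed=item_seed
        )
        img, msk, lab = generate_phantom(spec_i)
        images.append(img)
        masks.append(msk)
        labels.append(lab)
        subjects.append(subject)
        mods.append(modality)
        specs.append(spec_i)
    return PhantomDataset(images, masks, labels, subjects, mods, specs)
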