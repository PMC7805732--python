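"""Synthetic fixed-flexion knee-radiograph phantoms.

A phantom emulates the gross radiographic geometry of a knee X-ray: two
bright horizontal "bone" bands (femur above, tibia below) separated by a
darker joint-space gap whose width shrinks with increasing
Kellgren-Lawrence (KL) severity, optional osteophyte bumps intruding into
the gap at the joint margins, and additive clipped Gaussian noise.  The
geometry is deliberately simple — the phantoms exist so every downstream
stage (denoising, ROI search, segmentation, feature extraction, grading)
is testable end to end with known ground truth, not to look clinically
realistic.

Every generator output is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktransform

from .exceptions import InvalidArgumentError, KneegradeError
from .grades import KLGrade
from .roi import ROIBox

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_GAP_WIDTHS",
    "default_gap_width",
    "generate_phantom",
    "rotate_image",
    "scale_image",
    "smooth_blob",
    "generate_feature_dataset",
    "DEFAULT_COUNTS_PER_GRADE",
]

#: Default joint-gap width in pixels per KL grade at the default 256-row scale.
#: Strictly decreasing with severity; Severe may narrow to near bone-on-bone.
DEFAULT_GAP_WIDTHS = {
    KLGrade.NORMAL: 30,
    KLGrade.DOUBTFUL: 22,
    KLGrade.MILD: 14,
    KLGrade.MODERATE: 7,
    KLGrade.SEVERE: 2,
}

#: Default sample counts per grade for generated feature datasets; the
#: proportions mirror the expert annotation counts of the 2,000-image
#: reader study (651/528/279/260/282), scaled down by 10.
DEFAULT_COUNTS_PER_GRADE = (65, 53, 28, 26, 28)

_BONE, _GAP, _BACKGROUND = 200.0, 60.0, 30.0


def default_gap_width(grade: KLGrade | int | str) -> int:
    """Package-default joint-space width (pixels) for a KL grade."""
    return DEFAULT_GAP_WIDTHS[KLGrade.coerce(grade)]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic knee radiograph.

    ``image_size`` defaults to 256 x 465, preserving the 1,350 x 2,455
    aspect ratio of full-resolution clinical images at roughly 1/5 scale so
    single phantoms render in milliseconds.
    """

    grade: KLGrade
    image_size: tuple[int, int] = (256, 465)
    gap_width: int | None = None  # None -> default_gap_width(grade)
    osteophyte_count: int | None = None  # None -> grade ordinal
    noise_sd: float = 8.0
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        grade = KLGrade.coerce(self.grade)
        return replace(
            self,
            grade=grade,
            gap_width=default_gap_width(grade) if self.gap_width is None else self.gap_width,
            osteophyte_count=int(grade) if self.osteophyte_count is None else self.osteophyte_count,
        )


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    image: np.ndarray  # uint8, shape = spec.image_size
    true_roi: ROIBox
    true_mask: np.ndarray  # bool, shape = ROI crop; joint-space pixels
    grade: KLGrade
    gap_center_row: int


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom and its ground-truth ROI and joint-space mask.

    Construction: a smooth curved joint line (mimicking condyle roundness)
    splits the frame into femur and tibia bands of intensity ~200, separated
    by a gap of the requested width at intensity ~60 on a ~30 background
    margin; osteophytes are small bright half-discs eating into the gap;
    clipped Gaussian noise is added last.  Ground truth is taken from the
    noise-free labels.
    """
    spec = spec.resolved()
    rows, cols = spec.image_size
    if spec.gap_width >= rows:
        raise InvalidArgumentError("gap_width must be smaller than the image height")
    if spec.gap_width < 0 or spec.osteophyte_count < 0 or spec.noise_sd < 0:
        raise InvalidArgumentError("gap_width, osteophyte_count and noise_sd must be >= 0")

    rng = np.random.default_rng(spec.seed)
    gap_center = rows // 2 + int(rng.integers(-8, 9))

    # Smooth curved joint line: low-amplitude cosine, phase drawn per seed.
    x = np.arange(cols)
    amp = 2.0 + 2.0 * rng.random()
    phase = rng.uniform(0, 2 * np.pi)
    center_line = gap_center + amp * np.cos(2 * np.pi * x / cols + phase)

    half = spec.gap_width / 2.0
    yy = np.arange(rows)[:, None].astype(float)
    gap_top = center_line[None, :] - half
    gap_bot = center_line[None, :] + half
    margin = max(4, rows // 32)

    bone = ((yy >= margin) & (yy < gap_top)) | ((yy >= gap_bot) & (yy < rows - margin))
    gap = (yy >= gap_top) & (yy < gap_bot)

    # Osteophytes: bright half-discs protruding from a band edge into the gap.
    if spec.osteophyte_count and spec.gap_width > 0:
        radius = max(2, int(round(spec.gap_width * 0.4)))
        for _ in range(spec.osteophyte_count):
            cx = int(rng.integers(cols // 10, cols - cols // 10))
            top_side = bool(rng.integers(2))
            cy = float(center_line[cx] + (-half if top_side else half))
            dist2 = (yy - cy) ** 2 + (x[None, :] - cx) ** 2
            bump = dist2 <= radius**2
            bone |= bump & gap
            gap &= ~bump

    clean = np.full((rows, cols), _BACKGROUND)
    clean[gap] = _GAP
    clean[bone] = _BONE

    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    band = max(2, rows // 4)
    r0 = max(0, gap_center - band // 2)
    r1 = min(rows, r0 + band)
    roi = ROIBox(row_start=r1 - band, row_end=r1, col_start=0, col_end=cols)
    true_mask = gap[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    return PhantomTruth(
        image=image,
        true_roi=roi,
        true_mask=true_mask,
        grade=spec.grade,
        gap_center_row=gap_center,
    )


def rotate_image(image, angle_degrees: float) -> np.ndarray:
    """Rotate about the image center without cropping foreground.

    Multiples of 90 degrees are exact index permutations; any other angle
    uses bilinear interpolation on an enlarged canvas (zero padding).
    Output dtype matches the input for lossless rotations and is float64
    otherwise.
    """
    arr = np.asarray(image)
    if not np.isfinite(angle_degrees):
        raise InvalidArgumentError("rotation angle must be finite")
    angle = float(angle_degrees) % 360.0
    if angle == 0.0:
        return arr.copy()
    if angle % 90.0 == 0.0:
        return np.rot90(arr, k=int(angle // 90))
    out = sktransform.rotate(
        arr.astype(np.float64), angle, resize=True, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )
    return out


def scale_image(image, factor: float) -> np.ndarray:
    """Bilinear resampling to (rows*factor, cols*factor), rounded, min 1 px."""
    if not np.isfinite(factor) or factor <= 0:
        raise InvalidArgumentError("scale factor must be > 0")
    arr = np.asarray(image, dtype=np.float64)
    if factor == 1.0:
        return arr.copy()
    shape = tuple(max(1, int(round(s * factor))) for s in arr.shape)
    return sktransform.resize(
        arr, shape, order=1, mode="constant", cval=0.0, anti_aliasing=factor < 1.0,
        preserve_range=True,
    )


def smooth_blob(size: int = 256, seed: int = 7) -> np.ndarray:
    """An asymmetric, infinitely smooth test shape for invariance studies.

    A sum of three offset Gaussians of different widths and amplitudes: its
    second- and third-order moments are all comfortably non-zero (so
    relative comparisons of phi1..phi4 are well conditioned) while the
    profile is band-limited enough that bilinear rotation and rescaling add
    only tiny discretization error.  Values are floats in [0, 255].
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = size / 2.0
    components = [
        (180.0, c - size * 0.06, c - size * 0.04, size * 0.11),
        (120.0, c + size * 0.10, c + size * 0.03, size * 0.07),
        (90.0, c - size * 0.02, c + size * 0.12, size * 0.045),
    ]
    img = np.zeros((size, size))
    for amp, cy, cx, sigma in components:
        # tiny seeded jitter keeps distinct seeds from producing identical shapes
        cy += rng.normal(0, size * 0.002)
        cx += rng.normal(0, size * 0.002)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return np.clip(img, 0.0, 255.0)


def generate_feature_dataset(
    n_per_grade=None,
    seed: int = 0,
    noise_sd: float = 8.0,
    image_size: tuple[int, int] = (256, 465),
):
    """Labeled Hu feature vectors from end-to-end phantom processing.

    Each sample runs the full pipeline — phantom render, median denoising,
    ROI localization, active-contour segmentation, Hu invariants of the
    segmented joint-space region.  Deterministic given ``seed``.

    Parameters
    ----------
    n_per_grade : int (same count for all grades), sequence of five counts
        Normal..Severe, or None for the package default (proportions of the
        reader study's expert annotations scaled to 200 samples).

    Returns
    -------
    LabeledFeatureSet
    """
    from .classify import LabeledFeatureSet
    from .moments import features_from_region
    from .preprocessing import denoise
    from .roi import active_contour_segment, locate_joint_roi

    if n_per_grade is None:
        counts = DEFAULT_COUNTS_PER_GRADE
    elif np.isscalar(n_per_grade):
        counts = (int(n_per_grade),) * 5
    else:
        counts = tuple(int(c) for c in n_per_grade)
    if len(counts) != 5 or any(c < 1 for c in counts):
        raise InvalidArgumentError("need a count >= 1 for each of the five grades")

    rng = np.random.default_rng(seed)
    feats, labels, ids = [], [], []
    for grade, n in zip(KLGrade, counts):
        for i in range(n):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            spec = PhantomSpec(
                grade=grade, image_size=image_size, noise_sd=noise_sd, seed=sample_seed
            )
            stage = "generate_phantom"
            try:
                truth = generate_phantom(spec)
                stage = "denoise"
                clean = denoise(truth.image)
                stage = "locate_joint_roi"
                roi = locate_joint_roi(clean)
                stage = "active_contour_segment"
                seg = active_contour_segment(roi.crop(clean))
                stage = "features_from_region"
                hu = features_from_region(roi.crop(clean), seg.mask)
            except KneegradeError as exc:
                raise KneegradeError(
                    f"pipeline stage {stage!r} failed for grade={grade.label} "
                    f"seed={sample_seed}: {exc}"
                ) from exc
            feats.append(hu.as_array())
            labels.append(int(grade))
            ids.append(f"{grade.label.lower()}_{i:04d}_s{sample_seed}")
    return LabeledFeatureSet(features=np.array(feats), labels=np.array(labels), ids=ids)
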