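"""Geometric image moments and Hu's seven invariants.

For a grayscale image treated as a discrete intensity function f(x, y)
(x = column index, y = row index, both 0-based), the raw moment of order
p + q is

    m_pq = sum_x sum_y x**p * y**q * f(x, y)

Central moments mu_pq are taken about the intensity centroid
(xbar, ybar) = (m10/m00, m01/m00) and are translation-invariant.
Normalized central moments

    eta_pq = mu_pq / mu00**gamma,    gamma = (p + q)/2 + 1

add scale invariance, and Hu's seven polynomial combinations phi1..phi7 of
the second- and third-order eta are additionally invariant to in-plane
rotation.  phi7 is the skew invariant: it changes sign under reflection,
which lets it distinguish mirror images.

Intensities are used as-is (no binarization or rescaling); pixels outside a
region mask contribute zero.  All moments here are restricted to order
p + q <= 3, which is all Hu's invariants need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError, InvalidStateError

__all__ = [
    "MomentSet",
    "HuVector",
    "raw_moment",
    "centroid",
    "central_moment",
    "compute_moments",
    "normalized_moments",
    "hu_vector",
    "hu_from_image",
    "features_from_region",
]

#: (p, q) pairs with p + q <= 3
_ORDERS = [(p, q) for p in range(4) for q in range(4) if p + q <= 3]
#: (p, q) pairs entering the normalized moments (order 2 and 3)
_ETA_ORDERS = [(p, q) for (p, q) in _ORDERS if p + q in (2, 3)]


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidArgumentError("image must be a non-empty 2-D array")
    if np.any(arr < 0):
        raise InvalidArgumentError("image intensities must be non-negative")
    return arr


def raw_moment(image, p: int, q: int) -> float:
    """Raw moment m_pq = sum x^p y^q f(x,y), x = column, y = row."""
    if p < 0 or q < 0:
        raise InvalidArgumentError(f"moment orders must be >= 0, got ({p}, {q})")
    arr = _as_image(image)
    rows, cols = arr.shape
    x = np.arange(cols, dtype=np.float64) ** p  # column coordinate
    y = np.arange(rows, dtype=np.float64) ** q  # row coordinate
    return float(y @ arr @ x)


def centroid(image) -> tuple[float, float]:
    """Intensity centroid (xbar, ybar) = (m10/m00, m01/m00)."""
    arr = _as_image(image)
    m00 = float(arr.sum())
    if m00 <= 0:
        raise DegenerateInputError("centroid undefined: image has zero mass (m00 = 0)")
    return raw_moment(arr, 1, 0) / m00, raw_moment(arr, 0, 1) / m00


def central_moment(image, p: int, q: int) -> float:
    """Central moment mu_pq about the intensity centroid."""
    if p < 0 or q < 0:
        raise InvalidArgumentError(f"moment orders must be >= 0, got ({p}, {q})")
    arr = _as_image(image)
    xbar, ybar = centroid(arr)
    rows, cols = arr.shape
    dx = (np.arange(cols, dtype=np.float64) - xbar) ** p
    dy = (np.arange(rows, dtype=np.float64) - ybar) ** q
    return float(dy @ arr @ dx)


@dataclass
class MomentSet:
    """All moments of one image region up to order 3.

    Attributes
    ----------
    raw, central : dict mapping (p, q) -> value for p + q <= 3
    centroid : (xbar, ybar) in (column, row) pixel coordinates
    normalized : dict mapping (p, q) -> eta_pq for p + q in {2, 3};
        empty until :func:`normalized_moments` fills it
    gamma : dict mapping (p, q) -> (p + q)/2 + 1
    """

    raw: dict[tuple[int, int], float]
    centroid: tuple[float, float]
    central: dict[tuple[int, int], float]
    normalized: dict[tuple[int, int], float] = field(default_factory=dict)
    gamma: dict[tuple[int, int], float] = field(
        default_factory=lambda: {pq: (pq[0] + pq[1]) / 2 + 1 for pq in _ETA_ORDERS}
    )


def compute_moments(image) -> MomentSet:
    """Compute raw and central moments (p + q <= 3) in one pass."""
    arr = _as_image(image)
    m00 = float(arr.sum())
    if m00 <= 0:
        raise DegenerateInputError("moments undefined: image has zero mass (m00 = 0)")
    rows, cols = arr.shape
    xs = np.arange(cols, dtype=np.float64)
    ys = np.arange(rows, dtype=np.float64)
    raw = {(p, q): float((ys**q) @ arr @ (xs**p)) for (p, q) in _ORDERS}
    xbar = raw[(1, 0)] / m00
    ybar = raw[(0, 1)] / m00
    central = {
        (p, q): float(((ys - ybar) ** q) @ arr @ ((xs - xbar) ** p))
        for (p, q) in _ORDERS
    }
    return MomentSet(raw=raw, centroid=(xbar, ybar), central=central)


def normalized_moments(momset: MomentSet) -> MomentSet:
    """Fill ``momset.normalized`` with eta_pq = mu_pq / mu00**gamma."""
    mu00 = momset.central[(0, 0)]
    if mu00 <= 0:
        raise DegenerateInputError("normalized moments undefined: mu00 = 0")
    momset.normalized = {
        pq: momset.central[pq] / mu00 ** momset.gamma[pq] for pq in _ETA_ORDERS
    }
    return momset


@dataclass(frozen=True)
class HuVector:
    """Hu's seven rotation/scale/translation invariants for one region."""

    phi1: float
    phi2: float
    phi3: float
    phi4: float
    phi5: float
    phi6: float
    phi7: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.phi1, self.phi2, self.phi3, self.phi4, self.phi5, self.phi6, self.phi7]
        )

    @classmethod
    def from_array(cls, values) -> "HuVector":
        v = np.asarray(values, dtype=np.float64)
        if v.shape != (7,):
            raise InvalidArgumentError("a HuVector needs exactly 7 components")
        return cls(*map(float, v))


def hu_vector(momset: MomentSet) -> HuVector:
    """Hu's seven invariants from a MomentSet with normalized moments filled."""
    if not momset.normalized:
        raise InvalidStateError(
            "normalized moments missing; call normalized_moments() first"
        )
    n = momset.normalized
    n20, n02, n11 = n[(2, 0)], n[(0, 2)], n[(1, 1)]
    n30, n03, n21, n12 = n[(3, 0)], n[(0, 3)], n[(2, 1)], n[(1, 2)]

    a = n30 + n12
    b = n21 + n03
    c = n30 - 3 * n12
    d = 3 * n21 - n03

    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11**2
    phi3 = c**2 + d**2
    phi4 = a**2 + b**2
    phi5 = c * a * (a**2 - 3 * b**2) + d * b * (3 * a**2 - b**2)
    phi6 = (n20 - n02) * (a**2 - b**2) + 4 * n11 * a * b
    phi7 = d * a * (a**2 - 3 * b**2) - c * b * (3 * a**2 - b**2)
    return HuVector(phi1, phi2, phi3, phi4, phi5, phi6, phi7)


def hu_from_image(image) -> HuVector:
    """Full chain: raw -> central -> normalized moments -> Hu invariants."""
    return hu_vector(normalized_moments(compute_moments(image)))


def features_from_region(image, mask) -> HuVector:
    """Hu invariants of a masked region: pixels outside ``mask`` contribute 0.

    A single-pixel region is degenerate but defined: every central moment of
    order >= 1 vanishes, so all seven invariants are exactly zero.
    """
    arr = _as_image(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise InvalidArgumentError("mask and image shapes differ")
    if not m.any():
        raise DegenerateInputError("empty mask: no region to describe")
    return hu_from_image(np.where(m, arr, 0.0))
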