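"""Intensity-PDF energy fields and symmetry-filtered tumor segmentation.

A grayscale image is read as a one-dimensional intensity distribution
embedded in the two-dimensional pixel frame: each nonzero pixel is a point
mass M_n (its normalized intensity) at the pixel center.  The potential
term is then the discrete Coulomb sum u = sum_n M_n / |r - r_n| (self term
excluded), computed as an FFT convolution with a 1/r kernel; the kinetic
term is the 2-D KEDF of the normalized intensity, and the Lagrangian field
L = gamma^2 t - gamma u exposes tissue components as deep basins with
distinguishable co-edges.

Components are cut out of L by two-class (intra-class variance minimizing)
thresholding and connected-component labeling.  Healthy anatomy in axial
brain images is quasi-symmetric about the mid-sagittal line, so components
whose mirror image lands on other components (or that straddle the axis)
are discarded; what survives is the asymmetric lesion candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .boundaries import ScalarField, grid_coulomb
from .errors import DegenerateImageError, InvalidParameterError
from .functionals import WeightedPointSet, adaptive_gamma, energy_fields, kedf

__all__ = [
    "IntensityImage",
    "ComponentMask",
    "intensity_pdf",
    "image_energy_fields",
    "segment_components",
    "symmetry_filter",
    "find_symmetry_axis",
    "segment_mri",
]


@dataclass
class IntensityImage:
    """Nonnegative pixel intensities with their total mass."""

    pixels: np.ndarray
    total_mass: float = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidParameterError("image must be 2-D")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("pixel intensities must be nonnegative")
        if self.total_mass is None:
            self.total_mass = float(self.pixels.sum())
        if not self.total_mass > 0:
            raise DegenerateImageError("image carries no intensity mass")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ComponentMask:
    """One segmented component: boolean mask, id, area and centroid."""

    mask: np.ndarray
    id: int
    area: int = None
    centroid: tuple = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area is None:
            self.area = int(self.mask.sum())
        if self.area < 1:
            raise InvalidParameterError("component mask is empty")
        if self.centroid is None:
            rows, cols = np.nonzero(self.mask)
            self.centroid = (float(rows.mean()), float(cols.mean()))


def intensity_pdf(image: IntensityImage) -> WeightedPointSet:
    """Point masses at the (row, col) centers of nonzero pixels, normalized."""
    rows, cols = np.nonzero(image.pixels)
    if rows.size == 0:
        raise DegenerateImageError("all-zero image")
    coords = np.stack([rows, cols], axis=1).astype(float)
    weights = image.pixels[rows, cols] / image.total_mass
    return WeightedPointSet(coords, weights, quadrature="grid")


def _direct_coulomb(mass):
    """O(P^2) pairwise reference sum; for validation on small images."""
    h, w = mass.shape
    rows, cols = np.nonzero(mass)
    vals = mass[rows, cols]
    out = np.zeros_like(mass)
    rr, cc = np.mgrid[0:h, 0:w]
    for r, c, v in zip(rows, cols, vals):
        d = np.hypot(rr - r, cc - c)
        with np.errstate(divide="ignore"):
            out += np.where(d > 0, v / d, 0.0)
    return out


def image_energy_fields(image: IntensityImage, use_fft: bool = True):
    """Hamiltonian and Lagrangian fields of an intensity image.

    Returns ``(H, L)`` as :class:`ScalarField` objects on the pixel grid
    (origin (0, 0), unit spacing).  The FFT and direct convolution paths
    agree to 1e-6 relative.
    """
    mass = image.pixels / image.total_mass
    u = grid_coulomb(mass, (1.0, 1.0)) if use_fft else _direct_coulomb(mass)
    t = kedf(mass.ravel(), 2).reshape(mass.shape)
    gamma = adaptive_gamma(t.ravel(), u.ravel(), mass.ravel())
    fv = energy_fields(t.ravel(), u.ravel(), gamma)
    origin, spacing = (0.0, 0.0), (1.0, 1.0)
    hf = ScalarField(origin, spacing, fv.H.reshape(mass.shape), name="H", gamma=gamma)
    lf = ScalarField(origin, spacing, fv.L.reshape(mass.shape), name="L", gamma=gamma)
    return hf, lf


def segment_components(
    lfield: ScalarField, intensity: np.ndarray | None = None, min_area: int = 20
):
    """Two-class threshold of L, connected components, small ones dropped.

    The threshold minimizes intra-class variance of the L histogram (Otsu's
    rule).  The foreground is the sublevel side; when the original intensity
    is supplied the side is chosen as the one holding the densest decile of
    intensity mass.  Returns a (possibly empty) list of disjoint
    :class:`ComponentMask`.
    """
    values = lfield.values if isinstance(lfield, ScalarField) else np.asarray(lfield)
    if float(values.max() - values.min()) == 0.0:
        return []
    thr = threshold_otsu(values)
    fg = values <= thr
    if intensity is not None:
        intensity = np.asarray(intensity, dtype=float)
        flat = intensity.ravel()
        order = np.argsort(flat)[::-1]
        csum = np.cumsum(flat[order])
        top = np.zeros(flat.size, dtype=bool)
        top[order[: max(1, int(np.searchsorted(csum, 0.1 * flat.sum()) + 1))]] = True
        top = top.reshape(intensity.shape)
        if (fg & top).sum() < (~fg & top).sum():
            fg = ~fg
    if not fg.any():
        return []
    lbl = measure.label(fg, connectivity=2)
    comps = []
    cid = 0
    for region in measure.regionprops(lbl):
        if region.area < min_area:
            continue
        comps.append(ComponentMask(mask=lbl == region.label, id=cid))
        cid += 1
    return comps


def find_symmetry_axis(pixels: np.ndarray, search_frac: float = 0.1):
    """Column position of the best left-right mirror axis.

    Maximizes the normalized cross-correlation between the image and its
    horizontally flipped copy over integer shifts within ``search_frac`` of
    the width; the axis is at column ``(W - 1 + shift) / 2``.
    """
    pixels = np.asarray(pixels, dtype=float)
    w = pixels.shape[1]
    flipped = pixels[:, ::-1]
    max_shift = max(1, int(round(search_frac * w)))
    best_shift, best_score = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            a, b = pixels[:, s:], flipped[:, : w - s]
        else:
            a, b = pixels[:, :s], flipped[:, -s:]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        score = float((a * b).sum() / denom) if denom > 0 else -np.inf
        if score > best_score:
            best_score, best_shift = score, s
    return (w - 1 + best_shift) / 2.0


def _mirror_mask(mask: np.ndarray, axis_col: float):
    rows, cols = np.nonzero(mask)
    mcols = np.rint(2.0 * axis_col - cols).astype(int)
    keep = (mcols >= 0) & (mcols < mask.shape[1])
    out = np.zeros_like(mask)
    out[rows[keep], mcols[keep]] = True
    return out


def symmetry_filter(
    components,
    image: IntensityImage,
    overlap_thresh: float = 0.3,
    axis_col: float | None = None,
):
    """Drop components whose mirror image lands on segmented anatomy.

    The mirror axis is found from the image itself unless given.  A
    component is removed when the fraction of its mirrored mask covered by
    the union of all component masks reaches ``overlap_thresh`` — this
    removes both mirrored pairs and components that straddle the axis,
    leaving the asymmetric candidates.
    """
    if not components:
        raise InvalidParameterError("symmetry_filter needs at least one component")
    if axis_col is None:
        axis_col = find_symmetry_axis(image.pixels)
    union = np.zeros(image.shape, dtype=bool)
    for comp in components:
        union |= comp.mask
    kept = []
    for comp in components:
        mirrored = _mirror_mask(comp.mask, axis_col)
        m_area = int(mirrored.sum())
        overlap = int((mirrored & union).sum()) / max(1, m_area)
        if overlap < overlap_thresh:
            kept.append(comp)
    return kept


def segment_mri(
    pixels: np.ndarray,
    min_area: int = 20,
    overlap_thresh: float = 0.3,
    use_fft: bool = True,
):
    """Full pipeline: intensity PDF -> energy fields -> components -> symmetry
    filter.  Returns a dict with the fields, all components and the
    surviving tumor candidates."""
    image = IntensityImage(np.asarray(pixels, dtype=float))
    hfield, lfield = image_energy_fields(image, use_fft=use_fft)
    comps = segment_components(lfield, intensity=image.pixels, min_area=min_area)
    candidates = (
        symmetry_filter(comps, image, overlap_thresh=overlap_thresh) if comps else []
    )
    return {
        "image": image,
        "H": hfield,
        "L": lfield,
        "components": comps,
        "candidates": candidates,
    }
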