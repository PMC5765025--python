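"""Three-channel volume segmentation for Brainbow-style microscopy.

Neurons in a Brainbow preparation express stochastic mixtures of red, green
and blue fluorophores, so each cell lives on one of a small set of *color
routes*: a nonempty proper subset of {R, G, B} acts as the principal
channel set (2^3 - 2 = 6 mixed routes), or a single channel is extracted
on its own with the others actively suppressed (3 pure routes).

Per route, voxels are kept by a +-3n dB band around each channel's
full-width-at-half-maximum level (half the channel maximum): principal
channels must reach above the -3n dB offset; auxiliary channels must stay
below a +3n dB bound (mixed routes) or below a -3n dB suppression level
(pure routes, used to cut crosstalk such as green bleeding into a pure-red
cell).  A level-1 Haar wavelet keeps the per-slice approximation band,
halving the lateral resolution and denoising.  The digitized foreground is
scored by the Hamiltonian field built from a 26-neighborhood potential and
a local-density kinetic term; thresholding H at the valley between the two
histogram modes removes sparse background voxels, and 26-connected
components of what remains are the candidate neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pywt
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter1d
from skimage import measure

from .errors import DegenerateChannelError, InvalidParameterError
from .functionals import adaptive_gamma, kedf

__all__ = [
    "ColorVolume",
    "ChannelRoute",
    "LabeledVolume",
    "enumerate_channel_routes",
    "fwhm_filter",
    "wavelet_preprocess",
    "local_pedf_26",
    "segment_hdf",
]

_CHANNELS = ("R", "G", "B")


@dataclass
class ColorVolume:
    """Three co-registered nonnegative channel stacks (Z, H, W)."""

    channels: dict
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if set(self.channels) != set(_CHANNELS):
            raise InvalidParameterError("channels must be exactly R, G, B")
        arrs = {}
        shape = None
        for c in _CHANNELS:
            a = np.asarray(self.channels[c], dtype=float)
            if a.ndim != 3:
                raise InvalidParameterError(f"channel {c} must be 3-D (Z, H, W)")
            if np.any(a < 0):
                raise InvalidParameterError(f"channel {c} has negative intensities")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise InvalidParameterError("all channels must share one shape")
            arrs[c] = a
        self.channels = arrs
        if np.any(np.asarray(self.voxel_size, dtype=float) <= 0):
            raise InvalidParameterError("voxel size must be positive")

    @classmethod
    def from_array(cls, rgb: np.ndarray, voxel_size=(1.0, 1.0, 1.0)):
        """Build from a (Z, H, W, 3) array."""
        rgb = np.asarray(rgb, dtype=float)
        if rgb.ndim != 4 or rgb.shape[-1] != 3:
            raise InvalidParameterError("expected a (Z, H, W, 3) array")
        return cls(
            channels={c: rgb[..., k] for k, c in enumerate(_CHANNELS)},
            voxel_size=tuple(voxel_size),
        )

    @property
    def shape(self):
        return self.channels["R"].shape


@dataclass(frozen=True)
class ChannelRoute:
    """A color-mixing route: principal channel subset plus its kind."""

    principal: tuple
    kind: str

    def __post_init__(self):
        principal = tuple(sorted(self.principal, key=_CHANNELS.index))
        object.__setattr__(self, "principal", principal)
        if not principal or any(c not in _CHANNELS for c in principal):
            raise InvalidParameterError("principal must be a nonempty subset of RGB")
        if self.kind not in ("mixed", "pure"):
            raise InvalidParameterError("kind must be 'mixed' or 'pure'")
        if self.kind == "mixed" and len(principal) == 3:
            raise InvalidParameterError("mixed route cannot use all three channels")
        if self.kind == "pure" and len(principal) != 1:
            raise InvalidParameterError("pure route extracts a single channel")


@dataclass
class LabeledVolume:
    """Integer component labels (0 = background) and their count."""

    labels: np.ndarray
    n_labels: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > self.n_labels:
            raise InvalidParameterError("labels must lie in [0, n_labels]")


def enumerate_channel_routes():
    """All color routes: 6 mixed (nonempty proper subsets of RGB) and 3 pure,
    in canonical order (smaller principal sets first, R < G < B)."""
    mixed = [
        ChannelRoute(principal=combo, kind="mixed")
        for size in (1, 2)
        for combo in combinations(_CHANNELS, size)
    ]
    pure = [ChannelRoute(principal=(c,), kind="pure") for c in _CHANNELS]
    return mixed, pure


def fwhm_filter(volume: ColorVolume, principal, n: int, pure: bool = False):
    """Boolean voxel mask of the +-3n dB-FWHM band filter for one route.

    Per channel the FWHM reference level is half its maximum.  Mixed
    routes: principal channels pass at or above ``L * 10**(-3n/10)``,
    auxiliary channels at or below the bound ``L * 10**(+3n/10)``.  Pure
    extraction inhibits crosstalk instead: auxiliaries must stay below the
    suppression level ``L * 10**(-3n/10)`` while the principal keeps the
    plain -3 dB FWHM band edge (a deeper principal cut would admit noise,
    the opposite of what the suppression is for).  The mask is the
    conjunction over all three channels.
    """
    principal = tuple(principal)
    if not principal:
        raise InvalidParameterError("principal channel set must be nonempty")
    if int(n) != n or n < 1:
        raise InvalidParameterError("n must be a positive integer")
    mask = np.ones(volume.shape, dtype=bool)
    for c in _CHANNELS:
        ch = volume.channels[c]
        level = 0.5 * float(ch.max())
        if c in principal:
            if level <= 0:
                raise DegenerateChannelError(f"principal channel {c} is all zero")
            n_p = 1 if pure else n
            mask &= ch >= level * 10.0 ** (-0.3 * n_p)
        else:
            sign = -1.0 if pure else +1.0
            mask &= ch <= level * 10.0 ** (sign * 0.3 * n)
    return mask


def _haar_approx(plane: np.ndarray):
    h, w = plane.shape
    if h % 2 or w % 2:
        plane = np.pad(plane, ((0, h % 2), (0, w % 2)), mode="edge")
    ca, _ = pywt.dwt2(plane, "haar", mode="periodization")
    return ca / 2.0


def wavelet_preprocess(volume: ColorVolume) -> ColorVolume:
    """Level-1 Haar approximation per slice and channel.

    Keeps only the approximation band, rescaled by 1/2 so a constant input
    keeps its value; lateral dimensions shrink to ceil(size/2) (odd sizes
    are edge-padded first), depth is untouched.
    """
    z, h, w = volume.shape
    if h < 2 or w < 2:
        raise InvalidParameterError("lateral dimensions must be at least 2")
    out = {}
    for c in _CHANNELS:
        stack = [_haar_approx(volume.channels[c][k]) for k in range(z)]
        out[c] = np.stack(stack, axis=0)
    vz, vy, vx = volume.voxel_size
    return ColorVolume(channels=out, voxel_size=(vz, 2 * vy, 2 * vx))


_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def local_pedf_26(mass: np.ndarray) -> np.ndarray:
    """26-neighborhood potential: sum of neighbor mass / offset distance.

    Distances are 1, sqrt(2) or sqrt(3) by offset type; out-of-bounds
    neighbors contribute nothing and the voxel itself is excluded.
    """
    mass = np.asarray(mass, dtype=float)
    if mass.ndim != 3:
        raise InvalidParameterError("mass must be a 3-D array")
    if np.any(mass < 0):
        raise InvalidParameterError("mass must be nonnegative")
    z, y, x = mass.shape
    padded = np.pad(mass, 1)
    out = np.zeros_like(mass)
    for dz, dy, dx in _OFFSETS_26:
        d = np.sqrt(dz * dz + dy * dy + dx * dx)
        out += padded[1 + dz : 1 + dz + z, 1 + dy : 1 + dy + y, 1 + dx : 1 + dx + x] / d
    return out


def _density_kernel_26():
    """Normalized local-density kernel: center weight 1/2, the 26 neighbors
    share the other 1/2 proportionally to 1/distance."""
    kern = np.zeros((3, 3, 3))
    inv = {off: 1.0 / np.sqrt(sum(o * o for o in off)) for off in _OFFSETS_26}
    total = sum(inv.values())
    for (dz, dy, dx), v in inv.items():
        kern[dz + 1, dy + 1, dx + 1] = 0.5 * v / total
    kern[1, 1, 1] = 0.5
    return kern


def _valley_threshold(
    vals: np.ndarray, bins: int = 64, smooth: float = 2.0, min_height: float = 0.05
):
    """Level of the valley separating the low-H background mode from the
    structured high-H modes of a histogram.

    Significant modes are smoothed-histogram local maxima taller than
    ``min_height`` times the tallest; the threshold is the deepest point
    between the outermost significant modes (tube interiors produce a comb
    of high-H modes, so pairing by height would compare two pieces of the
    same structure).  Falls back to the median when the histogram is
    unimodal.
    """
    vals = np.asarray(vals, dtype=float)
    if vals.size < 8 or np.ptp(vals) == 0:
        return float(np.median(vals))
    hist, edges = np.histogram(vals, bins=bins)
    sm = gaussian_filter1d(hist.astype(float), smooth)
    interior = (sm[1:-1] > sm[:-2]) & (sm[1:-1] >= sm[2:])
    peaks = np.nonzero(interior)[0] + 1
    if sm[0] > sm[1]:
        peaks = np.r_[0, peaks]
    if sm[-1] > sm[-2]:
        peaks = np.r_[peaks, len(sm) - 1]
    peaks = peaks[sm[peaks] >= min_height * sm.max()]
    if peaks.size < 2:
        return float(np.median(vals))
    lo_pk, hi_pk = int(peaks[0]), int(peaks[-1])
    if hi_pk - lo_pk < 2:
        return float(np.median(vals))
    valley = lo_pk + int(np.argmin(sm[lo_pk : hi_pk + 1]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))


def segment_hdf(
    volume: ColorVolume,
    route: ChannelRoute,
    n: int | None = None,
    min_voxels: int = 10,
) -> LabeledVolume:
    """Segment one color route into labeled candidate neurons.

    Pipeline: Haar preprocessing, the route's FWHM band filter (pure routes
    default to n = 3, mixed to n = 1), binary digitization, 26-neighborhood
    potential and local-density kinetic term, adaptive gamma over the
    foreground, histogram-valley threshold on the Hamiltonian values, and
    26-connected labeling with small components dropped.
    """
    if n is None:
        n = 3 if route.kind == "pure" else 1
    shrunk = wavelet_preprocess(volume)
    try:
        mask = fwhm_filter(shrunk, route.principal, n, pure=route.kind == "pure")
    except DegenerateChannelError:
        mask = np.zeros(shrunk.shape, dtype=bool)
    if not mask.any():
        return LabeledVolume(labels=np.zeros(shrunk.shape, dtype=np.int32), n_labels=0)
    massarr = mask.astype(float)
    u = local_pedf_26(massarr)
    dens = ndi.convolve(massarr, _density_kernel_26(), mode="constant")
    t = kedf(dens.ravel(), 3).reshape(dens.shape)
    fg_t, fg_u = t[mask], u[mask]
    gamma = adaptive_gamma(fg_t, fg_u, np.full(fg_t.size, 1.0 / fg_t.size))
    hvals = gamma**2 * t + gamma * u
    thr = _valley_threshold(hvals[mask])
    keep = mask & (hvals >= thr)
    lbl = measure.label(keep, connectivity=3)
    out = np.zeros(lbl.shape, dtype=np.int32)
    nid = 0
    for region in measure.regionprops(lbl):
        if region.area < min_voxels:
            continue
        nid += 1
        out[lbl == region.label] = nid
    return LabeledVolume(labels=out, n_labels=nid)
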