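"""Deterministic synthetic fixtures for every pipeline.

Three generators emulate the statistical structure of the problems the
package targets without any external data:

* planar Gaussian-mixture cases — a lone cluster, an unequal-weight
  three-cluster mixture (30/30/40%), and a collinear triple whose
  peak-to-peak distance shrinks from 10 sigma down to sigma, driving the
  clusters from well separated to severely mixed;
* a quasi-symmetric axial "MRI" phantom — a skull-like ring and a mirrored
  ellipse pair symmetric about the vertical midline plus one off-axis
  bright lesion, with mirror-symmetric additive noise so the only
  asymmetry is the lesion itself;
* a three-channel tube phantom — tubes wander along the long axis in
  distinct color routes (two two-channel mixtures and one pure channel, the
  classic yellow/cyan/red combination), blurred and overlaid with a
  Gaussian noise floor plus sparse saturated per-channel speckles of the
  kind real detectors produce.

Every generator is a pure function of its arguments: the same seed yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .brainbow import ChannelRoute, ColorVolume
from .errors import InvalidParameterError

__all__ = [
    "FixtureBundle",
    "gen_gaussian_case",
    "gen_mri_phantom",
    "gen_brainbow_phantom",
]


@dataclass
class FixtureBundle:
    """A generated dataset plus the ground truth that produced it."""

    data: object
    truth: dict = field(default_factory=dict)
    seed: int = 0


_CASE_SEPARATIONS = {3: 10.0, 4: 6.0, 5: 3.0, 6: 1.0}


def gen_gaussian_case(
    case_id: int, n_points: int = 600, sigma: float = 1.0, seed: int = 0
) -> FixtureBundle:
    """Planar Gaussian-mixture cases 1-6.

    Case 1: one isotropic Gaussian.  Case 2: three isotropic Gaussians with
    weights (0.30, 0.30, 0.40) at mutual distance 6 sigma (equilateral
    triangle).  Cases 3-6: three equal-weight Gaussians on a line with
    peak-to-peak distances 10, 6, 3 and 1 sigma.
    """
    if case_id not in range(1, 7):
        raise InvalidParameterError(f"case_id must be 1..6, got {case_id}")
    if n_points < 1 or sigma <= 0:
        raise InvalidParameterError("need n_points >= 1 and sigma > 0")
    rng = np.random.default_rng(int(seed))
    if case_id == 1:
        weights = np.array([1.0])
        centers = np.array([[0.0, 0.0]])
    elif case_id == 2:
        weights = np.array([0.30, 0.30, 0.40])
        side = 6.0 * sigma
        centers = np.array(
            [[0.0, 0.0], [side, 0.0], [side / 2.0, side * np.sqrt(3) / 2.0]]
        )
    else:
        weights = np.full(3, 1.0 / 3.0)
        d = _CASE_SEPARATIONS[case_id] * sigma
        centers = np.array([[0.0, 0.0], [d, 0.0], [2.0 * d, 0.0]])
    counts = rng.multinomial(int(n_points), weights)
    chunks, labels = [], []
    for j, c in enumerate(counts):
        if c:
            chunks.append(rng.normal(centers[j], sigma, size=(c, 2)))
            labels.append(np.full(c, j, dtype=int))
    data = np.concatenate(chunks, axis=0)
    labels = np.concatenate(labels)
    perm = rng.permutation(int(n_points))
    return FixtureBundle(
        data=data[perm],
        truth={
            "labels": labels[perm],
            "weights": weights,
            "centers": centers,
            "sigma": float(sigma),
            "case_id": int(case_id),
        },
        seed=int(seed),
    )


def _ellipse_mask(shape, center, semi):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def gen_mri_phantom(height: int = 246, width: int = 205, seed: int = 0) -> FixtureBundle:
    """Quasi-symmetric brain-slice phantom with one asymmetric lesion.

    The skull ring and the ellipse pair are exactly mirror-symmetric about
    the vertical midline, as is the additive noise (sigma = 2% of peak), so
    masking out the lesion leaves a perfectly symmetric image.  The truth is
    the lesion mask.
    """
    if height < 64 or width < 64:
        raise InvalidParameterError("phantom needs height, width >= 64")
    rng = np.random.default_rng(int(seed))
    shape = (height, width)
    axis = (width - 1) / 2.0
    cy = height / 2.0
    img = np.zeros(shape)

    outer = _ellipse_mask(shape, (cy, axis), (0.45 * height, 0.43 * width))
    inner = _ellipse_mask(shape, (cy, axis), (0.40 * height, 0.38 * width))
    img[outer & ~inner] = 0.85

    dy, dx = 0.10 * height, 0.15 * width
    for side in (-1, 1):
        pair = _ellipse_mask(
            shape, (cy - dy, axis + side * dx), (0.07 * height, 0.05 * width)
        )
        img[pair] = 0.80

    lesion_center = (cy + 0.15 * height, axis + 0.19 * width)
    lesion = _ellipse_mask(shape, lesion_center, (0.045 * height, 0.05 * width))
    img_sym = img.copy()
    img[lesion] = 1.0

    noise = rng.normal(0.0, 0.02, size=shape)
    half = (width + 1) // 2
    noise[:, width - half :] = noise[:, :half][:, ::-1]
    img = np.clip(img + noise, 0.0, None)
    img_sym = np.clip(img_sym + noise, 0.0, None)

    return FixtureBundle(
        data=img,
        truth={
            "lesion_mask": lesion,
            "axis_col": axis,
            "symmetric_image": img_sym,
        },
        seed=int(seed),
    )


_DEFAULT_TUBE_ROUTES = [
    ChannelRoute(principal=("R", "G"), kind="mixed"),   # yellow
    ChannelRoute(principal=("G", "B"), kind="mixed"),   # cyan
    ChannelRoute(principal=("R",), kind="pure"),        # pure red
]


def gen_brainbow_phantom(
    shape=(16, 64, 64),
    n_tubes: int = 3,
    seed: int = 0,
    tube_radius: float = 3.0,
    blur_sigma: float = 0.6,
    noise_sigma: float = 0.02,
    speckle_frac: float = 0.004,
) -> FixtureBundle:
    """Tube phantom in distinct color routes with realistic noise.

    Each tube runs along the x axis in its own lateral lane with a smooth
    random wobble, painted as a tube of ``tube_radius`` voxels, blurred, and
    colored by its route's mixing vector (principal channels 1.0, others
    0.05).  Sparse saturated speckles (amplitude 2, per channel independent)
    emulate detector artifacts; they are what the Hamiltonian-threshold step
    of the segmentation exists to remove.  Truth holds per-tube voxel
    labels and routes.
    """
    if n_tubes < 1:
        raise InvalidParameterError("n_tubes must be >= 1")
    z_dim, y_dim, x_dim = shape
    rng = np.random.default_rng(int(seed))
    routes = [_DEFAULT_TUBE_ROUTES[k % len(_DEFAULT_TUBE_ROUTES)] for k in range(n_tubes)]

    zz, yy = np.mgrid[0:z_dim, 0:y_dim]
    labels = np.zeros(shape, dtype=np.int32)
    channels = {c: np.zeros(shape) for c in ("R", "G", "B")}
    lane = y_dim / (n_tubes + 1)
    for k in range(n_tubes):
        y0 = lane * (k + 1)
        z0 = z_dim / 2.0
        wob_y = np.clip(np.cumsum(rng.normal(0, 0.6, x_dim)), -lane / 2 + tube_radius,
                        lane / 2 - tube_radius)
        wob_z = np.clip(np.cumsum(rng.normal(0, 0.3, x_dim)),
                        -z_dim / 2 + tube_radius + 1, z_dim / 2 - tube_radius - 1)
        tube = np.zeros(shape, dtype=bool)
        for x in range(2, x_dim - 2):
            cy, cz = y0 + wob_y[x], z0 + wob_z[x]
            disk = (yy - cy) ** 2 + (zz - cz) ** 2 <= tube_radius**2
            tube[:, :, x] |= disk
        labels[tube] = k + 1
        intensity = gaussian_filter(tube.astype(float), blur_sigma)
        for c in ("R", "G", "B"):
            gain = 1.0 if c in routes[k].principal else 0.05
            channels[c] += gain * intensity

    n_vox = int(np.prod(shape))
    for c in ("R", "G", "B"):
        channels[c] += rng.normal(0.0, noise_sigma, size=shape)
    # saturated speckles with stochastic colors: each artifact is hot in a
    # random nonempty channel subset, like debris aggregating random
    # fluorophore combinations
    n_speck = max(1, int(speckle_frac * n_vox))
    flat_idx = rng.choice(n_vox, size=n_speck, replace=False)
    spots = np.unravel_index(flat_idx, shape)
    hot = rng.integers(1, 8, size=n_speck)  # bitmask over (R, G, B)
    for bit, c in enumerate(("R", "G", "B")):
        sel = (hot >> bit) & 1 == 1
        channels[c][tuple(s[sel] for s in spots)] = 2.0
    for c in ("R", "G", "B"):
        channels[c] = np.clip(channels[c], 0.0, None)

    volume = ColorVolume(channels=channels)
    return FixtureBundle(
        data=volume,
        truth={"labels": labels, "routes": routes, "n_tubes": int(n_tubes)},
        seed=int(seed),
    )
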