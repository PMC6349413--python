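"""Synthetic test data: bead phantoms and spot layouts.

Stands in for the bench measurements a projector is characterized with:
fluorescent-bead image stacks (1 um beads for spot calibration, 100 nm beads
for PSF measurement) and deterministic multi-spot target layouts.  Beads are
rendered incoherently — a solid sphere convolved with the supplied PSF —
because they act purely as fluorescence markers; everything is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from ._exceptions import InvalidParameterError, OutOfBoundsError
from .hologram import SpotTarget
from .propagation import IntensityVolume

__all__ = ["BeadPhantom", "make_bead_volume", "make_spot_grid"]


@dataclass
class BeadPhantom:
    """Specification of a synthetic fluorescent-bead sample.

    ``positions`` are bead centers in image-space um; ``diameter`` in um
    (1.0 emulates calibration beads, 0.1 sub-resolution PSF beads);
    ``noise`` is one of "none", "gaussian" (sigma = noise_scale x peak
    signal) or "poisson" (counts scaled by noise_scale); ``seed`` fixes all
    randomness.
    """

    positions: list[tuple[float, float, float]] = field(default_factory=list)
    diameter: float = 1.0
    background: float = 0.0
    noise: str = "none"
    noise_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError(f"bead diameter must be > 0, got {self.diameter}")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise InvalidParameterError(
                f"noise must be 'none', 'gaussian' or 'poisson', got {self.noise!r}"
            )
        if self.background < 0 or self.noise_scale < 0:
            raise InvalidParameterError("background and noise_scale must be >= 0")
        self.positions = [tuple(float(c) for c in pos) for pos in self.positions]


def make_bead_volume(phantom: BeadPhantom, psf_volume: IntensityVolume) -> IntensityVolume:
    """Render a bead stack: spheres convolved with the PSF, plus background and noise.

    The output volume shares the grid (shape, voxel size, origin) of
    ``psf_volume``; the PSF is normalized to unit sum before convolution so
    total signal scales linearly with bead count.  A bead center outside the
    grid is an error.
    """
    zc = psf_volume.z_coords()
    yc = psf_volume.y_coords()
    xc = psf_volume.x_coords()
    radius = phantom.diameter / 2.0

    sample = np.zeros_like(psf_volume.values)
    for bx, by, bz in phantom.positions:
        if not (
            xc[0] <= bx <= xc[-1]
            and yc[0] <= by <= yc[-1]
            and zc.min() <= bz <= zc.max()
        ):
            raise OutOfBoundsError(f"bead at ({bx}, {by}, {bz}) um lies outside the volume grid")
        dist2 = (
            (zc - bz)[:, None, None] ** 2
            + (yc - by)[None, :, None] ** 2
            + (xc - bx)[None, None, :] ** 2
        )
        mask = dist2 <= radius**2
        if not mask.any():
            # sub-voxel bead: deposit all signal at the nearest voxel
            iz = int(np.argmin(np.abs(zc - bz)))
            iy = int(np.argmin(np.abs(yc - by)))
            ix = int(np.argmin(np.abs(xc - bx)))
            sample[iz, iy, ix] += 1.0
        else:
            sample[mask] += 1.0

    psf = psf_volume.values
    total = psf.sum()
    if total <= 0:
        raise InvalidParameterError("PSF volume must have positive total signal")
    rendered = fftconvolve(sample, psf / total, mode="same")
    rendered = np.clip(rendered, 0.0, None) + phantom.background

    rng = np.random.default_rng(phantom.seed)
    if phantom.noise == "gaussian":
        sigma = phantom.noise_scale * (rendered.max() if rendered.max() > 0 else 1.0)
        rendered = np.clip(rendered + rng.normal(0.0, sigma, rendered.shape), 0.0, None)
    elif phantom.noise == "poisson":
        scale = max(phantom.noise_scale, 1e-12)
        rendered = rng.poisson(rendered / scale).astype(float) * scale
    return replace(psf_volume, values=rendered)


# R2 low-discrepancy sequence constants (plastic-number based)
_R2A, _R2B = 0.7548776662466927, 0.5698402909980532


def make_spot_grid(
    n: int, spacing: float, extent: float, jitter: float = 0.0
) -> list[SpotTarget]:
    """Deterministic serpentine grid of ``n`` spots at z = 0.

    Spots are laid out row-major on a square-ish lattice with pitch
    ``spacing``, centered on the origin and required to fit inside a square
    of side ``extent``.  n = 1 gives a single centered spot.  With
    ``jitter = 0`` (default) all pairwise distances are >= spacing; a
    positive ``jitter`` (um) displaces each spot by a deterministic
    low-discrepancy offset up to +-jitter per axis, breaking the lattice
    periodicity that otherwise puts intermodulation ghosts of the
    superposition hologram exactly onto other lattice sites (the guaranteed
    minimum distance drops to ``spacing - 2 sqrt(2) jitter``).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if spacing <= 0 or extent <= 0 or jitter < 0:
        raise InvalidParameterError("spacing and extent must be > 0 and jitter >= 0")
    if 2.0 * math.sqrt(2.0) * jitter >= spacing:
        raise InvalidParameterError(f"jitter {jitter} too large for spacing {spacing}")
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    if (cols - 1) * spacing + 2 * jitter > extent or (rows - 1) * spacing + 2 * jitter > extent:
        raise InvalidParameterError(
            f"cannot pack {n} spots with {spacing} um spacing inside a {extent} um extent"
        )
    spots = []
    for k in range(n):
        r, c = divmod(k, cols)
        if r % 2 == 1:  # serpentine: odd rows run right-to-left
            c = cols - 1 - c
        x = (c - (cols - 1) / 2.0) * spacing
        y = (r - (rows - 1) / 2.0) * spacing
        if jitter > 0:
            x += jitter * (2.0 * (((k + 1) * _R2A) % 1.0) - 1.0)
            y += jitter * (2.0 * (((k + 1) * _R2B) % 1.0) - 1.0)
        spots.append(SpotTarget(x=x, y=y, z=0.0))
    return spots


#: Relative positions of the standard 5-spot envelope-flattening line:
#: irregular fractions of the span, with a slight tilt (y = 0.2 x), so the
#: intermodulation ghosts of the direct superposition algorithm do not land
#: on other spots of the line.
FLATTENING_LINE_FRACTIONS = (-1.0, -0.38, 0.21, 0.66, 1.0)


def make_flattening_line(half_span: float, tilt: float = 0.2) -> list[SpotTarget]:
    """The standard 5-spot line used to characterize envelope flattening.

    Spots span ``+-half_span`` um along x at irregular fractions
    (:data:`FLATTENING_LINE_FRACTIONS`) with ``y = tilt * x``, z = 0.
    """
    if half_span <= 0:
        raise InvalidParameterError(f"half_span must be > 0, got {half_span}")
    return [
        SpotTarget(x=f * half_span, y=tilt * f * half_span, z=0.0)
        for f in FLATTENING_LINE_FRACTIONS
    ]
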