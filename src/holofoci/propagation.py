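"""Scalar Fourier-optics propagation of a pupil phase map to a 3D focal volume.

The objective performs an optical Fourier transform of its back-aperture
field, so the focal-plane amplitude at depth z is the 2D FFT of the pupil
field ``exp(i phase)`` multiplied by the paraxial defocus factor
``exp(-2 pi i gamma (u^2+v^2) z)`` (the conjugate of the hologram's lens term,
so a lens hologram for z_n comes to focus at the z = z_n plane) and apodized
by the pupil disk.  Zero-padding by ``pad_factor`` refines the image-plane
sampling to ``2 dx_max / (pad_factor N_pix)``; the unaliased image extent is
exactly the holographic FOV, +-dx_max.

Two hardware envelopes are modelled on top of the ideal transform:

* the sinc-squared pixel-footprint envelope of the SLM, applied analytically
  to the image-plane intensity (equivalent, by the array theorem, to
  unit-fill-factor pixels);
* the hard square relay-aperture window (:func:`apply_aperture`) that zeroes
  everything outside ``fov_aperture_halfwidth`` — the mechanism that makes
  parked spots deliver no power.

Two-photon excitation is quadratic in intensity; :func:`two_photon_volume`
squares the intensity voxel-wise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from ._exceptions import InvalidParameterError
from .optics import OpticsConfig, lateral_efficiency
from .hologram import PhaseMap

__all__ = [
    "IntensityVolume",
    "propagate",
    "apply_aperture",
    "two_photon_volume",
]


@dataclass
class IntensityVolume:
    """A 3D intensity (or two-photon signal) stack with voxel geometry.

    ``values`` is indexed (z, y, x); ``voxel_size`` is (dz, dy, dx) in um
    (dz is NaN when the z planes are non-uniform — use ``z_planes``);
    ``origin`` is the image-space coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    z_planes: list[float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("IntensityVolume values must be a 3D (z, y, x) array")
        if np.any(self.values < 0):
            raise InvalidParameterError("IntensityVolume values must be non-negative")
        dz, dy, dx = self.voxel_size
        if dy <= 0 or dx <= 0 or (not math.isnan(dz) and dz <= 0):
            raise InvalidParameterError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.z_planes is None:
            z0 = self.origin[0]
            step = 0.0 if math.isnan(dz) else dz
            self.z_planes = [z0 + k * step for k in range(self.values.shape[0])]
        self.z_planes = [float(z) for z in self.z_planes]

    # coordinate axes --------------------------------------------------

    def z_coords(self) -> np.ndarray:
        return np.asarray(self.z_planes)

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.voxel_size[1] * np.arange(self.values.shape[1])

    def x_coords(self) -> np.ndarray:
        return self.origin[2] + self.voxel_size[2] * np.arange(self.values.shape[2])

    # I/O --------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write a multi-page 32-bit float TIFF plus a JSON geometry sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32), photometric="minisblack")
        sidecar = {
            "voxel_size_um": list(self.voxel_size),
            "origin_um": list(self.origin),
            "z_planes_um": self.z_planes,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_tiff(cls, path) -> "IntensityVolume":
        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=float)
        if values.ndim == 2:
            values = values[None]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            return cls(
                values,
                voxel_size=tuple(meta["voxel_size_um"]),
                origin=tuple(meta["origin_um"]),
                z_planes=meta.get("z_planes_um"),
            )
        return cls(values, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def propagate(
    phase: PhaseMap,
    config: OpticsConfig,
    z_planes,
    *,
    pupil_aberration: np.ndarray | None = None,
    apply_envelope: bool = True,
) -> IntensityVolume:
    """Propagate a pupil phase map to intensity at the requested z planes.

    ``pupil_aberration`` (radians, on the SLM grid) injects a system
    aberration into the pupil during propagation — the simulation analogue of
    an imperfect optical path that the hologram's Zernike terms can then
    cancel.  ``apply_envelope=False`` skips the sinc-squared pixel-footprint
    envelope (useful for Parseval checks; the FFT step itself conserves
    energy to machine precision).
    """
    z_planes = [float(z) for z in np.atleast_1d(np.asarray(z_planes, dtype=float))]
    if len(z_planes) == 0:
        raise InvalidParameterError("z_planes must be non-empty")
    n = config.slm_pixels
    if phase.values.shape != (n, n):
        raise InvalidParameterError(
            f"phase map shape {phase.values.shape} does not match config slm_pixels {n}"
        )

    u, v = config.pupil_coords()
    rho2 = u**2 + v**2
    mask = rho2 <= 1.0
    base = np.exp(1j * phase.values)
    if pupil_aberration is not None:
        ab = np.asarray(pupil_aberration, dtype=float)
        if ab.shape != (n, n):
            raise InvalidParameterError("pupil_aberration must match the SLM grid shape")
        base = base * np.exp(1j * ab)
    base = base * mask

    m = config.pad_factor * n
    du = 2.0 / n
    gamma = config.defocus_scale
    freq = np.fft.fftshift(np.fft.fftfreq(m, d=du))
    x = freq / config.scale_x
    y = freq / config.scale_y
    lo = (m - n) // 2

    if apply_envelope:
        ex = lateral_efficiency(x, 0.0, config.dx_max)
        ey = lateral_efficiency(y, 0.0, config.dx_max)
        envelope = np.outer(ey, ex)

    planes = np.empty((len(z_planes), m, m), dtype=float)
    buf = np.zeros((m, m), dtype=complex)
    for k, z in enumerate(z_planes):
        # conjugate of the hologram lens term: focus of a z_n lens lands at z = z_n
        fz = base * np.exp(-2j * np.pi * gamma * rho2 * z) if z != 0 else base
        buf[:] = 0
        buf[lo : lo + n, lo : lo + n] = fz
        amp = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(buf), norm="ortho"))
        intensity = np.abs(amp) ** 2
        if apply_envelope:
            intensity *= envelope
        planes[k] = intensity

    dz = float("nan")
    if len(z_planes) > 1:
        steps = np.diff(z_planes)
        if np.allclose(steps, steps[0]) and steps[0] > 0:
            dz = float(steps[0])
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    return IntensityVolume(
        planes,
        voxel_size=(dz, dy, dx),
        origin=(z_planes[0], float(y[0]), float(x[0])),
        z_planes=z_planes,
    )


def apply_aperture(volume: IntensityVolume, config: OpticsConfig) -> IntensityVolume:
    """Zero everything outside the square relay-aperture window.

    The window is centered on the holographic-FOV center with half-width
    ``config.fov_aperture_halfwidth``; an infinite half-width is the identity.
    """
    hw = config.fov_aperture_halfwidth
    if hw <= 0:
        raise InvalidParameterError(f"aperture half-width must be > 0, got {hw}")
    if math.isinf(hw):
        return replace(volume, values=volume.values.copy())
    inside_x = np.abs(volume.x_coords()) <= hw
    inside_y = np.abs(volume.y_coords()) <= hw
    clipped = volume.values * (inside_y[:, None] * inside_x[None, :])[None, :, :]
    return replace(volume, values=clipped)


def two_photon_volume(volume: IntensityVolume) -> IntensityVolume:
    """Two-photon signal: the voxel-wise square of the excitation intensity."""
    return replace(volume, values=volume.values**2)
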