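"""Optical configuration, space-bandwidth field-of-view, and diffraction-efficiency envelopes.

The holographic field of view (FOV) of an SLM-based projector is bounded by the
space-bandwidth product of the phase display: a hologram with ``N_pix`` pixels
across the objective back aperture can steer a first-order focus at most

    dx_max = lambda * N_pix / (4 * NA)

away from the optical axis in each lateral direction, i.e. the FOV is a square
of side ``2 * dx_max``.  Within that range the first-order diffraction
efficiency declines with displacement because the SLM pixels have a finite
footprint: the envelope is sinc-squared laterally and is modelled as an
empirical Gaussian axially.  Both envelopes are used to *inversely* weight the
per-spot amplitudes during hologram synthesis so that delivered power is flat
across a multi-focus pattern.

Units: lengths in micrometres (um) throughout; pupil coordinates are
dimensionless, normalized so the pupil-edge radius is 1.
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import InvalidParameterError

__all__ = [
    "OpticsConfig",
    "EnvelopeModel",
    "fov_half_range",
    "lateral_efficiency",
    "axial_efficiency",
]


def fov_half_range(wavelength: float, n_pix: int, numerical_aperture: float) -> float:
    """Half-range ``dx_max`` of the holographic FOV from the space-bandwidth limit.

    Parameters
    ----------
    wavelength : float
        Excitation wavelength in um.
    n_pix : int
        Pixel count of the square SLM working area (``n_pix x n_pix``).
    numerical_aperture : float
        Objective NA.

    Returns
    -------
    float
        ``wavelength * n_pix / (4 * numerical_aperture)`` in um. The full FOV
        side is twice this value.
    """
    if wavelength <= 0 or n_pix <= 0 or numerical_aperture <= 0:
        raise InvalidParameterError(
            "fov_half_range requires positive wavelength, pixel count and NA; "
            f"got ({wavelength}, {n_pix}, {numerical_aperture})"
        )
    return wavelength * n_pix / (4.0 * numerical_aperture)


def _sinc(t):
    # unnormalized mathematical sinc: sin(t)/t with sinc(0) = 1
    # (np.sinc is the normalized dialect sin(pi t)/(pi t))
    return np.sinc(np.asarray(t, dtype=float) / np.pi)


def lateral_efficiency(x, y, dx_max: float):
    """First-order diffraction efficiency at lateral displacement (x, y).

    The pixelated SLM imposes a separable sinc-squared envelope::

        eta(x, y) = sinc^2(pi x / (2 dx_max)) * sinc^2(pi y / (2 dx_max))

    with the unnormalized sinc ``sin(t)/t``.  At the Nyquist displacement
    ``|x| = dx_max`` the envelope equals ``(2/pi)^2 ~= 0.405``.

    Accepts scalars or arrays; broadcasting applies.
    """
    if dx_max <= 0:
        raise InvalidParameterError(f"dx_max must be positive, got {dx_max}")
    tx = np.pi * np.asarray(x, dtype=float) / (2.0 * dx_max)
    ty = np.pi * np.asarray(y, dtype=float) / (2.0 * dx_max)
    out = _sinc(tx) ** 2 * _sinc(ty) ** 2
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


def axial_efficiency(z, sigma_z: float):
    """Axial diffraction-efficiency envelope ``exp(-z^2 / (2 sigma_z^2))``.

    An empirical Gaussian model of the measured decline of delivered power
    with axial displacement of a holographic focus.
    """
    if sigma_z <= 0:
        raise InvalidParameterError(f"sigma_z must be positive, got {sigma_z}")
    out = np.exp(-np.asarray(z, dtype=float) ** 2 / (2.0 * sigma_z**2))
    return float(out) if np.isscalar(z) else out


@dataclass
class OpticsConfig:
    """Physical and calibration parameters of the holographic projector.

    Attributes
    ----------
    wavelength : float
        Uncaging wavelength in um (default 0.75, i.e. 750 nm).
    numerical_aperture : float
        Objective NA (default 1.0).
    immersion_index : float
        Refractive index of the immersion medium (default 1.33, water).
    slm_pixels : int
        Side of the square SLM working area in pixels (default 600).
    slm_pitch : float
        SLM pixel pitch in um (default 20).
    scale_x, scale_y : float
        Prism scaling factors alpha, beta in cycles per (pupil-unit * um).
        Default ``NA / wavelength`` (Abbe-sine lateral shift); stored mutable
        because they are calibration-adjustable.
    defocus_scale : float
        Lens scaling factor gamma in cycles per (pupil-unit^2 * um).
        Default ``-NA^2 / (2 n wavelength)`` (paraxial defocus).
    axial_sigma : float
        Width (um) of the empirical Gaussian axial-efficiency model
        (default 50, giving >= 50% efficiency over +-35 um).
    fov_aperture_halfwidth : float
        Half-width (um) of the hard square transmission window that models
        beam fall-off at the relay optics (default 35 for a 20x profile;
        use 15 for a 60x profile). ``inf`` disables clipping.
    pad_factor : int
        FFT zero-padding factor for image-plane sampling (default 2,
        ~0.19 um lateral sampling for the default configuration).
    """

    wavelength: float = 0.75
    numerical_aperture: float = 1.0
    immersion_index: float = 1.33
    slm_pixels: int = 600
    slm_pitch: float = 20.0
    scale_x: float | None = None
    scale_y: float | None = None
    defocus_scale: float | None = None
    axial_sigma: float = 50.0
    fov_aperture_halfwidth: float = 35.0
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidParameterError(f"wavelength must be > 0, got {self.wavelength}")
        if not (0 < self.numerical_aperture <= self.immersion_index):
            raise InvalidParameterError(
                f"need 0 < NA <= immersion index, got NA={self.numerical_aperture}, "
                f"n={self.immersion_index}"
            )
        if not isinstance(self.slm_pixels, numbers.Integral) or self.slm_pixels < 2:
            raise InvalidParameterError(f"slm_pixels must be an integer >= 2, got {self.slm_pixels}")
        if self.slm_pitch <= 0:
            raise InvalidParameterError(f"slm_pitch must be > 0, got {self.slm_pitch}")
        if self.axial_sigma <= 0:
            raise InvalidParameterError(f"axial_sigma must be > 0, got {self.axial_sigma}")
        if self.fov_aperture_halfwidth <= 0:
            raise InvalidParameterError(
                f"fov_aperture_halfwidth must be > 0, got {self.fov_aperture_halfwidth}"
            )
        if not isinstance(self.pad_factor, numbers.Integral) or self.pad_factor < 1:
            raise InvalidParameterError(f"pad_factor must be an integer >= 1, got {self.pad_factor}")
        # physical defaults in normalized pupil coordinates (pupil-edge radius 1)
        if self.scale_x is None:
            self.scale_x = self.numerical_aperture / self.wavelength
        if self.scale_y is None:
            self.scale_y = self.numerical_aperture / self.wavelength
        if self.defocus_scale is None:
            self.defocus_scale = -self.numerical_aperture**2 / (
                2.0 * self.immersion_index * self.wavelength
            )

    @property
    def dx_max(self) -> float:
        """Lateral half-range of the holographic FOV (um)."""
        return fov_half_range(self.wavelength, self.slm_pixels, self.numerical_aperture)

    def pupil_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized pupil coordinate grids (u, v), each ``slm_pixels`` square.

        Samples are at ``(k - N/2) * (2/N)`` so the grid is FFT-aligned and the
        pupil edge (radius 1) falls on the array border.  u varies along the
        last axis (columns, image x), v along the first (rows, image y).
        """
        n = self.slm_pixels
        c = (np.arange(n) - n // 2) * (2.0 / n)
        u, v = np.meshgrid(c, c)  # u: columns, v: rows
        return u, v

    def pupil_mask(self) -> np.ndarray:
        """Boolean disk mask of the pupil (radius <= 1) on the SLM grid."""
        u, v = self.pupil_coords()
        return u**2 + v**2 <= 1.0

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "OpticsConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown OpticsConfig keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "OpticsConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


@dataclass
class EnvelopeModel:
    """Diffraction-efficiency envelopes used for inverse amplitude weighting.

    ``gain`` caps the inverse weighting at ``max_gain`` so that spots in the
    far tails of the envelope do not consume unbounded hologram amplitude.
    """

    dx_max: float
    axial_sigma: float = 50.0
    max_gain: float = 4.0

    def __post_init__(self) -> None:
        if self.dx_max <= 0:
            raise InvalidParameterError(f"dx_max must be > 0, got {self.dx_max}")
        if self.axial_sigma <= 0:
            raise InvalidParameterError(f"axial_sigma must be > 0, got {self.axial_sigma}")
        if self.max_gain < 1:
            raise InvalidParameterError(f"max_gain must be >= 1, got {self.max_gain}")

    @classmethod
    def from_config(cls, config: OpticsConfig, max_gain: float = 4.0) -> "EnvelopeModel":
        return cls(dx_max=config.dx_max, axial_sigma=config.axial_sigma, max_gain=max_gain)

    def lateral(self, x, y):
        return lateral_efficiency(x, y, self.dx_max)

    def axial(self, z):
        return axial_efficiency(z, self.axial_sigma)

    def efficiency(self, x, y, z):
        """Combined lateral x axial efficiency at a 3D position."""
        return self.lateral(x, y) * self.axial(z)

    def gain(self, x, y, z) -> float:
        """Inverse amplitude weight ``min(max_gain, 1/sqrt(efficiency))``.

        Delivered intensity scales as weight^2 * efficiency, so multiplying a
        spot's amplitude by this gain flattens delivered power across spots
        (until the cap engages).
        """
        eff = self.efficiency(x, y, z)
        return float(min(self.max_gain, 1.0 / math.sqrt(eff)))
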