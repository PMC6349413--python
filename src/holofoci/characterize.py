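"""Quantitative characterization of the simulated projector.

Covers the bench measurements used to validate the hologram engine:
FWHM of the focal spot, per-spot delivered power, the 1/N^2 fluorescence
scaling with spot count, the power-error formula, the Gaussian axial
efficiency fit, and the similarity (Procrustes) transform used to calibrate
hologram scaling/rotation factors against bead mirror images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._exceptions import (
    FitFailureError,
    InvalidParameterError,
    NotMeasurableError,
    OutOfBoundsError,
)
from .hologram import SpotTarget
from .propagation import IntensityVolume

__all__ = [
    "SpotMeasurement",
    "SimilarityTransform",
    "measure_fwhm",
    "per_spot_power",
    "fit_power_law",
    "power_error",
    "fit_axial_envelope",
    "fit_similarity_transform",
]


@dataclass
class SpotMeasurement:
    """Per-spot readout: position, delivered power P, fluorescence F, error dP."""

    position: tuple[float, float, float]
    delivered_power: float
    fluorescence: float
    power_error: float = 0.0

    def __post_init__(self) -> None:
        if self.delivered_power < 0 or self.fluorescence < 0:
            raise InvalidParameterError("power and fluorescence must be non-negative")


@dataclass
class SimilarityTransform:
    """Least-squares similarity map ``p -> scale * R p + translation``.

    ``rotation`` is the rotation angle in radians for 2D fits (None in 3D,
    where ``rotation_matrix`` carries the full orientation); ``reflection``
    records whether the fitted R has determinant -1.
    """

    scale: float
    rotation_matrix: np.ndarray
    translation: np.ndarray
    reflection: bool
    residual: float
    rotation: float | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")
        self.rotation_matrix = np.asarray(self.rotation_matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return self.scale * points @ self.rotation_matrix.T + self.translation


def measure_fwhm(profile, sample_spacing: float) -> float:
    """Full width at half maximum of a 1D intensity profile, in um.

    The half-maximum level is half the profile maximum (no baseline
    subtraction); crossings on either side of the peak are located by linear
    interpolation between samples.  A maximum on the boundary, or a side with
    no crossing, is not measurable.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise NotMeasurableError("profile must be 1D with at least 3 samples")
    if sample_spacing <= 0:
        raise InvalidParameterError(f"sample_spacing must be > 0, got {sample_spacing}")
    i = int(np.argmax(profile))
    if i == 0 or i == profile.size - 1:
        raise NotMeasurableError("profile maximum lies on the boundary")
    half = profile[i] / 2.0

    def cross(idx_range):
        prev = i
        for j in idx_range:
            if profile[j] <= half:
                # linear interpolation between j and prev
                frac = (profile[prev] - half) / (profile[prev] - profile[j])
                return prev + frac * (j - prev)
            prev = j
        raise NotMeasurableError("no half-maximum crossing found")

    left = cross(range(i - 1, -1, -1))
    right = cross(range(i + 1, profile.size))
    return float((right - left) * sample_spacing)


def _lateral_fwhm_at_peak(volume: IntensityVolume) -> float:
    """FWHM (um) of the x profile through the brightest voxel."""
    iz, iy, ix = np.unravel_index(np.argmax(volume.values), volume.values.shape)
    return measure_fwhm(volume.values[iz, iy, :], volume.voxel_size[2])


def per_spot_power(
    volume: IntensityVolume,
    spots: list[SpotTarget],
    radius: float | None = None,
    *,
    signal: str = "intensity",
) -> list[SpotMeasurement]:
    """Integrate the signal in a ball of ``radius`` um around each spot.

    ``radius`` defaults to 3x the lateral FWHM measured at the volume's
    brightest voxel.  ``signal`` declares what the volume holds:
    ``"intensity"`` reports the sum directly as delivered power;
    ``"two_photon"`` reports the square root of the summed signal as the
    power (inverting the quadratic excitation law).  The raw sum is always
    reported as ``fluorescence``.
    """
    if signal not in ("intensity", "two_photon"):
        raise InvalidParameterError(f"signal must be 'intensity' or 'two_photon', got {signal!r}")
    if radius is None:
        radius = 3.0 * _lateral_fwhm_at_peak(volume)
    if radius <= 0:
        raise InvalidParameterError(f"radius must be > 0, got {radius}")

    zc = volume.z_coords()
    yc = volume.y_coords()
    xc = volume.x_coords()
    bounds = (
        (xc[0], xc[-1]),
        (yc[0], yc[-1]),
        (zc.min(), zc.max()),
    )
    out = []
    for spot in spots:
        for val, (lo, hi), name in zip(
            (spot.x, spot.y, spot.z), bounds, ("x", "y", "z")
        ):
            if not (lo - 1e-9 <= val <= hi + 1e-9):
                raise OutOfBoundsError(
                    f"spot {name} = {val} um outside volume range [{lo:.3f}, {hi:.3f}]"
                )
        dz = zc - spot.z
        dy = yc - spot.y
        dx = xc - spot.x
        mask = (
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
            <= radius**2
        )
        total = float(volume.values[mask].sum())
        power = math.sqrt(total) if signal == "two_photon" else total
        out.append(
            SpotMeasurement(
                position=(spot.x, spot.y, spot.z),
                delivered_power=power,
                fluorescence=total,
            )
        )
    return out


def fit_power_law(n_values, f_values) -> tuple[float, float]:
    """Log-log OLS fit of F ~ N^(-exponent); returns (exponent, r).

    The exponent is reported as a positive magnitude (a 1/N^2 law gives 2.0);
    r is the magnitude of the Pearson correlation of log F with log N
    (1.0 for an exact power law, 0 when F is constant).
    """
    n = np.asarray(n_values, dtype=float)
    f = np.asarray(f_values, dtype=float)
    if n.size != f.size or n.size < 3:
        raise InvalidParameterError("need at least 3 (N, F) pairs of equal length")
    if np.any(n <= 0) or np.any(f <= 0):
        raise InvalidParameterError("power-law fit requires strictly positive N and F")
    log_n = np.log(n)
    log_f = np.log(f)
    slope, _ = np.polyfit(log_n, log_f, 1)
    if np.std(log_f) == 0 or np.std(log_n) == 0:
        r = 0.0
    else:
        r = float(abs(np.corrcoef(log_n, log_f)[0, 1]))
    return float(abs(slope)), r


def power_error(delta_f, p, *, fluorescence: float | None = None, relative: bool = False):
    """Error in delivered power inferred from a fluorescence error.

    The default form is ``dP = 0.5 * dF / P`` — the operational definition
    used with normalized bead fluorescence.  With ``relative=True`` the
    dimensionally homogeneous form ``dP = 0.5 * (dF / F) * P`` (i.e.
    dP/P = 0.5 dF/F, error propagation through F ~ P^2) is returned instead,
    requiring ``fluorescence``.
    """
    p = float(p)
    if p <= 0:
        raise InvalidParameterError(f"power must be > 0, got {p}")
    delta_f = float(delta_f)
    if relative:
        if fluorescence is None or fluorescence <= 0:
            raise InvalidParameterError("relative form requires fluorescence > 0")
        return 0.5 * (delta_f / fluorescence) * p
    return 0.5 * delta_f / p


def fit_axial_envelope(z_values, powers) -> float:
    """Least-squares sigma_z of the Gaussian axial-efficiency model.

    Fits ``exp(-z^2 / (2 sigma_z^2))`` to normalized powers (max ~ 1);
    data that do not decay away from z = 0 are rejected.
    """
    z = np.asarray(z_values, dtype=float)
    p = np.asarray(powers, dtype=float)
    if z.size != p.size or z.size < 3:
        raise InvalidParameterError("need at least 3 (z, power) pairs of equal length")
    if np.any(p <= 0) or np.any(p > 1.0 + 1e-9):
        raise InvalidParameterError("powers must lie in (0, 1] (normalize to the maximum)")
    order = np.argsort(np.abs(z))
    if p[order[-1]] >= 0.95 * p[order[0]]:
        raise FitFailureError("powers do not decay with |z|; Gaussian envelope not identifiable")

    def model(zz, sigma):
        return np.exp(-(zz**2) / (2.0 * sigma**2))

    sigma0 = max(np.abs(z).max() / 2.0, 1e-6)
    try:
        popt, _ = curve_fit(model, z, p, p0=[sigma0], maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit rarely fails here
        raise FitFailureError(f"axial envelope fit did not converge: {exc}") from exc
    sigma = float(abs(popt[0]))
    if sigma <= 0 or not math.isfinite(sigma):
        raise FitFailureError(f"axial envelope fit returned invalid sigma_z = {sigma}")
    return sigma


def fit_similarity_transform(
    measured, target, allow_reflection: bool = False
) -> SimilarityTransform:
    """Least-squares similarity (Procrustes) transform: measured -> target.

    Umeyama's closed-form solution for scale, rotation and translation
    minimizing the RMS residual.  With ``allow_reflection`` the optimum over
    the full orthogonal group is used (bead mirror images motivate this);
    otherwise the rotation is constrained to determinant +1.

    Requires >= 2 point pairs in 2D (>= 3 in 3D, non-collinear); coincident
    point sets are degenerate.
    """
    src = np.asarray(measured, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.shape != dst.shape or src.ndim != 2:
        raise InvalidParameterError("measured and target must be (n_points, dim) arrays of equal shape")
    n, dim = src.shape
    if dim not in (2, 3):
        raise InvalidParameterError(f"points must be 2D or 3D, got dim={dim}")
    if n < dim:
        raise InvalidParameterError(f"need at least {dim} point pairs in {dim}D, got {n}")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    src_c = src - mu_s
    dst_c = dst - mu_d
    var_s = float((src_c**2).sum() / n)
    if var_s <= 1e-24:
        raise FitFailureError("degenerate configuration: measured points coincide")
    rank = np.linalg.matrix_rank(src_c, tol=1e-9 * math.sqrt(var_s * n))
    if rank < dim - 1 or (dim == 3 and rank < 2):
        raise FitFailureError("degenerate configuration: points are collinear")

    cov = dst_c.T @ src_c / n
    u_mat, s_vec, vt = np.linalg.svd(cov)
    d = np.ones(dim)
    det_sign = np.sign(np.linalg.det(u_mat @ vt))
    if not allow_reflection and det_sign < 0:
        d[-1] = -1.0
    rot = u_mat @ np.diag(d) @ vt
    scale = float((s_vec * d).sum() / var_s)
    if scale <= 0:
        raise FitFailureError("fitted scale is non-positive; configuration degenerate")
    trans = mu_d - scale * rot @ mu_s
    fitted = scale * src @ rot.T + trans
    residual = float(np.sqrt(((fitted - dst) ** 2).sum(axis=1).mean()))
    reflection = bool(np.linalg.det(rot) < 0)
    angle = float(math.atan2(rot[1, 0], rot[0, 0])) if dim == 2 else None
    return SimilarityTransform(
        scale=scale,
        rotation_matrix=rot,
        translation=trans,
        reflection=reflection,
        residual=residual,
        rotation=angle,
    )
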