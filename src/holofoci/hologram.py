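"""Phase-only hologram synthesis by prism-lens-vortex-Zernike superposition.

Each target focus n at image-space position (x_n, y_n, z_n) with amplitude
weight A_n contributes one complex plane/spherical wave to the pupil field:

    psi(u, v) = sum_n A_n exp( i [ 2 pi (alpha u x_n + beta v y_n
                                         + gamma (u^2 + v^2) z_n)
                                   + W_n(u, v) + L_n theta(u, v) ] )

where (u, v) are normalized pupil coordinates, alpha/beta/gamma the prism and
lens scaling factors, W_n an optional Zernike phase surface (radians) and
L_n an integer vortex charge producing an annular (Laguerre-Gaussian) focus
used for alignment.  The hologram displayed on the SLM is the *phase* of psi,
quantized to the SLM's 256 grey levels; the discarded amplitude causes the
well-known inter-spot cross-talk of the direct superposition algorithm, which
is accepted (no iterative optimization is performed).
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, replace

import numpy as np

from ._exceptions import (
    DegenerateFieldError,
    EmptyInputError,
    InvalidParameterError,
)
from .optics import EnvelopeModel, OpticsConfig
from .zernike import ZernikeSpec, zernike_surface

__all__ = [
    "PHASE_DIVERSITY_COEFF",
    "SpotTarget",
    "PhaseMap",
    "QuantizedHologram",
    "superpose_field",
    "extract_phase",
    "quantize_phase",
    "compute_amplitude_weights",
    "with_phase_diversity",
    "park_position",
    "park_spots",
    "gen_hologram",
]

TWO_PI = 2.0 * np.pi


#: Coefficient of the deterministic quadratic phase-diversity sequence
#: phi_n = pi * c * n^2.  An irrational c decorrelates the intermodulation
#: ghosts of the direct superposition algorithm across spot counts; 1/sqrt(2)
#: was selected empirically over candidate constants (see docs/methods.md).
PHASE_DIVERSITY_COEFF = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class SpotTarget:
    """One stimulation focus.

    Coordinates are image-space um relative to the holographic-FOV center
    (z relative to the nominal focal plane, positive toward the objective).
    ``weight`` is the amplitude coefficient A_n; ``phase`` a constant phase
    offset in radians (the argument of a complex A_n — it does not move or
    re-weight the focus, but decorrelates inter-spot interference);
    ``vortex_charge`` the integer Laguerre-Gaussian charge L; ``active``
    False removes the spot from the superposition entirely.
    """

    x: float
    y: float
    z: float = 0.0
    weight: float = 1.0
    phase: float = 0.0
    vortex_charge: int = 0
    active: bool = True

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "weight", "phase"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise InvalidParameterError(f"SpotTarget.{name} must be finite, got {val}")
        if self.weight < 0:
            raise InvalidParameterError(f"SpotTarget.weight must be >= 0, got {self.weight}")
        if not isinstance(self.vortex_charge, numbers.Integral):
            raise InvalidParameterError(
                f"SpotTarget.vortex_charge must be an integer, got {self.vortex_charge!r}"
            )


def with_phase_diversity(
    spots: list[SpotTarget], coefficient: float = PHASE_DIVERSITY_COEFF
) -> list[SpotTarget]:
    """Assign the deterministic phase-diversity offsets phi_n = pi c n^2.

    Returns a new list with each spot's ``phase`` set from its list index.
    Offsets are constant per-spot phases, so ideal focus positions and powers
    are unchanged; what changes is the pupil interference pattern, which
    otherwise (all spots in phase) concentrates amplitude modulation that the
    phase-only extraction turns into strong inter-spot cross-talk.
    """
    return [
        replace(s, phase=math.pi * coefficient * i**2 % TWO_PI)
        for i, s in enumerate(spots)
    ]


@dataclass
class PhaseMap:
    """Continuous phase hologram in [0, 2 pi) on the SLM grid."""

    values: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("PhaseMap values must be a 2D array")
        if np.any(self.values < 0) or np.any(self.values >= TWO_PI):
            raise InvalidParameterError("PhaseMap values must lie in [0, 2 pi)")

    @property
    def n_pix(self) -> int:
        return self.values.shape[0]


@dataclass
class QuantizedHologram:
    """8-bit phase hologram: level k encodes phase 2 pi k / 256."""

    levels: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if levels.ndim != 2:
            raise InvalidParameterError("QuantizedHologram levels must be a 2D array")
        if levels.min(initial=0) < 0 or levels.max(initial=0) > 255:
            raise InvalidParameterError("QuantizedHologram levels must lie in 0..255")
        self.levels = levels.astype(np.uint8)

    def dequantize(self) -> PhaseMap:
        """Reconstruct the phase map; round-trip error is at most pi/256."""
        return PhaseMap(self.levels.astype(float) * (TWO_PI / 256.0), provenance=self.provenance)


def _resolve_zernike(zernike, n_spots: int) -> list[ZernikeSpec | None]:
    """Expand a global spec / per-spot sequence into one entry per spot."""
    if zernike is None:
        return [None] * n_spots
    if isinstance(zernike, ZernikeSpec):
        return [zernike] * n_spots
    specs = list(zernike)
    if len(specs) != n_spots:
        raise InvalidParameterError(
            f"per-spot Zernike sequence has {len(specs)} entries for {n_spots} spots"
        )
    for s in specs:
        if s is not None and not isinstance(s, ZernikeSpec):
            raise InvalidParameterError(f"expected ZernikeSpec or None, got {type(s).__name__}")
    return specs


def superpose_field(
    spots: list[SpotTarget],
    config: OpticsConfig,
    zernike: ZernikeSpec | list[ZernikeSpec | None] | None = None,
) -> np.ndarray:
    """Complex pupil field psi(u, v) of the prism-lens superposition.

    ``zernike`` may be None, a single global :class:`ZernikeSpec`, or a
    sequence with one entry per element of ``spots`` (per-spot,
    depth-dependent corrections).  Inactive or zero-weight spots contribute
    nothing; at least one active spot with positive weight is required.
    """
    specs = _resolve_zernike(zernike, len(spots))
    live = [(s, sp) for s, sp in zip(spots, specs) if s.active and s.weight > 0]
    if not live:
        raise EmptyInputError("superpose_field requires at least one active spot with weight > 0")

    u, v = config.pupil_coords()
    rho2 = u**2 + v**2
    theta = np.arctan2(v, u)
    alpha, beta, gamma = config.scale_x, config.scale_y, config.defocus_scale

    field_sum = np.zeros_like(u, dtype=complex)
    surface_cache: dict[int, np.ndarray] = {}
    for spot, spec in live:
        phase = TWO_PI * (alpha * u * spot.x + beta * v * spot.y + gamma * rho2 * spot.z)
        if spot.phase:
            phase = phase + spot.phase
        if spec is not None and spec:
            key = id(spec)
            if key not in surface_cache:
                surface_cache[key] = zernike_surface(spec, u, v)
            phase = phase + surface_cache[key]
        if spot.vortex_charge:
            phase = phase + spot.vortex_charge * theta
        field_sum += spot.weight * np.exp(1j * phase)
    return field_sum


def extract_phase(field: np.ndarray) -> PhaseMap:
    """Element-wise argument of the field, wrapped to [0, 2 pi).

    Points of exactly destructive interference (zero magnitude) have no
    defined phase and are assigned 0; an identically zero field is rejected.
    """
    field = np.asarray(field, dtype=complex)
    if not np.any(field):
        raise DegenerateFieldError("cannot extract the phase of an identically zero field")
    phase = np.mod(np.angle(field), TWO_PI)
    phase[field == 0] = 0.0
    # np.mod can return 2*pi for tiny negative angles
    phase[phase >= TWO_PI] = 0.0
    return PhaseMap(phase)


def quantize_phase(phase: PhaseMap) -> QuantizedHologram:
    """Quantize to the SLM's 256 phase levels: level = round(phase * 256 / 2pi) mod 256."""
    levels = np.mod(np.round(phase.values * (256.0 / TWO_PI)).astype(np.int64), 256)
    return QuantizedHologram(levels, provenance=phase.provenance)


def compute_amplitude_weights(
    spots: list[SpotTarget], envelope: EnvelopeModel
) -> list[SpotTarget]:
    """Inverse amplitude weighting against the diffraction-efficiency envelopes.

    Each active spot's weight is multiplied by
    ``min(max_gain, 1/sqrt(lateral_eff * axial_eff))`` so that delivered
    intensity (proportional to weight^2 * efficiency) is flattened across the
    pattern; weights are then renormalized so the maximum is 1.  Returns a new
    spot list; inactive spots pass through (but share the renormalization).
    """
    updated = []
    for spot in spots:
        if spot.active and spot.weight > 0:
            gain = envelope.gain(spot.x, spot.y, spot.z)
            updated.append(replace(spot, weight=spot.weight * gain))
        else:
            updated.append(spot)
    peak = max((s.weight for s in updated), default=0.0)
    if peak > 0:
        updated = [replace(s, weight=s.weight / peak) for s in updated]
    return updated


_GOLDEN = 0.6180339887498949


def park_position(j: int, config: OpticsConfig) -> tuple[float, float]:
    """Deterministic position of the j-th parked focus, just outside the aperture.

    Parked foci are spread around the aperture window on a golden-angle
    sequence at radii 1.25-1.48x the window half-width (clipped to stay
    within the holographic FOV).  Spreading matters: coincident parked foci
    would merge coherently into a single focus of k-fold amplitude (k^2-fold
    intensity) and steal the active spots' power budget, and collinear ones
    put strong intermodulation ghosts back inside the window.
    """
    hw = config.fov_aperture_halfwidth
    ang = TWO_PI * ((j * _GOLDEN) % 1.0)
    r = hw * (1.25 + 0.23 * ((j * 0.414) % 1.0))
    x, y = r * math.cos(ang), r * math.sin(ang)
    # guarantee a clear margin beyond the square window edge (15% of hw)
    cheb = max(abs(x), abs(y))
    if cheb < 1.15 * hw:
        x, y = x * 1.15 * hw / cheb, y * 1.15 * hw / cheb
    lim = 0.95 * config.dx_max
    return float(np.clip(x, -lim, lim)), float(np.clip(y, -lim, lim))


def park_spots(
    spots: list[SpotTarget],
    n_active: int,
    config: OpticsConfig,
) -> list[SpotTarget]:
    """Park all but the first ``n_active`` spots outside the holographic FOV.

    Keeping the *total* focus count fixed keeps the per-focus power constant
    while the number of stimulation sites varies: superfluous foci stay in the
    hologram (still consuming their share of the pupil energy) but are moved
    beyond the relay-aperture window (see :func:`park_position`) so they
    deliver nothing to the sample after clipping.
    """
    if not 0 < n_active <= len(spots):
        raise InvalidParameterError(
            f"n_active must be in 1..{len(spots)}, got {n_active}"
        )
    if not math.isfinite(config.fov_aperture_halfwidth):
        raise InvalidParameterError("cannot park spots with an infinite aperture window")
    if config.fov_aperture_halfwidth * 1.2 >= config.dx_max:
        raise InvalidParameterError(
            "aperture window too close to the FOV edge to park spots outside it"
        )
    out = list(spots[:n_active])
    for j, spot in enumerate(spots[n_active:]):
        x, y = park_position(j, config)
        out.append(replace(spot, x=x, y=y, z=0.0, active=True))
    return out


def _provenance_hash(spots, config, zernike) -> str:
    import hashlib
    import json

    def spec_rec(s):
        return None if s is None else {"terms": s.to_records(), "scope": s.scope}

    if isinstance(zernike, ZernikeSpec) or zernike is None:
        zrec = spec_rec(zernike)
    else:
        zrec = [spec_rec(s) for s in zernike]
    payload = {
        "spots": [
            [s.x, s.y, s.z, s.weight, s.phase, int(s.vortex_charge), bool(s.active)]
            for s in spots
        ],
        "config": config.to_dict(),
        "zernike": zrec,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def gen_hologram(
    spots: list[SpotTarget],
    config: OpticsConfig,
    zernike: ZernikeSpec | list[ZernikeSpec | None] | None = None,
    *,
    weighting: bool = False,
    envelope: EnvelopeModel | None = None,
    n_active: int | None = None,
    phase_diversity: bool = True,
) -> QuantizedHologram:
    """Full synthesis pipeline: (park) -> (diversify) -> (weight) -> superpose -> phase -> quantize.

    A pure function of its inputs: identical arguments give a bit-identical
    hologram.  ``weighting`` enables inverse amplitude weighting (using
    ``envelope`` or one derived from ``config``); ``n_active`` enables the
    parking protocol; ``phase_diversity`` (default on) assigns the
    deterministic per-spot phase offsets of :func:`with_phase_diversity`
    unless any spot already carries an explicit nonzero phase.
    """
    work = list(spots)
    if n_active is not None:
        work = park_spots(work, n_active, config)
    if phase_diversity and all(s.phase == 0.0 for s in work):
        work = with_phase_diversity(work)
    if weighting:
        env = envelope if envelope is not None else EnvelopeModel.from_config(config)
        work = compute_amplitude_weights(work, env)
    field = superpose_field(work, config, zernike)
    phase = extract_phase(field)
    phase.provenance = _provenance_hash(work, config, zernike)
    return quantize_phase(phase)
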