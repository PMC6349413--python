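"""Zernike polynomial basis on the normalized SLM pupil.

Aberrations picked up along the projector path (the dominant one in an
obliquely illuminated SLM being oblique astigmatism) are represented as a
linear combination of Zernike polynomials and encoded on the SLM on top of the
multi-focus hologram, with coefficients of opposite sign cancelling the system
aberration.

Convention: OSA/ANSI double indexing — radial order ``p >= 0``, signed
azimuthal order ``q`` with ``|q| <= p`` and ``p - |q|`` even; ``q >= 0`` pairs
with cos, ``q < 0`` with sin.  Polynomials are scaled to unit RMS over the
unit disk (piston Z_0^0 = 1, oblique astigmatism Z_2^{-2} = sqrt(6) rho^2
sin 2theta, ...), so a coefficient is directly the RMS phase it contributes,
in radians.  A Noll single-index conversion helper is provided for
interoperability with adaptive-optics tooling.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidParameterError

__all__ = ["ZernikeSpec", "zernike_eval", "zernike_surface", "noll_to_osa"]


def _check_index(p: int, q: int) -> None:
    if not (isinstance(p, numbers.Integral) and isinstance(q, numbers.Integral)):
        raise InvalidParameterError(f"Zernike indices must be integers, got (p={p}, q={q})")
    if p < 0 or abs(q) > p or (p - abs(q)) % 2 != 0:
        raise InvalidParameterError(
            f"invalid Zernike index (p={p}, q={q}): need p >= 0, |q| <= p, p - |q| even"
        )


def _radial(p: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_p^m(rho), m = |q| >= 0."""
    out = np.zeros_like(rho)
    for k in range((p - m) // 2 + 1):
        coeff = (
            (-1) ** k
            * math.factorial(p - k)
            / (
                math.factorial(k)
                * math.factorial((p + m) // 2 - k)
                * math.factorial((p - m) // 2 - k)
            )
        )
        out += coeff * rho ** (p - 2 * k)
    return out


def zernike_eval(p: int, q: int, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the orthonormal Zernike polynomial Z_p^q on a pupil grid.

    Parameters
    ----------
    p, q : int
        OSA/ANSI radial and signed azimuthal orders.
    u, v : ndarray
        Normalized pupil coordinates (pupil-edge radius 1); points with
        radius > 1 evaluate to 0.

    Returns
    -------
    ndarray
        Phase surface in radians with unit RMS over the unit disk.
    """
    _check_index(p, q)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    m = abs(q)
    norm = math.sqrt(p + 1) if q == 0 else math.sqrt(2 * (p + 1))
    surface = norm * _radial(p, m, rho)
    if q > 0:
        surface = surface * np.cos(m * theta)
    elif q < 0:
        surface = surface * np.sin(m * theta)
    return np.where(rho <= 1.0, surface, 0.0)


def noll_to_osa(j: int) -> tuple[int, int]:
    """Convert a Noll single index ``j >= 1`` to OSA/ANSI ``(p, q)``.

    Noll ordering assigns even j to cosine (q >= 0) terms and odd j to sine
    (q < 0) terms within each radial order.
    """
    if not isinstance(j, numbers.Integral) or j < 1:
        raise InvalidParameterError(f"Noll index must be an integer >= 1, got {j}")
    p = 0
    j1 = j - 1
    while j1 > p:
        p += 1
        j1 -= p
    m = p % 2 + 2 * ((j1 + (p + 1) % 2) // 2)
    q = 0 if m == 0 else (m if j % 2 == 0 else -m)
    return p, q


@dataclass
class ZernikeSpec:
    """A weighted set of Zernike terms.

    ``terms`` is a list of ``(p, q, coeff)`` with coefficients in radians of
    RMS phase.  ``scope`` records whether the set applies globally (one
    correction for the whole pupil, the default) or per-spot (depth-dependent
    corrections attached to individual foci).  An empty spec encodes zero
    aberration.
    """

    terms: list[tuple[int, int, float]] = field(default_factory=list)
    scope: str = "global"

    def __post_init__(self) -> None:
        if self.scope not in ("global", "per-spot"):
            raise InvalidParameterError(f"scope must be 'global' or 'per-spot', got {self.scope!r}")
        cleaned = []
        for term in self.terms:
            p, q, coeff = term
            _check_index(p, q)
            coeff = float(coeff)
            if not math.isfinite(coeff):
                raise InvalidParameterError(f"non-finite Zernike coefficient for (p={p}, q={q})")
            cleaned.append((int(p), int(q), coeff))
        self.terms = cleaned

    def __bool__(self) -> bool:
        return bool(self.terms)

    def negated(self) -> "ZernikeSpec":
        """The spec with every coefficient sign-flipped (aberration -> correction)."""
        return ZernikeSpec([(p, q, -c) for p, q, c in self.terms], scope=self.scope)

    def surface(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Alias for :func:`zernike_surface` on this spec."""
        return zernike_surface(self, u, v)

    # -- serialization ---------------------------------------------------

    def to_records(self) -> list[dict]:
        return [{"p": p, "q": q, "coeff": c} for p, q, c in self.terms]

    @classmethod
    def from_records(cls, records, scope: str = "global") -> "ZernikeSpec":
        terms = []
        for rec in records:
            try:
                terms.append((rec["p"], rec["q"], rec["coeff"]))
            except (KeyError, TypeError) as exc:
                raise InvalidParameterError(
                    f"Zernike record must have keys p, q, coeff; got {rec!r}"
                ) from exc
        return cls(terms, scope=scope)


def zernike_surface(spec: ZernikeSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Linear combination ``sum_i C_i Z_i(u, v)`` in radians; empty spec -> zeros."""
    u = np.asarray(u, dtype=float)
    out = np.zeros(np.broadcast(u, np.asarray(v)).shape, dtype=float)
    for p, q, coeff in spec.terms:
        out += coeff * zernike_eval(p, q, u, v)
    return out
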