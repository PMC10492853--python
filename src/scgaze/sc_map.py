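"""Complex-logarithmic mapping between gaze-shift vectors and SC map coordinates.

The superior-colliculus motor map represents a gaze-shift vector
``(dG, phi)`` — amplitude in degrees, direction in degrees — at an
anatomical location ``(u, v)`` in millimetres, where ``u`` runs along the
rostral-caudal axis and ``v`` along the medial-lateral axis.  The afferent
(visual-to-anatomical) transformation is the complex logarithm

    u = Bu * ln( sqrt(dG^2 + 2*A*dG*cos(phi) + A^2) / A )
    v = Bv * atan2( dG*sin(phi), dG*cos(phi) + A )

with scale factors ``Bu`` (mm), ``Bv`` (mm/rad) and foveal shift ``A``
(deg) taken from classic microstimulation calibrations.  Writing the gaze
vector as a complex number ``z = dG * exp(i*phi)`` the map is
``u + i*(Bu/Bv)*v' = Bu * log((z + A)/A)``, which makes the analytic
inverse (the efferent map, needed to assign mini spike-vectors to recorded
sites when decoding population activity) exact:

    z = A * exp(u/Bu + i*v/Bv) - A.

Directions are accepted and returned in degrees; all trigonometry is done
in radians internally.  The calibration covers the right hemifield; the
map is evaluated anywhere with |phi| < 180 deg, but directions far outside
roughly +/-80 deg are beyond the range the calibration was derived for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MapParams", "afferent_map", "efferent_map"]


@dataclass(frozen=True)
class MapParams:
    """Fixed scaling and shift parameters of the SC motor map.

    Attributes
    ----------
    Bu : float
        Scale along the rostral-caudal axis (mm).
    Bv : float
        Scale along the medial-lateral axis (mm/rad).
    A : float
        Foveal shift (deg).
    """

    Bu: float = 1.4
    Bv: float = 1.8
    A: float = 3.0

    def __post_init__(self) -> None:
        if not (self.Bu > 0 and self.Bv > 0 and self.A > 0):
            raise ValueError("MapParams requires Bu > 0, Bv > 0, A > 0")


def afferent_map(dG, phi_deg, params: MapParams = MapParams()):
    """Map gaze-shift vectors (deg) to SC anatomical coordinates (mm).

    Parameters
    ----------
    dG : array_like
        Gaze-shift amplitude(s) in degrees, >= 0.
    phi_deg : array_like
        Gaze-shift direction(s) in degrees (0 = horizontal contralateral,
        positive = upward), |phi| < 180.
    params : MapParams
        Map calibration constants.

    Returns
    -------
    (u, v) : ndarray or float
        Rostral-caudal and medial-lateral coordinates in mm.
    """
    dG = np.asarray(dG, dtype=float)
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    if np.any(~np.isfinite(dG)) or np.any(~np.isfinite(phi)):
        raise ValueError("afferent_map: non-finite inputs")
    if np.any(dG < 0):
        raise ValueError("afferent_map: gaze amplitude dG must be >= 0")
    A = params.A
    x = dG * np.cos(phi) + A
    y = dG * np.sin(phi)
    u = params.Bu * 0.5 * np.log((x * x + y * y) / (A * A))
    # two-argument arctangent preserves the quadrant beyond |phi| = 90 deg
    v = params.Bv * np.arctan2(y, x)
    if u.ndim == 0:
        return float(u), float(v)
    return u, v


def efferent_map(u, v, params: MapParams = MapParams()):
    """Map SC anatomical coordinates (mm) back to gaze-shift vectors (deg).

    Exact analytic inverse of :func:`afferent_map`:
    ``z = A*exp(u/Bu + i*v/Bv) - A`` with ``dG = |z|``, ``phi = arg(z)``.

    Returns
    -------
    (dG, phi_deg) : ndarray or float
        Amplitude (deg) and direction (deg).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(~np.isfinite(v)):
        raise ValueError("efferent_map: non-finite inputs")
    A = params.A
    r = A * np.exp(u / params.Bu)
    ang = v / params.Bv
    zx = r * np.cos(ang) - A
    zy = r * np.sin(ang)
    dG = np.hypot(zx, zy)
    phi = np.rad2deg(np.arctan2(zy, zx))
    # the origin maps to dG=0 where the direction is undefined; report 0
    phi = np.where(dG < 1e-12, 0.0, phi)
    if dG.ndim == 0:
        return float(dG), float(phi)
    return dG, phi
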