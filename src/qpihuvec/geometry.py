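"""Analytic geometry of phantom solids.

Phantom cells are modelled as solids of known closed-form (or high-accuracy
quadrature) volume, footprint area and upper-surface area, from which the
ground-truth shape metrics follow:

* sphericity = curved surface of the equal-volume hemisphere over the solid's
  upper surface, ``2*pi*r_eq**2 / S`` with ``r_eq = (3V / (2*pi))**(1/3)``.
  A hemisphere scores exactly 1; flatter solids score less.
* length/width ratio = ratio of the base-ellipse semi-axes.

All lengths in µm, areas µm², volumes µm³.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

GAUSSIAN_TRUNCATION_SIGMA = 3.0  # gaussian bumps are cut at 3 sigma


# ---------------------------------------------------------------------------
# spherical cap (base radius a, apex height h, h <= a for cells)
# ---------------------------------------------------------------------------

def cap_sphere_radius(a: float, h: float) -> float:
    """Radius of the sphere a cap of base radius ``a`` and height ``h`` sits on."""
    return (a * a + h * h) / (2.0 * h)


def spherical_cap_volume(a: float, h: float) -> float:
    return np.pi * h * (3.0 * a * a + h * h) / 6.0


def spherical_cap_surface(a: float, h: float) -> float:
    """Curved (upper) surface area of the cap, ``2*pi*R*h``."""
    return np.pi * (a * a + h * h)


def spherical_cap_profile(rho: np.ndarray, a: float, h: float) -> np.ndarray:
    """Cap thickness at normalised base radius ``rho`` in [0, 1]."""
    R = cap_sphere_radius(a, h)
    r = np.clip(np.asarray(rho, dtype=float), 0.0, 1.0) * a
    return np.sqrt(np.maximum(R * R - r * r, 0.0)) - (R - h)


def sphericity_from_vs(volume: float, surface: float) -> float:
    """Equal-volume-hemisphere sphericity; > 1 values are not clipped here."""
    r_eq = (3.0 * volume / (2.0 * np.pi)) ** (1.0 / 3.0)
    return 2.0 * np.pi * r_eq * r_eq / surface


def spherical_cap_sphericity(a: float, h: float) -> float:
    return sphericity_from_vs(spherical_cap_volume(a, h),
                              spherical_cap_surface(a, h))


def cap_sphericity_of_ratio(k: float) -> float:
    """Sphericity of a spherical cap as a function of k = height / base radius.

    Scale-free: psi(k) = 2 * (k*(3 + k^2)/4)^(2/3) / (1 + k^2); psi(1) = 1.
    """
    if k <= 0:
        raise ValueError("height/radius ratio must be positive")
    return 2.0 * (k * (3.0 + k * k) / 4.0) ** (2.0 / 3.0) / (1.0 + k * k)


def cap_ratio_for_sphericity(psi: float) -> float:
    """Invert ``cap_sphericity_of_ratio`` on (0, 1]: the k giving sphericity psi."""
    if not 0.0 < psi <= 1.0:
        raise ValueError(f"sphericity must be in (0, 1], got {psi}")
    if psi == 1.0:
        return 1.0
    return brentq(lambda k: cap_sphericity_of_ratio(k) - psi, 1e-9, 1.0,
                  xtol=1e-12, rtol=1e-12)


# ---------------------------------------------------------------------------
# hemi-ellipsoid ("ellipsoidal cap") and gaussian bump
# ---------------------------------------------------------------------------

def ellipsoidal_cap_volume(a: float, b: float, h: float) -> float:
    """Volume of the half-ellipsoid with base semi-axes a, b and height h."""
    return 2.0 * np.pi * a * b * h / 3.0


def ellipsoidal_cap_profile(rho: np.ndarray, h: float) -> np.ndarray:
    rho = np.clip(np.asarray(rho, dtype=float), 0.0, 1.0)
    return h * np.sqrt(np.maximum(1.0 - rho * rho, 0.0))


def gaussian_bump_volume(a: float, b: float, h: float) -> float:
    """Volume of a gaussian bump truncated at the footprint ellipse (3 sigma)."""
    k = GAUSSIAN_TRUNCATION_SIGMA
    sa, sb = a / k, b / k
    return 2.0 * np.pi * sa * sb * h * (1.0 - np.exp(-0.5 * k * k))


def gaussian_bump_profile(rho: np.ndarray, h: float) -> np.ndarray:
    k = GAUSSIAN_TRUNCATION_SIGMA
    rho = np.asarray(rho, dtype=float)
    out = h * np.exp(-0.5 * (k * rho) ** 2)
    return np.where(rho <= 1.0, out, 0.0)


# ---------------------------------------------------------------------------
# upper-surface quadrature for profiles t(x, y) = f(rho) over an ellipse
# ---------------------------------------------------------------------------

def surface_quadrature(f, a: float, b: float, n_rho: int = 256,
                       n_theta: int = 128, eps: float = 1e-7) -> float:
    """Upper-surface area of the solid t(x,y) = f(rho) over the base ellipse.

    ``rho = sqrt((x'/a)^2 + (y'/b)^2)``; the integral
    ``S = ∫∫ sqrt(1 + |grad t|^2) dA`` is evaluated in elliptic polar
    coordinates with the substitution ``rho = sin(phi)`` so rim-tangent
    singularities (vertical cap rims) stay integrable. ``f`` must be
    vectorised; its derivative is taken by central differences at spacing
    ``eps`` in rho.
    """
    xg, wg = leggauss(n_rho)
    phi = 0.25 * np.pi * (xg + 1.0)          # phi in (0, pi/2)
    wphi = 0.25 * np.pi * wg
    rho = np.sin(phi)
    drho = np.cos(phi)
    lo = np.clip(rho - eps, 0.0, 1.0)
    hi = np.clip(rho + eps, 0.0, 1.0)
    fp = (f(hi) - f(lo)) / (hi - lo)          # f'(rho)

    xt, wt = leggauss(n_theta)
    theta = 0.25 * np.pi * (xt + 1.0)         # quarter period; profile is even
    wtheta = 0.25 * np.pi * wt
    c2 = (np.cos(theta) / a) ** 2
    s2 = (np.sin(theta) / b) ** 2
    # integrand over (phi, theta): sqrt(1 + f'^2 (cos^2/a^2 + sin^2/b^2)) a b rho drho
    g = np.sqrt(1.0 + np.outer(fp * fp, c2 + s2))
    area_el = a * b * (rho * drho * wphi) @ g @ wtheta
    return 4.0 * area_el  # four symmetric quadrants


def solid_truth(model: str, a: float, b: float, height: float) -> dict:
    """Analytic volume, upper-surface area and sphericity of a phantom solid.

    ``model`` is one of ``spherical_cap`` (requires a == b),
    ``ellipsoidal_cap`` or ``gaussian_bump``; ``a >= b`` are the base
    semi-axes and ``height`` the apex thickness.
    """
    if model == "spherical_cap":
        if not np.isclose(a, b):
            raise ValueError("spherical_cap requires equal footprint radii")
        V = spherical_cap_volume(a, height)
        S = spherical_cap_surface(a, height)
    elif model == "ellipsoidal_cap":
        V = ellipsoidal_cap_volume(a, b, height)
        S = surface_quadrature(lambda r: ellipsoidal_cap_profile(r, height), a, b)
    elif model == "gaussian_bump":
        V = gaussian_bump_volume(a, b, height)
        S = surface_quadrature(lambda r: gaussian_bump_profile(r, height), a, b)
    else:
        raise ValueError(f"unknown phantom model {model!r}")
    return {
        "volume": V,
        "surface_area": S,
        "sphericity": min(sphericity_from_vs(V, S), 1.0),
        "area": np.pi * a * b,
        "length_width_ratio": a / b,
    }


def scaled_solid_truth(model: str, a: float, b: float, height: float,
                       zscale: float) -> dict:
    """Truth for a solid whose thickness profile is multiplied by ``zscale``.

    Volume and footprint scale in closed form; the surface needs quadrature
    except for the unscaled spherical cap.
    """
    if zscale == 1.0:
        return solid_truth(model, a, b, height)
    if model == "spherical_cap":
        base = lambda r: zscale * spherical_cap_profile(r, a, height)
        V = zscale * spherical_cap_volume(a, height)
    elif model == "ellipsoidal_cap":
        # a z-scaled hemi-ellipsoid is a hemi-ellipsoid of height zscale*h
        return solid_truth(model, a, b, zscale * height)
    elif model == "gaussian_bump":
        return solid_truth(model, a, b, zscale * height)
    else:
        raise ValueError(f"unknown phantom model {model!r}")
    S = surface_quadrature(base, a, b)
    return {
        "volume": V,
        "surface_area": S,
        "sphericity": min(sphericity_from_vs(V, S), 1.0),
        "area": np.pi * a * b,
        "length_width_ratio": a / b,
    }


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (N, 2) coordinate array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))
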