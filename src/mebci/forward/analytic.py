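"""Analytic dipole potentials: free medium, homogeneous sphere, three shells.

The concentric three-sphere solution expands the dipole potential in
Legendre harmonics. In each shell the degree-n radial dependence is
``A r^n + B r^-(n+1)``; coefficients follow from continuity of potential
and radial current at the interfaces and zero radial current at the outer
scalp surface. The homogeneous-sphere closed form (generating-function
summation of the same series) serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dipole",
    "ShellModel",
    "dipole_potential_free_medium",
    "homogeneous_sphere_potential",
    "analytic_three_sphere_potential",
    "analytic_leadfield",
]


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m), moment (A*m) and an anatomical label."""

    position: np.ndarray
    moment: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        m = np.asarray(self.moment, dtype=float)
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "moment", m)
        if p.shape != (3,) or m.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")
        if np.linalg.norm(m) == 0:
            raise ValueError("dipole moment must be non-zero")


@dataclass(frozen=True)
class ShellModel:
    """Concentric spherical three-shell head: brain < skull < scalp."""

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0 < self.radii[0] < self.radii[1] < self.radii[2]):
            raise ValueError("radii must be strictly increasing and positive")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be > 0")
        c = np.zeros(3) if self.center is None else np.asarray(self.center, float)
        object.__setattr__(self, "center", c)


def dipole_potential_free_medium(d: Dipole, x, kappa: float) -> float:
    """Far-field dipole potential U = |d| cos(theta) / (4 pi kappa r^2)."""
    x = np.asarray(x, dtype=float)
    rvec = x - d.position
    r = np.linalg.norm(rvec, axis=-1)
    if np.any(r == 0):
        raise ValueError("observation point coincides with the dipole")
    mnorm = np.linalg.norm(d.moment)
    cos_t = (rvec @ d.moment) / (r * mnorm)
    out = mnorm * cos_t / (4.0 * np.pi * kappa * r**2)
    return float(out) if np.ndim(out) == 0 else out


def _local_frame(d: Dipole, electrode: np.ndarray, center: np.ndarray):
    """Geometry helpers: eccentricity direction, angles, moment split."""
    p = d.position - center
    f = np.linalg.norm(p)
    if f < 1e-15:
        u = np.array([0.0, 0.0, 1.0])
    else:
        u = p / f
    e = electrode - center
    re = np.linalg.norm(e)
    eu = e / re
    cos_t = float(np.clip(eu @ u, -1.0, 1.0))
    m_r = float(d.moment @ u)
    m_t_vec = d.moment - m_r * u
    m_t = float(np.linalg.norm(m_t_vec))
    # azimuth of the electrode around u measured from the tangential moment
    e_perp = eu - cos_t * u
    n_perp = np.linalg.norm(e_perp)
    if m_t < 1e-18 * max(1.0, np.linalg.norm(d.moment)) or n_perp < 1e-12:
        cos_phi = 0.0
    else:
        cos_phi = float((e_perp / n_perp) @ (m_t_vec / m_t))
    sin_t = float(np.sqrt(max(0.0, 1.0 - cos_t**2)))
    return f, re, cos_t, sin_t, m_r, m_t, cos_phi


def homogeneous_sphere_potential(d: Dipole, electrode, radius: float,
                                 kappa: float, center=(0, 0, 0)) -> float:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Obtained by summing the Legendre series with generating functions:
    radial part  sum (2n+1) t^(n-1) P_n,
    tangential   sum (2n+1)/n t^(n-1) P_n^1.
    """
    center = np.asarray(center, dtype=float)
    electrode = np.asarray(electrode, dtype=float)
    f, re, x, sin_t, m_r, m_t, cos_phi = _local_frame(d, electrode, center)
    if abs(re - radius) > 1e-6 * radius:
        raise ValueError("electrode must lie on the sphere surface")
    t = f / radius
    if t >= 1.0:
        raise ValueError("dipole must be strictly inside the sphere")
    delta = np.sqrt(1.0 - 2.0 * t * x + t * t)
    g = 1.0 / delta
    if t < 1e-12:
        # central dipole: only n=1 survives, potential ~ 3 cos(theta)/R^2
        rad = 3.0 * x
        tan = 3.0 * sin_t
    else:
        s1 = (x - t) / delta**3  # sum n t^(n-1) P_n
        rad = 2.0 * s1 + (g - 1.0) / t
        tan = 2.0 * sin_t * g**3 + sin_t * (1.0 + delta) / (
            delta * (1.0 - t * x + delta)
        )
    return (m_r * rad + m_t * cos_phi * tan) / (4.0 * np.pi * kappa * radius**2)


def _shell_coefficients(n: np.ndarray, m: ShellModel) -> np.ndarray:
    """Scalp-surface radial factor per harmonic degree, unit source coefficient.

    For each degree n solves the 5x5 system for (A1, A2, B2, A3, B3) with the
    region-1 source term r^-(n+1), and returns the value
    A3 R^n + B3 R^-(n+1) at the scalp radius R.
    """
    r1, r2, r3 = m.radii
    s1, s2, s3 = m.conductivities
    out = np.empty(n.shape, dtype=float)
    for i, nn in enumerate(n):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at r1: A1 r1^n - A2 r1^n - B2 r1^-(n+1) = -r1^-(n+1)
        M[0] = [r1**nn, -(r1**nn), -(r1 ** -(nn + 1)), 0, 0]
        rhs[0] = -(r1 ** -(nn + 1))
        # current continuity at r1
        M[1] = [
            s1 * nn * r1 ** (nn - 1),
            -s2 * nn * r1 ** (nn - 1),
            s2 * (nn + 1) * r1 ** -(nn + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (nn + 1) * r1 ** -(nn + 2)
        # potential continuity at r2
        M[2] = [0, r2**nn, r2 ** -(nn + 1), -(r2**nn), -(r2 ** -(nn + 1))]
        # current continuity at r2
        M[3] = [
            0,
            s2 * nn * r2 ** (nn - 1),
            -s2 * (nn + 1) * r2 ** -(nn + 2),
            -s3 * nn * r2 ** (nn - 1),
            s3 * (nn + 1) * r2 ** -(nn + 2),
        ]
        # zero radial current at the scalp surface r3
        M[4] = [0, 0, 0, nn * r3 ** (nn - 1), -(nn + 1) * r3 ** -(nn + 2)]
        sol = np.linalg.solve(M, rhs)
        out[i] = sol[3] * r3**nn + sol[4] * r3 ** -(nn + 1)
    return out


def analytic_three_sphere_potential(
    d: Dipole,
    electrode,
    m: ShellModel,
    n_terms: int = 80,
    rtol: float = 1e-9,
    max_eccentricity: float = 0.95,
) -> float:
    """Legendre-series scalp potential of a dipole in three concentric shells."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    electrode = np.asarray(electrode, dtype=float)
    f, re, x, sin_t, m_r, m_t, cos_phi = _local_frame(d, electrode, m.center)
    if f > max_eccentricity * m.radii[0]:
        raise ValueError(
            f"dipole eccentricity {f / m.radii[0]:.3f} exceeds "
            f"{max_eccentricity}; series may not converge"
        )
    if abs(re - m.radii[2]) > 1e-6 * m.radii[2]:
        raise ValueError("electrode must lie on the scalp surface")
    s1 = m.conductivities[0]
    n = np.arange(1, n_terms + 1)
    radial_factor = _shell_coefficients(n, m)  # scalp value per unit source coeff
    # Legendre P_n and P_n^1 (no Condon-Shortley phase) by upward recurrence
    pn = np.empty(n_terms + 1)
    pn1 = np.empty(n_terms + 1)
    pn[0], pn1[0] = 1.0, 0.0
    pn[1], pn1[1] = x, sin_t
    for k in range(1, n_terms):
        pn[k + 1] = ((2 * k + 1) * x * pn[k] - k * pn[k - 1]) / (k + 1)
        pn1[k + 1] = ((2 * k + 1) * x * pn1[k] - (k + 1) * pn1[k - 1]) / k
    c_rad = n * m_r * (f ** (n - 1)) / (4.0 * np.pi * s1)
    c_tan = m_t * (f ** (n - 1)) / (4.0 * np.pi * s1)
    terms = radial_factor * (c_rad * pn[1:] + c_tan * cos_phi * pn1[1:])
    total = float(np.sum(terms))
    # convergence check on the tail
    tail = abs(terms[-1])
    if total != 0 and tail > rtol * abs(total) * 10:
        import warnings

        warnings.warn(
            "three-sphere series may not have converged; increase n_terms",
            RuntimeWarning,
            stacklevel=2,
        )
    return total


def analytic_leadfield(dipoles, montage_positions, m: ShellModel,
                       n_terms: int = 80) -> np.ndarray:
    """Electrode x (3*dipoles) gain matrix from the series solution."""
    montage_positions = np.asarray(montage_positions, dtype=float)
    ne = len(montage_positions)
    cols = []
    for d in dipoles:
        for ax in range(3):
            moment = np.zeros(3)
            moment[ax] = 1.0
            comp = Dipole(d.position, moment, d.region)
            cols.append(
                [
                    analytic_three_sphere_potential(comp, e, m, n_terms)
                    for e in montage_positions
                ]
            )
    return np.asarray(cols).T.reshape(ne, 3 * len(dipoles))
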