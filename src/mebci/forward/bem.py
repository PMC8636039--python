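"""Boundary-element forward solution on nested closed surfaces.

Constant (centroid) collocation of the surface-potential integral equation
for piecewise-homogeneous isotropic compartments:

    (sigma_k^- + sigma_k^+)/2 * u(r) =
        sigma_src * u_inf(r)
        + 1/(4 pi) * sum_j (sigma_j^- - sigma_j^+) int_{S_j} u dOmega_r

with the solid angle measured so that a closed surface subtends 4 pi from
inside. The singular system is deflated with the outer-surface constant
vector. Because the skull conductivity is ~80x lower than brain/scalp, the
raw equation loses accuracy; the isolated-skull correction is applied: the
inner-surface problem with an insulating exterior is solved first, and the
identity "double layer of the isolated solution = sigma_src * u_inf outside
S1" is used to cancel the large terms analytically before discretization.

Electrode potentials are interpolated from the three nearest scalp-triangle
centroids (inverse-distance weights) and re-referenced to CPz.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mebci.forward.analytic import Dipole, ShellModel
from mebci.forward.geometry import TriSurfaceSet, solid_angles, three_shell_mesh
from mebci.forward.montage import ElectrodeMontage, standard_montage

__all__ = [
    "LeadField",
    "BemSolution",
    "bem_solution",
    "bem_leadfield",
    "place_dipole",
    "project_to_scalp",
    "DIPOLE_TEMPLATES",
]

#: Canonical dipole positions (m) per microexpression class, head frame.
#: Both brow classes sit in the frontal lobe but at distinct loci (superior
#: vs inferior frontal) so their scalp patterns are separable.
DIPOLE_TEMPLATES: dict[str, tuple[str, tuple[float, float, float]]] = {
    "mRB": ("frontal", (0.0, 0.05, 0.06)),
    "mFB": ("frontal", (0.0, 0.068, 0.035)),
    "mLS": ("right_motor", (0.04, 0.01, 0.06)),
    "mRS": ("left_motor", (-0.04, 0.01, 0.06)),
}


@dataclass(frozen=True)
class LeadField:
    """Electrode x (3 * n_dipoles) gain matrix (V per A*m)."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    method: str  # "analytic" | "bem"
    provenance: str = ""

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "labels", tuple(self.labels))
        if not np.all(np.isfinite(mat)):
            raise ValueError("lead field contains non-finite entries")
        if mat.shape[0] != len(self.labels):
            raise ValueError("row count must match electrode labels")
        if mat.shape[1] % 3 != 0:
            raise ValueError("column count must be a multiple of 3")

    @property
    def n_dipoles(self) -> int:
        return self.matrix.shape[1] // 3

    def gains(self, dipole_index: int, moment: np.ndarray) -> np.ndarray:
        """Per-electrode gain for one dipole with the given moment."""
        block = self.matrix[:, 3 * dipole_index: 3 * dipole_index + 3]
        return block @ np.asarray(moment, dtype=float)

    def save(self, path) -> None:
        path = Path(path)
        header = {
            "labels": list(self.labels),
            "method": self.method,
            "provenance": self.provenance,
            "units": "V per A*m",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))
        np.savetxt(path, self.matrix, delimiter="\t")

    @classmethod
    def load(cls, path) -> "LeadField":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(mat, tuple(header["labels"]), header["method"],
                   header.get("provenance", ""))


def _mesh_hash(mesh: TriSurfaceSet, montage: ElectrodeMontage) -> str:
    h = hashlib.sha256()
    for s in mesh.surfaces:
        h.update(np.ascontiguousarray(s.vertices).tobytes())
        h.update(np.ascontiguousarray(s.triangles).tobytes())
    h.update(np.asarray(mesh.conductivities, dtype=float).tobytes())
    h.update(np.ascontiguousarray(montage.positions).tobytes())
    return h.hexdigest()[:16]


@dataclass
class BemSolution:
    """Factorized BEM operator reusable across dipoles."""

    mesh: TriSurfaceSet
    montage: ElectrodeMontage
    centroids: list[np.ndarray]
    offsets: np.ndarray  # surface start indices into the stacked unknowns
    lu: tuple
    lu_iso: tuple
    sigma_in: np.ndarray
    sigma_out: np.ndarray
    coeff: np.ndarray  # per-surface 2/(sigma^- + sigma^+)
    omega_to_electrodes: np.ndarray  # interpolation of scalp unknowns
    provenance: str


def _u_inf(points: np.ndarray, d: Dipole, sigma_src: float) -> np.ndarray:
    rvec = points - d.position
    r = np.linalg.norm(rvec, axis=1)
    return (rvec @ d.moment) / (4.0 * np.pi * sigma_src * r**3)


def bem_solution(mesh: TriSurfaceSet, montage: ElectrodeMontage) -> BemSolution:
    """Assemble and factorize the deflated three-surface BEM system."""
    from scipy.linalg import lu_factor

    mesh.validate()
    sig = mesh.conductivities
    sigma_in = np.array([sig[0], sig[1], sig[2]])
    sigma_out = np.array([sig[1], sig[2], 0.0])
    surfs = mesh.surfaces
    centroids = [s.centroids for s in surfs]
    counts = [len(c) for c in centroids]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n = offsets[-1]
    all_pts = np.concatenate(centroids, axis=0)

    # B[i, j] = (sigma_j^- - sigma_j^+) / (2 pi (sigma_i^- + sigma_i^+)) * Omega_ij
    B = np.empty((n, n))
    for j, s in enumerate(surfs):
        om = solid_angles(s, all_pts)  # (n, nt_j)
        # self solid angle: rows of the same surface must sum to 2 pi
        rows = slice(offsets[j], offsets[j + 1])
        own = om[rows, :]
        np.fill_diagonal(own, 0.0)
        np.fill_diagonal(own, 2.0 * np.pi - own.sum(axis=1))
        om[rows, :] = own
        B[:, offsets[j]: offsets[j + 1]] = om * (sigma_in[j] - sigma_out[j])
    denom = np.concatenate(
        [np.full(c, 2.0 * np.pi * (sigma_in[k] + sigma_out[k]))
         for k, c in enumerate(counts)]
    )
    B /= denom[:, None]

    A = np.eye(n) - B
    # deflation against the constant null vector, weighted on the outer surface
    w = np.zeros(n)
    w[offsets[2]: offsets[3]] = 1.0 / counts[2]
    A += np.ones((n, 1)) @ w[None, :]
    lu = lu_factor(A)

    # isolated inner-surface system (insulating outside S1)
    om11 = solid_angles(surfs[0], centroids[0])
    np.fill_diagonal(om11, 0.0)
    np.fill_diagonal(om11, 2.0 * np.pi - om11.sum(axis=1))
    A_iso = np.eye(counts[0]) - om11 / (2.0 * np.pi)
    A_iso += np.ones((counts[0], 1)) @ np.full((1, counts[0]), 1.0 / counts[0])
    lu_iso = lu_factor(A_iso)

    # electrode interpolation from the three nearest scalp centroids
    scalp = centroids[2]
    interp = np.zeros((montage.n_channels, n))
    for i, e in enumerate(montage.positions):
        dist = np.linalg.norm(scalp - e, axis=1)
        near = np.argsort(dist)[:3]
        wgt = 1.0 / np.maximum(dist[near], 1e-12)
        wgt /= wgt.sum()
        interp[i, offsets[2] + near] = wgt
    coeff = 2.0 / (sigma_in + sigma_out)
    return BemSolution(
        mesh, montage, centroids, offsets, lu, lu_iso,
        sigma_in, sigma_out, coeff, interp, _mesh_hash(mesh, montage),
    )


def _solve_dipole(sol: BemSolution, d: Dipole, sigma_src: float) -> np.ndarray:
    """Surface potentials for one dipole using the isolated-skull correction.

    With v the isolated inner-surface solution and u = w + [v, 0, 0], the
    corrected right-hand side is

        S1 rows:      coeff0 * sigma2 * (sigma_src/sigma1 * u_inf - v)
        S2, S3 rows:  coeff_k * (sigma2/sigma1) * sigma_src * u_inf

    where the large double-layer terms of v were cancelled analytically via
    the exterior identity of the isolated solution.
    """
    from scipy.linalg import lu_solve

    off = sol.offsets
    n = off[-1]
    c0 = sol.centroids[0]
    s1, s2 = sol.sigma_in[0], sol.sigma_in[1]

    u_inf_1 = _u_inf(c0, d, sigma_src)
    v = lu_solve(sol.lu_iso, (2.0 * sigma_src / s1) * u_inf_1)

    g = np.empty(n)
    g[off[0]: off[1]] = sol.coeff[0] * s2 * (sigma_src * u_inf_1 / s1 - v)
    for k in (1, 2):
        g[off[k]: off[k + 1]] = sol.coeff[k] * (s2 / s1) * sigma_src * _u_inf(
            sol.centroids[k], d, sigma_src
        )
    w = lu_solve(sol.lu, g)
    u = w
    u[off[0]: off[1]] += v
    # zero mean on the outer surface (reference fixed later per montage)
    u -= u[off[2]: off[3]].mean()
    return u


def bem_leadfield(
    mesh: TriSurfaceSet | None,
    montage: ElectrodeMontage | None,
    dipoles,
    reference: str | None = "CPz",
) -> LeadField:
    """Lead field via BEM; ``None`` arguments use the procedural defaults."""
    if mesh is None:
        mesh = three_shell_mesh()
    if montage is None:
        montage = standard_montage(scalp_radius=mesh.surfaces[2].max_radius(mesh.center))
    sol = bem_solution(mesh, montage)
    return leadfield_from_solution(sol, dipoles, reference)


def leadfield_from_solution(sol: BemSolution, dipoles,
                            reference: str | None = "CPz") -> LeadField:
    mesh = sol.mesh
    brain_r = mesh.surfaces[0].min_radius(mesh.center)
    sigma_src = mesh.conductivities[0]
    cols = []
    for d in dipoles:
        if np.linalg.norm(d.position - mesh.center) >= brain_r:
            raise ValueError("dipole must lie strictly inside the brain surface")
        for ax in range(3):
            mom = np.zeros(3)
            mom[ax] = 1.0
            u = _solve_dipole(sol, Dipole(d.position, mom, d.region), sigma_src)
            cols.append(sol.omega_to_electrodes @ u)
    mat = np.asarray(cols).T
    if reference is not None:
        mat = mat - mat[sol.montage.index(reference), :][None, :]
    return LeadField(mat, sol.montage.labels, "bem", sol.provenance)


def place_dipole(class_label: str, shell: ShellModel | None = None,
                 magnitude: float = 1e-8) -> Dipole:
    """Canonical radially-oriented dipole for a microexpression class."""
    if class_label not in DIPOLE_TEMPLATES:
        raise KeyError(
            f"unknown class {class_label!r}; expected one of "
            f"{sorted(DIPOLE_TEMPLATES)}"
        )
    region, pos = DIPOLE_TEMPLATES[class_label]
    p = np.asarray(pos, dtype=float)
    if shell is not None:
        p = p + shell.center
        radial = (p - shell.center) / np.linalg.norm(p - shell.center)
    else:
        radial = p / np.linalg.norm(p)
    return Dipole(p, magnitude * radial, region)


def project_to_scalp(
    source: np.ndarray,
    lf: LeadField,
    d_index: int,
    moment: np.ndarray,
    target_rms: float | None = None,
) -> np.ndarray:
    """Outer product of electrode gains with a source series.

    ``source`` is the mixed population potential (mV-scale, arbitrary units
    before calibration). When ``target_rms`` is given, the output is rescaled
    so that the median per-channel RMS equals it (amplitude calibration
    against a template session); otherwise raw gain * source is returned.
    Returns (samples, channels).
    """
    g = lf.gains(d_index, moment)  # (n_elec,)
    eeg = np.asarray(source, dtype=float)[:, None] * g[None, :]
    if target_rms is not None:
        rms = np.sqrt(np.mean(eeg**2, axis=0))
        med = np.median(rms[rms > 0])
        if med > 0:
            eeg = eeg * (target_rms / med)
    return eeg
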