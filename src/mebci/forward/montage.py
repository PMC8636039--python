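"""30-channel 10-20 electrode montage on a spherical scalp.

Positions are constructed geometrically on the unit sphere following the
10-20/10-10 arc rules (vertex Cz, nasion-inion and ear-to-ear great
circles, the 10% ring through Fpz/T7/Oz/T8, and intermediate rows obtained
by subdividing great-circle arcs), then scaled to the scalp radius. AFz is
the amplifier ground (not recorded); CPz is the recording reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CHANNELS_30",
    "ElectrodeMontage",
    "standard_montage",
    "read_sfp",
    "write_sfp",
]

#: Recorded channels, montage order.
CHANNELS_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
)


@dataclass(frozen=True)
class ElectrodeMontage:
    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) meters
    ground: str = "AFz"
    reference: str = "CPz"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    @property
    def n_channels(self) -> int:
        return len(self.labels)


def _slerp(p: np.ndarray, q: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` of the great-circle arc from p to q (unit vecs)."""
    w = np.arccos(np.clip(np.dot(p, q), -1.0, 1.0))
    if w < 1e-12:
        return p.copy()
    out = (np.sin((1 - t) * w) * p + np.sin(t * w) * q) / np.sin(w)
    return out / np.linalg.norm(out)


def _unit_sphere_positions() -> dict[str, np.ndarray]:
    nz = np.array([0.0, 1.0, 0.0])   # nasion
    iz = np.array([0.0, -1.0, 0.0])  # inion
    t9 = np.array([-1.0, 0.0, 0.0])  # left preauricular
    t10 = np.array([1.0, 0.0, 0.0])
    cz = np.array([0.0, 0.0, 1.0])

    pos: dict[str, np.ndarray] = {}

    def arc(p, q, mid, frac):
        # great-circle arc p -> mid -> q, fraction of the half-arcs
        return _slerp(p, mid, 2 * frac) if frac <= 0.5 else _slerp(mid, q, 2 * frac - 1)

    # midline nasion -> Cz -> inion, 10% steps
    midline = {
        "Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
        "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9,
    }
    for name, f in midline.items():
        pos[name] = arc(nz, iz, cz, f)

    # ear-to-ear through Cz
    coronal = {"T7": 0.1, "C3": 0.3, "C4": 0.7, "T8": 0.9}
    for name, f in coronal.items():
        pos[name] = arc(t9, t10, cz, f)

    # 10% ring through Fpz, T7, Oz, T8 (circle of constant z)
    zr = pos["Fpz"][2]
    rr = float(np.sqrt(1.0 - zr**2))

    def ring(azimuth_deg: float) -> np.ndarray:
        # azimuth measured from +y (nasion) toward -x (left ear)
        a = np.deg2rad(azimuth_deg)
        return np.array([-rr * np.sin(a), rr * np.cos(a), zr])

    pos["Fp1"], pos["Fp2"] = ring(18), ring(-18)
    pos["F7"], pos["F8"] = ring(54), ring(-54)
    pos["FT7"], pos["FT8"] = ring(72), ring(-72)
    pos["TP7"], pos["TP8"] = ring(108), ring(-108)
    pos["P7"], pos["P8"] = ring(126), ring(-126)
    pos["O1"], pos["O2"] = ring(162), ring(-162)

    # intermediate rows: arcs from the temporal ring point to the midline
    rows = {
        "F": ("F7", "Fz", "F8"),
        "FC": ("FT7", "FCz", "FT8"),
        "CP": ("TP7", "CPz", "TP8"),
        "P": ("P7", "Pz", "P8"),
    }
    # fractions along the half-arc lateral -> midline
    for row, (left, mid, right) in rows.items():
        for name, anchor, f in (
            (f"{row}5", left, 0.25), (f"{row}3", left, 0.5), (f"{row}1", left, 0.75),
            (f"{row}6", right, 0.25), (f"{row}4", right, 0.5), (f"{row}2", right, 0.75),
        ):
            pos[name] = _slerp(pos[anchor], pos[mid], f)
    return pos


def standard_montage(scalp_radius: float = 0.1,
                     center=(0.0, 0.0, 0.0)) -> ElectrodeMontage:
    """The 30-channel montage projected onto a spherical scalp."""
    unit = _unit_sphere_positions()
    c = np.asarray(center, dtype=float)
    positions = np.stack([unit[ch] for ch in CHANNELS_30]) * scalp_radius + c
    return ElectrodeMontage(CHANNELS_30, positions)


def write_sfp(path, montage: ElectrodeMontage) -> None:
    """Plain-text electrode file: ``label x y z`` per line (meters)."""
    lines = [
        f"{lab}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}"
        for lab, p in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfp(path) -> ElectrodeMontage:
    labels, coords = [], []
    for raw in Path(path).read_text().splitlines():
        parts = raw.split()
        if len(parts) < 4 or parts[0].startswith("#"):
            continue
        labels.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if not labels:
        raise ValueError(f"no electrode rows found in {path}")
    return ElectrodeMontage(tuple(labels), np.asarray(coords, float))
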