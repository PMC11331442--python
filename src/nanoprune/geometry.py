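"""Atomistic geometric descriptors: coordination numbers and the
Kneedle core/shell split.

These are the two descriptor computations reproducible from atomic
coordinates alone.  Coordination numbers count, for each atom, the
neighbours lying within R = 1.2 x (r_i + r_j) where r are the ionic
radii of the pair — for a metal oxide this captures the metal-oxygen
first shell while excluding the like-ion shell at sqrt(2) spacing.
The core/shell boundary of a radial property profile is located with
the Kneedle construction: both axes are normalized to [0, 1] and the
knee is the point of maximum deviation between the normalized curve
and its chord.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomSet",
    "RadialProfile",
    "read_xyz",
    "coordination_numbers",
    "kneedle_split",
]


@dataclass
class AtomSet:
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    radii: dict[str, float]  # element -> ionic radius, Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.elements) != len(self.coords):
            raise ValueError("one element symbol per coordinate row")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for el in set(self.elements):
            if el not in self.radii:
                raise KeyError(f"missing ionic radius for element {el!r}")
            if self.radii[el] <= 0:
                raise ValueError(f"radius for {el!r} must be positive")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class RadialProfile:
    """Shell radii (strictly increasing) and a per-shell property value."""

    radii: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.radii) != len(self.values):
            raise ValueError("radii and values must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


def read_xyz(path, radii: dict[str, float]) -> AtomSet:
    """Read a plain XYZ file (count line, comment line, `El x y z` rows)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[0])
    rows = lines[2 : 2 + n]
    if len(rows) < n:
        raise ValueError(f"XYZ declares {n} atoms but has {len(rows)} rows")
    elements, coords = [], []
    for ln in rows:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return AtomSet(elements=elements, coords=np.array(coords), radii=radii)


def coordination_numbers(atoms: AtomSet, factor: float = 1.2) -> np.ndarray:
    """Per-atom count of counter-ion neighbours within R = factor x (r_i + r_j).

    Metal atoms count oxygen neighbours and vice versa (like-ion pairs
    are not coordination partners in an ionic lattice); the pair cutoff
    uses the two atoms' ionic radii, self excluded.  In a rock-salt
    arrangement with spacing r_M + r_O this yields 6 for an interior
    atom: the like-ion shell at sqrt(2) spacing is never counted.
    """
    n = len(atoms)
    if n == 0:
        return np.zeros(0, dtype=int)
    r = np.array([atoms.radii[e] for e in atoms.elements])
    is_oxygen = np.array([e == "O" for e in atoms.elements])
    cutoff = factor * (r[:, None] + r[None, :])
    dist = cdist(atoms.coords, atoms.coords)
    within = (dist < cutoff) & (is_oxygen[:, None] != is_oxygen[None, :])
    np.fill_diagonal(within, False)
    return within.sum(axis=1).astype(int)


def kneedle_split(profile: RadialProfile, curvature_tol: float = 1e-6) -> float:
    """Locate the knee of a radial profile; returns the boundary radius.

    Both axes are min-max normalized; the knee maximises the absolute
    difference between the normalized curve and the straight chord
    between its endpoints.  A (numerically) straight profile has no
    knee and raises ``ValueError("no curvature")``.  The result is
    invariant to any affine rescaling of the property axis.
    """
    if len(profile.radii) < 4:
        raise ValueError("need >=4 profile points")
    x = profile.radii
    y = profile.values
    if np.ptp(y) == 0:
        raise ValueError("no curvature: profile is constant")
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / np.ptp(y)
    chord = yn[0] + (yn[-1] - yn[0]) * xn
    diff = np.abs(yn - chord)
    if diff.max() < curvature_tol:
        raise ValueError("no curvature: profile is linear")
    return float(x[int(np.argmax(diff))])
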