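"""Electrostatic potentials at reactive atoms, in kT/e.

Three sources are supported:

``grid``
    A scalar potential on a regular 3D lattice, as written by
    Poisson–Boltzmann solvers in OpenDX format.  Values are trilinearly
    interpolated at atom centers.
``table``
    A per-atom table ``(chain, resnum, atom name) → kT/e`` (TSV), for
    potentials sampled by external tooling.
``coulomb``
    A self-contained screened-Coulomb fallback over the structure's own
    partial charges (PQR input):  V(x) = Σ_i q_i e^{-r_i/λ} / (ε r_i),
    converted to kT/e at the configured temperature.  Defaults follow the
    usual continuum-electrostatics setup for buried active sites: solute
    dielectric 2, 298 K, no ionic screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.interpolate import RegularGridInterpolator

from .structio import Atom, Structure

__all__ = [
    "PotentialGrid",
    "PotentialSource",
    "PotentialDifference",
    "read_opendx",
    "read_potential_table",
    "assign_potentials",
    "potential_difference",
    "coulomb_prefactor_kT_e",
]


class PotentialError(ValueError):
    pass


def coulomb_prefactor_kT_e(temperature_K: float = 298.0) -> float:
    """kT/e value of the potential of a unit charge at 1 Å in vacuum.

    e / (4 π ε0 · 1 Å) expressed in units of kT/e at the given temperature.
    """
    volts = constants.e / (4 * math.pi * constants.epsilon_0 * 1e-10)
    return volts * constants.e / (constants.k * temperature_K)


@dataclass
class PotentialGrid:
    """Scalar field on a regular axis-aligned lattice."""

    origin: np.ndarray      # Å, position of grid node (0,0,0)
    delta: np.ndarray       # Å per step along each axis
    values: np.ndarray      # shape (nx, ny, nz), kT/e

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.delta <= 0):
            raise PotentialError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise PotentialError("grid values must be 3-dimensional")
        axes = [
            self.origin[i] + self.delta[i] * np.arange(self.values.shape[i])
            for i in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, self.values, method="linear", bounds_error=True
        )

    def interpolate(self, coords: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at one (3,) or many (n,3) points."""
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        try:
            out = self._interp(pts)
        except ValueError as exc:
            raise PotentialError(f"point outside potential grid: {exc}") from exc
        return out[0] if np.asarray(coords).ndim == 1 else out


def read_opendx(path: str) -> PotentialGrid:
    """Read an OpenDX scalar grid (the ``gridpositions counts`` dialect
    written by Poisson–Boltzmann solvers)."""
    counts = origin = None
    deltas: list[list[float]] = []
    data: list[float] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object") and "gridpositions" in line:
                counts = [int(t) for t in line.split()[-3:]]
            elif line.startswith("origin"):
                origin = [float(t) for t in line.split()[1:4]]
            elif line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:4]])
            elif line.startswith("object") and "class array" in line:
                in_data = True
            elif line.startswith(("attribute", "component", "object", "end")):
                in_data = False
            elif in_data:
                data.extend(float(t) for t in line.split())
    if counts is None or origin is None or len(deltas) != 3:
        raise PotentialError(f"not a gridpositions OpenDX file: {path}")
    delta = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    values = np.array(data).reshape(counts)  # x fastest-varying last: z runs fastest
    return PotentialGrid(origin=np.array(origin), delta=delta, values=values)


def write_opendx(grid: PotentialGrid, path: str) -> None:
    nx, ny, nz = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.delta[0]:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {grid.delta[1]:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {grid.delta[2]:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.values.reshape(-1)
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_potential_table(path: str) -> dict[tuple[str, int, str], float]:
    """TSV of (chain, resnum, atom name, potential kT/e); ``-`` or empty
    chain matches the empty chain id."""
    table: dict[tuple[str, int, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chain, resnum, atom, value = line.split("\t")
            chain = "" if chain == "-" else chain
            table[(chain, int(resnum), atom)] = float(value)
    return table


@dataclass
class PotentialSource:
    """Where potentials come from: ``grid``, ``table`` or ``coulomb``."""

    kind: str
    grid: PotentialGrid | None = None
    table: dict[tuple[str, int, str], float] | None = None
    solute_dielectric: float = 2.0
    temperature_K: float = 298.0
    screening_length: float | None = None   # Å; None = zero ionic strength
    min_distance: float = 0.5               # Å clamp against singularities

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "table", "coulomb"):
            raise PotentialError(f"unknown potential source kind {self.kind!r}")
        if self.kind == "grid" and self.grid is None:
            raise PotentialError("grid source requires a PotentialGrid")
        if self.kind == "table" and self.table is None:
            raise PotentialError("table source requires a table")
        if self.temperature_K <= 0 or self.solute_dielectric < 1:
            raise PotentialError("temperature must be > 0 K and dielectric >= 1")

    @classmethod
    def from_grid(cls, grid: PotentialGrid) -> "PotentialSource":
        return cls(kind="grid", grid=grid)

    @classmethod
    def from_table(cls, table: dict) -> "PotentialSource":
        return cls(kind="table", table=table)

    @classmethod
    def coulomb(cls, solute_dielectric: float = 2.0, temperature_K: float = 298.0,
                screening_length: float | None = None) -> "PotentialSource":
        return cls(kind="coulomb", solute_dielectric=solute_dielectric,
                   temperature_K=temperature_K, screening_length=screening_length)


def _coulomb_potentials(s: Structure, src: PotentialSource) -> None:
    atoms = s.atoms
    charges = np.array(
        [a.charge if a.charge is not None else np.nan for a in atoms]
    )
    if np.any(np.isnan(charges)):
        missing = [a.name for a, q in zip(atoms, charges) if np.isnan(q)]
        raise PotentialError(
            f"coulomb source needs per-atom charges (PQR input); missing on {missing[:5]}"
        )
    coords = np.array([a.coord for a in atoms])
    pref = coulomb_prefactor_kT_e(src.temperature_K) / src.solute_dielectric
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)      # self term excluded
    dist = np.maximum(dist, src.min_distance)
    kernel = 1.0 / dist
    if src.screening_length is not None:
        kernel *= np.exp(-dist / src.screening_length)
    pot = pref * kernel @ charges
    for a, v in zip(atoms, pot):
        a.potential = float(v)


def assign_potentials(s: Structure, src: PotentialSource) -> Structure:
    """Set every atom's ``potential`` (kT/e) from the source, in place."""
    if src.kind == "grid":
        coords = np.array([a.coord for a in s.atoms])
        vals = src.grid.interpolate(coords)
        for a, v in zip(s.atoms, vals):
            a.potential = float(v)
    elif src.kind == "table":
        for r in s.residues:
            for a in r.atoms:
                key = (r.chain_id, r.number, a.name)
                if key not in src.table:
                    raise PotentialError(f"no table entry for atom {key}")
                a.potential = float(src.table[key])
    else:
        _coulomb_potentials(s, src)
    return s


@dataclass(frozen=True)
class PotentialDifference:
    """Ordered potential difference V(a) − V(b), kT/e; antisymmetric
    under swapping the atoms."""

    value: float
    atom_a: str
    atom_b: str


def potential_difference(a: Atom, b: Atom) -> PotentialDifference:
    if a.potential is None or b.potential is None:
        raise PotentialError("potential not assigned; run assign_potentials first")
    return PotentialDifference(
        value=a.potential - b.potential, atom_a=a.name, atom_b=b.name
    )
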