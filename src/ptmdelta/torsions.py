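"""Torsion angles: measurement, normalization, and the packaged backbone/side-chain
torsion library.

The library emulates torsion-angle statistics of residues in high-resolution
X-ray structures: backbone (φ, ψ) pairs are drawn from a mixture of
Ramachandran basins with residue-appropriate weights, and side-chain χ angles
from the canonical gauche−/trans/gauche+ rotamer wells with small Gaussian
jitter.  It is a packaged surrogate for a curated structural database; the
downstream analysis needs only a representative, reproducible sample of
torsions, not any particular protein set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "TorsionSet",
    "normalize_angle",
    "measure_torsion",
    "TorsionLibrary",
    "load_torsion_library",
    "sample_torsions",
    "SUPPORTED_RESIDUES",
]

SUPPORTED_RESIDUES = ("LYS", "ARG", "SER", "THR", "ASN")

#: number of χ angles carried by the library sample for each residue
#: (further torsions introduced by a PTM are handled by the rotamer scheme
#: or by glycan-torsion enumeration, not by the library).
N_CHI = {"LYS": 4, "ARG": 4, "SER": 1, "THR": 1, "ASN": 2}


def normalize_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees onto the half-open interval (−180, 180]."""
    wrapped = np.asarray(angle, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 exactly to +180 so the interval is half-open on the left
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def measure_torsion(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in degrees, IUPAC sign convention.

    Looking from b towards c, a positive angle is a clockwise rotation of the
    far bond (c→d) relative to the near bond (b→a).  Returns a value in
    (−180, 180].

    Raises
    ------
    ValueError
        if three consecutive points are collinear (the dihedral is undefined).
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return normalize_angle(-np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class TorsionSet:
    """Torsion angles defining one backbone + side-chain conformation.

    ``phi``/``psi`` belong to the central (modified) residue.  ``chi`` holds
    its side-chain dihedrals in order χ1, χ2, ... — including, for
    glycosylated states, the glycosidic torsions that only exist on the
    modified side.  ``flanking`` carries the (φ, ψ) pairs of the two
    neighbouring residues inside the capped tripeptide.
    """

    phi: float
    psi: float
    chi: tuple[float, ...] = ()
    flanking: tuple[tuple[float, float], tuple[float, float]] = (
        (-120.0, 140.0),
        (-120.0, 140.0),
    )

    def __post_init__(self):
        for name, value in [("phi", self.phi), ("psi", self.psi)]:
            if not (-180.0 < value <= 180.0):
                raise ValueError(f"{name}={value} outside (-180, 180]")
        for value in self.chi:
            if not (-180.0 < value <= 180.0):
                raise ValueError(f"chi value {value} outside (-180, 180]")
        for pair in self.flanking:
            for value in pair:
                if not (-180.0 < value <= 180.0):
                    raise ValueError(f"flanking angle {value} outside (-180, 180]")


@dataclass(frozen=True)
class RamachandranBasin:
    name: str
    weight: float
    phi: float
    psi: float
    sd: float


@dataclass(frozen=True)
class ChiWell:
    angle: float
    weight: float
    sd: float


@dataclass(frozen=True)
class TorsionLibrary:
    """Residue-specific mixture model of backbone basins and χ rotamer wells."""

    residue: str
    basins: tuple[RamachandranBasin, ...]
    chi_wells: tuple[tuple[ChiWell, ...], ...] = field(default=())

    def basin_weights(self) -> np.ndarray:
        w = np.array([b.weight for b in self.basins], dtype=float)
        return w / w.sum()

    def sample(self, n: int, rng: np.random.Generator) -> list[TorsionSet]:
        if n == 0:
            return []
        weights = self.basin_weights()
        out = []
        for _ in range(n):
            phi, psi = self._sample_phipsi(rng, weights)
            chi = tuple(self._sample_chi(rng, wells) for wells in self.chi_wells)
            flank = (self._sample_phipsi(rng, weights), self._sample_phipsi(rng, weights))
            out.append(TorsionSet(phi=phi, psi=psi, chi=chi, flanking=flank))
        return out

    def _sample_phipsi(self, rng, weights) -> tuple[float, float]:
        basin = self.basins[rng.choice(len(self.basins), p=weights)]
        phi = normalize_angle(rng.normal(basin.phi, basin.sd))
        psi = normalize_angle(rng.normal(basin.psi, basin.sd))
        return float(phi), float(psi)

    @staticmethod
    def _sample_chi(rng, wells: Sequence[ChiWell]) -> float:
        w = np.array([x.weight for x in wells], dtype=float)
        w /= w.sum()
        well = wells[rng.choice(len(wells), p=w)]
        return float(normalize_angle(rng.normal(well.angle, well.sd)))

    def basin_assignment(self, torsions: Sequence[TorsionSet]) -> np.ndarray:
        """Index of the nearest basin (wrapped Euclidean distance in φ/ψ)."""
        idx = np.empty(len(torsions), dtype=int)
        for i, t in enumerate(torsions):
            d = [
                _wrapped_dist(t.phi, b.phi) ** 2 + _wrapped_dist(t.psi, b.psi) ** 2
                for b in self.basins
            ]
            idx[i] = int(np.argmin(d))
        return idx


def _wrapped_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def load_torsion_library(residue: str) -> TorsionLibrary:
    """Load the packaged torsion library for one supported residue."""
    residue = residue.upper()
    if residue not in SUPPORTED_RESIDUES:
        raise ValueError(
            f"unsupported residue {residue!r}; supported: {', '.join(SUPPORTED_RESIDUES)}"
        )
    text = resources.files("ptmdelta.data").joinpath("torsion_library.json").read_text()
    raw = json.loads(text)[residue]
    basins = tuple(RamachandranBasin(**b) for b in raw["basins"])
    chi = tuple(tuple(ChiWell(**w) for w in wells) for wells in raw["chi_wells"])
    return TorsionLibrary(residue=residue, basins=basins, chi_wells=chi)


def sample_torsions(residue: str, n: int, seed: int) -> list[TorsionSet]:
    """Draw ``n`` torsion sets for ``residue`` from the packaged library.

    Reproducible: identical (residue, n, seed) yields identical samples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lib = load_torsion_library(residue)
    rng = np.random.default_rng(seed)
    return lib.sample(n, rng)
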