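"""Conformation building and paired-ensemble generation.

Conformations are capped tripeptides (optionally glycan-linked) built from
idealized internal coordinates by sequential natural-extension (NeRF)
placement.  Modified/unmodified ensembles are generated as *pairs* sharing
identical backbone and side-chain torsions, so any torsion-driven shift
contribution cancels in the Δ statistic and only the modification effect
remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .topology import (
    AtomSpec,
    PTMState,
    RotamerScheme,
    RotamerSpec,
    VDW_RADII,
    GLYCAN_TORSION_POSITIONS,
    conformation_specs,
    enumerate_rotamer_scheme,
    n_chi_for_state,
    sequence_label,
    unmodified_partner,
)
from .torsions import TorsionSet, load_torsion_library, measure_torsion

__all__ = [
    "Conformation",
    "EnsemblePair",
    "build_conformation",
    "detect_clashes",
    "generate_paired_ensembles",
    "measure_named_torsions",
]


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, dih_deg: float) -> np.ndarray:
    """NeRF placement: new atom D bonded to c with angle at c and dihedral
    a-b-c-D equal to ``dih_deg`` (IUPAC sign)."""
    theta = math.radians(theta_deg)
    phi = math.radians(dih_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(phi),
        r * math.sin(theta) * math.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class Conformation:
    """All-atom (heavy-atom) coordinates of one capped tripeptide."""

    sequence: str
    state: PTMState
    rotamer: str
    torsions: TorsionSet
    backbone_index: int
    atom_keys: list[str]          # "res:name"
    elements: list[str]
    res_ids: list[int]
    res_names: list[str]
    hetero: list[bool]
    coords: np.ndarray            # (n_atoms, 3) Å
    bonds: list[tuple[int, int]]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {k: i for i, k in enumerate(self.atom_keys)}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_keys)

    def coord(self, key: str) -> np.ndarray:
        return self.coords[self._index[key]]

    def has_atom(self, key: str) -> bool:
        return key in self._index


@lru_cache(maxsize=256)
def _cached_specs(residue: str, state: str, rot_label: str):
    st = PTMState(residue, state)
    scheme = enumerate_rotamer_scheme(st)
    rot = next((r for r in scheme.rotamers if r.label == rot_label), None)
    if rot is None:
        rot = RotamerSpec(rot_label)
    specs, extra = conformation_specs(st, rot)
    keys = [s.key for s in specs]
    idx = {k: i for i, k in enumerate(keys)}
    bonds: list[tuple[int, int]] = [(idx["0:CH3"], idx["0:C"]), (idx["0:C"], idx["0:O"])]
    for s in specs:
        if s.refs is not None:
            bonds.append((idx[s.key], idx[s.refs[0]]))
    for a, b in extra:
        bonds.append((idx[a], idx[b]))
    return specs, tuple(bonds), rot


@lru_cache(maxsize=256)
def _cached_exclusion(residue: str, state: str, rot_label: str, depth: int) -> np.ndarray:
    """Boolean matrix of atom pairs within ``depth`` bonds (to skip in clash checks)."""
    specs, bonds, _ = _cached_specs(residue, state, rot_label)
    n = len(specs)
    adj = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    excl = np.eye(n, dtype=bool)
    for start in range(n):
        dist = {start: 0}
        frontier = [start]
        for _ in range(depth):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v in dist:
            excl[start, v] = True
    return excl


def build_conformation(state: PTMState, torsions: TorsionSet,
                       rotamer: RotamerSpec | str = "-",
                       backbone_index: int = 0) -> Conformation:
    """Build all-atom coordinates realizing the requested torsions.

    The chi tuple must cover the state's topology (extra trailing values are
    permitted so a glycosylated state's torsion set can be reused verbatim for
    its monosaccharide-removed twin).
    """
    if isinstance(rotamer, str):
        specs, bonds, rot = _cached_specs(state.residue, state.state, rotamer)
    else:
        rot = rotamer
        specs, bonds, _ = _cached_specs(state.residue, state.state, rot.label)
    needed = n_chi_for_state(state)
    if len(torsions.chi) < needed:
        raise ValueError(
            f"{state.label} requires {needed} chi angles, got {len(torsions.chi)}"
        )
    variables: dict[str, float] = {"": 0.0}
    variables["phi1"], variables["psi1"] = torsions.flanking[0]
    variables["phi3"], variables["psi3"] = torsions.flanking[1]
    variables["phi2"], variables["psi2"] = torsions.phi, torsions.psi
    for i, v in enumerate(torsions.chi, start=1):
        variables[f"chi{i}"] = v
    variables.update(rot.as_dict())

    n = len(specs)
    coords = np.empty((n, 3))
    index: dict[str, int] = {}
    # seed atoms of the acetyl cap
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (1.525, 0.0, 0.0)
    ang = math.radians(120.8)
    coords[2] = coords[1] + 1.229 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i, s in enumerate(specs[:3]):
        index[s.key] = i
    for i, s in enumerate(specs[3:], start=3):
        b, a_ref, d_ref = s.refs
        dih = variables[s.dih_var] + s.dih_off
        coords[i] = _place(coords[index[d_ref]], coords[index[a_ref]],
                           coords[index[b]], s.r, s.theta, dih)
        index[s.key] = i
    return Conformation(
        sequence=sequence_label(state),
        state=state,
        rotamer=rot.label,
        torsions=torsions,
        backbone_index=backbone_index,
        atom_keys=[s.key for s in specs],
        elements=[s.element for s in specs],
        res_ids=[s.res for s in specs],
        res_names=[s.res_name for s in specs],
        hetero=[s.hetero for s in specs],
        coords=coords,
        bonds=list(bonds),
        _index=index,
    )


# named torsion quadruples of the central residue, per residue type
_CHI_ATOMS = {
    "LYS": [("2:N", "2:CA", "2:CB", "2:CG"), ("2:CA", "2:CB", "2:CG", "2:CD"),
            ("2:CB", "2:CG", "2:CD", "2:CE"), ("2:CG", "2:CD", "2:CE", "2:NZ")],
    "ARG": [("2:N", "2:CA", "2:CB", "2:CG"), ("2:CA", "2:CB", "2:CG", "2:CD"),
            ("2:CB", "2:CG", "2:CD", "2:NE"), ("2:CG", "2:CD", "2:NE", "2:CZ")],
    "SER": [("2:N", "2:CA", "2:CB", "2:OG"), ("2:CA", "2:CB", "2:OG", "5:C1"),
            ("2:CB", "2:OG", "5:C1", "5:O5")],
    "THR": [("2:N", "2:CA", "2:CB", "2:OG1"), ("2:CA", "2:CB", "2:OG1", "5:C1"),
            ("2:CB", "2:OG1", "5:C1", "5:O5")],
    "ASN": [("2:N", "2:CA", "2:CB", "2:CG"), ("2:CA", "2:CB", "2:CG", "2:OD1"),
            ("2:CB", "2:CG", "2:ND2", "5:C1"), ("2:CG", "2:ND2", "5:C1", "5:O5")],
}


def measure_named_torsions(conf: Conformation) -> dict[str, float]:
    """Measure φ, ψ and all applicable χ angles from built coordinates."""
    out = {
        "phi": measure_torsion(conf.coord("1:C"), conf.coord("2:N"),
                               conf.coord("2:CA"), conf.coord("2:C")),
        "psi": measure_torsion(conf.coord("2:N"), conf.coord("2:CA"),
                               conf.coord("2:C"), conf.coord("3:N")),
    }
    for i, quad in enumerate(_CHI_ATOMS[conf.state.residue], start=1):
        if all(conf.has_atom(k) for k in quad):
            out[f"chi{i}"] = measure_torsion(*(conf.coord(k) for k in quad))
    return out


def detect_clashes(conf: Conformation, overlap_factor: float = 0.5,
                   bond_exclusion_depth: int = 3) -> list[tuple[int, int]]:
    """Atom pairs closer than ``overlap_factor × (vdW_i + vdW_j)``, ignoring
    pairs within ``bond_exclusion_depth`` bonds of each other."""
    excl = _cached_exclusion(conf.state.residue, conf.state.state,
                             conf.rotamer, bond_exclusion_depth)
    if excl.shape[0] != conf.n_atoms:  # conformation not from cached template
        excl = _exclusion_from_bonds(conf, bond_exclusion_depth)
    radii = np.array([VDW_RADII[e] for e in conf.elements])
    dmat = squareform(pdist(conf.coords))
    cutoff = overlap_factor * (radii[:, None] + radii[None, :])
    clash = (dmat < cutoff) & ~excl
    ii, jj = np.nonzero(np.triu(clash, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def _exclusion_from_bonds(conf: Conformation, depth: int) -> np.ndarray:
    n = conf.n_atoms
    adj = [[] for _ in range(n)]
    for a, b in conf.bonds:
        adj[a].append(b)
        adj[b].append(a)
    excl = np.eye(n, dtype=bool)
    for start in range(n):
        dist = {start: 0}
        frontier = [start]
        for _ in range(depth):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v in dist:
            excl[start, v] = True
    return excl


@dataclass
class EnsemblePair:
    """Matched modified/unmodified conformational ensembles.

    Members paired under one backbone index share the identical
    :class:`TorsionSet`; the modified side additionally enumerates (or, for
    glycans, samples) the rotamers of the added group.
    """

    state: PTMState
    seed: int
    unmodified: list[Conformation]
    modified: list[Conformation]
    pairing: dict[int, tuple[list[int], list[int]]]
    scheme: RotamerScheme
    rejection_stats: dict = field(default_factory=dict)

    @property
    def total_conformations(self) -> int:
        return len(self.unmodified) + len(self.modified)

    @property
    def n_backbones(self) -> int:
        return len(self.pairing)


def generate_paired_ensembles(state: PTMState, n_backbones: int = 500,
                              seed: int = 0, overlap_factor: float = 0.5,
                              bond_exclusion_depth: int = 3,
                              acceptance_floor: float = 0.02,
                              max_tries_per_backbone: int = 500) -> EnsemblePair:
    """Rejection-sample clash-free paired ensembles for a modified state.

    For every accepted backbone, the unmodified twin and all rotamer builds of
    the modified state are clash-free and share one torsion set.  Raises if
    the acceptance rate falls below ``acceptance_floor``.
    """
    if n_backbones < 1:
        raise ValueError("n_backbones must be >= 1")
    if not state.is_modified:
        raise ValueError(f"{state.label} is not a modified state; "
                         "pair generation needs a modification to remove")
    partner = unmodified_partner(state)
    scheme = enumerate_rotamer_scheme(state, conformers_per_rotamer=n_backbones)
    lib = load_torsion_library(state.residue)
    rng = np.random.default_rng(seed)
    unmod: list[Conformation] = []
    mod: list[Conformation] = []
    pairing: dict[int, tuple[list[int], list[int]]] = {}
    tries = 0
    accepted = 0
    for bb in range(n_backbones):
        for attempt in range(max_tries_per_backbone):
            tries += 1
            ts = lib.sample(1, rng)[0]
            if state.is_glycan:
                extra = tuple(rng.choice(GLYCAN_TORSION_POSITIONS)
                              for _ in range(2))
                ts = TorsionSet(phi=ts.phi, psi=ts.psi,
                                chi=ts.chi + extra, flanking=ts.flanking)
                rotamers = [RotamerSpec(f"{extra[0]:+.0f}/{extra[1]:+.0f}")]
            else:
                rotamers = list(scheme.rotamers)
            u = build_conformation(partner, ts, "-", backbone_index=bb)
            if detect_clashes(u, overlap_factor, bond_exclusion_depth):
                continue
            builds = []
            ok = True
            for rot in rotamers:
                m = build_conformation(state, ts, rot, backbone_index=bb)
                if detect_clashes(m, overlap_factor, bond_exclusion_depth):
                    ok = False
                    break
                builds.append(m)
            if not ok:
                continue
            accepted += 1
            ui = len(unmod)
            unmod.append(u)
            mi = list(range(len(mod), len(mod) + len(builds)))
            mod.extend(builds)
            pairing[bb] = ([ui], mi)
            break
        else:
            raise RuntimeError(
                f"acceptance rate too low for {state.label}: "
                f"{accepted}/{tries} accepted "
                f"(backbone {bb} exhausted {max_tries_per_backbone} tries)"
            )
        if tries >= 50 and accepted / tries < acceptance_floor:
            raise RuntimeError(
                f"acceptance rate below floor {acceptance_floor} for "
                f"{state.label}: {accepted}/{tries}"
            )
    stats = {"tries": tries, "accepted": accepted,
             "acceptance_rate": accepted / tries}
    return EnsemblePair(state=state, seed=seed, unmodified=unmod, modified=mod,
                        pairing=pairing, scheme=scheme, rejection_stats=stats)
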