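"""File formats around the geometry stage: multi-MODEL PDB, JSON ensemble
manifests, and quantum-chemistry shielding-job input files using the
locally-dense basis-set scheme (large basis on the focus nucleus and its bond
neighborhood, small basis elsewhere).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .geometry import Conformation, EnsemblePair
from .topology import PTMState, RotamerSpec
from .torsions import TorsionSet

__all__ = [
    "write_pdb",
    "read_pdb",
    "write_qc_input",
    "pair_manifest",
    "write_manifest",
    "read_manifest",
]


def _to_atom_array(conf: Conformation) -> struc.AtomArray:
    n = conf.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(conf.coords, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.array(conf.res_ids) + 1
    arr.res_name = np.array(conf.res_names)
    arr.atom_name = np.array([k.split(":")[1] for k in conf.atom_keys])
    arr.element = np.array(conf.elements)
    arr.hetero = np.array(conf.hetero, dtype=bool)
    return arr


def write_pdb(conformations: list[Conformation], path: str | Path) -> None:
    """Write conformations as a multi-MODEL PDB file (glycan atoms HETATM)."""
    path = Path(path)
    pdb = pdbio.PDBFile()
    if conformations:
        stack = struc.stack([_to_atom_array(c) for c in conformations])
        pdb.set_structure(stack)
    pdb.write(path)


def read_pdb(path: str | Path) -> list[dict]:
    """Read a multi-MODEL PDB written by :func:`write_pdb`.

    Returns one record per model with atom names, elements, residue ids,
    hetero flags and coordinates.  Torsion/state metadata lives in the JSON
    manifest, not the PDB.
    """
    path = Path(path)
    try:
        pdb = pdbio.PDBFile.read(path)
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if n_models == 0:
        return []
    out = []
    for model in range(1, n_models + 1):
        arr = pdb.get_structure(model=model)
        out.append({
            "atom_names": arr.atom_name.tolist(),
            "elements": arr.element.tolist(),
            "res_ids": arr.res_id.tolist(),
            "res_names": arr.res_name.tolist(),
            "hetero": arr.hetero.tolist(),
            "coords": np.asarray(arr.coord, dtype=float),
        })
    return out


def _bond_shell(conf: Conformation, focus_idx: int, depth: int) -> set[int]:
    adj: dict[int, list[int]] = {i: [] for i in range(conf.n_atoms)}
    for a, b in conf.bonds:
        adj[a].append(b)
        adj[b].append(a)
    shell = {focus_idx}
    frontier = [focus_idx]
    for _ in range(depth):
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in shell:
                    shell.add(v)
                    nxt.append(v)
        frontier = nxt
    return shell


def write_qc_input(conf: Conformation, focus_nucleus: str, path: str | Path,
                   neighbor_shell: int = 1,
                   basis_high: str = "6-311+G(2d,p)",
                   basis_low: str = "3-21G",
                   functional: str = "B98") -> None:
    """Write a GIAO shielding-job input with a locally-dense basis partition.

    ``focus_nucleus`` is an atom name of the central residue (e.g. ``CE``) or
    a full "res:name" key.  Atoms within ``neighbor_shell`` bonds of the focus
    get ``basis_high``; all remaining atoms get ``basis_low``.  The functional
    is a free configuration string.
    """
    key = focus_nucleus if ":" in focus_nucleus else f"2:{focus_nucleus}"
    if not conf.has_atom(key):
        raise ValueError(f"unknown nucleus {focus_nucleus!r} in conformation "
                         f"({conf.state.label})")
    focus_idx = conf._index[key]
    high = sorted(_bond_shell(conf, focus_idx, neighbor_shell))
    low = sorted(set(range(conf.n_atoms)) - set(high))
    lines = [
        f"%chk={Path(path).stem}.chk",
        f"#P {functional}/GEN NMR=GIAO",
        "",
        f"shielding job: {conf.sequence} [{conf.state.label}] rotamer {conf.rotamer} "
        f"focus {key}",
        "",
        "0 1",
    ]
    for i in range(conf.n_atoms):
        x, y, z = conf.coords[i]
        lines.append(f"{conf.elements[i]:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    lines.append("")
    # GEN basis sections: 1-based atom indices, then basis name
    lines.append(" ".join(str(i + 1) for i in high) + " 0")
    lines.append(basis_high)
    lines.append("****")
    if low:
        lines.append(" ".join(str(i + 1) for i in low) + " 0")
        lines.append(basis_low)
        lines.append("****")
    lines.append("")
    Path(path).write_text("\n".join(lines))


def _torsions_to_dict(t: TorsionSet) -> dict:
    return {"phi": t.phi, "psi": t.psi, "chi": list(t.chi),
            "flanking": [list(p) for p in t.flanking]}


def _torsions_from_dict(d: dict) -> TorsionSet:
    return TorsionSet(phi=d["phi"], psi=d["psi"], chi=tuple(d["chi"]),
                      flanking=tuple(tuple(p) for p in d["flanking"]))


def pair_manifest(pair: EnsemblePair) -> dict:
    """JSON-serializable manifest of an ensemble pair (torsions, rotamers,
    pairing map) sufficient to regenerate shift records."""
    return {
        "residue": pair.state.residue,
        "state": pair.state.state,
        "seed": pair.seed,
        "n_backbones": pair.n_backbones,
        "rejection_stats": pair.rejection_stats,
        "scheme": {"labels": list(pair.scheme.labels),
                   "enumerated": pair.scheme.enumerated,
                   "conformers_per_rotamer": pair.scheme.conformers_per_rotamer},
        "pairing": {str(bb): {"unmodified": u, "modified": m}
                    for bb, (u, m) in pair.pairing.items()},
        "unmodified": [
            {"backbone_index": c.backbone_index, "rotamer": c.rotamer,
             "torsions": _torsions_to_dict(c.torsions)}
            for c in pair.unmodified
        ],
        "modified": [
            {"backbone_index": c.backbone_index, "rotamer": c.rotamer,
             "torsions": _torsions_to_dict(c.torsions)}
            for c in pair.modified
        ],
    }


def write_manifest(pair: EnsemblePair, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pair_manifest(pair), indent=1))


def read_manifest(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    d["state_obj"] = PTMState(d["residue"], d["state"])
    for side in ("unmodified", "modified"):
        for rec in d[side]:
            rec["torsions_obj"] = _torsions_from_dict(rec["torsions"])
    return d
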