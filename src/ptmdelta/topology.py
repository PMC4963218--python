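"""Residue and PTM topology: valid (residue, state, nucleus) combinations,
rotamer enumeration schemes, and internal-coordinate atom templates for capped
tripeptides.

Templates use idealized bond lengths and angles (heavy atoms only) and are
built by sequential internal-to-Cartesian extension; monosaccharides are
attached as idealized chair templates via their glycosidic torsions.  The
analysis downstream consumes torsions and rotamer labels, so template geometry
only needs to be stereochemically plausible, not energy-minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PTMState",
    "RotamerSpec",
    "RotamerScheme",
    "enumerate_rotamer_scheme",
    "AtomSpec",
    "conformation_specs",
    "unmodified_partner",
    "REPORT_NUCLEUS",
    "VALID_STATES",
    "GLYCAN_TORSION_POSITIONS",
    "VDW_RADII",
    "n_chi_for_state",
]

# report nucleus sensed for each residue
REPORT_NUCLEUS = {"LYS": "CE", "ARG": "CZ", "SER": "CB", "THR": "CB", "ASN": "CG"}

# state labels per residue; first entry is the unmodified partner state
VALID_STATES = {
    "LYS": ("charged", "acetyl", "monomethyl", "dimethyl", "trimethyl"),
    "ARG": ("charged", "monomethyl-NE", "monomethyl-NH", "dimethyl-sym", "dimethyl-asym"),
    "SER": ("unmodified", "alpha-GalNAc", "beta-GlcNAc"),
    "THR": ("unmodified", "alpha-GalNAc", "beta-GlcNAc"),
    "ASN": ("unmodified", "beta-GlcNAc"),
}

GLYCAN_STATES = {"alpha-GalNAc", "beta-GlcNAc"}

#: glycosidic torsions introduced by glycosylation are explored at 3 positions
GLYCAN_TORSION_POSITIONS = (60.0, -60.0, 180.0)

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20, "S": 1.80}


@dataclass(frozen=True)
class PTMState:
    """A (residue, modification-state) pair with its report nucleus."""

    residue: str
    state: str

    def __post_init__(self):
        if self.residue not in VALID_STATES:
            raise ValueError(
                f"unsupported residue {self.residue!r}; supported: {sorted(VALID_STATES)}"
            )
        if self.state not in VALID_STATES[self.residue]:
            raise ValueError(
                f"invalid state {self.state!r} for {self.residue}; "
                f"valid: {VALID_STATES[self.residue]}"
            )

    @property
    def nucleus(self) -> str:
        return REPORT_NUCLEUS[self.residue]

    @property
    def is_modified(self) -> bool:
        return self.state not in ("charged", "unmodified")

    @property
    def is_glycan(self) -> bool:
        return self.state in GLYCAN_STATES

    @property
    def label(self) -> str:
        return f"{self.residue}/{self.state}"


def unmodified_partner(state: PTMState) -> PTMState:
    """The matched non-modified state sharing the residue's torsion space."""
    return PTMState(state.residue, VALID_STATES[state.residue][0])


def n_chi_for_state(state: PTMState) -> int:
    """Length of the chi tuple a TorsionSet must carry for this state."""
    base = {"LYS": 4, "ARG": 4, "SER": 1, "THR": 1, "ASN": 2}[state.residue]
    if state.is_glycan:
        base += 2  # two glycosidic torsions (χ2/χ3 for Ser/Thr, χ3/χ4 for Asn)
    return base


@dataclass(frozen=True)
class RotamerSpec:
    label: str
    variables: tuple[tuple[str, float], ...] = ()

    def as_dict(self) -> dict[str, float]:
        return dict(self.variables)


@dataclass(frozen=True)
class RotamerScheme:
    """Enumeration of the added-group rotamers for one PTM state.

    For states whose modification introduces a new internal rotation
    (acetyl, methyls), every rotamer is built for every backbone
    (``enumerated=True``) and shieldings are later averaged over them.
    Glycosylated states instead *sample* their glycosidic torsions per
    backbone (``enumerated=False``): one conformation per backbone.
    """

    state: PTMState
    rotamers: tuple[RotamerSpec, ...]
    conformers_per_rotamer: int
    enumerated: bool = True

    @property
    def total(self) -> int:
        if self.enumerated:
            return len(self.rotamers) * self.conformers_per_rotamer
        return self.conformers_per_rotamer

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rotamers)


def _rot(label: str, **v: float) -> RotamerSpec:
    return RotamerSpec(label, tuple(sorted(v.items())))


_SCHEMES: dict[tuple[str, str], tuple[RotamerSpec, ...]] = {
    # unmodified states: one trivial rotamer
    ("LYS", "charged"): (_rot("-"),),
    ("ARG", "charged"): (_rot("-"),),
    ("SER", "unmodified"): (_rot("-"),),
    ("THR", "unmodified"): (_rot("-"),),
    ("ASN", "unmodified"): (_rot("-"),),
    # acetyl-Lys: amide-plane rotamers at 0 and 180
    ("LYS", "acetyl"): (_rot("0", rot=0.0), _rot("180", rot=180.0)),
    # methyl-Lys: staggered rotamers at +60, -60, 180 about Cε–Nζ
    ("LYS", "monomethyl"): (
        _rot("+60", rot=60.0),
        _rot("-60", rot=-60.0),
        _rot("180", rot=180.0),
    ),
    ("LYS", "dimethyl"): (
        _rot("+60", rot=60.0),
        _rot("-60", rot=-60.0),
        _rot("180", rot=180.0),
    ),
    ("LYS", "trimethyl"): (_rot("fixed"),),
    # Arg methylation: Nε site is a single planar placement (500);
    # each Nη site contributes two planar placements (2 sites × 2 × 500 = 2000)
    ("ARG", "monomethyl-NE"): (_rot("NE"),),
    ("ARG", "monomethyl-NH"): (
        _rot("NH1:0", rot=0.0),
        _rot("NH1:180", rot=180.0),
        _rot("NH2:0", rot=0.0),
        _rot("NH2:180", rot=180.0),
    ),
    ("ARG", "dimethyl-sym"): (
        _rot("syn", r1=0.0, r2=0.0),
        _rot("anti", r1=180.0, r2=180.0),
    ),
    ("ARG", "dimethyl-asym"): (
        _rot("NH1:a"),
        _rot("NH1:b"),
        _rot("NH2:a"),
        _rot("NH2:b"),
    ),
}


def enumerate_rotamer_scheme(state: PTMState, conformers_per_rotamer: int = 500) -> RotamerScheme:
    """Rotamer scheme for a PTM state, honoring the study's conformer counts.

    With 500 conformers per rotamer the Lys states total
    500/1000/1500/1500/500 (= 5,000) and the Arg states 500/500/2000/1000/2000
    (= 6,000, i.e. 500 charged + 2,500 mono + 3,000 di).
    """
    if state.is_glycan:
        combos = tuple(
            _rot(f"{a:+.0f}/{b:+.0f}")
            for a in GLYCAN_TORSION_POSITIONS
            for b in GLYCAN_TORSION_POSITIONS
        )
        return RotamerScheme(state, combos, conformers_per_rotamer, enumerated=False)
    key = (state.residue, state.state)
    return RotamerScheme(state, _SCHEMES[key], conformers_per_rotamer, enumerated=True)


# ---------------------------------------------------------------------------
# internal-coordinate atom templates


@dataclass(frozen=True)
class AtomSpec:
    """One atom defined in internal coordinates relative to three placed atoms.

    ``refs`` are keys "res:name" of (bond, angle, dihedral) reference atoms;
    the realized dihedral is ``variables[dih_var] + dih_off`` (``dih_var=""``
    means a fixed template dihedral).
    """

    name: str
    element: str
    res: int
    res_name: str
    refs: tuple[str, str, str] | None
    r: float = 0.0
    theta: float = 0.0
    dih_var: str = ""
    dih_off: float = 0.0
    hetero: bool = False

    @property
    def key(self) -> str:
        return f"{self.res}:{self.name}"


# idealized geometry constants (Å, degrees)
_B = {
    "C-C": 1.525,
    "C=O": 1.229,
    "C-N": 1.335,   # amide
    "N-CA": 1.458,
    "C-Nsp3": 1.470,
    "C-O": 1.427,   # ether/alcohol
    "C-Ngua": 1.330,
    "N-CH3gua": 1.460,
}
_TET = 110.5
_SP2 = 120.0


def _bb(seq: tuple[str, str, str]) -> list[AtomSpec]:
    """Backbone specs for Ace-(r1)-(r2)-(r3)-Nme with φ/ψ variables.

    Residue indices: 0 = Ace cap, 1–3 = residues, 4 = Nme cap.
    """
    s: list[AtomSpec] = [
        AtomSpec("CH3", "C", 0, "ACE", None),
        AtomSpec("C", "C", 0, "ACE", None),
        AtomSpec("O", "O", 0, "ACE", None),
    ]
    prev_c, prev_ca, prev_n = "0:C", "0:CH3", "0:O"
    for i, rname in enumerate(seq, start=1):
        # amide N: trans to the carbonyl O of the previous residue
        s.append(AtomSpec("N", "N", i, rname, (prev_c, prev_ca, prev_n),
                          _B["C-N"], 116.2, "", 180.0))
        s.append(AtomSpec("CA", "C", i, rname, (f"{i}:N", prev_c, prev_ca),
                          _B["N-CA"], 121.7, "", 180.0))
        s.append(AtomSpec("C", "C", i, rname, (f"{i}:CA", f"{i}:N", prev_c),
                          _B["C-C"], 110.5, f"phi{i}", 0.0))
        s.append(AtomSpec("O", "O", i, rname, (f"{i}:C", f"{i}:CA", f"{i}:N"),
                          _B["C=O"], 120.8, f"psi{i}", 180.0))
        prev_c, prev_ca, prev_n = f"{i}:C", f"{i}:CA", f"{i}:N"
        if i < 3:
            # rewrite: next N needs dihedral ψ_i about CA_i–C_i, not 180
            pass
    # fix N placements for residues 2, 3 and the Nme cap to use ψ of the
    # preceding residue (the first N after Ace keeps the fixed 180 placement)
    fixed: list[AtomSpec] = []
    for a in s:
        if a.name == "N" and a.res in (2, 3):
            prev = a.res - 1
            fixed.append(AtomSpec("N", "N", a.res, a.res_name,
                                  (f"{prev}:C", f"{prev}:CA", f"{prev}:N"),
                                  _B["C-N"], 116.2, f"psi{prev}", 0.0))
        else:
            fixed.append(a)
    s = fixed
    s.append(AtomSpec("N", "N", 4, "NME", ("3:C", "3:CA", "3:N"),
                      _B["C-N"], 116.2, "psi3", 0.0))
    s.append(AtomSpec("CH3", "C", 4, "NME", ("4:N", "3:C", "3:CA"),
                      _B["N-CA"], 121.7, "", 180.0))
    return s


def _cb(res: int, rname: str) -> AtomSpec:
    # L-chirality improper: dihedral C–N–CA–CB ≈ −122.5°
    return AtomSpec("CB", "C", res, rname, (f"{res}:CA", f"{res}:N", f"{res}:C"),
                    _B["C-C"], _TET, "", -122.5)


def _chain(res: int, rname: str, names_elems: list[tuple[str, str, float]],
           start_refs: tuple[str, str, str], dih_vars: list[str]) -> list[AtomSpec]:
    """A linear side chain: each atom extends the previous three."""
    out = []
    refs = start_refs
    for (name, elem, r), var in zip(names_elems, dih_vars):
        out.append(AtomSpec(name, elem, res, rname, refs, r, _TET, var, 0.0))
        refs = (f"{res}:{name}", refs[0], refs[1])
    return out


def _side_chain(residue: str, res: int = 2) -> list[AtomSpec]:
    r = residue
    base = (f"{res}:CB", f"{res}:CA", f"{res}:N")
    if r == "GLY":
        return []
    if r == "ALA":
        return [_cb(res, r)]
    if r == "LYS":
        return [_cb(res, r)] + _chain(res, r, [
            ("CG", "C", _B["C-C"]), ("CD", "C", _B["C-C"]),
            ("CE", "C", _B["C-C"]), ("NZ", "N", _B["C-Nsp3"]),
        ], base, ["chi1", "chi2", "chi3", "chi4"])
    if r == "ARG":
        specs = [_cb(res, r)] + _chain(res, r, [
            ("CG", "C", _B["C-C"]), ("CD", "C", _B["C-C"]),
            ("NE", "N", _B["C-Nsp3"]), ("CZ", "C", _B["C-Ngua"]),
        ], base, ["chi1", "chi2", "chi3", "chi4"])
        specs.append(AtomSpec("NH1", "N", res, r, (f"{res}:CZ", f"{res}:NE", f"{res}:CD"),
                              _B["C-Ngua"], _SP2, "", 0.0))
        specs.append(AtomSpec("NH2", "N", res, r, (f"{res}:CZ", f"{res}:NE", f"{res}:CD"),
                              _B["C-Ngua"], _SP2, "", 180.0))
        return specs
    if r == "SER":
        return [_cb(res, r),
                AtomSpec("OG", "O", res, r, base, _B["C-O"], _TET, "chi1", 0.0)]
    if r == "THR":
        return [_cb(res, r),
                AtomSpec("OG1", "O", res, r, base, _B["C-O"], _TET, "chi1", 0.0),
                AtomSpec("CG2", "C", res, r, base, _B["C-C"], _TET, "chi1", -120.0)]
    if r == "ASN":
        return [_cb(res, r),
                AtomSpec("CG", "C", res, r, base, _B["C-C"], _TET, "chi1", 0.0),
                AtomSpec("OD1", "O", res, r, (f"{res}:CG", f"{res}:CB", f"{res}:CA"),
                         _B["C=O"], 121.0, "chi2", 0.0),
                AtomSpec("ND2", "N", res, r, (f"{res}:CG", f"{res}:CB", f"{res}:CA"),
                         _B["C-N"], 116.5, "chi2", 180.0)]
    raise ValueError(f"no side-chain template for residue {residue!r}")


def _ptm_specs(state: PTMState, rotamer: RotamerSpec) -> list[AtomSpec]:
    """Atoms added by the modification, for one rotamer of its scheme."""
    res = 2
    key = (state.residue, state.state)
    if not state.is_modified:
        return []
    if state.is_glycan:
        return _glycan_specs(state)
    nz = (f"{res}:NZ", f"{res}:CE", f"{res}:CD")
    if key == ("LYS", "acetyl"):
        return [
            AtomSpec("CX", "C", res, "ALY", nz, _B["C-N"], _SP2, "", 180.0),
            AtomSpec("OX", "O", res, "ALY", (f"{res}:CX", f"{res}:NZ", f"{res}:CE"),
                     _B["C=O"], 121.0, "rot", 0.0),
            AtomSpec("CT", "C", res, "ALY", (f"{res}:CX", f"{res}:NZ", f"{res}:CE"),
                     _B["C-C"], 116.0, "rot", 180.0),
        ]
    if key == ("LYS", "monomethyl"):
        return [AtomSpec("CM1", "C", res, "MLY", nz, _B["C-Nsp3"], _TET, "rot", 0.0)]
    if key == ("LYS", "dimethyl"):
        return [
            AtomSpec("CM1", "C", res, "M2L", nz, _B["C-Nsp3"], _TET, "rot", 0.0),
            AtomSpec("CM2", "C", res, "M2L", nz, _B["C-Nsp3"], _TET, "rot", 120.0),
        ]
    if key == ("LYS", "trimethyl"):
        return [
            AtomSpec("CM1", "C", res, "M3L", nz, _B["C-Nsp3"], _TET, "", 60.0),
            AtomSpec("CM2", "C", res, "M3L", nz, _B["C-Nsp3"], _TET, "", 180.0),
            AtomSpec("CM3", "C", res, "M3L", nz, _B["C-Nsp3"], _TET, "", -60.0),
        ]
    if key == ("ARG", "monomethyl-NE"):
        return [AtomSpec("CM1", "C", res, "MEA", (f"{res}:NE", f"{res}:CZ", f"{res}:NH1"),
                         _B["N-CH3gua"], _SP2, "", 180.0)]
    if key == ("ARG", "monomethyl-NH"):
        site = rotamer.label.split(":")[0]  # NH1 or NH2
        return [AtomSpec("CM1", "C", res, "MHA", (f"{res}:{site}", f"{res}:CZ", f"{res}:NE"),
                         _B["N-CH3gua"], _SP2, "rot", 0.0)]
    if key == ("ARG", "dimethyl-sym"):
        return [
            AtomSpec("CM1", "C", res, "SDA", (f"{res}:NH1", f"{res}:CZ", f"{res}:NE"),
                     _B["N-CH3gua"], _SP2, "r1", 0.0),
            AtomSpec("CM2", "C", res, "SDA", (f"{res}:NH2", f"{res}:CZ", f"{res}:NE"),
                     _B["N-CH3gua"], _SP2, "r2", 0.0),
        ]
    if key == ("ARG", "dimethyl-asym"):
        site = rotamer.label.split(":")[0]
        first = 0.0 if rotamer.label.endswith("a") else 180.0
        return [
            AtomSpec("CM1", "C", res, "ADA", (f"{res}:{site}", f"{res}:CZ", f"{res}:NE"),
                     _B["N-CH3gua"], _SP2, "", first),
            AtomSpec("CM2", "C", res, "ADA", (f"{res}:{site}", f"{res}:CZ", f"{res}:NE"),
                     _B["N-CH3gua"], _SP2, "", first + 180.0),
        ]
    raise ValueError(f"no PTM template for {state.label}")


def _glycan_specs(state: PTMState) -> list[AtomSpec]:
    """Idealized pyranose (GalNAc/GlcNAc) attached via two glycosidic torsions.

    The two torsions are the last two chi variables of the state
    (``chi2``/``chi3`` for Ser/Thr, ``chi3``/``chi4`` for Asn).  The ring is a
    rigid chair template built along C1→C2→…→C5 with O5 placed from C1; the
    C5–O5 closure is recorded as an explicit bond.
    """
    res = 2
    if state.residue == "SER":
        attach, p1, p2 = "2:OG", "2:CB", "2:CA"
        va, vb, r_link = "chi2", "chi3", 1.41
    elif state.residue == "THR":
        attach, p1, p2 = "2:OG1", "2:CB", "2:CA"
        va, vb, r_link = "chi2", "chi3", 1.41
    elif state.residue == "ASN":
        attach, p1, p2 = "2:ND2", "2:CG", "2:CB"
        va, vb, r_link = "chi3", "chi4", 1.45
    else:  # pragma: no cover
        raise ValueError(state.label)
    alpha = state.state.startswith("alpha")
    rname = "A2G" if "GalNAc" in state.state else "NAG"
    galacto = "GalNAc" in state.state
    g = 5  # glycan residue index
    het = dict(hetero=True)
    s = [
        AtomSpec("C1", "C", g, rname, (attach, p1, p2), r_link, 117.0, va, 0.0, **het),
        AtomSpec("O5", "O", g, rname, (f"{g}:C1", attach, p1), 1.43, 108.0, vb, 0.0, **het),
        AtomSpec("C2", "C", g, rname, (f"{g}:C1", attach, p1), 1.53, 110.0,
                 vb, -120.0 if alpha else 120.0, **het),
        AtomSpec("C3", "C", g, rname, (f"{g}:C2", f"{g}:C1", f"{g}:O5"),
                 1.52, 110.0, "", -55.0, **het),
        AtomSpec("C4", "C", g, rname, (f"{g}:C3", f"{g}:C2", f"{g}:C1"),
                 1.52, 110.0, "", 55.0, **het),
        AtomSpec("C5", "C", g, rname, (f"{g}:C4", f"{g}:C3", f"{g}:C2"),
                 1.52, 110.0, "", -55.0, **het),
        AtomSpec("C6", "C", g, rname, (f"{g}:C5", f"{g}:C4", f"{g}:C3"),
                 1.52, 110.0, "", 180.0, **het),
        AtomSpec("O6", "O", g, rname, (f"{g}:C6", f"{g}:C5", f"{g}:C4"),
                 1.43, 110.0, "", 60.0, **het),
        AtomSpec("N2", "N", g, rname, (f"{g}:C2", f"{g}:C1", f"{g}:O5"),
                 1.47, 110.0, "", 65.0, **het),
        AtomSpec("C7", "C", g, rname, (f"{g}:N2", f"{g}:C2", f"{g}:C1"),
                 1.34, 122.0, "", 180.0, **het),
        AtomSpec("O7", "O", g, rname, (f"{g}:C7", f"{g}:N2", f"{g}:C2"),
                 1.23, 122.0, "", 0.0, **het),
        AtomSpec("C8", "C", g, rname, (f"{g}:C7", f"{g}:N2", f"{g}:C2"),
                 1.51, 116.0, "", 180.0, **het),
        AtomSpec("O3", "O", g, rname, (f"{g}:C3", f"{g}:C2", f"{g}:C1"),
                 1.43, 110.0, "", -65.0, **het),
        AtomSpec("O4", "O", g, rname, (f"{g}:C4", f"{g}:C3", f"{g}:C2"),
                 1.43, 110.0, "", -175.0 if galacto else 65.0, **het),
    ]
    return s


def sequence_label(state: PTMState) -> str:
    if state.residue in ("LYS", "ARG"):
        return f"Ace-Gly-{state.residue}-Gly-Nme"
    return f"Ace-Ala-{state.residue}-Ala-Nme"


def conformation_specs(state: PTMState, rotamer: RotamerSpec) -> tuple[list[AtomSpec], list[tuple[str, str]]]:
    """Full atom-spec list and extra (non-tree) bonds for one conformation.

    Returns the ordered specs (backbone, flank side chains, central side
    chain, PTM atoms) and explicit bond closures (the glycan C5–O5 ring bond).
    """
    if state.residue in ("LYS", "ARG"):
        seq = ("GLY", state.residue, "GLY")
    else:
        seq = ("ALA", state.residue, "ALA")
    specs = _bb(seq)
    for i, rname in enumerate(seq, start=1):
        if i == 2:
            specs += _side_chain(state.residue, res=2)
        else:
            specs += _side_chain(rname, res=i)
    specs += _ptm_specs(state, rotamer)
    extra_bonds = [("5:C5", "5:O5")] if state.is_glycan else []
    return specs, extra_bonds
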