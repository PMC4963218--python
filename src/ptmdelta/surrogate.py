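"""Synthetic shielding/shift surrogate standing in for DFT computations.

Each conformation's ¹³C value is modeled as

    value = base(residue) + t(torsions) + rotamer_offset + effect(state) + ε

where ``t`` is a smooth periodic response to (φ, ψ, χ1) that is *identical*
for paired conformations (they share torsions, so it cancels from the mean Δ),
``rotamer_offset`` is a zero-sum per-rotamer shift carried by the calibration
table, ``effect`` is the additive modification effect (the publication-anchored
mean Δ for the four Lys states), and ε is i.i.d. Gaussian observation noise.

The surrogate operates natively in chemical-shift space (ppm); conversion to
isotropic shieldings (δ = σ_ref − σ) is provided for parity with parsed
quantum-chemistry logs.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EnsemblePair
from .topology import PTMState, unmodified_partner
from .torsions import TorsionSet

__all__ = [
    "CalibrationEntry",
    "SurrogateParams",
    "load_calibration",
    "simulate_shift_records",
    "read_records",
    "torsion_response",
    "to_shielding",
    "to_shift",
    "parse_shielding_log",
    "RECORD_COLUMNS",
    "BASE_SHIFT",
]

RECORD_COLUMNS = ["conformation_id", "backbone_index", "rotamer", "residue",
                  "state", "nucleus", "value", "kind", "provenance"]

#: typical experimental shift of the report nucleus of the unmodified residue
#: (ppm, DSS scale); the Δ statistic is invariant to these values.
BASE_SHIFT = {"LYS": 41.9, "ARG": 159.4, "SER": 63.8, "THR": 69.6, "ASN": 176.8}


@dataclass(frozen=True)
class CalibrationEntry:
    """Additive shift effect of one modification state on its report nucleus."""

    residue: str
    state: str
    nucleus: str
    effect: float
    rotamer_offsets: dict[str, float]
    anchor: str              # "PUBLISHED" | "ILLUSTRATIVE"
    citation: str = ""

    def __post_init__(self):
        if self.anchor not in ("PUBLISHED", "ILLUSTRATIVE"):
            raise ValueError(f"anchor must be PUBLISHED or ILLUSTRATIVE, got {self.anchor!r}")
        if self.anchor == "PUBLISHED" and not self.citation:
            raise ValueError("PUBLISHED-anchored entries must cite their location")
        if self.rotamer_offsets:
            total = sum(self.rotamer_offsets.values())
            if abs(total) > 1e-9:
                raise ValueError(
                    f"rotamer offsets for {self.residue}/{self.state} must sum "
                    f"to zero (got {total}); the state mean is carried by 'effect'"
                )


def load_calibration(source: str | Path | None = None) -> dict[tuple[str, str], CalibrationEntry]:
    """Load the packaged default calibration table or a user JSON file.

    Returns a mapping ``(residue, state) → CalibrationEntry`` and validates
    zero-sum rotamer offsets and PUBLISHED-anchor citations.
    """
    if source is None:
        text = resources.files("ptmdelta.data").joinpath("calibration_default.json").read_text()
    else:
        text = Path(source).read_text()
    raw = json.loads(text)
    table = {}
    for d in raw["entries"]:
        entry = CalibrationEntry(**d)
        PTMState(entry.residue, entry.state)  # validates the combination
        table[(entry.residue, entry.state)] = entry
    return table


@dataclass(frozen=True)
class SurrogateParams:
    """Knobs of the synthetic shift model (all in ppm unless noted)."""

    torsion_amplitude: float = 0.9
    torsion_form: str = "cos-phi-psi-chi1"
    rotamer_spread_target: float = 1.3
    noise_sd: float = 0.5
    reference_shielding: float = 170.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.torsion_amplitude < 0:
            raise ValueError("torsion_amplitude must be >= 0")


def torsion_response(torsions: TorsionSet, params: SurrogateParams) -> float:
    """Smooth low-order periodic shift response to (φ, ψ, χ1).

    At the default amplitude the response has ≈1 ppm standard deviation over
    library-sampled torsions; it is identical for paired twins by
    construction.
    """
    if params.torsion_form != "cos-phi-psi-chi1":
        raise ValueError(f"unknown torsion response form {params.torsion_form!r}")
    phi, psi = math.radians(torsions.phi), math.radians(torsions.psi)
    chi1 = math.radians(torsions.chi[0]) if torsions.chi else 0.0
    return params.torsion_amplitude * (
        math.cos(phi - math.radians(60.0))
        + math.sin(psi + math.radians(45.0))
        + 0.5 * math.cos(chi1)
    )


def _sides(pair) -> tuple[PTMState, list, list]:
    """Normalize an EnsemblePair or a read manifest to (state, mod, unmod)
    where each side is a list of (backbone_index, rotamer, TorsionSet)."""
    if isinstance(pair, EnsemblePair):
        mod = [(c.backbone_index, c.rotamer, c.torsions) for c in pair.modified]
        unmod = [(c.backbone_index, c.rotamer, c.torsions) for c in pair.unmodified]
        return pair.state, mod, unmod
    state = pair["state_obj"]
    mod = [(r["backbone_index"], r["rotamer"], r["torsions_obj"]) for r in pair["modified"]]
    unmod = [(r["backbone_index"], r["rotamer"], r["torsions_obj"]) for r in pair["unmodified"]]
    return state, mod, unmod


def simulate_shift_records(pair, calibration: dict[tuple[str, str], CalibrationEntry],
                           params: SurrogateParams | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit surrogate shift records for both sides of an ensemble pair.

    Accepts an :class:`EnsemblePair` or a manifest read back by
    :func:`ptmdelta.serialization.read_manifest`.  Returns
    ``(modified_records, unmodified_records)`` DataFrames; reproducible under
    ``params.seed``.
    """
    params = params or SurrogateParams()
    state, mod, unmod = _sides(pair)
    key = (state.residue, state.state)
    if key not in calibration:
        raise KeyError(f"no calibration entry for {state.label}")
    entry = calibration[key]
    base = BASE_SHIFT[state.residue]
    rng = np.random.default_rng(params.seed)

    def make(side, records, effect, offsets, label):
        rows = []
        for i, (bb, rot, ts) in enumerate(records):
            off = offsets.get(rot, 0.0)
            eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
            value = base + torsion_response(ts, params) + off + effect + eps
            rows.append((f"{label}-{i:05d}", bb, rot, state.residue, side,
                         state.nucleus, value, "shift", "surrogate"))
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    if entry.rotamer_offsets:
        missing = {rot for _, rot, _ in mod} - set(entry.rotamer_offsets)
        if missing:
            raise KeyError(f"calibration for {state.label} lacks rotamer "
                           f"offsets for {sorted(missing)}")
    df_mod = make(state.state, mod, entry.effect, entry.rotamer_offsets, "mod")
    partner = unmodified_partner(state)
    df_unmod = make(partner.state, unmod, 0.0, {}, "unm")
    return df_mod, df_unmod


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a shift-record CSV preserving the schema (rotamer labels like
    "0"/"180" stay strings)."""
    return pd.read_csv(path, dtype={"rotamer": str, "state": str,
                                    "conformation_id": str, "nucleus": str})


def to_shielding(records: pd.DataFrame, reference_shielding: float) -> pd.DataFrame:
    """Convert shift records to shieldings via σ = σ_ref − δ."""
    if (records["kind"] != "shift").any():
        raise ValueError("records must be of kind 'shift'")
    out = records.copy()
    out["value"] = reference_shielding - out["value"]
    out["kind"] = "shielding"
    return out


def to_shift(records: pd.DataFrame, reference_shielding: float) -> pd.DataFrame:
    """Convert shielding records to shifts via δ = σ_ref − σ."""
    if (records["kind"] != "shielding").any():
        raise ValueError("records must be of kind 'shielding'")
    out = records.copy()
    out["value"] = reference_shielding - out["value"]
    out["kind"] = "shift"
    return out


_ISO_RE = re.compile(
    r"^\s*(\d+)\s+([A-Z][a-z]?)\s+Isotropic\s*=\s*(-?\d+\.\d+)", re.MULTILINE)


def parse_shielding_log(path: str | Path, atom_names: list[str] | None = None,
                        ) -> pd.DataFrame:
    """Parse per-atom isotropic shieldings from a quantum-chemistry text log.

    Lines of the form ``<index> <element> Isotropic = <value> ...`` are
    collected; ``atom_names`` (e.g. from an ensemble manifest) maps 1-based
    atom indices to nucleus names.
    """
    text = Path(path).read_text()
    matches = _ISO_RE.findall(text)
    if not matches:
        raise ValueError(f"no isotropic shielding block found in {path}")
    rows = []
    for idx_s, elem, val_s in matches:
        idx = int(idx_s)
        name = atom_names[idx - 1] if atom_names else f"{elem}{idx}"
        rows.append((name, idx - 1, "-", "", "", name, float(val_s),
                     "shielding", "parsed-log"))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
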