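"""Conformation building, clash detection, paired-ensemble invariants and
geometry serialization."""

import numpy as np
import pytest

from ptmdelta.geometry import (
    Conformation,
    build_conformation,
    detect_clashes,
    generate_paired_ensembles,
    measure_named_torsions,
)
from ptmdelta.serialization import (
    pair_manifest,
    read_manifest,
    read_pdb,
    write_manifest,
    write_pdb,
    write_qc_input,
)
from ptmdelta.topology import (
    PTMState,
    VALID_STATES,
    VDW_RADII,
    enumerate_rotamer_scheme,
    n_chi_for_state,
)
from ptmdelta.torsions import TorsionSet, sample_torsions


ALL_MODIFIED = [PTMState(r, s) for r in VALID_STATES for s in VALID_STATES[r][1:]]


class TestRotamerSchemes:
    @pytest.mark.parametrize("state,labels,total", [
        (("LYS", "charged"), 1, 500),
        (("LYS", "acetyl"), 2, 1000),
        (("LYS", "monomethyl"), 3, 1500),
        (("LYS", "dimethyl"), 3, 1500),
        (("LYS", "trimethyl"), 1, 500),
        (("ARG", "charged"), 1, 500),
        (("ARG", "monomethyl-NE"), 1, 500),
        (("ARG", "monomethyl-NH"), 4, 2000),
        (("ARG", "dimethyl-sym"), 2, 1000),
        (("ARG", "dimethyl-asym"), 4, 2000),
    ])
    def test_scheme_counts(self, state, labels, total):
        scheme = enumerate_rotamer_scheme(PTMState(*state), 500)
        assert len(scheme.rotamers) == labels
        assert scheme.total == total

    def test_acetyl_rotamer_values(self):
        scheme = enumerate_rotamer_scheme(PTMState("LYS", "acetyl"))
        assert {r.as_dict().get("rot") for r in scheme.rotamers} == {0.0, 180.0}

    def test_methyl_rotamer_values(self):
        scheme = enumerate_rotamer_scheme(PTMState("LYS", "monomethyl"))
        assert {r.as_dict().get("rot") for r in scheme.rotamers} == {60.0, -60.0, 180.0}

    def test_study_totals(self):
        lys = sum(enumerate_rotamer_scheme(PTMState("LYS", s), 500).total
                  for s in VALID_STATES["LYS"])
        arg = sum(enumerate_rotamer_scheme(PTMState("ARG", s), 500).total
                  for s in VALID_STATES["ARG"])
        assert lys == 5000
        assert arg == 6000

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            PTMState("LYS", "phospho")


class TestBuildConformation:
    @pytest.mark.parametrize("state", ALL_MODIFIED, ids=lambda s: s.label)
    def test_requested_torsions_realized(self, state):
        """Measured φ/ψ/χ match the requested values within 1e-3 degrees."""
        base = sample_torsions(state.residue, 3, seed=9)
        for k, ts in enumerate(base):
            need = n_chi_for_state(state)
            chi = ts.chi + tuple([60.0, -60.0, 180.0][:need - len(ts.chi)])
            ts = TorsionSet(phi=ts.phi, psi=ts.psi, chi=chi, flanking=ts.flanking)
            scheme = enumerate_rotamer_scheme(state)
            conf = build_conformation(state, ts, scheme.rotamers[0])
            measured = measure_named_torsions(conf)
            assert measured["phi"] == pytest.approx(ts.phi, abs=1e-3)
            assert measured["psi"] == pytest.approx(ts.psi, abs=1e-3)
            for i in range(need):
                assert measured[f"chi{i+1}"] == pytest.approx(ts.chi[i], abs=1e-3), \
                    f"chi{i+1} of {state.label}"

    def test_bond_lengths_equal_template_values(self):
        ts = sample_torsions("LYS", 1, seed=0)[0]
        conf = build_conformation(PTMState("LYS", "charged"), ts)
        d = np.linalg.norm(conf.coord("2:CA") - conf.coord("2:CB"))
        assert d == pytest.approx(1.525, abs=1e-9)
        d = np.linalg.norm(conf.coord("2:CE") - conf.coord("2:NZ"))
        assert d == pytest.approx(1.470, abs=1e-9)

    def test_atom_count_is_template_sum(self):
        ts = sample_torsions("LYS", 1, seed=0)[0]
        conf = build_conformation(PTMState("LYS", "charged"), ts)
        # Ace(3) + Gly(4) + Lys(4 bb + 5 side) + Gly(4) + Nme(2)
        assert conf.n_atoms == 3 + 4 + 9 + 4 + 2

    def test_chi_arity_mismatch_raises(self):
        ts = TorsionSet(phi=-60.0, psi=-45.0, chi=(60.0,))
        with pytest.raises(ValueError, match="chi"):
            build_conformation(PTMState("LYS", "charged"), ts)


def _clash_oracle(conf: Conformation, factor: float, depth: int):
    """Exhaustive O(n²) clash scan with BFS bond-distance exclusion."""
    n = conf.n_atoms
    adj = {i: set() for i in range(n)}
    for a, b in conf.bonds:
        adj[a].add(b)
        adj[b].add(a)

    def bond_dist(i, j):
        seen, frontier = {i}, {i}
        for step in range(1, depth + 1):
            frontier = {v for u in frontier for v in adj[u]} - seen
            if j in frontier:
                return step
            seen |= frontier
        return depth + 1

    out = []
    for i in range(n):
        for j in range(i + 1, n):
            cut = factor * (VDW_RADII[conf.elements[i]] + VDW_RADII[conf.elements[j]])
            if np.linalg.norm(conf.coords[i] - conf.coords[j]) < cut:
                if bond_dist(i, j) > depth:
                    out.append((i, j))
    return out


class TestClashDetection:
    def test_close_nonbonded_pair_flagged(self):
        ts = sample_torsions("LYS", 1, seed=4)[0]
        conf = build_conformation(PTMState("LYS", "charged"), ts)
        # teleport the terminal cap on top of the Ace cap
        conf.coords[-1] = conf.coords[0] + np.array([0.1, 0.0, 0.0])
        pairs = detect_clashes(conf)
        assert any(0 in p and conf.n_atoms - 1 in p for p in pairs)

    def test_bonded_pair_not_flagged(self):
        ts = sample_torsions("LYS", 1, seed=4)[0]
        conf = build_conformation(PTMState("LYS", "charged"), ts)
        i, j = conf.bonds[0]
        assert all({i, j} != set(p) for p in detect_clashes(conf))

    @pytest.mark.parametrize("residue,state", [("LYS", "dimethyl"),
                                               ("SER", "alpha-GalNAc")])
    def test_matches_bruteforce_oracle(self, residue, state):
        st = PTMState(residue, state)
        scheme = enumerate_rotamer_scheme(st)
        k = 0
        for ts in sample_torsions(residue, 25, seed=8):
            need = n_chi_for_state(st)
            chi = ts.chi + tuple([60.0, 180.0][:need - len(ts.chi)])
            ts = TorsionSet(phi=ts.phi, psi=ts.psi, chi=chi, flanking=ts.flanking)
            conf = build_conformation(st, ts, scheme.rotamers[k % len(scheme.rotamers)])
            k += 1
            # permissive factor so some conformations do clash
            assert detect_clashes(conf, 0.7, 3) == _clash_oracle(conf, 0.7, 3)


class TestPairedEnsembles:
    def test_pair_members_share_torsions(self, lys_mono_pair):
        for bb, (ui, mi) in lys_mono_pair.pairing.items():
            u = lys_mono_pair.unmodified[ui[0]]
            for j in mi:
                assert lys_mono_pair.modified[j].torsions == u.torsions

    def test_counts_follow_scheme(self, lys_mono_pair):
        assert len(lys_mono_pair.unmodified) == 40
        assert len(lys_mono_pair.modified) == 120  # 3 rotamers × 40
        assert lys_mono_pair.total_conformations == 160

    def test_glycan_twin_has_monosaccharide_removed(self, ser_glyco_pair):
        mod = ser_glyco_pair.modified[0]
        unmod = ser_glyco_pair.unmodified[0]
        assert any(k.startswith("5:") for k in mod.atom_keys)
        assert not any(k.startswith("5:") for k in unmod.atom_keys)
        assert mod.torsions == unmod.torsions

    def test_all_members_clash_free(self, lys_mono_pair):
        for conf in lys_mono_pair.unmodified + lys_mono_pair.modified:
            assert detect_clashes(conf) == []

    def test_seed_determinism(self):
        st = PTMState("LYS", "acetyl")
        a = generate_paired_ensembles(st, 10, seed=3)
        b = generate_paired_ensembles(st, 10, seed=3)
        for x, y in zip(a.modified, b.modified):
            assert np.array_equal(x.coords, y.coords)

    def test_unmodified_state_rejected(self):
        with pytest.raises(ValueError, match="not a modified state"):
            generate_paired_ensembles(PTMState("LYS", "charged"), 5, seed=0)


class TestSerialization:
    def test_pdb_round_trip(self, tmp_path, lys_mono_pair):
        confs = lys_mono_pair.modified[:5]
        path = tmp_path / "m.pdb"
        write_pdb(confs, path)
        models = read_pdb(path)
        assert len(models) == 5
        for conf, model in zip(confs, models):
            assert np.allclose(model["coords"], conf.coords, atol=1e-3)
            assert model["atom_names"] == [k.split(":")[1] for k in conf.atom_keys]

    def test_empty_model_list(self, tmp_path):
        path = tmp_path / "empty.pdb"
        write_pdb([], path)
        assert read_pdb(path) == []

    def test_glycan_atoms_are_hetatm(self, tmp_path, ser_glyco_pair):
        path = tmp_path / "g.pdb"
        write_pdb(ser_glyco_pair.modified[:1], path)
        text = path.read_text()
        assert "HETATM" in text
        hetatm_lines = [l for l in text.splitlines() if l.startswith("HETATM")]
        # exactly the 14 monosaccharide atoms are HETATM
        assert len(hetatm_lines) == 14

    def test_byte_identical_pdb_under_same_seed(self, tmp_path):
        st = PTMState("LYS", "trimethyl")
        for name in ("a.pdb", "b.pdb"):
            pair = generate_paired_ensembles(st, 5, seed=21)
            write_pdb(pair.modified, tmp_path / name)
        assert (tmp_path / "a.pdb").read_bytes() == (tmp_path / "b.pdb").read_bytes()

    def test_manifest_round_trip(self, tmp_path, lys_mono_pair):
        path = tmp_path / "m.json"
        write_manifest(lys_mono_pair, path)
        d = read_manifest(path)
        assert d["state_obj"] == lys_mono_pair.state
        assert len(d["modified"]) == len(lys_mono_pair.modified)
        first = d["modified"][0]
        assert first["torsions_obj"] == lys_mono_pair.modified[0].torsions


class TestQcInput:
    def test_basis_partition_exhaustive_and_disjoint(self, tmp_path, lys_mono_pair):
        conf = lys_mono_pair.modified[0]
        path = tmp_path / "job.com"
        write_qc_input(conf, "CE", path, neighbor_shell=1)
        text = path.read_text()
        sections = []
        for line in text.splitlines():
            if line.endswith(" 0") and line[0].isdigit():
                sections.append([int(x) for x in line.split()[:-1]])
        flat = [i for sec in sections for i in sec]
        assert sorted(flat) == list(range(1, conf.n_atoms + 1))
        assert len(flat) == len(set(flat))

    def test_high_basis_covers_focus_and_bonded_neighbors(self, tmp_path, lys_mono_pair):
        conf = lys_mono_pair.modified[0]
        path = tmp_path / "job.com"
        write_qc_input(conf, "CE", path, neighbor_shell=1)
        lines = path.read_text().splitlines()
        hi_idx = next(i for i, l in enumerate(lines)
                      if l.endswith(" 0") and l[0].isdigit())
        high = {int(x) for x in lines[hi_idx].split()[:-1]}
        assert lines[hi_idx + 1] == "6-311+G(2d,p)"
        ce = conf.atom_keys.index("2:CE") + 1
        cd = conf.atom_keys.index("2:CD") + 1
        nz = conf.atom_keys.index("2:NZ") + 1
        assert {ce, cd, nz} <= high

    def test_shell_zero_is_focus_only(self, tmp_path, lys_mono_pair):
        conf = lys_mono_pair.modified[0]
        path = tmp_path / "job.com"
        write_qc_input(conf, "CE", path, neighbor_shell=0)
        lines = path.read_text().splitlines()
        hi = next(l for l in lines if l.endswith(" 0") and l[0].isdigit())
        assert hi.split()[:-1] == [str(conf.atom_keys.index("2:CE") + 1)]

    def test_unknown_nucleus_raises(self, tmp_path, lys_mono_pair):
        with pytest.raises(ValueError, match="unknown nucleus"):
            write_qc_input(lys_mono_pair.modified[0], "XX", tmp_path / "x.com")
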