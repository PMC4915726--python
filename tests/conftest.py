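"""Shared fixtures: tiny PDB texts, toy sequences, and the calibrated
divergence-pattern fixture used by both unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from graftsite.active_site_profile import Ensemble, ResidueProfile, ResidueStat
from graftsite.homolog_compare import Correspondence
from graftsite.structures import AtomRecord, StructureModel


# ---------------------------------------------------------------------------
# PDB fixture texts
# ---------------------------------------------------------------------------

def pdb_atom_line(serial, name, res_name, chain, res_num, x, y, z,
                  altloc=" ", occ=1.0, b=0.0, element=None, record="ATOM"):
    element = element or name[0]
    name_field = name if len(name) >= 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{res_name:<3} {chain}{res_num:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}"
    )


@pytest.fixture
def two_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        "END",
    ]
    p = tmp_path / "two_atom.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def multi_model_pdb(tmp_path):
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL     {model:>4}")
        lines.append(pdb_atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, float(model)))
        lines.append(pdb_atom_line(2, "CA", "GLY", "A", 1, 1.5, 0.0, float(model)))
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "two_model.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.6),
        pdb_atom_line(2, "CA", "SER", "A", 1, 0.5, 0.0, 0.0, altloc="B", occ=0.4),
        pdb_atom_line(3, "CB", "SER", "A", 1, 1.0, 1.0, 0.0),
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def lysine_model():
    """A lysine plus a few satellite atoms at known distances from NZ."""
    atoms = [
        AtomRecord(1, "NZ", "N", "", "LYS", "A", 167, "", np.zeros(3)),
        AtomRecord(2, "CE", "C", "", "LYS", "A", 167, "", np.array([1.5, 0.0, 0.0])),
        AtomRecord(3, "CA", "C", "", "VAL", "A", 20, "", np.array([5.9, 0.0, 0.0])),
        AtomRecord(4, "CB", "C", "", "VAL", "A", 20, "", np.array([6.1, 0.0, 0.0])),
        AtomRecord(5, "CA", "C", "", "GLY", "A", 30, "", np.array([0.0, 4.0, 0.0])),
    ]
    return StructureModel("toy", 1, atoms)


def make_random_ensemble(n_atoms: int, n_snapshots: int, seed: int) -> Ensemble:
    """Generic random ensemble with a LYS NZ reference as atom 0."""
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord(1, "NZ", "N", "", "LYS", "A", 1, "", np.zeros(3))]
    for i in range(1, n_atoms):
        atoms.append(
            AtomRecord(i + 1, "CA", "C", "", "VAL", "A", i + 1, "", rng.uniform(-5, 5, 3))
        )
    base = np.array([a.coords for a in atoms])
    coords = base[None] + rng.normal(0, 0.5, size=(n_snapshots, n_atoms, 3))
    return Ensemble(atoms=atoms, coords=coords, dt=1.0, source_id=f"rand{seed}")


# ---------------------------------------------------------------------------
# Toy sequences (synthetic stand-ins; required letters planted at the
# positions the variant bookkeeping refers to)
# ---------------------------------------------------------------------------

def _planted_seq(length: int, planted: dict[int, str], fill: str = "K") -> str:
    chars = [fill] * length
    for pos, aa in planted.items():
        chars[pos - 1] = aa
    return "".join(chars)


@pytest.fixture
def dera_like_seq():
    return _planted_seq(260, {18: "T", 20: "L", 203: "A", 204: "G", 205: "G", 206: "W"})


@pytest.fixture
def kdpgal_like_seq():
    return _planted_seq(205, {12: "I", 17: "V", 18: "V", 19: "P", 20: "V", 21: "I", 37: "E", 154: "V"})


@pytest.fixture
def kdpg_like_seq():
    return _planted_seq(213, {9: "L", 10: "I", 11: "A", 12: "I", 13: "L", 20: "V", 45: "E", 161: "T"})


# ---------------------------------------------------------------------------
# Calibrated divergence-pattern fixture: three divergent pairs planted in
# residue-level profiles, one of them a glutamate to be excluded explicitly.
# ---------------------------------------------------------------------------

def make_divergence_pattern_fixture():
    """Residue profiles + correspondence with the pattern
    {I12/V20, E37/E45, V154/T161} divergent and everything else flat."""
    residues_a = [  # KDPGal-like numbering
        ("ILE", 12, 4.0), ("GLU", 37, 5.5), ("VAL", 154, 6.0),
        ("GLY", 10, 5.0), ("THR", 40, 4.5), ("PHE", 60, 6.5), ("ALA", 80, 7.0),
    ]
    residues_b = [  # KDPG-like numbering; divergent pairs offset by 2.0 Å
        ("VAL", 20, 6.0), ("GLU", 45, 7.5), ("THR", 161, 4.0),
        ("GLY", 18, 5.0), ("THR", 48, 4.5), ("PHE", 67, 6.5), ("ALA", 87, 7.0),
    ]
    sd = 0.3
    prof_a = ResidueProfile(
        [ResidueStat("A", num, "", name, mean, sd, 3) for name, num, mean in residues_a]
    )
    prof_b = ResidueProfile(
        [ResidueStat("A", num, "", name, mean, sd, 3) for name, num, mean in residues_b]
    )
    pairs = [
        (("KDPGal", "A", a[1]), ("KDPG", "A", b[1]))
        for a, b in zip(residues_a, residues_b)
    ]
    corr = Correspondence(pairs=pairs, method="user")
    return prof_a, prof_b, corr


@pytest.fixture
def divergence_pattern():
    return make_divergence_pattern_fixture()
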