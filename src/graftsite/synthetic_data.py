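"""Generators for every input the pipeline consumes, with known ground truth.

All generators are pure functions of (config, seed).  Each one draws from an
independent stream derived from the root seed through a fixed per-generator
tag (``default_rng([tag, seed])``), so adding a generator never perturbs
existing fixtures.

The ensemble model is an isotropic Gaussian jitter around a static
structure — deliberately NOT a physical MD surrogate, just enough to
exercise mean/SD distance profiling.  Assay noise is multiplicative
lognormal (positivity-preserving).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .active_site_profile import Ensemble
from .homolog_compare import Correspondence
from .selectivity import PeakPair, michaelis_menten
from .structures import AtomRecord, StructureModel, Superposition, write_pdb

__all__ = [
    "HomologPairTruth",
    "EnsembleSimConfig",
    "MsaSimConfig",
    "make_homolog_pair",
    "sample_ensemble",
    "make_msa",
    "simulate_peak_areas",
    "simulate_kinetics",
    "write_ensemble_pdb",
    "write_fasta",
    "parse_column_spec",
]

# per-generator stream tags (never reuse or renumber)
_TAG_PAIR = 1
_TAG_ENSEMBLE = 2
_TAG_MSA = 3
_TAG_PEAKS = 4
_TAG_KINETICS = 5

_SCAFFOLD_RESNAMES = ("VAL", "ILE", "LEU", "ALA", "THR", "SER", "GLY", "PHE")


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


# ---------------------------------------------------------------------------
# Homolog structure pairs with planted geometry differences
# ---------------------------------------------------------------------------

@dataclass
class HomologPairTruth:
    """Two toy homolog structures sharing a scaffold, plus ground truth.

    Structure B carries the planted per-residue radial offsets (distance to
    the reference atom increased by exactly the stated amount) and sits in a
    recorded rigid-transformed frame.
    """

    model_a: StructureModel
    model_b: StructureModel
    correspondence: Correspondence
    superposition: Superposition  # maps A-frame coordinates into B's frame
    planted: dict[int, float]  # A-side res_num -> offset in Å
    reference_res_a: int
    reference_res_b: int
    res_num_shift: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "model_a": _model_to_dict(self.model_a),
            "model_b": _model_to_dict(self.model_b),
            "pairs": [list(map(list, p)) for p in self.correspondence.pairs],
            "rotation": self.superposition.rotation.tolist(),
            "translation": self.superposition.translation.tolist(),
            "planted": {str(k): v for k, v in self.planted.items()},
            "reference_res_a": self.reference_res_a,
            "reference_res_b": self.reference_res_b,
            "res_num_shift": self.res_num_shift,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomologPairTruth":
        pairs = [tuple(tuple(side) for side in p) for p in d["pairs"]]
        return cls(
            model_a=_model_from_dict(d["model_a"]),
            model_b=_model_from_dict(d["model_b"]),
            correspondence=Correspondence(pairs=pairs, method="user"),
            superposition=Superposition(
                rotation=np.array(d["rotation"]),
                translation=np.array(d["translation"]),
                rmsd=0.0,
                n_pairs=3,
            ),
            planted={int(k): v for k, v in d["planted"].items()},
            reference_res_a=d["reference_res_a"],
            reference_res_b=d["reference_res_b"],
            res_num_shift=d["res_num_shift"],
            seed=d["seed"],
        )

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "HomologPairTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _model_to_dict(m: StructureModel) -> dict:
    return {
        "structure_id": m.structure_id,
        "model_id": m.model_id,
        "atoms": [
            {
                "serial": a.serial,
                "atom_name": a.atom_name,
                "element": a.element,
                "alt_loc": a.alt_loc,
                "res_name": a.res_name,
                "chain_id": a.chain_id,
                "res_num": a.res_num,
                "insertion_code": a.insertion_code,
                "coords": a.coords.tolist(),
                "occupancy": a.occupancy,
                "b_factor": a.b_factor,
            }
            for a in m.atoms
        ],
    }


def _model_from_dict(d: dict) -> StructureModel:
    atoms = [AtomRecord(**a) for a in d["atoms"]]
    return StructureModel(d["structure_id"], d["model_id"], atoms)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_homolog_pair(
    n_residues: int,
    planted: Sequence[tuple[int, float]] = (),
    seed: int = 0,
    res_num_shift: int = 7,
    min_separation: float = 4.0,
    shell: tuple[float, float] = (3.5, 7.5),
) -> HomologPairTruth:
    """Toy homolog pair: shared scaffold, planted radial offsets in B.

    Structure A has a reference lysine (NZ at the origin) at residue 1 and
    ``n_residues`` scaffold residues (Cα + a Cβ side-chain proxy on the same
    ray) at radii within ``shell``.  Structure B's planted residues are
    displaced radially from the reference atom by the stated offsets, its
    residues are renumbered by ``res_num_shift``, and a recorded random
    rigid transform is applied.
    """
    planted_map = dict(planted)
    for res, off in planted_map.items():
        if not 2 <= res <= n_residues + 1:
            raise ValueError(f"planted residue {res} outside scaffold range 2..{n_residues + 1}")
    rng = _rng(_TAG_PAIR, seed)

    lys_ca = np.array([0.0, 0.0, -3.0])
    placed_ca = [lys_ca]
    directions = []
    radii = []
    for _ in range(n_residues):
        for _attempt in range(1000):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(*shell)
            ca = u * r
            if all(np.linalg.norm(ca - p) >= min_separation for p in placed_ca):
                placed_ca.append(ca)
                directions.append(u)
                radii.append(r)
                break
        else:
            raise ValueError(
                f"cannot place {n_residues} residues with {min_separation} Å separation; "
                "reduce n_residues or min_separation"
            )

    def build_atoms(offsets: dict[int, float]) -> list[AtomRecord]:
        atoms = [
            AtomRecord(1, "NZ", "N", "", "LYS", "A", 1, "", np.zeros(3)),
            AtomRecord(2, "CA", "C", "", "LYS", "A", 1, "", lys_ca.copy()),
        ]
        serial = 3
        for i, (u, r) in enumerate(zip(directions, radii)):
            res_num = i + 2
            r_eff = r + offsets.get(res_num, 0.0)
            if r_eff <= 0.5:
                raise ValueError(f"offset at residue {res_num} places atoms atop the reference")
            res_name = _SCAFFOLD_RESNAMES[i % len(_SCAFFOLD_RESNAMES)]
            atoms.append(AtomRecord(serial, "CA", "C", "", res_name, "A", res_num, "", u * r_eff))
            atoms.append(AtomRecord(serial + 1, "CB", "C", "", res_name, "A", res_num, "", u * (r_eff + 1.2)))
            serial += 2
        return atoms

    atoms_a = build_atoms({})
    atoms_b = build_atoms(planted_map)

    # reject degenerate plants: no two heavy atoms atop one another in B
    coords_b = np.array([a.coords for a in atoms_b])
    diff = coords_b[:, None, :] - coords_b[None, :, :]
    dists = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 0.8:
        raise ValueError("planted offsets place atoms atop one another")

    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    sup = Superposition(rotation=R, translation=t, rmsd=0.0, n_pairs=len(atoms_a))

    id_a = f"toyA-{seed}"
    id_b = f"toyB-{seed}"
    model_a = StructureModel(id_a, 1, atoms_a)
    for a in atoms_b:
        a.res_num = a.res_num + res_num_shift
        a.coords = sup.apply(a.coords)
    model_b = StructureModel(id_b, 1, atoms_b)

    pairs = [
        ((id_a, "A", n), (id_b, "A", n + res_num_shift)) for n in range(1, n_residues + 2)
    ]
    corr = Correspondence(pairs=pairs, method="user")
    return HomologPairTruth(
        model_a=model_a,
        model_b=model_b,
        correspondence=corr,
        superposition=sup,
        planted=planted_map,
        reference_res_a=1,
        reference_res_b=1 + res_num_shift,
        res_num_shift=res_num_shift,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Conformational ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSimConfig:
    base: StructureModel
    sigma: float = 0.3
    n_snapshots: int = 1000
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")


def sample_ensemble(cfg: EnsembleSimConfig) -> Ensemble:
    """Snapshots = base coordinates + i.i.d. isotropic Gaussian(0, σ²) per atom."""
    rng = _rng(_TAG_ENSEMBLE, cfg.seed)
    base = cfg.base.coords_array()
    noise = rng.normal(0.0, cfg.sigma, size=(cfg.n_snapshots, *base.shape)) if cfg.sigma > 0 else 0.0
    coords = base[None, :, :] + noise
    if cfg.sigma == 0:
        coords = np.broadcast_to(base[None, :, :], (cfg.n_snapshots, *base.shape)).copy()
    return Ensemble(
        atoms=list(cfg.base.atoms), coords=coords, dt=cfg.dt, source_id=cfg.base.structure_id
    )


def write_ensemble_pdb(ens: Ensemble, path) -> None:
    models = [ens.snapshot_model(i) for i in range(ens.n_snapshots)]
    write_pdb(models, path)


# ---------------------------------------------------------------------------
# Homolog sequence families
# ---------------------------------------------------------------------------

@dataclass
class MsaSimConfig:
    """Column-wise alignment model: each column is an amino-acid distribution.

    Columns are given as {aa: frequency} dicts; a fully conserved column is
    {"V": 1.0}.  Gaps are introduced independently at ``gap_rate``.
    """

    n_sequences: int
    columns: Sequence[dict[str, float]]
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        if not 0.0 <= self.gap_rate <= 1.0:
            raise ValueError("gap_rate must be in [0, 1]")
        for i, col in enumerate(self.columns):
            total = sum(col.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {i + 1}: frequencies sum to {total}, not 1")
            if any(f < 0 for f in col.values()):
                raise ValueError(f"column {i + 1}: negative frequency")


def make_msa(cfg: MsaSimConfig) -> list[str]:
    """Draw an alignment, per column, from the stated distributions."""
    rng = _rng(_TAG_MSA, cfg.seed)
    n, L = cfg.n_sequences, len(cfg.columns)
    cols = []
    for col in cfg.columns:
        letters = sorted(col)
        probs = np.array([col[a] for a in letters])
        probs = probs / probs.sum()
        cols.append(rng.choice(list(letters), size=n, p=probs))
    matrix = np.array(cols).T  # (n, L)
    if cfg.gap_rate > 0:
        gaps = rng.random(size=(n, L)) < cfg.gap_rate
        matrix = np.where(gaps, "-", matrix)
    return ["".join(row) for row in matrix]


def parse_column_spec(text: str) -> dict[str, float]:
    """Parse ``conserved(V)`` or ``mixture(I:0.5,V:0.5)`` column specs."""
    text = text.strip()
    if text.startswith("conserved(") and text.endswith(")"):
        aa = text[len("conserved(") : -1].strip()
        return {aa: 1.0}
    if text.startswith("mixture(") and text.endswith(")"):
        out = {}
        for item in text[len("mixture(") : -1].split(","):
            aa, freq = item.split(":")
            out[aa.strip()] = float(freq)
        return out
    raise ValueError(f"invalid column spec {text!r}")


def write_fasta(sequences: Sequence[str], path, prefix: str = "seq") -> None:
    with open(path, "wt") as fh:
        for i, s in enumerate(sequences):
            fh.write(f">{prefix}{i + 1}\n{s}\n")


# ---------------------------------------------------------------------------
# Assay readouts
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    mu = -0.5 * sigma**2
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def simulate_peak_areas(
    true_ee: float,
    total_area: float = 100.0,
    cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> list[PeakPair]:
    """Replicate enantiomer peak-area pairs at a stated true ee.

    Noise-free areas are total·(1 ± ee)/2; each area is multiplied by an
    independent unit-mean lognormal factor of coefficient of variation
    ``cv``.
    """
    if not -1.0 <= true_ee <= 1.0:
        raise ValueError("true_ee must lie in [-1, 1]")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    rng = _rng(_TAG_PEAKS, seed)
    ref0 = total_area * (1.0 + true_ee) / 2.0
    oth0 = total_area * (1.0 - true_ee) / 2.0
    f_ref = _lognormal_factors(rng, cv, n_reps)
    f_oth = _lognormal_factors(rng, cv, n_reps)
    return [
        PeakPair(area_ref=ref0 * f_ref[i], area_other=oth0 * f_oth[i], run_id=f"rep{i + 1}")
        for i in range(n_reps)
    ]


def simulate_kinetics(
    K_M: float,
    k_cat: float,
    S_grid: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(S, rate) pairs from v = k_cat·S/(K_M + S) with lognormal noise."""
    if K_M <= 0 or k_cat <= 0:
        raise ValueError("K_M and k_cat must be positive")
    S = np.asarray(S_grid, dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")
    rng = _rng(_TAG_KINETICS, seed)
    v = michaelis_menten(S, k_cat, K_M) * _lognormal_factors(rng, noise_cv, len(S))
    return S, v
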