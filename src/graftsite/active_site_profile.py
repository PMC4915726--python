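"""Per-atom distance statistics over a conformational ensemble.

For every atom in the stereoselectivity-determining region, compute the
mean and standard deviation of its distance to the reference atom (the
catalytic-lysine NZ) across all snapshots, then aggregate to residue level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .structures import (
    AtomRecord,
    RegionSpec,
    StructureModel,
    StructureError,
    get_reference_atom,
    read_structure,
    select_region,
)

__all__ = [
    "Ensemble",
    "AtomStat",
    "DistanceProfile",
    "ResidueStat",
    "ResidueProfile",
    "load_ensemble",
    "distance_profile",
    "aggregate_by_residue",
    "write_profile_tsv",
    "write_residue_profile_tsv",
    "read_residue_profile_tsv",
]


def _atom_key(a: AtomRecord) -> tuple[str, int, str, str]:
    return (a.chain_id, a.res_num, a.insertion_code, a.atom_name)


@dataclass
class Ensemble:
    """Ordered snapshots of a fixed atom set.

    ``coords`` has shape (n_snapshots, n_atoms, 3); ``dt`` is the snapshot
    spacing in ps (metadata only).
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    dt: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_snapshots, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one snapshot")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"atom count mismatch: {len(self.atoms)} identities vs {self.coords.shape[1]} coordinates"
            )

    @property
    def n_snapshots(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def snapshot_model(self, i: int = 0) -> StructureModel:
        """Materialize snapshot ``i`` as a StructureModel (the reference conformer)."""
        atoms = []
        for a, xyz in zip(self.atoms, self.coords[i]):
            b = AtomRecord(
                serial=a.serial,
                atom_name=a.atom_name,
                element=a.element,
                alt_loc=a.alt_loc,
                res_name=a.res_name,
                chain_id=a.chain_id,
                res_num=a.res_num,
                insertion_code=a.insertion_code,
                coords=np.array(xyz),
                occupancy=a.occupancy,
                b_factor=a.b_factor,
            )
            atoms.append(b)
        return StructureModel(self.source_id or "ensemble", model_id=i + 1, atoms=atoms)

    @classmethod
    def from_models(cls, models: Sequence[StructureModel], dt: float = 1.0) -> "Ensemble":
        if not models:
            raise ValueError("no models")
        ref_keys = [_atom_key(a) for a in models[0].atoms]
        ref_set = dict.fromkeys(ref_keys)
        for m in models[1:]:
            keys = [_atom_key(a) for a in m.atoms]
            if keys != ref_keys:
                missing = [k for k in ref_set if k not in set(keys)]
                extra = [k for k in keys if k not in ref_set]
                offender = (missing or extra)[0]
                raise StructureError(
                    f"model {m.model_id}: atom set differs from model {models[0].model_id}; "
                    f"first offending atom: {offender[0]}:{offender[1]}{offender[2]} {offender[3]}"
                )
        coords = np.stack([m.coords_array() for m in models])
        return cls(atoms=list(models[0].atoms), coords=coords, dt=dt, source_id=models[0].structure_id)


def load_ensemble(
    path,
    atom_filter: Callable[[AtomRecord], bool] | None = None,
    dt: float = 1.0,
    **read_kw,
) -> Ensemble:
    """Load a multi-model PDB as an ensemble (snapshots in model order).

    All models must share an identical atom set; the first offending atom is
    named otherwise.
    """
    models = read_structure(path, **read_kw)
    if atom_filter is not None:
        models = [
            StructureModel(m.structure_id, m.model_id, [a for a in m.atoms if atom_filter(a)])
            for m in models
        ]
    return Ensemble.from_models(models, dt=dt)


@dataclass(frozen=True)
class AtomStat:
    atom: AtomRecord
    mean: float
    sd: float
    n_snapshots: int


@dataclass
class DistanceProfile:
    """Mean/SD of distance to the reference atom per region atom."""

    stats: list[AtomStat]
    reference: AtomRecord
    radius: float

    def __len__(self) -> int:
        return len(self.stats)

    def __iter__(self):
        return iter(self.stats)


def distance_profile(ens: Ensemble, spec: RegionSpec) -> DistanceProfile:
    """Distance statistics d_i(t) = ||x_i(t) − x_ref(t)|| over all snapshots.

    The region membership and the reference atom are resolved once, on the
    reference conformer (first snapshot), and held fixed for the whole
    trajectory.  SD is the sample standard deviation (n−1 denominator);
    a single-snapshot ensemble reports SD 0.
    """
    model0 = ens.snapshot_model(0)
    ref = get_reference_atom(model0, spec)
    region = select_region(model0, spec)
    if not region:
        raise StructureError("empty region: no atoms to profile")

    index = {_atom_key(a): i for i, a in enumerate(ens.atoms)}
    try:
        ref_idx = index[_atom_key(ref)]
    except KeyError:  # pragma: no cover - ref comes from the ensemble itself
        raise StructureError("reference atom absent from ensemble")
    region_idx = np.array([index[_atom_key(a)] for a in region], dtype=int)

    diffs = ens.coords[:, region_idx, :] - ens.coords[:, ref_idx, None, :]
    d = np.linalg.norm(diffs, axis=2)  # (n_snapshots, n_region)
    means = d.mean(axis=0)
    if ens.n_snapshots > 1:
        sds = d.std(axis=0, ddof=1)
        # exact zero for constant series (summation noise otherwise leaves ~1e-15)
        sds[d.max(axis=0) == d.min(axis=0)] = 0.0
    else:
        sds = np.zeros_like(means)

    stats = [
        AtomStat(atom=ens.atoms[j], mean=float(m), sd=float(s), n_snapshots=ens.n_snapshots)
        for j, m, s in zip(region_idx, means, sds)
    ]
    return DistanceProfile(stats=stats, reference=ref, radius=spec.radius)


@dataclass(frozen=True)
class ResidueStat:
    chain_id: str
    res_num: int
    insertion_code: str
    res_name: str
    mean: float
    sd: float
    n_atoms: int

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.insertion_code)


@dataclass
class ResidueProfile:
    """Residue-level representative distance statistics."""

    entries: list[ResidueStat]

    def lookup(self, chain_id: str, res_num: int, insertion_code: str = "") -> ResidueStat | None:
        for e in self.entries:
            if e.residue_key == (chain_id, res_num, insertion_code):
                return e
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def aggregate_by_residue(profile: DistanceProfile, method: str = "closest") -> ResidueProfile:
    """Collapse the atom-level profile to one representative entry per residue.

    ``closest`` (default): the atom with the smallest mean distance
    represents the residue; ties break toward the lower atom serial.
    ``mean``: average of the per-atom means/SDs.
    """
    if not profile.stats:
        raise ValueError("empty profile")
    groups: dict[tuple, list[AtomStat]] = {}
    order: list[tuple] = []
    for s in profile.stats:
        k = s.atom.residue_key
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(s)

    entries = []
    for k in order:
        members = groups[k]
        a0 = members[0].atom
        if method == "closest":
            rep = min(members, key=lambda s: (s.mean, s.atom.serial))
            mean, sd = rep.mean, rep.sd
        elif method == "mean":
            mean = float(np.mean([s.mean for s in members]))
            sd = float(np.mean([s.sd for s in members]))
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
        entries.append(
            ResidueStat(
                chain_id=a0.chain_id,
                res_num=a0.res_num,
                insertion_code=a0.insertion_code,
                res_name=a0.res_name,
                mean=mean,
                sd=sd,
                n_atoms=len(members),
            )
        )
    return ResidueProfile(entries=entries)


def write_profile_tsv(profile: DistanceProfile, path) -> None:
    with open(path, "wt") as fh:
        fh.write("chain\tres_num\tres_name\tatom_name\tmean_A\tsd_A\tn_snapshots\n")
        for s in profile.stats:
            a = s.atom
            fh.write(
                f"{a.chain_id}\t{a.res_num}{a.insertion_code}\t{a.res_name}\t{a.atom_name}\t"
                f"{s.mean:.6f}\t{s.sd:.6f}\t{s.n_snapshots}\n"
            )


def write_residue_profile_tsv(profile: ResidueProfile, path) -> None:
    with open(path, "wt") as fh:
        fh.write("chain\tres_num\tres_name\tmean_A\tsd_A\tn_atoms\n")
        for e in profile.entries:
            fh.write(
                f"{e.chain_id}\t{e.res_num}{e.insertion_code}\t{e.res_name}\t"
                f"{e.mean:.6f}\t{e.sd:.6f}\t{e.n_atoms}\n"
            )


def read_residue_profile_tsv(path) -> ResidueProfile:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chain", "res_num", "res_name", "mean_A", "sd_A", "n_atoms"]
        if header != expected:
            raise ValueError(f"unexpected residue-profile header: {header}")
        for line in fh:
            chain, res, name, mean, sd, n = line.rstrip("\n").split("\t")
            icode = ""
            if res and not res[-1].isdigit():
                res, icode = res[:-1], res[-1]
            entries.append(
                ResidueStat(chain, int(res), icode, name, float(mean), float(sd), int(n))
            )
    return ResidueProfile(entries=entries)
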