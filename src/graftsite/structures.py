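"""Structure I/O, cleaning, active-site region selection and rigid superposition.

Reads PDB v3.3 coordinate files (gzip-transparent), collapses alternate
locations to the highest-occupancy conformer, relabels selenomethionine to
methionine, and provides the geometric primitives used by the rest of the
pipeline: reference-atom lookup (the catalytic-lysine NZ by default),
radius-based region selection around a chosen centre, and Kabsch
least-squares superposition.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "AtomSelector",
    "RegionSpec",
    "Superposition",
    "StructureError",
    "AtomNotFoundError",
    "read_structure",
    "write_pdb",
    "get_reference_atom",
    "select_region",
    "kabsch_superpose",
    "rmsd_between",
    "write_region_tsv",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "DIS"})


class StructureError(ValueError):
    """Raised for malformed or unusable structure input."""


class AtomNotFoundError(StructureError):
    """Raised when a selector cannot be resolved against a structure."""


@dataclass
class AtomRecord:
    """One atom as read from a coordinate file.

    Residue numbering is author numbering, preserved verbatim from the
    input (1-based, insertion codes carried).
    """

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_num: int
    insertion_code: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    record_type: str = "ATOM"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.serial} {self.atom_name}: coordinates must be a finite 3-vector"
            )

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.res_num, self.insertion_code, self.atom_name, self.alt_loc)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class StructureModel:
    """One conformer: an ordered set of atoms."""

    structure_id: str
    model_id: int
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"{self.structure_id}: model {self.model_id} has no atoms")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise StructureError(f"{self.structure_id}: duplicate atom after cleaning: {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def get_atom(
        self, chain_id: str, res_num: int, atom_name: str, insertion_code: str = ""
    ) -> AtomRecord:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.res_num == res_num
                and a.insertion_code == insertion_code
                and a.atom_name == atom_name
            ):
                return a
        raise AtomNotFoundError(
            f"{self.structure_id}: atom {atom_name} of {chain_id}:{res_num}{insertion_code} not found"
        )

    def residue_atoms(self, chain_id: str, res_num: int, insertion_code: str = "") -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.res_num == res_num and a.insertion_code == insertion_code
        ]

    def ca_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.atom_name == "CA"]


@dataclass(frozen=True)
class AtomSelector:
    """Names a single atom by chain, author residue number and atom name.

    ``require_res_name`` (if set) makes resolution fail unless the residue
    carries that name; the default reference selector requires LYS so that
    the catalytic-lysine convention cannot silently pick up another residue.
    Passing ``require_res_name=None`` overrides the check.
    """

    chain_id: str
    res_num: int
    atom_name: str = "NZ"
    insertion_code: str = ""
    require_res_name: str | None = None

    def resolve(self, model: StructureModel) -> AtomRecord:
        residue = model.residue_atoms(self.chain_id, self.res_num, self.insertion_code)
        if not residue:
            raise AtomNotFoundError(
                f"{model.structure_id}: residue {self.chain_id}:{self.res_num}{self.insertion_code} not found"
            )
        if self.require_res_name is not None and residue[0].res_name != self.require_res_name:
            raise StructureError(
                f"{model.structure_id}: residue {self.chain_id}:{self.res_num} is "
                f"{residue[0].res_name}, expected {self.require_res_name}"
            )
        for a in residue:
            if a.atom_name == self.atom_name:
                return a
        raise AtomNotFoundError(
            f"{model.structure_id}: reference atom absent — no {self.atom_name} in "
            f"{residue[0].res_name} {self.chain_id}:{self.res_num}"
        )


@dataclass
class RegionSpec:
    """The stereoselectivity-determining region: a sphere of ``radius``
    around ``center``, with distances measured from ``reference_atom``.

    ``center`` may be explicit coordinates, an :class:`AtomSelector`, or
    ``None`` (fall back to the reference atom's position).  The boundary is
    inclusive.
    """

    reference_atom: AtomSelector
    center: np.ndarray | AtomSelector | None = None
    radius: float = 6.0
    keep_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.center is not None and not isinstance(self.center, AtomSelector):
            self.center = np.asarray(self.center, dtype=float)
            if self.center.shape != (3,):
                raise ValueError("explicit center must be a 3-vector")

    @classmethod
    def for_lysine(
        cls,
        chain_id: str,
        res_num: int,
        center: np.ndarray | AtomSelector | None = None,
        radius: float = 6.0,
        **kw,
    ) -> "RegionSpec":
        """Default parameterization: NZ of the catalytic lysine as reference."""
        ref = AtomSelector(chain_id, res_num, "NZ", require_res_name="LYS")
        return cls(reference_atom=ref, center=center, radius=radius, **kw)

    def resolve_center(self, model: StructureModel) -> np.ndarray:
        if self.center is None:
            return get_reference_atom(model, self).coords
        if isinstance(self.center, AtomSelector):
            return self.center.resolve(model).coords
        return self.center


@dataclass(frozen=True)
class Superposition:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if self.n_pairs < 3:
            raise ValueError("n_pairs must be >= 3")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls, n_pairs: int = 3) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0, n_pairs)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _open_text(path) -> Iterable[str]:
    path = Path(path)
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return gzip.open(raw, "rt")
    return open(path, "rt")


def _parse_atom_line(line: str) -> AtomRecord:
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # infer from the atom name: strip digits, take the leading letter(s)
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    occ_field = line[54:60].strip()
    b_field = line[60:66].strip()
    return AtomRecord(
        serial=serial,
        atom_name=name,
        element=element,
        alt_loc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain_id=line[21].strip(),
        res_num=int(line[22:26]),
        insertion_code=line[26].strip(),
        coords=np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]),
        occupancy=float(occ_field) if occ_field else 1.0,
        b_factor=float(b_field) if b_field else 0.0,
        record_type=line[:6].strip(),
    )


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep, per (chain, residue, atom name), the highest-occupancy altloc.

    Equal occupancies break alphabetically (lowest altloc letter wins).
    """
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain_id, a.res_num, a.insertion_code, a.atom_name)
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _altloc_rank(a.alt_loc)) > (b.occupancy, _altloc_rank(b.alt_loc)):
                best[k] = a
    return [best[k] for k in order]


def _altloc_rank(alt: str) -> int:
    # higher rank = preferred at equal occupancy; '' > 'A' > 'B' > ...
    return 0 if alt == "" else -ord(alt)


def read_structure(
    path,
    chain: str | None = None,
    keep_het: bool = False,
    keep_hydrogens: bool = False,
) -> list[StructureModel]:
    """Read a (possibly gzipped) PDB file into one model per MODEL block.

    Cleaning rules: alternate locations are collapsed to the
    highest-occupancy conformer; water and other HETATM records are dropped
    unless ``keep_het``; selenomethionine (MSE) is relabelled MET with its
    atoms retained; hydrogens are dropped unless ``keep_hydrogens``.
    """
    structure_id = Path(path).name
    for suffix in (".gz", ".pdb", ".ent"):
        if structure_id.endswith(suffix):
            structure_id = structure_id[: -len(suffix)]

    raw_models: list[tuple[int, list[AtomRecord]]] = []
    current: list[AtomRecord] = []
    current_id = 1
    in_model_block = False
    seen_chains: set[str] = set()
    any_atom = False

    try:
        fh = _open_text(path)
    except OSError as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc

    with fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model_block and current:
                    raw_models.append((current_id, current))
                current = []
                in_model_block = True
                try:
                    current_id = int(line[10:14])
                except ValueError:
                    current_id = len(raw_models) + 1
            elif rec == "ENDMDL":
                raw_models.append((current_id, current))
                current = []
                in_model_block = False
            elif rec in ("ATOM", "HETATM"):
                any_atom = True
                atom = _parse_atom_line(line)
                seen_chains.add(atom.chain_id)
                if atom.res_name == "MSE":
                    atom.res_name = "MET"
                    if atom.atom_name == "SE":
                        atom.atom_name, atom.element = "SD", "S"
                    atom.record_type = "ATOM"
                elif rec == "HETATM" and not keep_het:
                    continue
                if atom.res_name in WATER_RESNAMES and not keep_het:
                    continue
                if chain is not None and atom.chain_id != chain:
                    continue
                if atom.is_hydrogen and not keep_hydrogens:
                    continue
                current.append(atom)
    if current:
        raw_models.append((current_id, current))

    if not any_atom:
        raise StructureError(f"{path}: no ATOM records found")
    if chain is not None and chain not in seen_chains:
        raise StructureError(f"{path}: requested chain {chain!r} absent (have {sorted(seen_chains)})")

    models = []
    for model_id, atoms in raw_models:
        atoms = _collapse_altlocs(atoms)
        if not atoms:
            raise StructureError(f"{path}: model {model_id} has zero atoms after filtering")
        models.append(StructureModel(structure_id=structure_id, model_id=model_id, atoms=atoms))
    if not models:
        raise StructureError(f"{path}: zero atoms after filtering")
    return models


def _format_atom_line(a: AtomRecord) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
    return (
        f"{a.record_type:<6}{a.serial:>5} {name}{a.alt_loc or ' ':1}"
        f"{a.res_name:<3} {a.chain_id or ' ':1}{a.res_num:>4}{a.insertion_code or ' ':1}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2}"
    )


def write_pdb(models: Sequence[StructureModel], path) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    multi = len(models) > 1
    with open(path, "wt") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL     {m.model_id:>4}\n")
            for a in m.atoms:
                fh.write(_format_atom_line(a) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def get_reference_atom(model: StructureModel, spec: RegionSpec) -> AtomRecord:
    """Resolve the distance-reference atom (default: catalytic lysine NZ)."""
    return spec.reference_atom.resolve(model)


def select_region(model: StructureModel, spec: RegionSpec) -> list[AtomRecord]:
    """All atoms within ``spec.radius`` (inclusive) of the region centre.

    Atoms are returned in input order.  An empty region triggers a warning
    and returns an empty list.
    """
    center = spec.resolve_center(model)
    out = []
    for a in model.atoms:
        if a.is_hydrogen and not spec.keep_hydrogens:
            continue
        if np.linalg.norm(a.coords - center) <= spec.radius:
            out.append(a)
    if not out:
        warnings.warn(
            f"{model.structure_id}: no atoms within {spec.radius} Å of region centre",
            stacklevel=2,
        )
    return out


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares proper rigid superposition of ``mobile`` onto ``target``.

    Returns the transform minimizing the RMSD over paired coordinates;
    reflections are rejected by sign-flipping the smallest singular
    direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must be paired (n, 3) arrays of equal shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points for superposition")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    P = mobile - cm
    Q = target - ct
    sv = np.linalg.svd(P, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinate set")

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    fitted = mobile @ R.T + t
    rmsd = rmsd_between(fitted, target)
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of paired coordinates, without re-fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 1:
        a = a[None, :]
        b = b[None, :]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def write_region_tsv(atoms: Sequence[AtomRecord], center: np.ndarray, path) -> None:
    """Region membership table: chain, res_num, res_name, atom_name, distance_A."""
    center = np.asarray(center, dtype=float)
    with open(path, "wt") as fh:
        fh.write("chain\tres_num\tres_name\tatom_name\tdistance_A\n")
        for a in atoms:
            d = float(np.linalg.norm(a.coords - center))
            fh.write(f"{a.chain_id}\t{a.res_num}{a.insertion_code}\t{a.res_name}\t{a.atom_name}\t{d:.3f}\n")
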