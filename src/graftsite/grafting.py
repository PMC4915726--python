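"""Variant design: mapping candidate sites onto a target enzyme and emitting
point substitutions (degenerate-codon sets), motif swaps, deletions, and
their residue-disjoint combinations.

Edits are bookkept in the ORIGINAL target numbering; renumbering happens
only when the mutated sequence is emitted.  Variant names follow the
"X{n}Y" / "Δ{X}{n}" grammar joined by "/".
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homolog_compare import Correspondence, ResidueId

__all__ = [
    "Edit",
    "VariantSpec",
    "SiteMapEntry",
    "SiteMap",
    "CodonExpansion",
    "GraftError",
    "map_sites",
    "expand_degenerate_codon",
    "design_point_variants",
    "design_motif_swap",
    "design_deletion",
    "combine_edits",
    "apply_edits",
    "write_variants_tsv",
    "NDT_AMINO_ACIDS",
]

logger = logging.getLogger(__name__)

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

def _standard_genetic_code() -> dict[str, str]:
    """Standard genetic code (NCBI table 1), stops encoded as '*'."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


GENETIC_CODE = _standard_genetic_code()


class GraftError(ValueError):
    """Raised for invalid edits or unmappable sites."""


@dataclass(frozen=True)
class Edit:
    """A single substitution or deletion at one target position."""

    kind: str  # "substitution" | "deletion"
    res_num: int
    from_aa: str
    to_aa: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion"):
            raise GraftError(f"unknown edit kind {self.kind!r}")
        if self.kind == "substitution":
            if not self.to_aa:
                raise GraftError("substitution needs a target amino acid")
            if self.to_aa == self.from_aa:
                raise GraftError(f"substitution at {self.res_num} does not change {self.from_aa}")
        elif self.to_aa is not None:
            raise GraftError("deletion carries no target amino acid")

    @property
    def name(self) -> str:
        if self.kind == "deletion":
            return f"Δ{self.from_aa}{self.res_num}"
        return f"{self.from_aa}{self.res_num}{self.to_aa}"

    @classmethod
    def substitution(cls, from_aa: str, res_num: int, to_aa: str) -> "Edit":
        return cls("substitution", res_num, from_aa, to_aa)

    @classmethod
    def deletion(cls, from_aa: str, res_num: int) -> "Edit":
        return cls("deletion", res_num, from_aa)


@dataclass(frozen=True)
class VariantSpec:
    """A named, ordered, residue-disjoint list of edits."""

    name: str
    edits: tuple[Edit, ...]

    def __post_init__(self) -> None:
        nums = [e.res_num for e in self.edits]
        if len(set(nums)) != len(nums):
            dup = next(n for n in nums if nums.count(n) > 1)
            raise GraftError(f"variant {self.name!r}: two edits at residue {dup}")
        object.__setattr__(self, "edits", tuple(sorted(self.edits, key=lambda e: e.res_num)))

    @classmethod
    def from_edits(cls, edits: Iterable[Edit], name: str | None = None) -> "VariantSpec":
        edits = tuple(sorted(edits, key=lambda e: e.res_num))
        if name is None:
            name = "/".join(e.name for e in edits)
        return cls(name=name, edits=edits)


@dataclass(frozen=True)
class SiteMapEntry:
    label: str  # source pair label, e.g. "V154/T161"
    chain_id: str
    res_num: int
    wt_aa: str


@dataclass
class SiteMap:
    entries: list[SiteMapEntry]
    provenance: str = ""

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _check_wt(target_seq: str, res_num: int, expected: str, context: str) -> None:
    if not 1 <= res_num <= len(target_seq):
        raise GraftError(f"{context}: position {res_num} outside sequence of length {len(target_seq)}")
    actual = target_seq[res_num - 1]
    if actual != expected:
        raise GraftError(
            f"{context}: wild-type mismatch at {res_num}: sequence has {actual!r}, edit expects {expected!r}"
        )


def map_sites(
    candidates: Sequence[tuple[str, ResidueId]],
    corr_target: Correspondence,
    target_seq: str,
    expected_wt: Mapping[ResidueId, str] | None = None,
) -> SiteMap:
    """Map candidate sites onto the target via a source→target correspondence.

    ``candidates`` are (label, source residue id) pairs.  The wild-type amino
    acid of every mapped target position is read off ``target_seq``; if
    ``expected_wt`` provides an expectation for a source site, a mismatch is
    an error naming position and letters.
    """
    entries = []
    for label, source_id in candidates:
        target_id = corr_target.target_of(source_id)
        if target_id is None:
            raise GraftError(f"candidate {label} ({source_id}) has no partner in the target correspondence")
        _, chain, res_num = target_id
        if not 1 <= res_num <= len(target_seq):
            raise GraftError(f"candidate {label}: target position {res_num} outside sequence")
        wt = target_seq[res_num - 1]
        if expected_wt is not None and source_id in expected_wt:
            exp = expected_wt[source_id]
            if wt != exp:
                raise GraftError(
                    f"candidate {label}: wild-type mismatch at target {res_num}: "
                    f"sequence has {wt!r}, expected {exp!r}"
                )
        entries.append(SiteMapEntry(label=label, chain_id=chain, res_num=res_num, wt_aa=wt))
    return SiteMap(entries=entries, provenance=corr_target.method)


@dataclass(frozen=True)
class CodonExpansion:
    degenerate: str
    codons: tuple[str, ...]
    amino_acids: frozenset[str]
    stops: int


def expand_degenerate_codon(codon: str) -> CodonExpansion:
    """Enumerate and translate all codons matched by a 3-letter IUPAC pattern.

    Stops are counted but excluded from the amino-acid set.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise GraftError(f"degenerate codon must have 3 letters, got {codon!r}")
    for c in codon:
        if c not in IUPAC_NT:
            raise GraftError(f"invalid IUPAC nucleotide code {c!r} in {codon!r}")
    codons = tuple(
        "".join(p) for p in itertools.product(*(IUPAC_NT[c] for c in codon))
    )
    translated = [GENETIC_CODE[c] for c in codons]
    stops = sum(1 for t in translated if t == "*")
    aas = frozenset(t for t in translated if t != "*")
    return CodonExpansion(degenerate=codon, codons=codons, amino_acids=aas, stops=stops)


NDT_AMINO_ACIDS = expand_degenerate_codon("NDT").amino_acids


def design_point_variants(
    site: SiteMapEntry,
    aa_set: Iterable[str],
    exclusions: Iterable[str] = (),
) -> list[VariantSpec]:
    """One single-substitution variant per amino acid in the set.

    The wild type is always removed; ``exclusions`` may be bare letters
    ("N") or full variant names scoped to this site ("L20N").
    """
    excluded_letters = set()
    for x in exclusions:
        x = x.strip()
        if len(x) == 1:
            excluded_letters.add(x.upper())
        elif x.upper() == f"{site.wt_aa}{site.res_num}{x[-1]}".upper():
            excluded_letters.add(x[-1].upper())
    targets = sorted(set(a.upper() for a in aa_set) - {site.wt_aa} - excluded_letters)
    if not targets:
        warnings.warn(f"site {site.wt_aa}{site.res_num}: no variants after exclusions", stacklevel=2)
        return []
    return [
        VariantSpec.from_edits([Edit.substitution(site.wt_aa, site.res_num, aa)])
        for aa in targets
    ]


def design_motif_swap(name: str, edits: Sequence[Edit], target_seq: str) -> VariantSpec:
    """A named multi-substitution variant (e.g. a β-strand chimera)."""
    for e in edits:
        _check_wt(target_seq, e.res_num, e.from_aa, f"motif swap {name!r}")
    return VariantSpec.from_edits(edits, name=name)


def design_deletion(target_seq: str, res_nums: Sequence[int], name: str | None = None) -> VariantSpec:
    """A deletion variant removing the given (original-numbering) positions."""
    edits = []
    for n in res_nums:
        if not 1 <= n <= len(target_seq):
            raise GraftError(f"deletion: position {n} outside sequence of length {len(target_seq)}")
        edits.append(Edit.deletion(target_seq[n - 1], n))
    return VariantSpec.from_edits(edits, name=name)


def combine_edits(variants: Sequence[VariantSpec], arity: int = 2) -> list[VariantSpec]:
    """All arity-wise unions of variants whose edit sets are residue-disjoint.

    Conflicting combinations (two edits at the same residue) are dropped and
    reported at debug level.  Combined names join the component names with
    "/" in input order.
    """
    if arity < 2:
        raise GraftError("arity must be >= 2")
    out = []
    for combo in itertools.combinations(variants, arity):
        nums: list[int] = []
        for v in combo:
            nums.extend(e.res_num for e in v.edits)
        if len(set(nums)) != len(nums):
            logger.debug("dropped conflicting combination: %s", "/".join(v.name for v in combo))
            continue
        name = "/".join(v.name for v in combo)
        edits = [e for v in combo for e in v.edits]
        out.append(VariantSpec.from_edits(edits, name=name))
    return out


def apply_edits(spec: VariantSpec, target_seq: str) -> str:
    """Apply a variant to the target sequence.

    Substitutions are applied in place; deleted positions are removed and
    the emitted sequence is implicitly renumbered contiguously.  Edit
    positions always refer to the ORIGINAL numbering.
    """
    chars = list(target_seq)
    deleted: list[int] = []
    for e in spec.edits:
        _check_wt(target_seq, e.res_num, e.from_aa, f"variant {spec.name!r}")
        if e.kind == "substitution":
            chars[e.res_num - 1] = e.to_aa
        else:
            deleted.append(e.res_num - 1)
    for i in sorted(deleted, reverse=True):
        del chars[i]
    return "".join(chars)


def write_variants_tsv(variants: Sequence[VariantSpec], target_seq: str, path) -> None:
    with open(path, "wt") as fh:
        fh.write("name\tedits\tn_edits\tmutated_sequence\n")
        for v in variants:
            edits = ";".join(e.name for e in v.edits)
            fh.write(f"{v.name}\t{edits}\t{len(v.edits)}\t{apply_edits(v, target_seq)}\n")
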