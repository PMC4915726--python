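"""Cross-homolog comparison: residue correspondence, divergence calls,
and conservation (sequence-logo information content) filtering.

Residues of two homologs are paired by mutual-nearest-neighbour Cα matching
after structural superposition.  Paired residue-level distance profiles are
screened for divergent sites (large mean-distance difference relative to the
pooled spread), knowledge-based exclusions are applied explicitly, and the
surviving candidates are filtered by per-column information content in the
two family alignments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .active_site_profile import ResidueProfile, ResidueStat
from .structures import StructureModel, Superposition

__all__ = [
    "ResidueId",
    "Correspondence",
    "CompareConfig",
    "DivergenceRecord",
    "ColumnStats",
    "build_correspondence",
    "divergence_table",
    "column_stats",
    "information_content",
    "conserved_divergent_sites",
    "read_alignment_fasta",
    "write_logo_matrix_tsv",
    "write_divergence_tsv",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")
MAX_IC_BITS = math.log2(20)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def one_letter(res_name: str) -> str:
    return _THREE_TO_ONE.get(res_name.upper(), "X")


ResidueId = tuple[str, str, int]  # (structure_id, chain_id, res_num)


@dataclass
class Correspondence:
    """One-to-one residue pairing between two homologs."""

    pairs: list[tuple[ResidueId, ResidueId]]
    method: str = "structural"
    labels: dict[tuple[ResidueId, ResidueId], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_a: set[ResidueId] = set()
        seen_b: set[ResidueId] = set()
        for a, b in self.pairs:
            if a in seen_a or b in seen_b:
                raise ValueError(f"correspondence is not one-to-one at pair {a} / {b}")
            seen_a.add(a)
            seen_b.add(b)

    def __len__(self) -> int:
        return len(self.pairs)

    def target_of(self, a: ResidueId) -> ResidueId | None:
        for pa, pb in self.pairs:
            if pa == a:
                return pb
        return None


def build_correspondence(
    model_a: StructureModel,
    model_b: StructureModel,
    seed_superposition: Superposition,
    cutoff: float = 2.5,
) -> Correspondence:
    """Pair residues by mutual-nearest-neighbour Cα matching.

    ``seed_superposition`` maps A coordinates into B's frame; Cα atoms closer
    than ``cutoff`` Å that are each other's nearest neighbours are paired.
    """
    ca_a = model_a.ca_atoms()
    ca_b = model_b.ca_atoms()
    if not ca_a or not ca_b:
        raise ValueError("both models need Cα atoms for structural correspondence")
    xa = seed_superposition.apply(np.array([a.coords for a in ca_a]))
    xb = np.array([b.coords for b in ca_b])

    tree_a = cKDTree(xa)
    tree_b = cKDTree(xb)
    d_ab, j_ab = tree_b.query(xa)  # for each A atom: nearest B
    d_ba, j_ba = tree_a.query(xb)  # for each B atom: nearest A

    pairs = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if d <= cutoff and j_ba[j] == i:
            a, b = ca_a[i], ca_b[int(j)]
            pairs.append(
                ((model_a.structure_id, a.chain_id, a.res_num),
                 (model_b.structure_id, b.chain_id, b.res_num))
            )
    if not pairs:
        raise ValueError(f"no residue pairs within {cutoff} Å after superposition")
    return Correspondence(pairs=pairs, method="structural")


@dataclass
class CompareConfig:
    """Divergence-call thresholds and explicit mechanistic exclusions.

    ``exclusions`` maps (chain_id, res_num) — matched against either side of
    a pair — to a human-readable reason.  Exclusions are always explicit
    user input, never inferred.
    """

    score_threshold: float = 2.0
    min_delta: float = 1.0
    exclusions: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score_threshold <= 0 or self.min_delta <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class DivergenceRecord:
    pair: tuple[ResidueId, ResidueId]
    label: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    delta: float
    pooled_sd: float
    score: float
    candidate: bool
    excluded_reason: str | None = None


def _pair_label(ea: ResidueStat, eb: ResidueStat) -> str:
    return f"{one_letter(ea.res_name)}{ea.res_num}/{one_letter(eb.res_name)}{eb.res_num}"


def divergence_table(
    profile_a: ResidueProfile,
    profile_b: ResidueProfile,
    corr: Correspondence,
    cfg: CompareConfig | None = None,
) -> list[DivergenceRecord]:
    """One divergence record per corresponding residue pair.

    delta = |mean_A − mean_B|, pooled SD = sqrt(sd_A² + sd_B²),
    score = delta / pooled SD (infinite when the pooled SD vanishes but the
    means differ).  A pair is a candidate when score ≥ threshold AND
    delta ≥ min_delta AND it is not excluded.
    """
    cfg = cfg or CompareConfig()
    records = []
    for (sid_a, chain_a, num_a), (sid_b, chain_b, num_b) in corr.pairs:
        ea = profile_a.lookup(chain_a, num_a)
        eb = profile_b.lookup(chain_b, num_b)
        if ea is None or eb is None:
            missing = f"{chain_a}:{num_a}" if ea is None else f"{chain_b}:{num_b}"
            warnings.warn(f"pair skipped: residue {missing} absent from profile", stacklevel=2)
            continue
        delta = abs(ea.mean - eb.mean)
        pooled = math.sqrt(ea.sd**2 + eb.sd**2)
        if pooled > 0:
            score = delta / pooled
        else:
            score = math.inf if delta > 0 else 0.0
        reason = cfg.exclusions.get((chain_a, num_a)) or cfg.exclusions.get((chain_b, num_b))
        candidate = (
            reason is None and score >= cfg.score_threshold and delta >= cfg.min_delta
        )
        records.append(
            DivergenceRecord(
                pair=((sid_a, chain_a, num_a), (sid_b, chain_b, num_b)),
                label=_pair_label(ea, eb),
                mean_a=ea.mean,
                sd_a=ea.sd,
                mean_b=eb.mean,
                sd_b=eb.sd,
                delta=delta,
                pooled_sd=pooled,
                score=score,
                candidate=candidate,
                excluded_reason=reason,
            )
        )
    if not records:
        raise ValueError("empty intersection: no correspondence pair found in both profiles")
    return records


# ---------------------------------------------------------------------------
# Conservation (sequence-logo) statistics
# ---------------------------------------------------------------------------

@dataclass
class ColumnStats:
    """Per-column logo statistics of a protein alignment.

    ``information_content`` is log2(20) − H in bits; ``heights`` are the
    letter heights f_a · IC; columns that are entirely gaps are flagged and
    carry NaN statistics; columns over 50 % gap are flagged unreliable.
    """

    index: int  # 1-based column index
    counts: dict[str, int]
    frequencies: dict[str, float]
    entropy: float
    information_content: float
    heights: dict[str, float]
    gap_fraction: float
    n_sequences: int
    all_gap: bool = False
    unreliable: bool = False


def column_stats(
    sequences: Sequence[str],
    small_sample_correction: bool = False,
) -> list[ColumnStats]:
    """Frequencies, Shannon entropy and information content per column.

    Gaps are excluded from frequency normalization.  By default no
    small-sample correction is applied; with ``small_sample_correction`` the
    standard e(n) = 19 / (2·ln2·n) term is subtracted from the IC.
    """
    if not sequences:
        raise ValueError("empty alignment")
    length = len(sequences[0])
    for i, s in enumerate(sequences):
        if len(s) != length:
            raise ValueError(f"ragged alignment: sequence {i} has length {len(s)} != {length}")

    out = []
    n_total = len(sequences)
    for col in range(length):
        counts: dict[str, int] = {}
        gaps = 0
        for s in sequences:
            c = s[col].upper()
            if c in GAP_CHARS:
                gaps += 1
                continue
            if c not in AA_ALPHABET:
                raise ValueError(f"invalid alignment symbol {c!r} at column {col + 1}")
            counts[c] = counts.get(c, 0) + 1
        n_res = n_total - gaps
        gap_fraction = gaps / n_total
        if n_res == 0:
            out.append(
                ColumnStats(
                    index=col + 1,
                    counts={},
                    frequencies={},
                    entropy=math.nan,
                    information_content=math.nan,
                    heights={},
                    gap_fraction=1.0,
                    n_sequences=n_total,
                    all_gap=True,
                    unreliable=True,
                )
            )
            continue
        freqs = {a: c / n_res for a, c in counts.items()}
        H = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        ic = MAX_IC_BITS - H
        if small_sample_correction:
            ic -= (len(AA_ALPHABET) - 1) / (2 * math.log(2) * n_res)
            ic = max(ic, 0.0)
        heights = {a: f * ic for a, f in freqs.items()}
        out.append(
            ColumnStats(
                index=col + 1,
                counts=counts,
                frequencies=freqs,
                entropy=H,
                information_content=ic,
                heights=heights,
                gap_fraction=gap_fraction,
                n_sequences=n_total,
                all_gap=False,
                unreliable=gap_fraction > 0.5,
            )
        )
    return out


def information_content(stats: ColumnStats) -> float:
    """IC accessor with the bound check 0 ≤ IC ≤ log2(20)."""
    if stats.all_gap:
        raise ValueError(f"column {stats.index}: all-gap, IC undefined")
    ic = stats.information_content
    if not (-1e-9 <= ic <= MAX_IC_BITS + 1e-9):
        raise ValueError(f"column {stats.index}: IC {ic} outside [0, log2 20]")
    return ic


def conserved_divergent_sites(
    records: Sequence[DivergenceRecord],
    stats_a: Sequence[ColumnStats],
    stats_b: Sequence[ColumnStats],
    column_map_a: Mapping[tuple[str, int], int],
    column_map_b: Mapping[tuple[str, int], int],
    ic_min: float = 3.0,
) -> list[DivergenceRecord]:
    """Retain candidates whose alignment columns are conserved in BOTH families.

    ``column_map_*`` take (chain_id, res_num) to a 1-based alignment column.
    An unmapped candidate residue is an error.
    """
    kept = []
    for rec in records:
        if not rec.candidate:
            continue
        (_, chain_a, num_a), (_, chain_b, num_b) = rec.pair
        try:
            col_a = column_map_a[(chain_a, num_a)]
        except KeyError:
            raise KeyError(f"candidate {rec.label}: residue {chain_a}:{num_a} unmapped in family A")
        try:
            col_b = column_map_b[(chain_b, num_b)]
        except KeyError:
            raise KeyError(f"candidate {rec.label}: residue {chain_b}:{num_b} unmapped in family B")
        ic_a = information_content(stats_a[col_a - 1])
        ic_b = information_content(stats_b[col_b - 1])
        if ic_a >= ic_min and ic_b >= ic_min:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment_fasta(path) -> list[str]:
    """Aligned FASTA → list of sequences (ragged alignments rejected later)."""
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    return seqs


def write_logo_matrix_tsv(stats: Sequence[ColumnStats], path) -> None:
    """Letter-height matrix (column, aa, height) for external logo renderers."""
    with open(path, "wt") as fh:
        fh.write("column\taa\theight\n")
        for s in stats:
            for aa in sorted(s.heights):
                fh.write(f"{s.index}\t{aa}\t{s.heights[aa]:.6f}\n")


def write_divergence_tsv(records: Sequence[DivergenceRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "pair\tmean_A\tsd_A\tmean_B\tsd_B\tdelta\tscore\tcandidate\texcluded_reason\n"
        )
        for r in records:
            fh.write(
                f"{r.label}\t{r.mean_a:.4f}\t{r.sd_a:.4f}\t{r.mean_b:.4f}\t{r.sd_b:.4f}\t"
                f"{r.delta:.4f}\t{r.score:.4f}\t{int(r.candidate)}\t{r.excluded_reason or ''}\n"
            )
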