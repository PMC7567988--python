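"""Reference-dataset curation: structural filters and eligibility rules.

Builds the two labeled sets the classifier trains on.  The monomorphic
side keeps a "parent" structure only when every deposited close homolog
("child", >= 50% sequence similarity) superposes onto it within 2.4 Å RMSD
and never disagrees in secondary structure by more than a windowed
mismatch score of 9 — structures whose relatives reveal an alternative
fold are exactly what the monomorphic set must exclude.  The metamorphic
side drops entries too short to classify or whose fold-switching region
hugs a terminus.  All filters consume locally supplied, pre-aligned
records so that alignment settings can never silently change a decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StructurePairRecord",
    "StructureMetadata",
    "MetamorphicCandidate",
    "CurationDecision",
    "ListEditLedger",
    "DEFAULT_KEYWORDS",
    "ss_mismatch_score",
    "pairwise_rmsd",
    "monomorphic_metadata_filter",
    "monomorphic_structure_filter",
    "keyword_screen",
    "metamorphic_eligibility",
    "apply_list_edits",
    "align_ss_pair",
    "read_ca_coordinates",
]

_SS_ALPHABET = frozenset("HEC-")

# per-column substitution cost between aligned three-state SS strings;
# gaps cost 0 (the summation runs over aligned residues only)
_MISMATCH_COST = {
    frozenset(("H", "E")): 2,
    frozenset(("C", "H")): 1,
    frozenset(("C", "E")): 1,
}

DEFAULT_KEYWORDS = (
    "fold switching",
    "fold-switching",
    "fold switch",
    "metamorphic",
    "metamorphism",
    "two folds",
    "two distinct folds",
    "alternative fold",
    "alternate fold",
    "chameleon",
)


@dataclass
class StructurePairRecord:
    """One aligned parent–child structure pair.

    ``aligned_ss_a``/``aligned_ss_b`` are equal-length three-state strings
    (with '-' for gaps) from a sequence alignment; ``ca_a``/``ca_b`` are
    equal-length Cα coordinate arrays (Å) at mutually aligned non-gap
    positions.
    """

    parent_id: str
    child_id: str
    aligned_ss_a: str
    aligned_ss_b: str
    ca_a: np.ndarray
    ca_b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.aligned_ss_a) != len(self.aligned_ss_b):
            raise ValueError(
                f"{self.parent_id}/{self.child_id}: aligned SS strings differ in length"
            )
        self.ca_a = np.asarray(self.ca_a, dtype=float)
        self.ca_b = np.asarray(self.ca_b, dtype=float)
        if self.ca_a.shape != self.ca_b.shape or self.ca_a.ndim != 2 or self.ca_a.shape[1] != 3:
            raise ValueError(
                f"{self.parent_id}/{self.child_id}: coordinate arrays must be matching (N, 3)"
            )
        if not (np.all(np.isfinite(self.ca_a)) and np.all(np.isfinite(self.ca_b))):
            raise ValueError(f"{self.parent_id}/{self.child_id}: coordinates must be finite")


@dataclass
class StructureMetadata:
    """Deposition metadata consumed by the monomorphic pre-filter."""

    structure_id: str
    deposition_age_years: float
    resolution_angstrom: Optional[float]  # None for non-X-ray entries (NMR etc.)
    n_children_50pct: int
    sequence_length: int
    abstract_text: str = ""


@dataclass
class MetamorphicCandidate:
    """A candidate entry for the metamorphic reference set."""

    structure_id: str
    sequence_length: int
    switch_region_start: Optional[int] = None
    switch_region_end: Optional[int] = None

    def __post_init__(self) -> None:
        s, e = self.switch_region_start, self.switch_region_end
        if (s is None) != (e is None):
            raise ValueError(f"{self.structure_id}: switch region needs both bounds")
        if s is not None and not (1 <= s <= e <= self.sequence_length):
            raise ValueError(
                f"{self.structure_id}: switch region {s}-{e} outside 1..{self.sequence_length}"
            )


@dataclass(frozen=True)
class CurationDecision:
    """Keep/drop outcome with the single primary reason for a drop."""

    keep: bool
    reason: Optional[str] = None
    detail: Optional[str] = None

    def __bool__(self) -> bool:
        return self.keep


def ss_mismatch_score(aligned_ss_a: str, aligned_ss_b: str, window: int = 30) -> int:
    """Windowed secondary-structure mismatch score between aligned strings.

    Per aligned column: H vs E costs 2, C vs H or C vs E costs 1,
    identical states cost 0, and any gapped column costs 0.  The score is
    the maximum cost sum over all contiguous windows of ``window``
    alignment columns; alignments shorter than the window are scored over
    their full length.
    """
    if len(aligned_ss_a) != len(aligned_ss_b):
        raise ValueError(
            f"aligned strings differ in length: {len(aligned_ss_a)} vs {len(aligned_ss_b)}"
        )
    if window < 1:
        raise ValueError("window must be >= 1")
    costs = np.zeros(len(aligned_ss_a), dtype=int)
    for i, (x, y) in enumerate(zip(aligned_ss_a, aligned_ss_b)):
        if x not in _SS_ALPHABET or y not in _SS_ALPHABET:
            bad = x if x not in _SS_ALPHABET else y
            raise ValueError(f"invalid secondary-structure character {bad!r} at column {i + 1}")
        if x == "-" or y == "-":
            continue
        costs[i] = _MISMATCH_COST.get(frozenset((x, y)), 0)
    if costs.size == 0:
        return 0
    if costs.size <= window:
        return int(costs.sum())
    csum = np.concatenate(([0], np.cumsum(costs)))
    return int((csum[window:] - csum[:-window]).max())


def pairwise_rmsd(ca_a: np.ndarray, ca_b: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid-body (Kabsch) superposition.

    Both coordinate sets are centered and the rotation minimizing the
    residual sum of squares is found by the Kabsch/least-squares method;
    the result is invariant under rigid motions of either set.

    Raises
    ------
    ValueError
        For fewer than 3 points or a degenerate (collinear) configuration,
        where the optimal rotation is not unique.
    """
    A = np.asarray(ca_a, dtype=float)
    B = np.asarray(ca_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate arrays must be matching (N, 3), got {A.shape} / {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    for name, M in (("first", Ac), ("second", Bc)):
        sv = np.linalg.svd(M, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise ValueError(f"{name} coordinate set is degenerate (collinear points)")
    rotation, _ = Rotation.align_vectors(Ac, Bc)
    # recompute the residual explicitly: scipy's reported rssd loses
    # precision to cancellation when the sets are near-congruent
    diff = Ac - rotation.apply(Bc)
    return float(math.sqrt(np.einsum("ij,ij->", diff, diff) / n))


def monomorphic_metadata_filter(
    meta: StructureMetadata,
    min_age_years: float = 10,
    max_resolution: float = 2.2,
    min_children: int = 30,
    min_len: int = 40,
    max_len: int = 250,
) -> CurationDecision:
    """Metadata gate for monomorphic parents.

    Keeps a structure iff it was deposited at least ``min_age_years`` ago,
    is not an X-ray structure worse than ``max_resolution`` Å (non-X-ray
    entries pass the resolution gate), has more than ``min_children``
    deposited structures at >= 50% sequence similarity, and has a sequence
    length strictly between ``min_len`` and ``max_len``.  The drop reason
    names the first failing criterion.
    """
    if meta.deposition_age_years < min_age_years:
        return CurationDecision(
            False, "age", f"deposited {meta.deposition_age_years:g} y ago, need >= {min_age_years}"
        )
    if meta.resolution_angstrom is not None and meta.resolution_angstrom > max_resolution:
        return CurationDecision(
            False, "resolution",
            f"X-ray resolution {meta.resolution_angstrom:g} Å > {max_resolution} Å",
        )
    if meta.n_children_50pct <= min_children:
        return CurationDecision(
            False, "children",
            f"{meta.n_children_50pct} structures at >=50% similarity, need > {min_children}",
        )
    if not (min_len < meta.sequence_length < max_len):
        return CurationDecision(
            False, "length",
            f"sequence length {meta.sequence_length} outside ({min_len}, {max_len})",
        )
    return CurationDecision(True)


def monomorphic_structure_filter(
    pairs: Sequence[StructurePairRecord],
    rmsd_max: float = 2.4,
    ss_max: int = 9,
    ss_window: int = 30,
) -> CurationDecision:
    """Structural gate for one monomorphic parent and all its pairs.

    The parent is dropped as soon as any pair exceeds ``rmsd_max`` Å RMSD
    after superposition or scores above ``ss_max`` on the windowed
    secondary-structure mismatch (both strictly); the decision reports the
    first offending pair and the rule that fired.
    """
    if not pairs:
        raise ValueError("structure filter needs at least one pair")
    for pair in pairs:
        rmsd = pairwise_rmsd(pair.ca_a, pair.ca_b)
        if rmsd > rmsd_max:
            return CurationDecision(
                False, "rmsd",
                f"{pair.parent_id}/{pair.child_id}: RMSD {rmsd:.2f} Å > {rmsd_max} Å",
            )
        score = ss_mismatch_score(pair.aligned_ss_a, pair.aligned_ss_b, ss_window)
        if score > ss_max:
            return CurationDecision(
                False, "ss_mismatch",
                f"{pair.parent_id}/{pair.child_id}: SS mismatch {score} > {ss_max}",
            )
    return CurationDecision(True)


def keyword_screen(
    abstract_text: str, keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> Tuple[bool, List[str]]:
    """Case-insensitive substring screen of an abstract for fold-switching
    vocabulary.  Returns (flagged, matched terms)."""
    text = abstract_text.lower()
    matched = [kw for kw in keywords if kw.lower() in text]
    return bool(matched), matched


def metamorphic_eligibility(
    cand: MetamorphicCandidate,
    min_len: int = 40,
    terminal_margin: int = 20,
) -> CurationDecision:
    """Eligibility of a metamorphic candidate for the reference set.

    Drops sequences shorter than ``min_len`` residues (too short for the
    windowed classifier once termini are trimmed) and entries whose
    annotated fold-switching region lies entirely within
    ``terminal_margin`` residues of either terminus.
    """
    if cand.sequence_length < min_len:
        return CurationDecision(
            False, "length",
            f"sequence length {cand.sequence_length} < {min_len}",
        )
    if cand.switch_region_start is not None:
        if cand.switch_region_end <= terminal_margin:
            return CurationDecision(
                False, "terminal_region",
                f"switch region {cand.switch_region_start}-{cand.switch_region_end} "
                f"within {terminal_margin} residues of the N-terminus",
            )
        if cand.switch_region_start > cand.sequence_length - terminal_margin:
            return CurationDecision(
                False, "terminal_region",
                f"switch region {cand.switch_region_start}-{cand.switch_region_end} "
                f"within {terminal_margin} residues of the C-terminus",
            )
    return CurationDecision(True)


@dataclass
class ListEditLedger:
    """Audit trail of removals/additions applied to a base listing."""

    base_count: int
    final_count: int
    rows: List[Dict[str, str]] = field(default_factory=list)


def apply_list_edits(
    base_count: int,
    removals: Sequence[Tuple[str, str]],
    additions: Sequence[Tuple[str, str]],
) -> ListEditLedger:
    """Apply audited removals and additions to a base entry count.

    ``removals`` and ``additions`` are ``(identifier, reason)`` pairs; the
    final count is ``base - len(removals) + len(additions)`` and every
    edit is recorded in the ledger.  A duplicate identifier anywhere in
    the edits is an error.
    """
    if base_count < 0:
        raise ValueError("base_count must be >= 0")
    ids = [ident for ident, _ in removals] + [ident for ident, _ in additions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate identifiers in list edits: {dupes}")
    final = base_count - len(removals) + len(additions)
    if final < 0:
        raise ValueError(f"edits remove more entries than exist (final count {final})")
    rows = [
        {"action": "remove", "identifier": ident, "reason": reason}
        for ident, reason in removals
    ] + [
        {"action": "add", "identifier": ident, "reason": reason}
        for ident, reason in additions
    ]
    return ListEditLedger(base_count=base_count, final_count=final, rows=rows)


def align_ss_pair(
    seq_a: str, seq_b: str, ss_a: str, ss_b: str
) -> Tuple[str, str]:
    """Globally align two sequences and project their SS strings.

    Alignment uses BLOSUM62 with gap open -10 / extend -0.5.  Returns the
    two aligned three-state strings with '-' in gapped columns, ready for
    :func:`ss_mismatch_score`.  Provided as a convenience; the curation
    filters themselves accept pre-aligned inputs.
    """
    if len(seq_a) != len(ss_a) or len(seq_b) != len(ss_b):
        raise ValueError("each SS string must match its sequence in length")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    out_a, out_b = [], []
    a_pos = b_pos = 0
    aligned_a, aligned_b = alignment[0], alignment[1]
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            out_a.append("-")
        else:
            out_a.append(ss_a[a_pos])
            a_pos += 1
        if cb == "-":
            out_b.append("-")
        else:
            out_b.append(ss_b[b_pos])
            b_pos += 1
    return "".join(out_a), "".join(out_b)


def read_ca_coordinates(
    path: Union[str, Path], chain: Optional[str] = None
) -> np.ndarray:
    """Extract Cα coordinates (Å) from a PDB or mmCIF file.

    Reads the first model; restricts to ``chain`` when given, otherwise
    the first chain containing Cα atoms.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    model = structure[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        coords = [
            [atom.pos.x, atom.pos.y, atom.pos.z]
            for residue in ch
            for atom in residue
            if atom.name == "CA"
        ]
        if coords:
            return np.asarray(coords, dtype=float)
    raise ValueError(f"{path}: no Cα atoms found" + (f" in chain {chain}" if chain else ""))
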