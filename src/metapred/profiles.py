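"""Per-residue three-state secondary-structure probability profiles.

Secondary-structure prediction (SSP) programs emit, for every residue of a
query sequence, a probability for each of the three reduced DSSP states:
helix (H), strand (E) and coil (C).  This module reads those outputs
(PSIPRED ``.ss2`` files and the package's own normalized TSV dialect),
validates them, and renormalizes each row onto the probability simplex so
that downstream diversity-index calculations see rows that sum exactly to
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence, Union

import numpy as np

__all__ = [
    "ProfileError",
    "ProfileParseError",
    "SSProbRow",
    "SSProfile",
    "read_profile",
    "write_profile",
    "reduce_dssp_8to3",
    "PROFILE_FORMATS",
]

#: tolerated deviation of a raw row sum from 1 before the row is rejected
ROW_SUM_TOLERANCE = 0.05

PROFILE_FORMATS = ("psipred_ss2", "normalized_tsv")

# standard reduction of the eight DSSP states to three
_DSSP_8TO3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C",
}


class ProfileError(ValueError):
    """A profile violates a structural or probabilistic invariant."""


class ProfileParseError(ProfileError):
    """A profile file could not be parsed."""


@dataclass(frozen=True)
class SSProbRow:
    """One residue's three-state probability distribution.

    Attributes
    ----------
    position : int
        1-based residue index.
    residue : str
        One-letter amino-acid code ('X' when unknown).
    p_h, p_e, p_c : float
        Probabilities of helix, strand and coil; non-negative and summing
        to one after ingest normalization.
    """

    position: int
    residue: str
    p_h: float
    p_e: float
    p_c: float


@dataclass
class SSProfile:
    """An ordered per-residue probability profile for one sequence.

    ``probs`` is an (L, 3) array with columns (H, E, C); residue ``i``
    (1-based position ``i + 1``) lives in row ``i``.  Positions are always
    the contiguous range 1..L.
    """

    identifier: str
    residues: List[str]
    probs: np.ndarray
    source_program: str = "unknown"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ProfileError(
                f"{self.identifier}: probability array must be (L, 3), "
                f"got {self.probs.shape}"
            )
        L = self.probs.shape[0]
        if L < 1:
            raise ProfileError(f"{self.identifier}: profile must have at least one row")
        if len(self.residues) != L:
            raise ProfileError(
                f"{self.identifier}: {len(self.residues)} residues for {L} probability rows"
            )
        if np.any(self.probs < -1e-12) or not np.all(np.isfinite(self.probs)):
            raise ProfileError(f"{self.identifier}: probabilities must be finite and >= 0")
        sums = self.probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ProfileError(
                f"{self.identifier}: row {bad[0] + 1} sums to {sums[bad[0]]:.6f}, "
                "expected 1 (renormalize on ingest)"
            )

    def __len__(self) -> int:
        return self.probs.shape[0]

    def __iter__(self) -> Iterator[SSProbRow]:
        return iter(self.rows)

    @property
    def rows(self) -> List[SSProbRow]:
        return [
            SSProbRow(i + 1, aa, float(h), float(e), float(c))
            for i, (aa, (h, e, c)) in enumerate(zip(self.residues, self.probs))
        ]


def _normalize_rows(
    raw: np.ndarray, identifier: str, line_numbers: Sequence[int]
) -> np.ndarray:
    """Divide each row by its own sum, rejecting rows too far off the simplex."""
    sums = raw.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOLERANCE)[0]
    if bad.size:
        i = int(bad[0])
        raise ProfileError(
            f"{identifier}: line {line_numbers[i]}: probabilities sum to "
            f"{sums[i]:.4f}, outside [{1 - ROW_SUM_TOLERANCE}, {1 + ROW_SUM_TOLERANCE}]"
        )
    return raw / sums[:, None]


def _parse_psipred_ss2(lines: List[str], identifier: str):
    """PSIPRED VFORMAT: index, residue, state letter, P(C), P(H), P(E)."""
    positions, residues, raw, line_numbers = [], [], [], []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 6:
            raise ProfileParseError(
                f"{identifier}: line {lineno}: expected 6 columns, got {len(fields)}"
            )
        try:
            pos = int(fields[0])
            p_c, p_h, p_e = (float(fields[i]) for i in (3, 4, 5))
        except ValueError as exc:
            raise ProfileParseError(f"{identifier}: line {lineno}: {exc}") from exc
        positions.append(pos)
        residues.append(fields[1])
        raw.append((p_h, p_e, p_c))
        line_numbers.append(lineno)
    return positions, residues, raw, line_numbers


def _parse_normalized_tsv(lines: List[str], identifier: str):
    """Header ``# id=<identifier> source=<program>`` then
    ``position  residue  p_h  p_e  p_c`` rows."""
    positions, residues, raw, line_numbers = [], [], [], []
    parsed_id, parsed_source = identifier, None
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            for token in stripped.lstrip("#").split():
                if token.startswith("id="):
                    parsed_id = token[3:]
                elif token.startswith("source="):
                    parsed_source = token[7:]
            continue
        fields = stripped.split()
        if len(fields) != 5:
            raise ProfileParseError(
                f"{identifier}: line {lineno}: expected 5 columns "
                f"(position residue p_h p_e p_c), got {len(fields)}"
            )
        try:
            pos = int(fields[0])
            p_h, p_e, p_c = (float(f) for f in fields[2:5])
        except ValueError as exc:
            raise ProfileParseError(f"{identifier}: line {lineno}: {exc}") from exc
        positions.append(pos)
        residues.append(fields[1])
        raw.append((p_h, p_e, p_c))
        line_numbers.append(lineno)
    return positions, residues, raw, line_numbers, parsed_id, parsed_source


def read_profile(
    path: Union[str, Path],
    format: str,
    identifier: str | None = None,
) -> SSProfile:
    """Read an SSP probability profile and renormalize rows onto the simplex.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"psipred_ss2", "normalized_tsv"}
        File dialect.
    identifier : str, optional
        Sequence identifier; defaults to the file stem (``normalized_tsv``
        headers override it).

    Raises
    ------
    ProfileParseError
        On malformed lines (the message names the line number).
    ProfileError
        When a row's probability sum falls outside ``1 ± 0.05``, when
        positions are not contiguous 1..L, or when the file is empty.
    """
    path = Path(path)
    ident = identifier or path.stem
    lines = path.read_text().splitlines()

    source = None
    if format == "psipred_ss2":
        positions, residues, raw, line_numbers = _parse_psipred_ss2(lines, ident)
        source = "psipred"
    elif format == "normalized_tsv":
        positions, residues, raw, line_numbers, ident, source = _parse_normalized_tsv(
            lines, ident
        )
    else:
        raise ValueError(f"unknown profile format {format!r}; expected one of {PROFILE_FORMATS}")

    if not raw:
        raise ProfileError(f"{ident}: {path}: no data rows")
    if positions != list(range(1, len(positions) + 1)):
        raise ProfileError(f"{ident}: residue positions must be contiguous 1..L")

    probs = _normalize_rows(np.asarray(raw, dtype=float), ident, line_numbers)
    return SSProfile(
        identifier=ident,
        residues=residues,
        probs=probs,
        source_program=source or "unknown",
    )


def write_profile(profile: SSProfile, path: Union[str, Path]) -> None:
    """Write a profile in the normalized TSV dialect (round-trips to 1e-6)."""
    path = Path(path)
    out = [f"# id={profile.identifier} source={profile.source_program}"]
    for row in profile.rows:
        out.append(
            f"{row.position}\t{row.residue}\t{row.p_h:.6f}\t{row.p_e:.6f}\t{row.p_c:.6f}"
        )
    path.write_text("\n".join(out) + "\n")


def reduce_dssp_8to3(ss8: str) -> str:
    """Reduce an eight-state DSSP string to the three-state H/E/C alphabet.

    H, G, I (helices) map to H; E, B (strands) map to E; everything else
    (turn, bend, coil, blank) maps to C.  Idempotent on strings already in
    {H, E, C}.
    """
    out = []
    for i, ch in enumerate(ss8):
        mapped = _DSSP_8TO3.get(ch)
        if mapped is None:
            raise ValueError(
                f"unknown secondary-structure state {ch!r} at position {i + 1}"
            )
        out.append(mapped)
    return "".join(out)
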