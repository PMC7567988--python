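"""Synthetic labeled profiles and toy curation inputs.

The generator emulates the qualitative signature the classifier relies
on: a monomorphic sequence yields confidently predicted secondary
structure (per-residue diversity index near 1) with occasional single-row
jumps at element boundaries that a moving average smooths out, while a
metamorphic sequence additionally carries one contiguous segment of
elevated prediction uncertainty.  It also builds toy structure clusters —
a fold-switching-like cluster whose members disagree wildly in both
geometry and secondary structure, and a single-fold-like cluster whose
members are near-congruent — for exercising the curation filters.

Everything is deterministic given the spec's seed; no external programs
or databases are touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .curation import StructurePairRecord
from .evaluation import LabeledDataset
from .classifier import METAMORPHIC, MONOMORPHIC
from .profiles import SSProfile

__all__ = [
    "FixtureSpec",
    "generate_dataset",
    "generate_curation_cluster",
    "simplex_point_for_di",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# residues kept clear at each end when placing the uncertain segment, so
# the segment survives the classifier's default terminal trimming
_SEGMENT_MARGIN = 5


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic labeled dataset.

    Attributes
    ----------
    n_metamorphic, n_monomorphic : int
        Class sizes.
    length_range : (int, int)
        Inclusive bounds on sequence length, residues.
    mono_confidence : float
        Probability assigned to the dominant state in a confident row
        (0.95 mimics a well-determined prediction).
    meta_segment_length : int
        Length of the contiguous high-uncertainty segment in metamorphic
        sequences.
    meta_segment_di : float
        Target mean diversity index of that segment, in (1, 3].
    noise_scale : float
        Dirichlet concentration for row-level jitter around each target
        distribution; 0 disables jitter.
    boundary_jump_prob : float
        Probability, at each secondary-structure element boundary, of one
        row splitting its probability between the flanking states — the
        single-row DI spikes that make the moving average (not the raw
        DI) the discriminator.
    seed : int
        Seed for all randomness.
    """

    n_metamorphic: int = 50
    n_monomorphic: int = 50
    length_range: Tuple[int, int] = (60, 120)
    mono_confidence: float = 0.95
    meta_segment_length: int = 20
    meta_segment_di: float = 2.8
    noise_scale: float = 300.0
    boundary_jump_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metamorphic < 0 or self.n_monomorphic < 0:
            raise ValueError("class sizes must be >= 0")
        if self.meta_segment_length < 1:
            raise ValueError("meta_segment_length must be >= 1")
        if not 1.0 < self.meta_segment_di <= 3.0:
            raise ValueError("meta_segment_di must be in (1, 3]")
        if not 1 / 3 <= self.mono_confidence <= 1.0:
            raise ValueError("mono_confidence must be in [1/3, 1]")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.noise_scale < 0 or not 0 <= self.boundary_jump_prob <= 1:
            raise ValueError("noise_scale >= 0 and boundary_jump_prob in [0, 1] required")


def simplex_point_for_di(d: float) -> np.ndarray:
    """The (H, E, C) distribution of the form (p, q, q) whose diversity
    index equals ``d``.

    On the path from a pure state (1, 0, 0) to the uniform distribution,
    points have the form (p, (1-p)/2, (1-p)/2); solving
    ``1 / (p^2 + (1-p)^2 / 2) = d`` gives the closed form
    ``p = (1 + sqrt(6/d - 2)) / 3``, which covers the full DI range
    (1, 3].
    """
    if not 1.0 <= d <= 3.0:
        raise ValueError(f"target DI must be in [1, 3], got {d}")
    p = (1.0 + math.sqrt(6.0 / d - 2.0)) / 3.0
    q = (1.0 - p) / 2.0
    return np.array([p, q, q])


def _confident_row(state: int, confidence: float) -> np.ndarray:
    row = np.full(3, (1.0 - confidence) / 2.0)
    row[state] = confidence
    return row


def _jitter(rng: np.random.Generator, target: np.ndarray, kappa: float) -> np.ndarray:
    if kappa <= 0:
        return target.copy()
    alpha = np.maximum(kappa * target, 1e-8)
    return rng.dirichlet(alpha)


def _background_rows(
    rng: np.random.Generator, length: int, spec: FixtureSpec
) -> np.ndarray:
    """Confident rows in runs of one dominant state, with optional
    single-row boundary splits between consecutive elements."""
    rows = np.empty((length, 3))
    pos = 0
    prev_state = None
    while pos < length:
        state = int(rng.integers(3))
        if state == prev_state:
            state = (state + 1 + int(rng.integers(2))) % 3
        run = int(rng.integers(4, 13))
        if prev_state is not None and rng.random() < spec.boundary_jump_prob:
            # boundary residue: the predictor splits mass between elements
            target = (_confident_row(prev_state, spec.mono_confidence)
                      + _confident_row(state, spec.mono_confidence)) / 2.0
            rows[pos] = _jitter(rng, target, spec.noise_scale)
            pos += 1
        for _ in range(min(run, length - pos)):
            rows[pos] = _jitter(rng, _confident_row(state, spec.mono_confidence),
                                spec.noise_scale)
            pos += 1
        prev_state = state
    return rows


def _make_profile(
    rng: np.random.Generator, identifier: str, spec: FixtureSpec, metamorphic: bool
) -> SSProfile:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    if metamorphic and spec.meta_segment_length + 2 * _SEGMENT_MARGIN > lo:
        raise ValueError(
            f"meta_segment_length {spec.meta_segment_length} plus {_SEGMENT_MARGIN}-residue "
            f"margins does not fit the minimum sequence length {lo}"
        )
    rows = _background_rows(rng, length, spec)
    if metamorphic:
        start = int(rng.integers(_SEGMENT_MARGIN, length - spec.meta_segment_length - _SEGMENT_MARGIN + 1))
        target = simplex_point_for_di(spec.meta_segment_di)
        perm = rng.permutation(3)  # which state carries the residual confidence
        for i in range(start, start + spec.meta_segment_length):
            rows[i] = _jitter(rng, target[perm], spec.noise_scale)
    residues = rng.choice(_AMINO_ACIDS, size=length).tolist()
    return SSProfile(
        identifier=identifier,
        residues=residues,
        probs=rows / rows.sum(axis=1, keepdims=True),
        source_program="synthetic",
    )


def generate_dataset(spec: FixtureSpec) -> LabeledDataset:
    """Generate a labeled dataset of synthetic profiles.

    Deterministic for a fixed spec (including its seed): two calls with
    the same spec return identical probabilities, residues and
    identifiers.
    """
    rng = np.random.default_rng(spec.seed)
    entries = []
    for i in range(spec.n_metamorphic):
        ident = f"meta_{i:03d}"
        entries.append((ident, _make_profile(rng, ident, spec, metamorphic=True), METAMORPHIC))
    for i in range(spec.n_monomorphic):
        ident = f"mono_{i:03d}"
        entries.append((ident, _make_profile(rng, ident, spec, metamorphic=False), MONOMORPHIC))
    return LabeledDataset(entries)


def _helix_curve(n: int) -> np.ndarray:
    """Idealized α-helical Cα trace: 2.3 Å radius, 1.5 Å rise, 100°/residue."""
    t = np.arange(n)
    angle = np.deg2rad(100.0) * t
    return np.column_stack([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * t])


def _extended_curve(n: int) -> np.ndarray:
    """Extended (β-strand-like) Cα trace: 3.5 Å rise with a small zigzag."""
    t = np.arange(n)
    return np.column_stack([3.5 * t, 1.0 * (-1.0) ** t, np.zeros(n)])


def _rigid_motion(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return coords @ R.T + t


def generate_curation_cluster(kind: str, seed: int = 0) -> List[StructurePairRecord]:
    """Generate all pairs of a toy parent/children structure cluster.

    ``kind="monomorphic_like"`` (a 1AB9-style single-fold family): every
    member is a small perturbation of one fold under a random rigid
    motion, so all pairwise RMSDs stay below 2.4 Å and SS mismatch scores
    stay at or below 9.

    ``kind="kaib_like"`` (a fold-switching family): the cluster mixes two
    conformers — a helical fold and an extended fold over the same
    region — so at least one pair shows an SS mismatch of 23 or more and
    an RMSD above 7 Å.
    """
    rng = np.random.default_rng(seed)
    n = 60
    ss_helical = "CC" + "H" * 40 + "C" * (n - 42)
    if kind == "monomorphic_like":
        base = _helix_curve(n)
        ss_variants = [ss_helical,
                       "CCC" + "H" * 39 + "C" * (n - 42),  # one boundary shifted: cost 1
                       ss_helical]
        members = []
        for i in range(4):
            coords = base + rng.normal(scale=0.25, size=base.shape)
            members.append((f"mono_parent" if i == 0 else f"mono_child_{i}",
                            _rigid_motion(rng, coords),
                            ss_variants[i % len(ss_variants)]))
    elif kind == "kaib_like":
        helical = _helix_curve(n)
        extended = _extended_curve(n)
        ss_switched = "CC" + "H" * 20 + "E" * 20 + "C" * (n - 42)
        members = [
            ("switch_parent", _rigid_motion(rng, helical + rng.normal(scale=0.25, size=helical.shape)), ss_helical),
            ("switch_child_1", _rigid_motion(rng, helical + rng.normal(scale=0.25, size=helical.shape)), ss_helical),
            ("switch_child_2", _rigid_motion(rng, extended + rng.normal(scale=0.25, size=extended.shape)), ss_switched),
        ]
    else:
        raise ValueError(f"unknown cluster kind {kind!r}")

    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            id_a, ca_a, ss_a = members[i]
            id_b, ca_b, ss_b = members[j]
            pairs.append(
                StructurePairRecord(
                    parent_id=id_a, child_id=id_b,
                    aligned_ss_a=ss_a, aligned_ss_b=ss_b,
                    ca_a=ca_a, ca_b=ca_b,
                )
            )
    return pairs
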