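"""Diversity-index classifier for metamorphic versus monomorphic sequences.

The diversity index (DI) of one residue is the reciprocal Simpson /
Herfindahl concentration of its predicted three-state secondary-structure
distribution::

    DI = 1 / (P(H)^2 + P(E)^2 + P(C)^2)

It ranges from 1 (one state has all the probability: the predictor is
certain) to 3 (uniform over H/E/C: maximal uncertainty), and coincides with
the exponentiated Shannon entropy at those two extremes.  Metamorphic
(fold-switching) proteins tend to confuse secondary-structure predictors
over a contiguous stretch of sequence, so the classifier thresholds the
maximum moving average of the DI over windows of ``cr`` consecutive
residues: a sequence is called metamorphic when that maximum strictly
exceeds ``di_thre``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np

from .profiles import SSProfile

__all__ = [
    "METAMORPHIC",
    "MONOMORPHIC",
    "ClassifierParams",
    "DITrace",
    "SequenceTooShortError",
    "ClassificationResult",
    "diversity_index",
    "di_trace",
    "max_moving_average",
    "classify",
]

METAMORPHIC = "metamorphic"
MONOMORPHIC = "monomorphic"

_SIMPLEX_ATOL = 1e-9


class SequenceTooShortError(ValueError):
    """The usable sequence is shorter than the averaging window."""


@dataclass(frozen=True)
class ClassifierParams:
    """Parameters of the windowed diversity-index classifier.

    Attributes
    ----------
    cr : int
        Window length: the number of consecutive residues averaged.
    di_thre : float
        Decision threshold on the maximum windowed mean DI, in [1, 3].
    terminal_exclude : int
        Residues ignored at each terminus before windowing (default 5);
        termini are noisy for secondary-structure predictors and are not
        informative about fold switching.
    """

    cr: int
    di_thre: float
    terminal_exclude: int = 5

    def __post_init__(self) -> None:
        if self.cr < 1:
            raise ValueError(f"cr must be >= 1, got {self.cr}")
        if not 1.0 <= self.di_thre <= 3.0:
            raise ValueError(f"di_thre must be in [1, 3], got {self.di_thre}")
        if self.terminal_exclude < 0:
            raise ValueError("terminal_exclude must be >= 0")


@dataclass
class DITrace:
    """Per-residue diversity-index values for one sequence."""

    identifier: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("DI trace must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.values.size


class ClassificationResult(NamedTuple):
    label: str
    window_max: float


def diversity_index(p_h: float, p_e: float, p_c: float) -> float:
    """Diversity index of one residue's (H, E, C) probability distribution.

    Returns ``1 / (p_h**2 + p_e**2 + p_c**2)``, in [1, 3].

    Raises
    ------
    ValueError
        If any probability is negative or the three do not sum to 1
        within 1e-9.
    """
    if p_h < 0 or p_e < 0 or p_c < 0:
        raise ValueError(f"probabilities must be non-negative, got ({p_h}, {p_e}, {p_c})")
    total = p_h + p_e + p_c
    if abs(total - 1.0) > _SIMPLEX_ATOL:
        raise ValueError(f"probabilities must sum to 1 (got {total!r})")
    return 1.0 / (p_h * p_h + p_e * p_e + p_c * p_c)


def di_trace(profile: SSProfile) -> DITrace:
    """Element-wise diversity index over a profile's rows."""
    concentration = np.einsum("ij,ij->i", profile.probs, profile.probs)
    return DITrace(identifier=profile.identifier, values=1.0 / concentration)


def max_moving_average(
    trace: Union[DITrace, Sequence[float], np.ndarray],
    cr: int,
    terminal_exclude: int = 0,
) -> float:
    """Maximum over all length-``cr`` windows of the mean diversity index.

    Windows must lie entirely within positions
    ``[terminal_exclude + 1, L - terminal_exclude]`` (1-based).

    Raises
    ------
    SequenceTooShortError
        When fewer than ``cr`` residues remain after terminal exclusion —
        the sequence is too short to classify at these parameters.
    """
    values = trace.values if isinstance(trace, DITrace) else np.asarray(trace, dtype=float)
    if cr < 1:
        raise ValueError(f"cr must be >= 1, got {cr}")
    if terminal_exclude < 0:
        raise ValueError("terminal_exclude must be >= 0")
    L = values.size
    usable = values[terminal_exclude : L - terminal_exclude] if terminal_exclude else values
    if cr > usable.size:
        raise SequenceTooShortError(
            f"window of {cr} residues does not fit: only {usable.size} residues "
            f"remain after excluding {terminal_exclude} at each terminus of a "
            f"{L}-residue sequence; supply a longer sequence"
        )
    # cumulative-sum window means: exact enough at DI scale (values in [1,3])
    csum = np.concatenate(([0.0], np.cumsum(usable)))
    window_means = (csum[cr:] - csum[:-cr]) / cr
    return float(window_means.max())


def classify(profile: SSProfile, params: ClassifierParams) -> ClassificationResult:
    """Classify one sequence as metamorphic or monomorphic.

    The call is metamorphic iff the maximum windowed mean DI strictly
    exceeds ``params.di_thre``; a window maximum exactly at the threshold
    is monomorphic.  Returns the label together with the achieved window
    maximum for reporting.
    """
    trace = di_trace(profile)
    window_max = max_moving_average(trace, params.cr, params.terminal_exclude)
    label = METAMORPHIC if window_max > params.di_thre else MONOMORPHIC
    return ClassificationResult(label=label, window_max=window_max)
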