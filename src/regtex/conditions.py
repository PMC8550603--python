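"""Experimental condition grid: element spacing x size x positional jitter.

The design crosses three element-spacing levels, three element-size levels
and five jitter-range levels into 45 texture conditions.  A single canonical
linear ordering of the conditions is used everywhere in the package:
jitter level varies slowest, then element size, then element spacing --
matching the block layout of the conjoint-proportions matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

N_SPACING = 3
N_SIZE = 3
N_JITTER = 5
N_CONDITIONS = N_SPACING * N_SIZE * N_JITTER


@dataclass(frozen=True, order=True)
class StimulusCondition:
    """One cell of the 3 (spacing) x 3 (size) x 5 (jitter) design."""

    spacing_level: int
    size_level: int
    jitter_level: int

    def __post_init__(self) -> None:
        if not 1 <= self.spacing_level <= N_SPACING:
            raise ValueError(f"spacing_level must be in 1..{N_SPACING}, "
                             f"got {self.spacing_level}")
        if not 1 <= self.size_level <= N_SIZE:
            raise ValueError(f"size_level must be in 1..{N_SIZE}, "
                             f"got {self.size_level}")
        if not 1 <= self.jitter_level <= N_JITTER:
            raise ValueError(f"jitter_level must be in 1..{N_JITTER}, "
                             f"got {self.jitter_level}")

    @property
    def index(self) -> int:
        """Canonical linear index (0-based): jitter-major, spacing innermost."""
        return ((self.jitter_level - 1) * N_SIZE * N_SPACING
                + (self.size_level - 1) * N_SPACING
                + (self.spacing_level - 1))

    @property
    def label(self) -> str:
        return f"sp{self.spacing_level}.sz{self.size_level}.jt{self.jitter_level}"


def condition_from_index(index: int) -> StimulusCondition:
    """Inverse of :attr:`StimulusCondition.index`."""
    if not 0 <= index < N_CONDITIONS:
        raise ValueError(f"condition index must be in 0..{N_CONDITIONS - 1}, "
                         f"got {index}")
    k, rest = divmod(index, N_SIZE * N_SPACING)
    j, i = divmod(rest, N_SPACING)
    return StimulusCondition(i + 1, j + 1, k + 1)


def all_conditions() -> list[StimulusCondition]:
    """The 45 conditions in canonical order."""
    return [condition_from_index(i) for i in range(N_CONDITIONS)]
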