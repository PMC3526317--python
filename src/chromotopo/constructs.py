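"""Geometry of the DNA constructs used across the assays.

The tethering template is a 5049-bp fragment carrying 24 tandem repeats of
a 177-bp segment containing the 601 nucleosome-positioning sequence —
built by ligating a 12-repeat insert into a vector already holding 12
repeats — flanked on one end by a biotin-labelled handle (~990 bp) and on
the other by a digoxigenin-labelled handle (~1.1 kb) for attachment to the
bead and the chamber surface.
"""

from __future__ import annotations

from dataclasses import dataclass

from .wlc import contour_from_bp

__all__ = [
    "TetherConstruct",
    "NUCLEOSOME_REPEAT_BP",
    "CORE_FRAGMENT_BP",
    "BIOTIN_HANDLE_BP",
    "DIG_HANDLE_BP",
]

#: Length of one 601-bearing repeat unit (bp).
NUCLEOSOME_REPEAT_BP = 177

#: The SpeI/ApaLI repeat-array fragment (bp).
CORE_FRAGMENT_BP = 5049

#: Biotin handle: half of a 1981-bp PCR product cut by XbaI (bp).
BIOTIN_HANDLE_BP = 990

#: Digoxigenin handle: ApaLI fragment of a 2254-bp PCR product (bp).
DIG_HANDLE_BP = 1100


@dataclass(frozen=True)
class TetherConstruct:
    """A bead-tethering DNA assembly: core repeat array plus two handles."""

    core_bp: int = CORE_FRAGMENT_BP
    biotin_handle_bp: int = BIOTIN_HANDLE_BP
    dig_handle_bp: int = DIG_HANDLE_BP
    repeats_per_insert: int = 12
    n_inserts: int = 2
    repeat_bp: int = NUCLEOSOME_REPEAT_BP

    @property
    def positioning_sites(self) -> int:
        """Number of 601 nucleosome-positioning sites on the template."""
        return self.repeats_per_insert * self.n_inserts

    @property
    def array_bp(self) -> int:
        """Length of the positioning-sequence array alone."""
        return self.positioning_sites * self.repeat_bp

    @property
    def total_bp(self) -> int:
        """Full tether length including both attachment handles."""
        return self.core_bp + self.biotin_handle_bp + self.dig_handle_bp

    @property
    def core_contour_nm(self) -> float:
        """B-form contour length of the bead-to-surface core fragment."""
        return contour_from_bp(self.core_bp)

    @property
    def total_kb(self) -> float:
        return self.total_bp / 1000.0
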