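"""Subunit identifiers.

Every high-molecular-weight glutenin subunit is identified by its locus
type (Ax, Bx, By, Dx or Dy) plus an allele label, e.g. ``Bx7OE`` or
``Dx2.2``.  The labels ``20x``/``20y`` disambiguate the Bx20/By20 pair
that shares the printed label "20".
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

LOCUS_TYPES = ("Ax", "Bx", "By", "Dx", "Dy")

#: x-type and y-type members of each Glu-1 locus.
LOCUS_OF_TYPE = {"Ax": "Glu-A1", "Bx": "Glu-B1", "By": "Glu-B1", "Dx": "Glu-D1", "Dy": "Glu-D1"}

#: The canonical allele labels per locus type (the 20 reference subunits).
CANONICAL_LABELS = {
    "Ax": ("1", "2*"),
    "Bx": ("6", "7", "7OE", "13", "17", "20x"),
    "By": ("8", "8*", "9", "16", "18", "20y"),
    "Dx": ("2", "2.2", "4", "5"),
    "Dy": ("10", "12"),
}


@dataclass(frozen=True, order=True)
class SubunitId:
    """A (locus type, allele label) pair, hashable and orderable."""

    locus_type: str
    label: str

    def __post_init__(self) -> None:
        if self.locus_type not in LOCUS_TYPES:
            raise ValidationError(f"unknown locus type {self.locus_type!r}")
        if not self.label:
            raise ValidationError("empty subunit label")

    @property
    def locus(self) -> str:
        return LOCUS_OF_TYPE[self.locus_type]

    def __str__(self) -> str:  # e.g. "1Bx7OE"
        return f"1{self.locus_type}{self.label}"


def subunit(locus_type: str, label: str) -> SubunitId:
    """Convenience constructor."""
    return SubunitId(locus_type, label)


#: All 20 subunits of the reference set, in elution-table order.
CANONICAL_SUBUNITS = tuple(
    SubunitId(t, lab) for t in LOCUS_TYPES for lab in CANONICAL_LABELS[t]
)
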