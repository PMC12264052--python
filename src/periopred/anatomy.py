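"""Tooth-level anatomy derived from FDI two-digit notation.

FDI notation encodes quadrant (first digit, 1-4 starting upper right and
proceeding clockwise when facing the patient) and position within the
quadrant (second digit, 1 central incisor .. 8 third molar).  Tooth type and
root count follow from position; the root-count table is configurable
because clinics differ in how they treat anatomic variants (e.g. two-rooted
lower canines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ToothAttributes",
    "InvalidFDIError",
    "parse_fdi",
    "ALL_FDI",
    "OCCLUDING_PAIRS",
    "DEFAULT_ROOT_COUNTS",
    "tooth_type_for_position",
]


class InvalidFDIError(ValueError):
    """Raised for tooth numbers outside permanent-dentition FDI notation."""


_POSITION_TYPES = {
    1: "incisor",
    2: "incisor",
    3: "canine",
    4: "premolar",
    5: "premolar",
    6: "molar",
    7: "molar",
    8: "molar",
}

#: Default root counts keyed by (arch, position). Upper molars have three
#: roots, upper first premolars two, lower molars two, everything else one.
DEFAULT_ROOT_COUNTS: Mapping[tuple[str, int], int] = {
    **{("upper", p): 1 for p in (1, 2, 3, 5)},
    ("upper", 4): 2,
    **{("upper", p): 3 for p in (6, 7, 8)},
    **{("lower", p): 1 for p in (1, 2, 3, 4, 5)},
    **{("lower", p): 2 for p in (6, 7, 8)},
}

#: Every valid permanent-dentition FDI number.
ALL_FDI: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)

#: The 14 standard maxillary-mandibular occluding pairs (third molars
#: excluded): same position, quadrant 1 opposes 4 and 2 opposes 3.
OCCLUDING_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (10 * upper + p, 10 * lower + p)
    for upper, lower in ((1, 4), (2, 3))
    for p in range(1, 8)
)


@dataclass(frozen=True)
class ToothAttributes:
    """Anatomy of one tooth as inferred from its FDI number."""

    fdi: int
    quadrant: int
    position: int
    tooth_type: str
    root_count: int
    furcation_capable: bool

    @property
    def arch(self) -> str:
        return "upper" if self.quadrant in (1, 2) else "lower"

    @property
    def is_third_molar(self) -> bool:
        return self.position == 8


def tooth_type_for_position(position: int) -> str:
    try:
        return _POSITION_TYPES[position]
    except KeyError:
        raise InvalidFDIError(f"no tooth type for position {position}") from None


def parse_fdi(
    fdi: int, root_counts: Mapping[tuple[str, int], int] | None = None
) -> ToothAttributes:
    """Resolve an FDI tooth number to quadrant, position, type and roots.

    Parameters
    ----------
    fdi
        Two-digit FDI tooth number (11-48).
    root_counts
        Optional override of :data:`DEFAULT_ROOT_COUNTS`, keyed by
        ``(arch, position)`` with arch in ``{"upper", "lower"}``.

    Raises
    ------
    InvalidFDIError
        If the quadrant digit is not 1-4 or the position digit not 1-8.
    """
    fdi = int(fdi)
    quadrant, position = divmod(fdi, 10)
    if quadrant not in (1, 2, 3, 4) or position not in range(1, 9):
        raise InvalidFDIError(f"{fdi} is not a valid FDI tooth number")
    arch = "upper" if quadrant in (1, 2) else "lower"
    counts = DEFAULT_ROOT_COUNTS if root_counts is None else root_counts
    roots = counts[(arch, position)]
    if roots < 1:
        raise ValueError(f"root count for {fdi} must be positive, got {roots}")
    return ToothAttributes(
        fdi=fdi,
        quadrant=quadrant,
        position=position,
        tooth_type=_POSITION_TYPES[position],
        root_count=roots,
        furcation_capable=roots > 1,
    )
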