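"""Parsing and classification of fatty-acid shorthand codes.

The shorthand grammar accepted here is ``C<carbons>:<double_bonds>`` with an
optional omega suffix ``n<int>`` (position of the first double bond from the
methyl terminus) and an optional geometry suffix ``c`` (cis) or ``t``
(trans), e.g. ``C16:0``, ``C20:5n3``, ``C18:1n9t``.  Double-bond position
lists, branched chains and hydroxy acids are out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import ShorthandParseError, UnsupportedPolyeneClassError

__all__ = [
    "FattyAcidDescriptor",
    "Geometry",
    "SaturationClass",
    "parse_shorthand",
    "format_shorthand",
    "saturation_class",
    "polyene_class",
    "OMEGA_CLASSES",
]

#: Omega positions that receive a named class tag; anything else parses but
#: is classified as unspecified (with a warning).
OMEGA_CLASSES = (3, 6, 9)

_CODE_RE = re.compile(
    r"""^C
        (?P<carbons>\d+)
        :
        (?P<double_bonds>\d+)
        (?:n(?P<omega>\d+))?
        (?P<geometry>[ct])?
        $""",
    re.VERBOSE,
)


class Geometry(str, Enum):
    """Double-bond geometry as encoded by the shorthand suffix."""

    CIS = "cis"
    TRANS = "trans"
    UNSPECIFIED = "unspecified"


class SaturationClass(str, Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Structured identity of one fatty acid.

    Parameters
    ----------
    carbons : int
        Chain length; must be >= 2.
    double_bonds : int
        Number of double bonds; 0 for saturated acids.
    omega : int or None
        Position of the first double bond from the methyl end (the ``n<int>``
        suffix), or None when the code carries no omega tag.
    geometry : Geometry
        cis/trans/unspecified, from the ``c``/``t`` suffix.
    common_name : str or None
        Opaque free-text label; never interpreted structurally.
    """

    carbons: int
    double_bonds: int
    omega: Optional[int] = None
    geometry: Geometry = Geometry.UNSPECIFIED
    common_name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"chain length must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.double_bonds} double bonds not representable on a "
                f"C{self.carbons} chain"
            )
        if self.double_bonds == 0:
            if self.omega is not None:
                raise ValueError("saturated acid cannot carry an omega tag")
            if self.geometry is not Geometry.UNSPECIFIED:
                raise ValueError("saturated acid cannot carry a geometry tag")

    @property
    def code(self) -> str:
        """Canonical shorthand code regenerated from the fields."""
        return format_shorthand(self)

    @property
    def omega_class(self) -> Optional[str]:
        """``"n3"``/``"n6"``/``"n9"`` or None for untagged/uncommon positions."""
        if self.omega in OMEGA_CLASSES:
            return f"n{self.omega}"
        return None


def format_shorthand(d: FattyAcidDescriptor) -> str:
    """Render a descriptor back to its canonical shorthand code."""
    out = f"C{d.carbons}:{d.double_bonds}"
    if d.omega is not None:
        out += f"n{d.omega}"
    if d.geometry is Geometry.CIS:
        out += "c"
    elif d.geometry is Geometry.TRANS:
        out += "t"
    return out


def parse_shorthand(code: str, common_name: Optional[str] = None) -> FattyAcidDescriptor:
    """Parse one shorthand code into a :class:`FattyAcidDescriptor`.

    Whitespace around the code is tolerated.  Raises
    :class:`~lipidqi.errors.ShorthandParseError` on malformed input, naming
    the offending token.
    """
    raw = code
    code = code.strip()
    if not code.startswith("C"):
        raise ShorthandParseError(raw, code[:1] or "", "expected leading 'C'")
    m = _CODE_RE.match(code)
    if m is None:
        if ":" not in code:
            raise ShorthandParseError(raw, code, "missing ':' separator")
        head, _, tail = code.partition(":")
        bad = head[1:] if not head[1:].isdigit() else tail
        raise ShorthandParseError(raw, bad, "non-numeric or malformed count")
    carbons = int(m.group("carbons"))
    double_bonds = int(m.group("double_bonds"))
    omega = int(m.group("omega")) if m.group("omega") else None
    geometry = {
        "c": Geometry.CIS,
        "t": Geometry.TRANS,
        None: Geometry.UNSPECIFIED,
    }[m.group("geometry")]
    if double_bonds > (carbons - 2) // 2:
        raise ShorthandParseError(
            raw,
            f"{double_bonds}",
            f"{double_bonds} double bonds exceed what a C{carbons} chain can hold",
        )
    if double_bonds == 0 and (omega is not None or geometry is not Geometry.UNSPECIFIED):
        token = f"n{omega}" if omega is not None else m.group("geometry")
        raise ShorthandParseError(raw, token, "saturated code cannot carry omega/geometry suffixes")
    if omega is not None and omega not in OMEGA_CLASSES:
        warnings.warn(
            f"omega position n{omega} in {code!r} has no named class; "
            "treated as unspecified in n-3/n-6 sums",
            stacklevel=2,
        )
    return FattyAcidDescriptor(
        carbons=carbons,
        double_bonds=double_bonds,
        omega=omega,
        geometry=geometry,
        common_name=common_name,
    )


def saturation_class(d: FattyAcidDescriptor) -> SaturationClass:
    """SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
    if d.double_bonds == 0:
        return SaturationClass.SFA
    if d.double_bonds == 1:
        return SaturationClass.MUFA
    return SaturationClass.PUFA


def polyene_class(d: FattyAcidDescriptor) -> Optional[int]:
    """Polyene class 1..6 (monoenoic..hexaenoic) or None for saturated acids.

    Acids with more than six double bonds fall outside the unsaturation-index
    term list and raise :class:`UnsupportedPolyeneClassError`.
    """
    if d.double_bonds == 0:
        return None
    if d.double_bonds > 6:
        raise UnsupportedPolyeneClassError(
            f"{d.code}: {d.double_bonds} double bonds exceed the hexaenoic class"
        )
    return d.double_bonds
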