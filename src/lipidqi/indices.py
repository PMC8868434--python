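"""The eight fatty-acid nutritional quality indices.

All indices are computed from :class:`~lipidqi.profile.GroupSums`:

* ``ps``       PUFA/SFA ratio
* ``ia``       index of atherogenicity, [C12:0 + 4*C14:0 + C16:0] / UFA
* ``it``       index of thrombogenicity,
               (C14:0 + C16:0 + C18:0) /
               [0.5*MUFA + 0.5*n6 + 3*n3 + n3/n6]
* ``h_over_h`` hypo/hypercholesterolemic ratio,
               (cis-C18:1 + PUFA) / (C12:0 + C14:0 + C16:0)
* ``hpi``      health-promoting index — the reciprocal of ``ia``
* ``ui``       unsaturation index, sum over classes k=1..6 of k * (% class k)
* ``sed``      EPA + DHA (C20:5n3 + C22:6n3), in %
* ``tfa``      total explicitly-trans fatty acids, in %

Single-index functions raise :class:`UndefinedIndexError` when a
denominator is zero; :func:`compute_all` instead flags the affected index
as undefined so batch runs survive degenerate samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import UndefinedIndexError
from .profile import FattyAcidProfile, GroupSums, aggregate

__all__ = [
    "IndexReport",
    "ps",
    "ia",
    "it",
    "h_over_h",
    "hpi",
    "ui",
    "sed",
    "tfa",
    "compute_all",
    "INDEX_NAMES",
]

INDEX_NAMES = ("ps", "ia", "it", "h_over_h", "hpi", "ui", "sed", "tfa")


def ps(g: GroupSums) -> float:
    """PUFA-to-SFA ratio."""
    if g.sfa <= 0:
        raise UndefinedIndexError("ps", "SFA sum is zero")
    return g.pufa / g.sfa


def ia(g: GroupSums) -> float:
    """Index of atherogenicity."""
    if g.ufa <= 0:
        raise UndefinedIndexError("ia", "unsaturated-FA sum is zero")
    return (g.named["C12:0"] + 4.0 * g.named["C14:0"] + g.named["C16:0"]) / g.ufa


def it(g: GroupSums) -> float:
    """Index of thrombogenicity.

    The trailing denominator term is the ratio n-3/n-6 of the omega sums.
    """
    if g.n6 <= 0:
        raise UndefinedIndexError("it", "omega-6 PUFA sum is zero")
    denom = 0.5 * g.mufa + 0.5 * g.n6 + 3.0 * g.n3 + g.n3 / g.n6
    if denom <= 0:
        raise UndefinedIndexError("it", "denominator is zero")
    return (g.named["C14:0"] + g.named["C16:0"] + g.named["C18:0"]) / denom


def h_over_h(g: GroupSums) -> float:
    """Hypocholesterolemic-to-hypercholesterolemic ratio.

    cis-C18:1 means the explicitly-cis isomer (oleic) only.
    """
    denom = g.named["C12:0"] + g.named["C14:0"] + g.named["C16:0"]
    if denom <= 0:
        raise UndefinedIndexError("h_over_h", "C12:0 + C14:0 + C16:0 is zero")
    return (g.cis_c18_1 + g.pufa) / denom


def hpi(g: GroupSums) -> float:
    """Health-promoting index, the algebraic reciprocal of :func:`ia`."""
    denom = g.named["C12:0"] + 4.0 * g.named["C14:0"] + g.named["C16:0"]
    if denom <= 0:
        raise UndefinedIndexError("hpi", "C12:0 + 4*C14:0 + C16:0 is zero")
    return g.ufa / denom


def ui(g: GroupSums) -> float:
    """Unsaturation index: sum of (double-bond count) x (% of class)."""
    return sum(k * g.polyene.get(k, 0.0) for k in range(1, 7))


def sed(g: GroupSums) -> float:
    """EPA + DHA, in percent of total FA."""
    return g.named["C20:5n3"] + g.named["C22:6n3"]


def tfa(g: GroupSums) -> float:
    """Total trans fatty acids (explicitly-trans codes only), in percent."""
    return g.tfa


_INDEX_FUNCS = {
    "ps": ps,
    "ia": ia,
    "it": it,
    "h_over_h": h_over_h,
    "hpi": hpi,
    "ui": ui,
    "sed": sed,
    "tfa": tfa,
}


@dataclass(frozen=True)
class IndexReport:
    """All eight index values for one sample.

    An index whose denominator vanished is None and listed in ``undefined``.
    """

    sample_id: str
    ps: Optional[float]
    ia: Optional[float]
    it: Optional[float]
    h_over_h: Optional[float]
    hpi: Optional[float]
    ui: Optional[float]
    sed: Optional[float]
    tfa: Optional[float]
    undefined: tuple[str, ...] = ()

    def values(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_NAMES}

    def rounded(self, precision: int = 2) -> dict:
        """Round-half-even display values; None stays None."""
        return {
            name: (None if v is None else round(v, precision))
            for name, v in self.values().items()
        }


def compute_all(profile: FattyAcidProfile) -> IndexReport:
    """Aggregate a profile and evaluate all eight indices.

    Never raises for degenerate compositions: any index with a zero
    denominator comes back as None with its name in ``undefined``.
    """
    g = aggregate(profile)
    values: dict[str, Optional[float]] = {}
    undefined: list[str] = []
    for name, func in _INDEX_FUNCS.items():
        try:
            values[name] = func(g)
        except UndefinedIndexError:
            values[name] = None
            undefined.append(name)
    return IndexReport(sample_id=profile.sample_id, undefined=tuple(undefined), **values)
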