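"""Fatty-acid composition profiles and the aggregate sums the nutritional
index equations consume.

A profile is one sample's list of (descriptor, percentage-of-total-FA)
entries.  "N.D." (not detected) entries are kept with percentage 0 and a
flag; they contribute exactly 0 to every aggregate.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import DuplicateCodeError, ProfileLoadError, ShorthandParseError
from .nomenclature import (
    FattyAcidDescriptor,
    Geometry,
    SaturationClass,
    parse_shorthand,
    polyene_class,
    saturation_class,
)

__all__ = [
    "ProfileEntry",
    "FattyAcidProfile",
    "GroupSums",
    "read_profile_csv",
    "write_profile_csv",
    "aggregate",
    "NAMED_CODES",
]

#: Codes exposed by name in :class:`GroupSums` because the index equations
#: reference them individually.
NAMED_CODES = ("C12:0", "C14:0", "C16:0", "C18:0", "C20:5n3", "C22:6n3")

#: Column totals outside this band record a warning (printed tables sum to
#: roughly but not exactly 100).
_TOTAL_BAND = (95.0, 105.0)


@dataclass(frozen=True)
class ProfileEntry:
    descriptor: FattyAcidDescriptor
    percentage: float
    sd: Optional[float] = None
    nd: bool = False  # "not detected": percentage forced to 0

    def __post_init__(self) -> None:
        if self.percentage < 0:
            raise ValueError(f"{self.descriptor.code}: negative percentage")
        if self.nd and self.percentage != 0:
            raise ValueError(f"{self.descriptor.code}: N.D. entry must have percentage 0")


@dataclass(frozen=True)
class FattyAcidProfile:
    """One sample's fatty-acid composition (percent of total FA)."""

    sample_id: str
    entries: tuple[ProfileEntry, ...]
    lipid_content: Optional[float] = None  # % of dry weight

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            code = e.descriptor.code
            if code in seen:
                raise DuplicateCodeError(f"duplicate fatty-acid code {code!r} in {self.sample_id!r}")
            seen.add(code)
        total = self.total_percentage
        if self.entries and not (_TOTAL_BAND[0] <= total <= _TOTAL_BAND[1]):
            warnings.warn(
                f"profile {self.sample_id!r}: percentages sum to {total:.2f}, "
                f"outside [{_TOTAL_BAND[0]:g}, {_TOTAL_BAND[1]:g}]",
                stacklevel=2,
            )

    @property
    def total_percentage(self) -> float:
        return math.fsum(e.percentage for e in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GroupSums:
    """Every aggregate quantity the index equations consume, in % of total FA.

    ``ufa`` always equals ``mufa + pufa``; trans isomers are counted inside
    ``mufa``/``pufa`` (and hence ``ufa``).  ``n3``/``n6`` sum only PUFAs
    (>= 2 double bonds) carrying the matching omega tag.  ``cis_c18_1`` is
    the explicitly-cis C18:1 total (oleic acid); the trans isomer is
    excluded.  ``named`` maps each code in :data:`NAMED_CODES` to its
    percentage (0 when absent); ``polyene`` maps double-bond class 1..6 to
    the summed percentage of that class.
    """

    sfa: float
    mufa: float
    pufa: float
    n3: float
    n6: float
    tfa: float
    cis_c18_1: float
    named: Mapping[str, float] = field(default_factory=dict)
    polyene: Mapping[int, float] = field(default_factory=dict)

    @property
    def ufa(self) -> float:
        return self.mufa + self.pufa

    @property
    def total(self) -> float:
        return self.sfa + self.mufa + self.pufa

    def to_dict(self) -> dict:
        return {
            "sfa": self.sfa,
            "mufa": self.mufa,
            "pufa": self.pufa,
            "ufa": self.ufa,
            "n3": self.n3,
            "n6": self.n6,
            "tfa": self.tfa,
            "cis_c18_1": self.cis_c18_1,
            "named": dict(self.named),
            "polyene": {str(k): v for k, v in sorted(self.polyene.items())},
        }


def aggregate(profile: FattyAcidProfile) -> GroupSums:
    """Compute all group sums for one profile.

    Absent fatty acids contribute zero; no error is possible for a valid
    profile.  Aggregation is independent of entry order.
    """
    # buckets of addends, reduced with math.fsum so that the sums are
    # exactly rounded and therefore independent of entry order
    buckets: dict = {
        "sfa": [], "mufa": [], "pufa": [], "n3": [], "n6": [],
        "tfa": [], "cis_c18_1": [],
    }
    named: dict[str, list[float]] = {c: [] for c in NAMED_CODES}
    polyene: dict[int, list[float]] = {k: [] for k in range(1, 7)}

    for entry in profile:
        d = entry.descriptor
        pct = entry.percentage
        cls = saturation_class(d)
        buckets[cls.value.lower()].append(pct)
        if cls is SaturationClass.PUFA:
            if d.omega == 3:
                buckets["n3"].append(pct)
            elif d.omega == 6:
                buckets["n6"].append(pct)
        if d.geometry is Geometry.TRANS:
            buckets["tfa"].append(pct)
        if d.carbons == 18 and d.double_bonds == 1 and d.geometry is Geometry.CIS:
            buckets["cis_c18_1"].append(pct)
        code = d.code
        if code in named:
            named[code].append(pct)
        k = polyene_class(d)
        if k is not None:
            polyene[k].append(pct)

    return GroupSums(
        named={c: math.fsum(v) for c, v in named.items()},
        polyene={k: math.fsum(v) for k, v in polyene.items()},
        **{name: math.fsum(v) for name, v in buckets.items()},
    )


def _parse_percentage(raw: str) -> tuple[float, bool]:
    """Return (percentage, nd_flag) for one CSV percentage cell."""
    raw = raw.strip()
    if raw == "" or raw.upper() in {"N.D.", "ND", "N.D"}:
        return 0.0, True
    return float(raw), False


def read_profile_csv(
    path: Union[str, Path, io.TextIOBase],
    sample_id: Optional[str] = None,
    value_column: str = "percentage",
    sd_column: Optional[str] = "sd",
    lipid_content: Optional[float] = None,
) -> FattyAcidProfile:
    """Load a profile from CSV with header ``name,code,percentage[,sd]``.

    ``value_column``/``sd_column`` let a wide multi-sample table be read one
    sample column at a time.  The literal ``N.D.`` (or an empty cell) marks
    a not-detected entry, stored with percentage 0 and ``nd=True``.

    Raises :class:`~lipidqi.errors.ProfileLoadError` (with the 1-based data
    row number) on malformed codes, negative percentages or duplicates.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        name = sample_id or "sample"
        close = False
    else:
        p = Path(path)
        handle = p.open(newline="", encoding="utf-8")
        name = sample_id or p.stem
        close = True
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ProfileLoadError("empty file: no header row")
        fields = [f.strip() for f in reader.fieldnames]
        for required in ("code", value_column):
            if required not in fields:
                raise ProfileLoadError(f"missing required column {required!r}")
        entries: list[ProfileEntry] = []
        codes_seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            row = {(k or "").strip(): (v or "") for k, v in row.items()}
            try:
                descriptor = parse_shorthand(row["code"], common_name=row.get("name") or None)
            except ShorthandParseError as exc:
                raise ProfileLoadError(str(exc), row=rownum) from exc
            if descriptor.code in codes_seen:
                raise DuplicateCodeError(
                    f"duplicate fatty-acid code {descriptor.code!r}", row=rownum
                )
            codes_seen.add(descriptor.code)
            try:
                pct, nd = _parse_percentage(row[value_column])
            except ValueError as exc:
                raise ProfileLoadError(
                    f"unreadable percentage {row[value_column]!r}", row=rownum
                ) from exc
            sd: Optional[float] = None
            if sd_column and sd_column in row and row[sd_column].strip() not in {"", "N.D."}:
                sd = float(row[sd_column])
            try:
                entries.append(ProfileEntry(descriptor, pct, sd=sd, nd=nd))
            except ValueError as exc:
                raise ProfileLoadError(str(exc), row=rownum) from exc
        if not entries:
            raise ProfileLoadError("no data rows")
        return FattyAcidProfile(sample_id=name, entries=tuple(entries), lipid_content=lipid_content)
    finally:
        if close:
            handle.close()


def write_profile_csv(profile: FattyAcidProfile, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a profile as ``name,code,percentage,sd`` CSV (N.D. preserved)."""
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = Path(path).open("w", newline="", encoding="utf-8")
        close = True
    try:
        writer = csv.writer(handle)
        writer.writerow(["name", "code", "percentage", "sd"])
        for e in profile:
            pct = "N.D." if e.nd else repr(e.percentage)
            sd = "" if e.sd is None else repr(e.sd)
            writer.writerow([e.descriptor.common_name or "", e.descriptor.code, pct, sd])
    finally:
        if close:
            handle.close()
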