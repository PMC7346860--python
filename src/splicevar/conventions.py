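"""Window conventions for splice-site sequences.

A splice-site window is a fixed-length nucleotide string with the obligate
core dinucleotide (GT for donor sites, AG for acceptor sites) pinned at a
convention-defined 1-based position:

* ``DLAI40`` — 40 nt windows; GT at positions 20-21 (donor), AG at 19-20
  (acceptor).
* ``GWH398`` — 398 nt windows; GT at 201-202 (donor), AG at 198-199
  (acceptor).
* derived windows — any length ``L`` obtained by trimming a GWH398 window;
  the dimer sits at ``L/2`` (donor) or ``L/2 - 1`` (acceptor), which
  reproduces the DLAI40 positions at ``L = 40``.

All positions exposed here are 1-based, matching how splice-site positions
are conventionally reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class SiteType(str, enum.Enum):
    """Which side of the intron the window is centred on."""

    DONOR = "donor"
    ACCEPTOR = "acceptor"


class Label(str, enum.Enum):
    """Classification label of a window: true splice site or decoy."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


#: Core dinucleotide per site type.
DIMERS: dict[SiteType, str] = {SiteType.DONOR: "GT", SiteType.ACCEPTOR: "AG"}

#: Named convention registry: (site_type, name) -> (length, dimer_start).
_FIXED: dict[tuple[SiteType, str], tuple[int, int]] = {
    (SiteType.DONOR, "DLAI40"): (40, 20),
    (SiteType.ACCEPTOR, "DLAI40"): (40, 19),
    (SiteType.DONOR, "GWH398"): (398, 201),
    (SiteType.ACCEPTOR, "GWH398"): (398, 198),
}


@dataclass(frozen=True)
class DimerConvention:
    """Placement rule for the core dinucleotide within a window.

    Parameters
    ----------
    site_type : SiteType
        Donor or acceptor.
    length : int
        Window length ``L`` in nucleotides.
    dimer_start : int
        1-based position of the first base of the core dinucleotide.
    name : str
        ``"DLAI40"``, ``"GWH398"`` or ``"derived"``.
    """

    site_type: SiteType
    length: int
    dimer_start: int
    name: str = "derived"

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError(f"window length must be >= 2, got {self.length}")
        if not 1 <= self.dimer_start <= self.length - 1:
            raise ValueError(
                f"dimer_start {self.dimer_start} outside window of "
                f"length {self.length}"
            )

    @property
    def dimer(self) -> str:
        return DIMERS[self.site_type]

    @property
    def dimer_slice(self) -> slice:
        """0-based slice of the dimer within the window string."""
        return slice(self.dimer_start - 1, self.dimer_start + 1)


def get_convention(site_type: SiteType | str, name: str,
                   length: int | None = None) -> DimerConvention:
    """Look up a named convention, or build a derived one for ``length``.

    ``name`` is ``"DLAI40"``, ``"GWH398"`` or ``"derived"`` (the latter
    requires ``length``, which must be even).
    """
    site_type = SiteType(site_type)
    if name in ("DLAI40", "GWH398"):
        L, start = _FIXED[(site_type, name)]
        return DimerConvention(site_type, L, start, name)
    if name == "derived":
        if length is None:
            raise ValueError("derived convention requires an explicit length")
        return derived_convention(site_type, length)
    raise ValueError(f"unknown convention {name!r}")


def derived_convention(site_type: SiteType | str, length: int) -> DimerConvention:
    """Convention for a window of ``length`` nt trimmed from a GWH398 window.

    The dimer lands at ``L/2`` for donor windows and ``L/2 - 1`` for
    acceptor windows; ``L = 398`` keeps the original GWH398 placement.
    """
    site_type = SiteType(site_type)
    if length == 398:
        return get_convention(site_type, "GWH398")
    if length % 2 != 0:
        raise ValueError(f"derived window length must be even, got {length}")
    if site_type is SiteType.DONOR:
        start = length // 2
    else:
        start = length // 2 - 1
    name = "DLAI40" if length == 40 else "derived"
    return DimerConvention(site_type, length, start, name)
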