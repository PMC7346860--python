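"""The :class:`SpliceSequence` record and its validation rules."""

from __future__ import annotations

from dataclasses import dataclass, field

from .conventions import DimerConvention, Label, SiteType

VALID_BASES = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """A sequence violates its window convention."""


@dataclass(frozen=True)
class SpliceSequence:
    """A fixed-length nucleotide window around a (putative) splice junction.

    Invariants, enforced at construction:

    * ``seq`` contains only A/C/G/T (input is uppercased on ingest);
    * ``len(seq)`` equals the convention's window length;
    * the core dinucleotide (GT for donor, AG for acceptor) occupies the
      convention's dimer positions.

    The dimer requirement holds for positives and negatives alike — decoy
    negatives carry the same core dinucleotide, which is what makes the
    classification problem non-trivial.
    """

    seq: str
    site_type: SiteType
    label: Label
    convention: DimerConvention
    identifier: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        object.__setattr__(self, "label", Label(self.label))
        self._validate()

    def _validate(self) -> None:
        conv = self.convention
        if conv.site_type is not self.site_type:
            raise SequenceValidationError(
                f"{self._tag}: convention is for {conv.site_type.value}, "
                f"record says {self.site_type.value}"
            )
        bad = [i for i, b in enumerate(self.seq, start=1) if b not in VALID_BASES]
        if bad:
            raise SequenceValidationError(
                f"{self._tag}: non-ACGT character {self.seq[bad[0] - 1]!r} "
                f"at position {bad[0]}"
            )
        if len(self.seq) != conv.length:
            raise SequenceValidationError(
                f"{self._tag}: length {len(self.seq)} != convention "
                f"length {conv.length}"
            )
        found = self.seq[conv.dimer_slice]
        if found != conv.dimer:
            raise SequenceValidationError(
                f"{self._tag}: dimer missing — expected {conv.dimer} at "
                f"positions {conv.dimer_start}-{conv.dimer_start + 1}, "
                f"found {found}"
            )

    @property
    def _tag(self) -> str:
        return self.identifier or "sequence"

    def __len__(self) -> int:
        return len(self.seq)
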