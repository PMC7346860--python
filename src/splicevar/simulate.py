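"""Synthetic splice-site datasets with controllable motif strength.

Real donor and acceptor windows carry, besides the near-invariant GT/AG
core dinucleotide, a characteristic position-specific base composition:
donors an exonic (A/C)AG just upstream of GT and a purine-rich GTRAGT-like
intronic run just downstream; acceptors a pyrimidine tract ending in YAG.
The generator models this as a position weight matrix (PWM): consensus
frequency tables around the dimer, mixed with a uniform-per-strand
background by a ``strength`` knob in [0, 1]. At strength 0 every non-dimer
column is pure background, so positives and negatives are statistically
identical apart from nothing at all — a null dataset; at strength 1 the
full consensus shape is present.

Negatives are decoys: i.i.d. background sequences with the obligate dimer
forced at the convention positions, exactly the construction used for
decoy non-splice-site sets. Positives and negatives share one background
distribution so the PWM columns are the only systematic signal.

The shipped consensus tables are a synthetic stand-in shaped like the
canonical human splice-site consensus; they are not estimated from any
real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conventions import DimerConvention, Label, SiteType, get_convention
from .encoding import ALPHABET
from .sequences import SpliceSequence
from .variants import ClinicalClass, VariantRecord

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# Consensus frequency tables, keyed by offset from the first dimer base
# (offset 0 = G of GT / A of AG). Columns ordered (A, C, G, T).
# Shapes follow the canonical human splice consensus: donor (A/C)AG|GTRAGT,
# acceptor pyrimidine tract + YAG|G. Synthetic stand-in values.
_DONOR_CONSENSUS: dict[int, tuple[float, float, float, float]] = {
    -3: (0.32, 0.37, 0.19, 0.12),
    -2: (0.58, 0.13, 0.15, 0.14),
    -1: (0.10, 0.04, 0.78, 0.08),
    2: (0.59, 0.03, 0.34, 0.04),   # +3: R (purine)
    3: (0.71, 0.08, 0.12, 0.09),
    4: (0.05, 0.06, 0.84, 0.05),
    5: (0.16, 0.15, 0.22, 0.47),
}
_ACCEPTOR_CONSENSUS: dict[int, tuple[float, float, float, float]] = {
    # polypyrimidine tract
    **{off: (0.10, 0.33, 0.08, 0.49) for off in range(-13, -2)},
    -2: (0.24, 0.31, 0.05, 0.40),
    -1: (0.03, 0.65, 0.02, 0.30),  # Y of YAG, C-rich
    2: (0.25, 0.13, 0.52, 0.10),   # first exonic base, G-rich
}
_CONSENSUS = {SiteType.DONOR: _DONOR_CONSENSUS,
              SiteType.ACCEPTOR: _ACCEPTOR_CONSENSUS}

# Flank base composition on the two sides of a true junction. Real windows
# are exonic on one side and intronic on the other (donor: exon|GT-intron;
# acceptor: intron-AG|exon), and the two compartments differ in composition;
# decoy windows drawn from bulk sequence carry no such asymmetry. Synthetic
# stand-in values shaped like human exon (GC-richer) and 5'/3' intron
# (T-richer) composition.
_EXON_COMPOSITION = (0.26, 0.26, 0.27, 0.21)
_INTRON_COMPOSITION = (0.22, 0.18, 0.25, 0.35)


@dataclass(frozen=True)
class MotifModel:
    """A PWM over a whole window with the dimer columns degenerate.

    ``pwm`` has shape (L, 4) with rows summing to 1; at the two dimer
    positions the consensus base has probability exactly 1.
    """

    pwm: np.ndarray
    convention: DimerConvention
    strength: float
    background: np.ndarray

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.shape != (self.convention.length, 4):
            raise ValueError(
                f"pwm shape {pwm.shape} does not match window length "
                f"{self.convention.length}"
            )
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        d0 = self.convention.dimer_start - 1
        for k, base in enumerate(self.convention.dimer):
            if pwm[d0 + k, _BASE_INDEX[base]] != 1.0:
                raise ValueError(
                    f"dimer column {d0 + k + 1} must be degenerate on {base}"
                )

    @property
    def dimer_positions(self) -> tuple[int, int]:
        """1-based positions of the core dinucleotide."""
        return (self.convention.dimer_start, self.convention.dimer_start + 1)

    def information(self) -> np.ndarray:
        """Per-column KL divergence (nats) from the background distribution.

        Zero for pure-background columns; used to rank motif columns when
        designing disruptive vs neutral variants.
        """
        p = np.clip(self.pwm, 1e-12, None)
        q = np.clip(self.background, 1e-12, None)
        return np.sum(p * np.log(p / q[None, :]), axis=1)

    def log_odds(self, seq: str) -> float:
        """Sum over positions of log(pwm / background) for the observed base."""
        idx = [_BASE_INDEX[b] for b in seq.upper()]
        p = np.clip(self.pwm[np.arange(len(idx)), idx], 1e-12, None)
        q = self.background[idx]
        return float(np.sum(np.log(p / q)))

    def log_likelihood(self, seq: str) -> float:
        """Sum of log PWM probabilities of the observed bases."""
        idx = [_BASE_INDEX[b] for b in seq.upper()]
        return float(np.sum(np.log(np.clip(self.pwm[np.arange(len(idx)), idx],
                                           1e-12, None))))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset draw.

    ``background_gc`` sets the GC fraction of the background distribution
    (A/T and G/C each split evenly); 0.42 approximates the human genome.
    The same seed always reproduces the identical dataset.
    """

    site_type: SiteType = SiteType.DONOR
    convention: str = "DLAI40"
    n_positive: int = 1000
    n_negative: int = 1000
    strength: float = 1.0
    background_gc: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("sequence counts must be non-negative")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticVariantSet:
    """Variants drawn from positive windows, split by design intent.

    ``class_design`` records which window positions each class draws from:
    disruptive variants hit high-information motif columns, neutral ones
    hit near-background columns.
    """

    records: list[VariantRecord]
    class_design: dict[str, list[int]] = field(default_factory=dict)


def background_distribution(gc: float) -> np.ndarray:
    """(A, C, G, T) probabilities for a GC fraction, strand-symmetric."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def default_motif(site_type: SiteType | str, convention: str = "DLAI40",
                  strength: float = 1.0, background_gc: float = 0.42,
                  length: int | None = None) -> MotifModel:
    """Build the shipped consensus PWM at a given motif strength.

    Each consensus column is mixed with the background as
    ``strength * consensus + (1 - strength) * background``; positions
    outside the consensus footprint are pure background; the two dimer
    columns are always degenerate.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    site_type = SiteType(site_type)
    conv = get_convention(site_type, convention, length)
    bg = background_distribution(background_gc)
    pwm = np.tile(bg, (conv.length, 1))
    d0 = conv.dimer_start - 1  # 0-based first dimer index
    # exon/intron flank composition, mixed with background by strength
    exon = np.asarray(_EXON_COMPOSITION)
    intron = np.asarray(_INTRON_COMPOSITION)
    if site_type is SiteType.DONOR:
        upstream, downstream = exon, intron   # exon | GT...intron
    else:
        upstream, downstream = intron, exon   # intron...AG | exon
    pwm[:d0] = strength * upstream + (1 - strength) * bg
    pwm[d0 + 2:] = strength * downstream + (1 - strength) * bg
    for offset, freqs in _CONSENSUS[site_type].items():
        j = d0 + offset
        if 0 <= j < conv.length:
            pwm[j] = strength * np.asarray(freqs) + (1 - strength) * bg
    for k, base in enumerate(conv.dimer):
        pwm[d0 + k] = 0.0
        pwm[d0 + k, _BASE_INDEX[base]] = 1.0
    return MotifModel(pwm, conv, strength, bg)


def _draw(pwm: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    L = pwm.shape[0]
    cols = np.empty((n, L), dtype=np.int8)
    for j in range(L):
        cols[:, j] = rng.choice(4, size=n, p=pwm[j])
    lookup = np.array(list(ALPHABET))
    return ["".join(row) for row in lookup[cols]]


def sample_positive(motif: MotifModel, n: int, seed: int) -> list[SpliceSequence]:
    """Draw ``n`` positive windows column-independently from the PWM."""
    rng = np.random.default_rng(seed)
    conv = motif.convention
    return [SpliceSequence(s, conv.site_type, Label.POSITIVE, conv,
                           identifier=f"pos{i + 1}")
            for i, s in enumerate(_draw(motif.pwm, n, rng))]


def sample_negative(config: GeneratorConfig) -> list[SpliceSequence]:
    """Draw decoy windows: pure background with the dimer forced in."""
    conv = get_convention(config.site_type, config.convention)
    rng = np.random.default_rng(config.seed)
    bg = background_distribution(config.background_gc)
    pwm = np.tile(bg, (conv.length, 1))
    d0 = conv.dimer_start - 1
    for k, base in enumerate(conv.dimer):
        pwm[d0 + k] = 0.0
        pwm[d0 + k, _BASE_INDEX[base]] = 1.0
    return [SpliceSequence(s, conv.site_type, Label.NEGATIVE, conv,
                           identifier=f"neg{i + 1}")
            for i, s in enumerate(_draw(pwm, config.n_negative, rng))]


def generate_dataset(config: GeneratorConfig) -> list[SpliceSequence]:
    """Positives followed by negatives for one :class:`GeneratorConfig`.

    Positive and negative draws use distinct sub-seeds derived from
    ``config.seed`` so the two halves are independent but reproducible.
    """
    motif = default_motif(config.site_type, config.convention,
                          config.strength, config.background_gc)
    pos = sample_positive(motif, config.n_positive, config.seed * 2 + 1)
    neg = sample_negative(
        GeneratorConfig(config.site_type, config.convention, 0,
                        config.n_negative, config.strength,
                        config.background_gc, config.seed * 2 + 2)
    )
    return pos + neg


def generate_variants(positives: list[SpliceSequence], n_disruptive: int,
                      n_neutral: int, seed: int, motif: MotifModel,
                      include_dimer: bool = True,
                      n_motif_columns: int = 6) -> SyntheticVariantSet:
    """Build a variant set split into motif-disrupting and neutral classes.

    Disruptive variants (labelled pathogenic) change a base at one of the
    ``n_motif_columns`` highest-information non-dimer PWM columns — plus
    the dimer columns themselves when ``include_dimer`` — to the allele
    with the lowest PWM probability (alphabetical tie-break, so mutating
    the G of a GT dimer yields A). Neutral variants (labelled benign)
    change a base at one of the lowest-information columns to a uniformly
    random alternative. (window, position) pairs are sampled without
    replacement within each class.
    """
    if not positives:
        raise ValueError("need at least one positive window")
    rng = np.random.default_rng(seed)
    conv = motif.convention
    info = motif.information()
    dimer_idx = {conv.dimer_start - 1, conv.dimer_start}
    non_dimer = [j for j in range(conv.length) if j not in dimer_idx]
    by_info = sorted(non_dimer, key=lambda j: (-info[j], j))
    disruptive_pos = sorted(by_info[:n_motif_columns])
    if include_dimer:
        disruptive_pos = sorted(disruptive_pos + sorted(dimer_idx))
    neutral_pos = sorted(by_info[-max(n_motif_columns, 1):])

    def pick(positions: list[int], n: int) -> list[tuple[int, int]]:
        combos = len(positives) * len(positions)
        if n > combos:
            raise ValueError(
                f"requested {n} variants but only {combos} "
                f"(sequence, position) pairs are available"
            )
        flat = rng.choice(combos, size=n, replace=False)
        return [(int(f) // len(positions), positions[int(f) % len(positions)])
                for f in flat]

    records: list[VariantRecord] = []
    for (si, j) in pick(disruptive_pos, n_disruptive):
        window = positives[si].seq
        ref = window[j]
        alts = [b for b in ALPHABET if b != ref]
        alt = min(alts, key=lambda b: (motif.pwm[j, _BASE_INDEX[b]], b))
        records.append(VariantRecord(window, j + 1, ref, alt,
                                     ClinicalClass.PATHOGENIC, conv.site_type))
    for (si, j) in pick(neutral_pos, n_neutral):
        window = positives[si].seq
        ref = window[j]
        alts = [b for b in ALPHABET if b != ref]
        alt = alts[int(rng.integers(len(alts)))]
        records.append(VariantRecord(window, j + 1, ref, alt,
                                     ClinicalClass.BENIGN, conv.site_type))
    design = {"disruptive": [j + 1 for j in disruptive_pos],
              "neutral": [j + 1 for j in neutral_pos]}
    return SyntheticVariantSet(records, design)
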