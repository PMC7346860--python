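"""Variant records and log-ratio effect scoring.

A single-nucleotide variant is scored by comparing the model's splice
probability on the reference window with the probability on the window
carrying the alternative allele:

    score(m) = log10( PM(ref) / PM(alt) )

where PM(.) is the classifier's probability that the window is a true
splice site. Positive scores mean the alternative allele reduces the
predicted splicing probability; variants that disrupt the splicing signal
therefore score high, while neutral changes score near zero. Probabilities
are clamped into [eps, 1 - eps] before the ratio so the score stays finite
and antisymmetric under a ref/alt swap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import SiteType
from .metrics import welch_t_one_sided

#: Probability clamp applied before the log ratio.
EPSILON = 1e-6

VARIANT_TSV_COLUMNS = ["window", "position", "ref", "alt", "class", "site_type"]


class ClinicalClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide change inside a splice-site window.

    ``position`` is 1-based within the window; the window itself is the
    reference sequence, so ``window[position]`` must equal ``ref_allele``.
    """

    window: str
    position: int
    ref_allele: str
    alt_allele: str
    clinical_class: ClinicalClass = ClinicalClass.UNKNOWN
    site_type: SiteType = SiteType.DONOR

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", self.window.upper())
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        object.__setattr__(self, "clinical_class", ClinicalClass(self.clinical_class))
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        if not 1 <= self.position <= len(self.window):
            raise ValueError(
                f"position {self.position} outside window of length "
                f"{len(self.window)}"
            )
        found = self.window[self.position - 1]
        if found != self.ref_allele:
            raise ValueError(
                f"reference mismatch at position {self.position}: "
                f"expected {self.ref_allele}, window has {found}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("alt allele equals ref allele")


@dataclass(frozen=True)
class VariantScore:
    """Result of scoring one variant: PM(ref), PM(alt) and the log ratio."""

    record: VariantRecord
    pm_ref: float
    pm_alt: float
    score: float


def apply_variant(record: VariantRecord) -> str:
    """Return the window with the alternative allele substituted in.

    The result differs from the reference window at exactly one position.
    Substitutions hitting the core dinucleotide are allowed — the mutated
    window no longer passes the dimer check, but models still score it.
    """
    i = record.position - 1
    return record.window[:i] + record.alt_allele + record.window[i + 1:]


def log_ratio_score(pm_ref: float, pm_alt: float, eps: float = EPSILON) -> float:
    """log10(PM(ref) / PM(alt)) with both probabilities clamped to [eps, 1-eps]."""
    r = min(max(pm_ref, eps), 1.0 - eps)
    a = min(max(pm_alt, eps), 1.0 - eps)
    return math.log10(r / a)


def score_variant(model, record: VariantRecord) -> VariantScore:
    """Score one variant with a fitted splice-site classifier."""
    return score_variants(model, [record])[0]


def score_variants(model, records: list[VariantRecord]) -> list[VariantScore]:
    """Score a batch of variants (one model call for all ref+alt windows)."""
    if not records:
        return []
    windows = [r.window for r in records] + [apply_variant(r) for r in records]
    probs = np.asarray(model.predict_proba_splice(windows))
    n = len(records)
    return [
        VariantScore(rec, float(probs[i]), float(probs[n + i]),
                     log_ratio_score(float(probs[i]), float(probs[n + i])))
        for i, rec in enumerate(records)
    ]


def filter_by_ref_probability(scores: list[VariantScore],
                              threshold: float = 0.8) -> tuple[list[VariantScore], dict]:
    """Keep variants whose reference window scores strictly above ``threshold``.

    Mirrors the analysis restriction to windows the model is confident are
    real splice sites (reference probability over 80%). Returns the kept
    scores and a per-clinical-class tally of kept/dropped counts.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    kept, counts = [], {}
    for s in scores:
        cls = s.record.clinical_class.value
        bucket = counts.setdefault(cls, {"kept": 0, "dropped": 0})
        if s.pm_ref > threshold:
            kept.append(s)
            bucket["kept"] += 1
        else:
            bucket["dropped"] += 1
    return kept, counts


def compare_groups(scores_pathogenic, scores_benign):
    """One-sided Welch's t-test that pathogenic scores exceed benign scores.

    Accepts lists of :class:`VariantScore` or raw score arrays. Returns
    ``(t, p, summaries)`` where ``summaries`` maps group name to
    ``{"n", "mean", "sd"}``.
    """
    x = _as_scores(scores_pathogenic)
    y = _as_scores(scores_benign)
    t, p = welch_t_one_sided(x, y, alternative="greater")
    summaries = {
        "pathogenic": {"n": len(x), "mean": float(np.mean(x)),
                       "sd": float(np.std(x, ddof=1))},
        "benign": {"n": len(y), "mean": float(np.mean(y)),
                   "sd": float(np.std(y, ddof=1))},
    }
    return t, p, summaries


def _as_scores(values) -> np.ndarray:
    arr = [v.score if isinstance(v, VariantScore) else float(v) for v in values]
    return np.asarray(arr, dtype=float)


def per_position_summary(scores: list[VariantScore]) -> pd.DataFrame:
    """Per-(position, clinical class) score distribution summary.

    One row per combination present, with count, mean, median and standard
    deviation of the log-ratio scores; positions are 1-based within the
    window. Row counts sum to the number of scored records.
    """
    frame = pd.DataFrame(
        {"position": [s.record.position for s in scores],
         "clinical_class": [s.record.clinical_class.value for s in scores],
         "score": [s.score for s in scores]}
    )
    if frame.empty:
        return pd.DataFrame(
            columns=["position", "clinical_class", "n", "mean", "median", "sd"]
        )
    out = (frame.groupby(["position", "clinical_class"], as_index=False)["score"]
           .agg(n="size", mean="mean", median="median", sd="std")
           .sort_values(["position", "clinical_class"], ignore_index=True))
    return out


def read_variant_tsv(path) -> list[VariantRecord]:
    """Read a variant table: window, position, ref, alt, class, site_type."""
    frame = pd.read_csv(path, sep="\t", dtype={"position": int})
    missing = set(VARIANT_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    return [
        VariantRecord(row["window"], int(row["position"]), row["ref"],
                      row["alt"], row["class"], row["site_type"])
        for row in frame.to_dict("records")
    ]


def write_variant_tsv(records: list[VariantRecord], path,
                      scores: list[VariantScore] | None = None,
                      kept: set[int] | None = None) -> None:
    """Write variants (optionally with pm_ref/pm_alt/score/kept columns)."""
    data = {
        "window": [r.window for r in records],
        "position": [r.position for r in records],
        "ref": [r.ref_allele for r in records],
        "alt": [r.alt_allele for r in records],
        "class": [r.clinical_class.value for r in records],
        "site_type": [r.site_type.value for r in records],
    }
    if scores is not None:
        data["pm_ref"] = [s.pm_ref for s in scores]
        data["pm_alt"] = [s.pm_alt for s in scores]
        data["score"] = [s.score for s in scores]
        if kept is not None:
            data["kept"] = [int(i in kept) for i in range(len(records))]
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)
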