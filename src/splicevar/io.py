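"""Reading and writing labeled splice-site sequence datasets.

Two on-disk formats are supported:

* ``tsv`` — a single file with header ``sequence<TAB>site_type<TAB>label``.
* ``fasta-pair`` — two plain FASTA files (positives, negatives); each
  record description carries ``site=<donor|acceptor> label=<pos|neg>`` tags.

Both round-trip exactly (sequence, site type, label). Window conventions
are not stored in the files; the caller states the convention when reading
and every record is validated against it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conventions import DimerConvention, Label, SiteType, derived_convention, get_convention
from .sequences import SequenceValidationError, SpliceSequence

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["sequence", "site_type", "label"]
_LABEL_TAGS = {Label.POSITIVE: "pos", Label.NEGATIVE: "neg"}
_TAG_LABELS = {v: k for k, v in _LABEL_TAGS.items()}


def _convention_for(site_type: SiteType, convention: str | DimerConvention,
                    length: int) -> DimerConvention:
    if isinstance(convention, DimerConvention):
        return convention
    if convention == "derived":
        return derived_convention(site_type, length)
    return get_convention(site_type, convention)


def read_dataset(path, format: str = "tsv", *, convention: str | DimerConvention = "DLAI40",
                 negatives_path=None) -> list[SpliceSequence]:
    """Read a labeled sequence dataset into validated records.

    Parameters
    ----------
    path : path-like
        The TSV file, or the positives FASTA for ``fasta-pair``.
    format : {"tsv", "fasta-pair"}
    convention : str or DimerConvention
        ``"DLAI40"``, ``"GWH398"``, ``"derived"`` (length inferred per
        record) or an explicit :class:`DimerConvention`.
    negatives_path : path-like, optional
        The negatives FASTA; required for ``fasta-pair``.

    Raises
    ------
    SequenceValidationError
        Listing the identifier and reason of the first invalid record.
    """
    if format == "tsv":
        records = _read_tsv(path, convention)
    elif format == "fasta-pair":
        if negatives_path is None:
            raise ValueError("fasta-pair format requires negatives_path")
        records = (_read_fasta(path, Label.POSITIVE, convention)
                   + _read_fasta(negatives_path, Label.NEGATIVE, convention))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        logger.warning("read_dataset: %s contains no records", path)
    return records


def _read_tsv(path, convention) -> list[SpliceSequence]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty and list(frame.columns) != TSV_COLUMNS:
        return []
    missing = set(TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        site = SiteType(row.site_type)
        conv = _convention_for(site, convention, len(row.sequence))
        records.append(SpliceSequence(row.sequence, site, Label(row.label),
                                      conv, identifier=f"{path}:row {i}"))
    return records


def _read_fasta(path, label: Label, convention) -> list[SpliceSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(tok.split("=", 1) for tok in rec.description.split()
                    if "=" in tok)
        if "site" not in tags:
            raise SequenceValidationError(
                f"{path}:{rec.id}: description lacks a site=<type> tag"
            )
        site = SiteType(tags["site"])
        file_label = _TAG_LABELS.get(tags.get("label", ""), label)
        seq = str(rec.seq)
        conv = _convention_for(site, convention, len(seq))
        records.append(SpliceSequence(seq, site, file_label, conv,
                                      identifier=f"{path}:{rec.id}"))
    return records


def write_dataset(records: list[SpliceSequence], path, format: str = "tsv",
                  *, negatives_path=None) -> None:
    """Write records to disk; inverse of :func:`read_dataset`.

    For ``fasta-pair``, positives go to ``path`` and negatives to
    ``negatives_path``.
    """
    if format == "tsv":
        frame = pd.DataFrame(
            {"sequence": [r.seq for r in records],
             "site_type": [r.site_type.value for r in records],
             "label": [r.label.value for r in records]},
            columns=TSV_COLUMNS,
        )
        frame.to_csv(path, sep="\t", index=False)
    elif format == "fasta-pair":
        if negatives_path is None:
            raise ValueError("fasta-pair format requires negatives_path")
        for target, lab in ((path, Label.POSITIVE), (negatives_path, Label.NEGATIVE)):
            subset = [r for r in records if r.label is lab]
            seqrecs = [
                SeqRecord(Seq(r.seq), id=r.identifier or f"seq{i}",
                          description=f"site={r.site_type.value} "
                                      f"label={_LABEL_TAGS[lab]}")
                for i, r in enumerate(subset, start=1)
            ]
            SeqIO.write(seqrecs, str(target), "fasta")
    else:
        raise ValueError(f"unknown format {format!r}")
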