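"""Reading, validating, filtering and writing aligned mtDNA data.

The unit of data is an :class:`Alignment` — equal-length DNA sequences keyed
by specimen id — together with a :class:`SpecimenTable` holding per-specimen
geography and invasion status.  Sequences are stored as plain uppercase
strings over ``{A, C, G, T, N, -}`` plus IUPAC ambiguity codes; downstream
statistics require the unambiguous alphabet only, which
:func:`filter_and_trim` enforces.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    BoundsError,
    DuplicateIdError,
    EmptyInputError,
    EmptyResultError,
    JoinError,
    MetadataError,
)

#: Bases accepted by distance and diversity computations.
UNAMBIGUOUS = frozenset("ACGT")

#: Recognised specimen statuses.  ``native``/``introduced`` specimens form the
#: analysis set; ``interception`` specimens (port-of-entry seizures with no
#: confirmed field population) and the ``outgroup`` record are carried along
#: for network/tree context but excluded from population statistics.
STATUS_VALUES = ("native", "introduced", "interception", "outgroup")

REQUIRED_COLUMNS = ("specimen_id", "country", "location", "status", "host", "year")


@dataclass
class Alignment:
    """Equal-length DNA sequences keyed by ordered, unique specimen ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment contains no sequences")
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError(
                f"{len(self.ids)} ids but {len(self.seqs)} sequences"
            )
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentShapeError("sequences have zero length")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise DuplicateIdError(f"duplicate specimen id {sid!r}")
            seen.add(sid)
        self.seqs = [s.upper() for s in self.seqs]
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def L(self) -> int:
        """Alignment length in bp."""
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, sid: str) -> bool:
        return sid in self._index

    def seq(self, sid: str) -> str:
        """Return the sequence for specimen ``sid``."""
        return self.seqs[self._index[sid]]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """New alignment restricted to ``ids``, in the given order."""
        ids = list(ids)
        return Alignment(ids, [self.seq(i) for i in ids])

    def is_unambiguous(self) -> bool:
        """True when every base of every sequence is one of A/C/G/T."""
        return all(set(s) <= UNAMBIGUOUS for s in self.seqs)


@dataclass
class SpecimenTable:
    """Per-specimen geography/status metadata.

    Wraps a :class:`pandas.DataFrame` with the required columns
    ``specimen_id, country, location, status, host, year``; any extra columns
    are preserved untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise MetadataError(f"missing required column(s): {missing}")
        ids = self.df["specimen_id"]
        dups = ids[ids.duplicated()].tolist()
        if dups:
            raise DuplicateIdError(f"duplicate specimen id(s): {sorted(set(dups))}")
        bad = sorted(set(self.df["status"]) - set(STATUS_VALUES))
        if bad:
            raise MetadataError(
                f"status value(s) {bad} not in {list(STATUS_VALUES)}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["specimen_id"].tolist()

    def status_of(self) -> dict[str, str]:
        """Map specimen_id -> status."""
        return dict(zip(self.df["specimen_id"], self.df["status"]))

    def group_of(self, grouping: str = "country") -> dict[str, str]:
        """Map specimen_id -> group label under ``grouping``.

        ``grouping`` is ``country`` or ``location``.
        """
        if grouping not in ("country", "location"):
            raise MetadataError(f"unknown grouping {grouping!r}")
        return dict(zip(self.df["specimen_id"], self.df[grouping]))

    def subset(self, ids: Iterable[str]) -> "SpecimenTable":
        wanted = set(ids)
        return SpecimenTable(
            self.df[self.df["specimen_id"].isin(wanted)].reset_index(drop=True)
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; record order is preserved.  Raises
    :class:`AlignmentShapeError` on unequal lengths, :class:`DuplicateIdError`
    on repeated ids and :class:`EmptyInputError` for an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as single-line-per-sequence FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_specimen_table(path: str | Path) -> SpecimenTable:
    """Read the tab-separated specimen metadata table.

    The header must contain ``specimen_id country location status host year``;
    unknown extra columns are preserved as opaque annotations.  Empty ``host``
    and ``year`` cells are allowed and kept as empty strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise EmptyInputError(f"no specimen rows in {path}")
    table = SpecimenTable(df)
    bad_years = [
        y for y in table.df["year"] if y != "" and not y.strip().isdigit()
    ]
    if bad_years:
        raise MetadataError(f"non-integer year value(s): {sorted(set(bad_years))}")
    return table


def write_specimen_table(meta: SpecimenTable, path: str | Path) -> None:
    """Write specimen metadata as TSV (UTF-8, no index)."""
    meta.df.to_csv(path, sep="\t", index=False)


def validate_join(
    aln: Alignment, meta: SpecimenTable, allow_unmatched: bool = False
) -> None:
    """Check that alignment and metadata cover the same specimens.

    Joins are strict by default: a specimen present in exactly one of the two
    inputs is a hard :class:`JoinError`, because silently dropping records
    corrupts downstream frequency tables.  ``allow_unmatched`` permits extra
    metadata rows (but never alignment records without metadata).
    """
    aln_ids = set(aln.ids)
    meta_ids = set(meta.ids)
    missing_meta = sorted(aln_ids - meta_ids)
    if missing_meta:
        raise JoinError(f"specimens missing from metadata: {missing_meta[:10]}")
    extra_meta = sorted(meta_ids - aln_ids)
    if extra_meta and not allow_unmatched:
        raise JoinError(
            f"metadata rows without alignment records: {extra_meta[:10]} "
            "(pass allow_unmatched=True to permit)"
        )


def filter_and_trim(
    aln: Alignment,
    start: int = 0,
    end: int | None = None,
    drop_ambiguous: bool = True,
) -> tuple[Alignment, list[str]]:
    """Trim every sequence to the window ``[start, end)`` and optionally drop
    specimens with ambiguous sites.

    With ``drop_ambiguous`` (the default), any retained sequence contains only
    A/C/G/T within the window; specimens with any other character — N, IUPAC
    codes or gaps — are rejected wholesale, mirroring the QC rule of removing
    individuals with any ambiguous or unconfirmed site.  Gaps count as
    ambiguous because the target region is gap-free protein-coding sequence.

    Returns ``(trimmed_alignment, rejected_ids)``.  Raises
    :class:`BoundsError` for an invalid window and :class:`EmptyResultError`
    when nothing survives.
    """
    if end is None:
        end = aln.L
    if not (0 <= start < end <= aln.L):
        raise BoundsError(
            f"window [{start}, {end}) invalid for alignment of length {aln.L}"
        )
    kept_ids: list[str] = []
    kept_seqs: list[str] = []
    rejected: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        window = seq[start:end]
        if drop_ambiguous and not set(window) <= UNAMBIGUOUS:
            rejected.append(sid)
        else:
            kept_ids.append(sid)
            kept_seqs.append(window)
    if not kept_ids:
        raise EmptyResultError(
            "filter_and_trim removed every specimen "
            f"({len(rejected)} rejected as ambiguous)"
        )
    return Alignment(kept_ids, kept_seqs), rejected


def write_haplotype_fasta(catalog, path: str | Path) -> None:
    """Write one FASTA record per haplotype, header = haplotype label.

    Labels contain no whitespace, so records round-trip exactly through
    :func:`read_alignment`.
    """
    haplotypes = catalog.haplotypes
    if not haplotypes:
        raise EmptyInputError("haplotype catalog is empty")
    with open(path, "w", encoding="utf-8") as fh:
        for hap in haplotypes:
            fh.write(f">{hap.label}\n{hap.seq}\n")
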