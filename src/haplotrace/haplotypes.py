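"""Haplotype collapsing, labeling and geographic classification.

Two specimens share a haplotype iff their (trimmed, unambiguous) sequences
are identical — after strict QC no fuzzy matching is defined.  Haplotypes are
classified by where they occur:

* ``private`` — found in exactly one group (country by default);
* ``shared_native`` — found in two or more groups, but never carried by a
  specimen from an introduced population;
* ``invasive`` — found in two or more groups AND carried by at least one
  specimen with status ``introduced``.  These are the haplotypes whose
  geography traces an invasion back to its source.

Interception specimens (and the outgroup record) are cataloged so they can
appear in networks and trees, but they never contribute to abundance ranking,
frequency tables or classification.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import pandas as pd

from .errors import JoinError, MetadataError
from .seqio import Alignment, SpecimenTable, validate_join

#: statuses excluded from the analysis set by default
DEFAULT_EXCLUDE_STATUS = frozenset({"interception", "outgroup"})

CLASSIFICATIONS = ("private", "shared_native", "invasive")


@dataclass
class Haplotype:
    """A distinct sequence with its carriers.

    ``members`` are analysis specimens (native/introduced); ``aux_members``
    maps excluded specimens (interceptions, outgroup) sharing the sequence to
    their status.  ``per_group_counts`` counts analysis members per country.
    """

    label: str
    seq: str
    members: list[str]
    aux_members: dict[str, str] = field(default_factory=dict)
    per_group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        """Number of analysis specimens carrying this haplotype."""
        return len(self.members)


@dataclass
class HaplotypeCatalog:
    """Ordered haplotypes plus specimen assignment and classification maps."""

    haplotypes: list[Haplotype]
    assignment: dict[str, str]
    classification: dict[str, str]

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def get(self, label: str) -> Haplotype:
        for hap in self.haplotypes:
            if hap.label == label:
                return hap
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    @property
    def invasive_labels(self) -> list[str]:
        """Letter-labeled invasive haplotypes in abundance order."""
        return [
            h.label for h in self.haplotypes
            if self.classification.get(h.label) == "invasive"
        ]

    def counts(self) -> dict[str, int]:
        return {h.label: h.count for h in self.haplotypes}


def _classify_one(groups: set[str], has_introduced: bool) -> str:
    if len(groups) >= 2:
        return "invasive" if has_introduced else "shared_native"
    return "private"


def _letter_label(k: int) -> str:
    """0 -> Hap-A, 25 -> Hap-Z, 26 -> Hap-AA, ..."""
    letters = ""
    k += 1
    while k > 0:
        k, rem = divmod(k - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return f"Hap-{letters}"


def collapse_and_label(
    aln: Alignment,
    meta: SpecimenTable,
    exclude_status: frozenset[str] | set[str] = DEFAULT_EXCLUDE_STATUS,
    allow_unmatched: bool = False,
) -> HaplotypeCatalog:
    """Collapse identical sequences into haplotypes and label them.

    Haplotypes are ranked by descending abundance among analysis specimens
    (ties broken by first occurrence in input order).  Haplotypes satisfying
    the invasive rule get letter labels ``Hap-A``, ``Hap-B``, ... in that
    order; all others get zero-padded numeric labels ``H01``, ``H02``, ...
    Specimens whose status is in ``exclude_status`` are cataloged as auxiliary
    members and excluded from ranking and classification.
    """
    validate_join(aln, meta, allow_unmatched=allow_unmatched)
    status = meta.status_of()
    country = meta.group_of("country")

    by_seq: dict[str, dict] = {}
    for order, (sid, seq) in enumerate(zip(aln.ids, aln.seqs)):
        entry = by_seq.setdefault(
            seq, {"first": order, "members": [], "aux": {}}
        )
        if status[sid] in exclude_status:
            entry["aux"][sid] = status[sid]
        else:
            entry["members"].append(sid)

    ordered = sorted(
        by_seq.items(), key=lambda kv: (-len(kv[1]["members"]), kv[1]["first"])
    )

    # classify on country occupancy of analysis members to decide letter labels
    classes: list[str] = []
    for seq, entry in ordered:
        groups = {country[sid] for sid in entry["members"]}
        has_intro = any(status[sid] == "introduced" for sid in entry["members"])
        classes.append(_classify_one(groups, has_intro))

    n_other = sum(1 for c in classes if c != "invasive")
    width = max(2, len(str(n_other)))
    haplotypes: list[Haplotype] = []
    assignment: dict[str, str] = {}
    classification: dict[str, str] = {}
    letter_i = numeric_i = 0
    for (seq, entry), cls in zip(ordered, classes):
        if cls == "invasive":
            label = _letter_label(letter_i)
            letter_i += 1
        else:
            numeric_i += 1
            label = f"H{numeric_i:0{width}d}"
        per_group: dict[str, int] = {}
        for sid in entry["members"]:
            per_group[country[sid]] = per_group.get(country[sid], 0) + 1
        haplotypes.append(
            Haplotype(label, seq, entry["members"], entry["aux"], per_group)
        )
        classification[label] = cls
        for sid in entry["members"]:
            assignment[sid] = label
        for sid in entry["aux"]:
            assignment[sid] = label
    return HaplotypeCatalog(haplotypes, assignment, classification)


def classify_haplotypes(
    catalog: HaplotypeCatalog,
    meta: SpecimenTable,
    grouping: str = "country",
) -> dict[str, str]:
    """Classify every haplotype as private / shared_native / invasive.

    Group occupancy is evaluated under ``grouping`` (``country`` or
    ``location``); only analysis members count — interception and outgroup
    specimens never contribute.  A haplotype with no analysis members (e.g.
    interception-only) is private by convention: it occupies no group and
    carries no geographic signal.
    """
    group = meta.group_of(grouping)
    status = meta.status_of()
    out: dict[str, str] = {}
    for hap in catalog:
        groups = {group[sid] for sid in hap.members}
        has_intro = any(status[sid] == "introduced" for sid in hap.members)
        out[hap.label] = _classify_one(groups, has_intro)
    return out


def group_frequency_table(
    catalog: HaplotypeCatalog,
    meta: SpecimenTable,
    grouping: str = "country",
) -> pd.DataFrame:
    """Wide table of haplotype counts: rows = groups, columns = labels.

    Covers analysis specimens only; row sums equal group sample sizes and the
    grand total equals the number of analysis specimens.  Row order follows
    first appearance in the metadata, column order the catalog.
    """
    group = meta.group_of(grouping)
    analysis = {sid for hap in catalog for sid in hap.members}
    rows: list[str] = []
    for sid in meta.ids:
        g = group[sid]
        if sid in analysis and g not in rows:
            rows.append(g)
    table = pd.DataFrame(0, index=rows, columns=catalog.labels, dtype=int)
    for hap in catalog:
        for sid in hap.members:
            table.loc[group[sid], hap.label] += 1
    table.index.name = grouping
    return table
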