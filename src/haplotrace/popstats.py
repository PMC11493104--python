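"""Per-population diversity statistics.

For each group (country or sub-country population) the summary reports:

* ``hap_div`` — haplotype (gene) diversity with the small-sample correction,
  ``H = n/(n-1) * (1 - sum_i p_i^2)`` where ``p_i`` are haplotype relative
  frequencies.  This is the probability that two sequences drawn without
  replacement are different haplotypes.
* ``nuc_div`` — nucleotide diversity per site,
  ``pi = [sum_{i<j} d_ij / C(n, 2)] / L`` over all specimen pairs, with no
  further small-sample correction.
* ``max_pwd_pct`` — the largest pairwise divergence in the group, as a
  percentage of sites.
* ``pct_invasive`` — percentage of specimens carrying an invasive haplotype.

All three sequence statistics are undefined for n < 2 and reported as
missing (NaN), never as 0: a monomorphic group of n >= 2 legitimately scores
0, but a singleton carries no information.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, hamming_matrix
from .errors import UndefinedStatisticError
from .haplotypes import HaplotypeCatalog
from .seqio import Alignment, SpecimenTable

#: decimal places used when writing report tables
REPORT_PRECISION = {"hap_div": 4, "nuc_div": 6, "max_pwd_pct": 3, "pct_invasive": 1}


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype diversity from haplotype counts.

    ``H = (n / (n - 1)) * (1 - sum p_i^2)`` with ``p_i = count_i / n``.
    Raises :class:`UndefinedStatisticError` for n < 2.
    """
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise UndefinedStatisticError(f"haplotype diversity undefined for n={n}")
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def _pairsum_from_counts(dist: DistanceMatrix, counts: Sequence[int]) -> tuple[float, int]:
    """Total pairwise distance and pair count for count-weighted haplotypes."""
    c = np.asarray(list(counts), dtype=float)
    n = int(c.sum())
    # cross-haplotype pairs: c_i * c_j * d_ij for i < j; within-hap pairs add 0
    total = float(c @ dist.D @ c) / 2.0
    return total, n * (n - 1) // 2


def nucleotide_diversity(
    dist: DistanceMatrix,
    L: int,
    counts: Sequence[int] | None = None,
) -> float:
    """Nucleotide diversity per site.

    ``dist`` holds pairwise substitution counts either over specimens
    (``counts=None``) or over distinct haplotypes, in which case ``counts``
    gives the number of carriers of each haplotype and pairs are weighted
    accordingly.
    """
    if L <= 0:
        raise UndefinedStatisticError("alignment length must be positive")
    if counts is None:
        counts = [1] * len(dist)
    total, n_pairs = _pairsum_from_counts(dist, counts)
    if n_pairs < 1:
        raise UndefinedStatisticError("nucleotide diversity undefined for n < 2")
    return total / n_pairs / L


def max_pairwise_divergence(
    dist: DistanceMatrix,
    L: int,
    counts: Sequence[int] | None = None,
) -> float:
    """Maximum pairwise divergence among carriers, in percent of sites.

    When ``counts`` is given the matrix is over haplotypes and only
    haplotypes with at least one carrier enter the maximum.
    """
    if counts is None:
        counts = [1] * len(dist)
    c = np.asarray(list(counts))
    n = int(c.sum())
    if n < 2:
        raise UndefinedStatisticError("max pairwise divergence undefined for n < 2")
    present = c > 0
    if present.sum() == 1:
        return 0.0
    sub = dist.D[np.ix_(present, present)]
    return float(sub.max()) / L * 100.0


def summarize_groups(
    catalog: HaplotypeCatalog,
    meta: SpecimenTable,
    grouping: str = "country",
) -> pd.DataFrame:
    """One diversity summary row per group.

    Returns a DataFrame with columns ``group, n, n_haps, n_private,
    max_pwd_pct, hap_div, nuc_div, n_<invasive label>..., pct_invasive``.
    Invasive membership always uses the catalog's country-level
    classification, while rows may be split by ``location``.  Groups whose
    specimens are all excluded from analysis are omitted with a warning;
    n = 1 groups report missing (NaN) sequence statistics.
    """
    group = meta.group_of(grouping)
    L = len(catalog.haplotypes[0].seq)
    hap_aln = Alignment(catalog.labels, [h.seq for h in catalog.haplotypes])
    hap_dist = hamming_matrix(hap_aln)
    invasive = catalog.invasive_labels

    # group -> label -> count, in metadata order
    order: list[str] = []
    counts: dict[str, dict[str, int]] = {}
    for hap in catalog:
        for sid in hap.members:
            g = group[sid]
            counts.setdefault(g, {})
    for sid in meta.ids:
        g = group[sid]
        if g in counts and g not in order:
            order.append(g)
    for hap in catalog:
        for sid in hap.members:
            g = group[sid]
            counts[g][hap.label] = counts[g].get(hap.label, 0) + 1

    all_groups = [g for g in dict.fromkeys(group[sid] for sid in meta.ids)]
    for g in all_groups:
        if g not in counts:
            warnings.warn(
                f"group {g!r} has no analysis specimens; omitted from summary",
                stacklevel=2,
            )

    rows = []
    for g in order:
        gc = counts[g]
        labels = list(gc)
        cvec = [gc[l] for l in labels]
        n = sum(cvec)
        n_private = sum(
            1
            for l in labels
            if all(l not in counts[other] for other in counts if other != g)
        )
        if n >= 2:
            sub = hap_dist.submatrix(labels)
            hd = haplotype_diversity(cvec)
            nd = nucleotide_diversity(sub, L, counts=cvec)
            mp = max_pairwise_divergence(sub, L, counts=cvec)
        else:
            hd = nd = mp = float("nan")
        inv_counts = {f"n_{l}": gc.get(l, 0) for l in invasive}
        n_inv = sum(inv_counts.values())
        rows.append(
            {
                "group": g,
                "n": n,
                "n_haps": len(labels),
                "n_private": n_private,
                "max_pwd_pct": mp,
                "hap_div": hd,
                "nuc_div": nd,
                **inv_counts,
                "pct_invasive": 100.0 * n_inv / n,
            }
        )
    return pd.DataFrame(rows)


def round_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Apply report rounding (4 dp for H, 6 for pi, 3 for max PWD, 1 for %)."""
    out = summary.copy()
    for col, nd in REPORT_PRECISION.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out
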