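"""Single-level analysis of molecular variance (AMOVA).

Partitions molecular variance among and within populations from a matrix of
pairwise sequence distances, following the sums-of-squares decomposition of
Excoffier, Smouse & Quattro.  For DNA sequence data the number of pairwise
substitutions plays the role of the squared Euclidean distance
(``delta^2_ij = d_ij``), so with N individuals in P populations:

    SS_total  = (1/N) * sum_{i<j} delta^2_ij
    SS_within = sum_p (1/n_p) * sum_{i<j in p} delta^2_ij
    SS_among  = SS_total - SS_within

    df_among = P - 1,  df_within = N - P
    sigma2_w = SS_within / df_within
    n_bar    = (N - sum_p n_p^2 / N) / (P - 1)
    sigma2_a = (SS_among / df_among - sigma2_w) / n_bar
    Phi_ST   = sigma2_a / (sigma2_a + sigma2_w)

Significance is assessed by permuting individuals across populations while
holding group sizes fixed; the p-value uses the add-one estimator
``p = (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm)``, which never returns an
exact zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import DistanceMatrix, hamming_matrix  # re-exported surface
from .errors import BoundsError, MetadataError

__all__ = [
    "AmovaResult",
    "DistanceMatrix",
    "hamming_matrix",
    "amova_one_level",
]


@dataclass
class AmovaResult:
    """Sums of squares, variance components, Phi-statistic and permutation p."""

    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    degenerate: bool = False


def _group_indices(labels: Sequence[str]) -> list[np.ndarray]:
    order = list(dict.fromkeys(labels))
    arr = np.asarray(labels)
    return [np.flatnonzero(arr == g) for g in order]


def _ss_within(D: np.ndarray, groups: list[np.ndarray]) -> float:
    total = 0.0
    for idx in groups:
        if len(idx) > 1:
            total += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _phi(ss_among: float, ss_within: float, df_among: int, df_within: int,
         n_bar: float) -> tuple[float, float, float]:
    sigma2_w = ss_within / df_within if df_within > 0 else 0.0
    sigma2_a = (ss_among / df_among - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0 else 0.0
    return phi, sigma2_a, sigma2_w


def amova_one_level(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 1000,
    *,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA over the populations given by ``labels``.

    ``labels[i]`` assigns ``dist.ids[i]`` to a population.  Requires at least
    two populations, each non-empty, and more individuals than populations.
    ``seed`` is mandatory whenever ``n_perm > 0`` so permutation p-values are
    reproducible; ``n_perm=0`` skips the test (``p_value=None``).

    If every pairwise distance is zero the decomposition is degenerate; Phi
    is reported as 0 with ``degenerate=True`` rather than NaN.
    """
    N = len(dist)
    if len(labels) != N:
        raise MetadataError(
            f"{len(labels)} population labels for {N} individuals"
        )
    groups = _group_indices(labels)
    P = len(groups)
    if P < 2:
        raise MetadataError("AMOVA requires at least two populations")
    if any(len(g) == 0 for g in groups):
        raise MetadataError("AMOVA populations must be non-empty")
    if N <= P:
        raise MetadataError("AMOVA requires more individuals than populations")
    if n_perm < 0:
        raise BoundsError("n_perm must be >= 0")
    if n_perm > 0 and seed is None:
        raise MetadataError("seed is required when n_perm > 0")

    D = dist.D
    sizes = np.array([len(g) for g in groups], dtype=float)
    df_among, df_within = P - 1, N - P
    n_bar = (N - float(np.sum(sizes**2)) / N) / df_among

    ss_total = D.sum() / (2.0 * N)
    ss_within = _ss_within(D, groups)
    ss_among = ss_total - ss_within

    degenerate = ss_total == 0.0
    phi, s2a, s2w = _phi(ss_among, ss_within, df_among, df_within, n_bar)
    if degenerate:
        phi, s2a, s2w = 0.0, 0.0, 0.0

    total_var = s2a + s2w
    if total_var != 0:
        pct_among = 100.0 * s2a / total_var
        pct_within = 100.0 * s2w / total_var
    else:
        pct_among, pct_within = 0.0, 100.0

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        bounds = np.cumsum([len(g) for g in groups])[:-1]
        for _ in range(n_perm):
            perm = rng.permutation(N)
            pgroups = np.split(perm, bounds)
            pss_w = _ss_within(D, pgroups)
            pphi, _, _ = _phi(ss_total - pss_w, pss_w, df_among, df_within, n_bar)
            if pphi >= phi:
                hits += 1
        p_value = (1 + hits) / (1 + n_perm)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=N - 1,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=pct_among,
        pct_within=pct_within,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
        degenerate=degenerate,
    )


def amova_table(result: AmovaResult) -> "pd.DataFrame":
    """AMOVA result as a report table (Source / df / SS / Sigma 2 / %Variation / p)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Source": "Among populations",
                "df": result.df_among,
                "Sum of squares": round(result.ss_among, 3),
                "Sigma 2": round(result.sigma2_among, 3),
                "%Variation": round(result.pct_among, 5),
                "p Value": result.p_value,
            },
            {
                "Source": "Within populations",
                "df": result.df_within,
                "Sum of squares": round(result.ss_within, 3),
                "Sigma 2": round(result.sigma2_within, 3),
                "%Variation": round(result.pct_within, 5),
                "p Value": None,
            },
            {
                "Source": "Total",
                "df": result.df_total,
                "Sum of squares": round(result.ss_total, 3),
                "Sigma 2": None,
                "%Variation": None,
                "p Value": None,
            },
        ]
    )
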