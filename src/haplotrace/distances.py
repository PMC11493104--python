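"""Pairwise Hamming distances over aligned, unambiguous DNA sequences."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import AmbiguityError, BoundsError, DuplicateIdError
from .seqio import Alignment, UNAMBIGUOUS


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances keyed by sequence ids.

    Entries are substitution counts (integers) or proportions per site when
    built with ``normalize=True``.
    """

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise DuplicateIdError("distance matrix ids are not unique")
        if self.D.shape != (n, n):
            raise BoundsError(
                f"distance matrix shape {self.D.shape} does not match {n} ids"
            )
        if not np.allclose(self.D, self.D.T):
            raise BoundsError("distance matrix is not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise BoundsError("distance matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise BoundsError("distances must be non-negative")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(ids, self.D[np.ix_(idx, idx)])


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def hamming_matrix(aln: Alignment, normalize: bool = False) -> DistanceMatrix:
    """All-pairs Hamming distances for an unambiguous alignment.

    ``d[i, j]`` is the number of mismatching sites between sequences *i* and
    *j* (divided by the alignment length when ``normalize`` is set).
    Ambiguous characters violate the precondition and raise
    :class:`AmbiguityError` — filter first with
    :func:`haplotrace.seqio.filter_and_trim`.
    """
    bad = sorted(set("".join(aln.seqs)) - UNAMBIGUOUS)
    if bad:
        raise AmbiguityError(
            f"alignment contains ambiguous character(s) {bad}; "
            "apply filter_and_trim(drop_ambiguous=True) first"
        )
    enc = _encode(aln.seqs)
    n = len(aln)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        # broadcast row i against all later rows at once
        D[i, i + 1 :] = np.count_nonzero(enc[i + 1 :] != enc[i], axis=1)
    D = D + D.T
    if normalize:
        D = D / aln.L
    return DistanceMatrix(list(aln.ids), D)


def jukes_cantor(dist: DistanceMatrix) -> DistanceMatrix:
    """Jukes–Cantor correction of a normalized p-distance matrix.

    ``d = -(3/4) ln(1 - (4/3) p)``.  Input entries must be proportions
    < 0.75; substitution-count matrices should be normalized first.
    """
    P = dist.D
    if np.any(P >= 0.75):
        raise BoundsError(
            "Jukes-Cantor undefined for p >= 0.75; pass normalized p-distances"
        )
    return DistanceMatrix(list(dist.ids), -0.75 * np.log1p(-4.0 * P / 3.0))
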