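"""Barcode-marker divergence scoring from multi-species alignments.

p-distance (proportion of differing sites among compared positions) with
pairwise or complete gap deletion, variable-site counts excluding indel
columns, overall mean distance over all sequence pairs, and marker ranking.
N is treated as missing data, never as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

_ALPHABET = set("ACGTN-")


class UndefinedDistanceError(ValueError):
    """No comparable (ungapped, non-N) sites between two sequences."""


@dataclass
class MarkerAlignment:
    """One aligned marker: equal-length gapped sequences keyed by species."""

    marker: str
    sequences: dict[str, str]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError(f"{self.marker}: need >= 2 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.marker}: unequal aligned lengths {lengths}")
        for name, s in self.sequences.items():
            bad = set(s.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"{self.marker}/{name}: bad characters {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences.values()])


@dataclass(frozen=True)
class DivergenceRecord:
    marker: str
    aligned_length: int
    variable_sites: int
    mean_distance: float


def variable_sites(msa: MarkerAlignment) -> int:
    """Columns with >= 2 distinct bases, no gap in any sequence, N ignored."""
    m = msa.matrix()
    no_gap = ~(m == "-").any(axis=0)
    count = 0
    for j in np.flatnonzero(no_gap):
        bases = set(m[:, j]) - {"N"}
        if len(bases) >= 2:
            count += 1
    return count


def p_distance(a: str, b: str, deletion: str = "pairwise",
               exclude_columns=None) -> float:
    """Proportion of mismatches among comparable sites.

    ``pairwise`` deletion drops positions gapped or N in either sequence;
    ``complete`` additionally drops the columns listed in
    ``exclude_columns`` (positions gapped in any member of the full MSA,
    supplied by :func:`overall_mean_distance`).
    """
    if len(a) != len(b):
        raise ValueError("sequences have unequal aligned lengths")
    aa = np.array(list(a.upper()))
    bb = np.array(list(b.upper()))
    ok = ~np.isin(aa, ("-", "N")) & ~np.isin(bb, ("-", "N"))
    if deletion == "complete" and exclude_columns is not None:
        mask = np.ones(len(aa), dtype=bool)
        mask[list(exclude_columns)] = False
        ok &= mask
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites")
    return float((aa[ok] != bb[ok]).sum()) / n


def overall_mean_distance(msa: MarkerAlignment,
                          deletion: str = "pairwise") -> float:
    """Unweighted mean of all C(n,2) pairwise p-distances."""
    names = list(msa.sequences)
    exclude = None
    if deletion == "complete":
        m = msa.matrix()
        exclude = np.flatnonzero((m == "-").any(axis=0))
    dists = [p_distance(msa.sequences[x], msa.sequences[y],
                        deletion=deletion, exclude_columns=exclude)
             for x, y in combinations(names, 2)]
    return float(np.mean(dists))


def score_marker(msa: MarkerAlignment,
                 deletion: str = "pairwise") -> DivergenceRecord:
    return DivergenceRecord(
        marker=msa.marker,
        aligned_length=msa.length,
        variable_sites=variable_sites(msa),
        mean_distance=overall_mean_distance(msa, deletion=deletion),
    )


def rank_markers(records: list[DivergenceRecord]) -> list[DivergenceRecord]:
    """Stable sort by mean distance descending; ties broken by variable-site
    count (descending) then marker name."""
    return sorted(records, key=lambda r: (-r.mean_distance,
                                          -r.variable_sites, r.marker))
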