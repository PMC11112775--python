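"""Genetic map and local-ancestry tract primitives.

An admixed genome is represented as a mosaic of ancestry tracts on a genetic
map measured in Morgans.  Each haplotype of each chromosome is a sequence of
contiguous segments, each carrying a discrete label: either an ancestral
population (1 or 2) or, for identity-by-descent bookkeeping, the parental
haplotype of origin.  Tracts tile their chromosome exactly, so genome-wide
ancestry proportions are Morgan-weighted sums with no discretisation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GeneticMap", "HaplotypeTracts", "default_map", "ibd_state_fractions"]

# Sex-averaged autosomal genetic lengths (Morgans), approximately human,
# summing to ~35.4 M.
_AUTOSOME_MORGANS = (
    2.78, 2.63, 2.24, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81, 1.58,
    1.75, 1.26, 1.20, 1.42, 1.35, 1.30, 1.19, 1.08, 1.08, 0.62, 0.74,
)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered set of chromosomes with genetic lengths in Morgans."""

    chromosomes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genetic map must contain at least one chromosome")
        for name, length in self.chromosomes:
            if not length > 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([length for _, length in self.chromosomes])

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> float:
        """Total genetic length in Morgans."""
        return float(self.lengths.sum())


def default_map() -> GeneticMap:
    """22 autosomes with human-like lengths summing to ~35 Morgans."""
    return GeneticMap(tuple((str(i + 1), L) for i, L in enumerate(_AUTOSOME_MORGANS)))


def _simplify(ends: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length segments and merge adjacent segments with equal labels."""
    starts = np.concatenate([[0.0], ends[:-1]])
    keep = ends > starts
    ends, labels = ends[keep], labels[keep]
    if len(ends) > 1:
        # keep a segment only if its label differs from the next one's
        keep = np.concatenate([labels[:-1] != labels[1:], [True]])
        ends, labels = ends[keep], labels[keep]
    return ends, labels


@dataclass
class HaplotypeTracts:
    """Per-chromosome segment labels for one haplotype.

    ``ends[c]`` holds strictly increasing segment end positions (Morgans) for
    chromosome ``c``, with the final end equal to the chromosome length;
    segment ``i`` covers the half-open interval ``[ends[i-1], ends[i])``.
    ``labels[c]`` holds the matching integer labels.
    """

    ends: list[np.ndarray]
    labels: list[np.ndarray]

    @classmethod
    def uniform(cls, gmap: GeneticMap, label: int) -> "HaplotypeTracts":
        """A haplotype carrying a single label along the whole genome."""
        return cls(
            ends=[np.array([L]) for L in gmap.lengths],
            labels=[np.array([label], dtype=np.int8) for _ in gmap.lengths],
        )

    def validate(self, gmap: GeneticMap) -> None:
        if len(self.ends) != gmap.n_chromosomes:
            raise ValueError("tracts do not match the map's chromosome count")
        for c, L in enumerate(gmap.lengths):
            e = self.ends[c]
            if len(e) != len(self.labels[c]):
                raise ValueError(f"chromosome {c}: ends/labels length mismatch")
            if len(e) == 0:
                raise ValueError(f"chromosome {c}: empty tract set")
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"chromosome {c}: breakpoints not strictly increasing")
            if not np.isclose(e[-1], L):
                raise ValueError(f"chromosome {c}: tracts do not tile the chromosome")

    def label_fraction(self, gmap: GeneticMap, label: int) -> float:
        """Morgan-weighted genome fraction carrying ``label``."""
        total = 0.0
        for c in range(gmap.n_chromosomes):
            starts = np.concatenate([[0.0], self.ends[c][:-1]])
            seg = self.ends[c] - starts
            total += float(seg[self.labels[c] == label].sum())
        return total / gmap.total_length

    def labels_at(self, chrom: int, positions: np.ndarray) -> np.ndarray:
        """Labels at the given positions (Morgans) on one chromosome."""
        idx = np.searchsorted(self.ends[chrom], positions, side="right")
        idx = np.minimum(idx, len(self.ends[chrom]) - 1)
        return self.labels[chrom][idx]

    def n_breakpoints(self) -> int:
        """Number of internal label switches across the genome."""
        return sum(max(len(e) - 1, 0) for e in self.ends)


def _interval_labels(
    tracts: Sequence[HaplotypeTracts], chrom: int, merged_ends: np.ndarray
) -> list[np.ndarray]:
    """Evaluate each tract set's label on the merged partition of one chromosome."""
    mids = (merged_ends + np.concatenate([[0.0], merged_ends[:-1]])) / 2.0
    return [t.labels_at(chrom, mids) for t in tracts]


def ibd_state_fractions(
    sib1: tuple[HaplotypeTracts, HaplotypeTracts],
    sib2: tuple[HaplotypeTracts, HaplotypeTracts],
    gmap: GeneticMap,
) -> tuple[float, float, float]:
    """Exact genome fractions where two siblings share 0, 1 or 2 alleles IBD.

    Inputs are (paternal, maternal) gametes whose labels record the parental
    haplotype of origin (1 or 2).  At any position the siblings share the
    paternal allele IBD iff both paternal gametes carry the same origin label,
    and likewise for the maternal allele; the IBD state is the number of
    matches.  Fractions are computed by exact interval intersection, so they
    are Morgan-weighted with no grid discretisation.
    """
    pat1, mat1 = sib1
    pat2, mat2 = sib2
    shares = np.zeros(3)
    for c in range(gmap.n_chromosomes):
        merged = np.unique(
            np.concatenate([pat1.ends[c], mat1.ends[c], pat2.ends[c], mat2.ends[c]])
        )
        widths = merged - np.concatenate([[0.0], merged[:-1]])
        lp1, lm1, lp2, lm2 = _interval_labels((pat1, mat1, pat2, mat2), c, merged)
        state = (lp1 == lp2).astype(int) + (lm1 == lm2).astype(int)
        for m in range(3):
            shares[m] += widths[state == m].sum()
    shares /= gmap.total_length
    return float(shares[0]), float(shares[1]), float(shares[2])
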