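"""Genetic maps: chromosomes with marker positions in centimorgan."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng

__all__ = ["GeneticMap", "make_genetic_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions on one or more chromosomes.

    Markers are stored in a single flat order: grouped by chromosome, with
    strictly increasing positions within each chromosome.  All genotype and
    haplotype arrays in this package use this flat marker order.
    """

    chrom_ids: tuple[str, ...]
    chrom_lengths: tuple[float, ...]
    marker_ids: tuple[str, ...]
    marker_chrom: np.ndarray  # int index into chrom_ids, per marker
    positions_cm: np.ndarray  # float cM, per marker

    _chrom_slices: tuple[slice, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.chrom_ids) != len(self.chrom_lengths):
            raise ValueError("chrom_ids and chrom_lengths differ in length")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        n = len(self.marker_ids)
        if len(self.marker_chrom) != n or len(self.positions_cm) != n:
            raise ValueError("marker arrays differ in length")
        if len(set(self.marker_ids)) != n:
            raise ValueError("marker ids must be unique")
        slices = []
        start = 0
        for c, length in enumerate(self.chrom_lengths):
            idx = np.flatnonzero(self.marker_chrom == c)
            if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("markers must be grouped contiguously by chromosome")
            if idx.size:
                if idx[0] != start:
                    raise ValueError("chromosome blocks must appear in chromosome order")
                pos = self.positions_cm[idx]
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"positions not strictly increasing on {self.chrom_ids[c]}")
                if pos[0] < 0 or pos[-1] > length:
                    raise ValueError(f"marker position outside chromosome {self.chrom_ids[c]}")
                slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
                start = int(idx[-1]) + 1
            else:
                slices.append(slice(start, start))
        object.__setattr__(self, "_chrom_slices", tuple(slices))

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    def chrom_slice(self, c: int) -> slice:
        """Flat-index slice of the markers on chromosome ``c``."""
        return self._chrom_slices[c]


def make_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_cm: float,
    seed: int | np.random.Generator | None = None,
) -> GeneticMap:
    """Uniform-random marker placement on equally sized chromosomes.

    Positions are drawn i.i.d. uniform on ``[0, chrom_length_cm]`` and sorted
    within each chromosome; deterministic given ``seed``.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if markers_per_chrom < 2:
        raise ValueError("markers_per_chrom must be >= 2")
    if chrom_length_cm <= 0:
        raise ValueError("chrom_length_cm must be positive")
    rng = as_rng(seed)
    chrom_ids = tuple(f"chr{c + 1}" for c in range(n_chrom))
    marker_ids: list[str] = []
    marker_chrom = np.empty(n_chrom * markers_per_chrom, dtype=np.int64)
    positions = np.empty(n_chrom * markers_per_chrom, dtype=float)
    for c in range(n_chrom):
        pos = np.sort(rng.uniform(0.0, chrom_length_cm, size=markers_per_chrom))
        # nudge exact ties apart; uniform draws collide with probability ~0
        for i in range(1, markers_per_chrom):
            if pos[i] <= pos[i - 1]:
                pos[i] = np.nextafter(pos[i - 1], np.inf)
        sl = slice(c * markers_per_chrom, (c + 1) * markers_per_chrom)
        marker_chrom[sl] = c
        positions[sl] = pos
        marker_ids.extend(f"m{c + 1}_{i + 1}" for i in range(markers_per_chrom))
    return GeneticMap(
        chrom_ids=chrom_ids,
        chrom_lengths=tuple([float(chrom_length_cm)] * n_chrom),
        marker_ids=tuple(marker_ids),
        marker_chrom=marker_chrom,
        positions_cm=positions,
    )
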