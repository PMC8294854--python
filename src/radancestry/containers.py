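"""Core in-memory containers: diploid genotype panel and window grid.

A :class:`GenotypeTable` holds unphased diploid biallelic genotypes for a set
of samples, together with per-sample *callable coverage* intervals — the
regions (e.g. assembled RAD loci) where a sample has sequence data. Coverage
is what turns sparse SNP calls into per-site rates: invariant callable sites
count toward comparison denominators even though they never appear in a VCF.

Coordinates are 0-based half-open internally; the VCF parser boundary
converts from 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

from .errors import CoordinateError, IdentifierError
from .intervals import merge_intervals, total_length


@dataclass
class ChromGenotypes:
    """Genotypes at the biallelic variant sites of one chromosome.

    positions : int64 (n_sites,), 0-based, strictly increasing
    alleles   : int8 (n_samples, n_sites, 2); each pair sorted (0 before 1);
                (-1, -1) where the genotype is missing
    ref, alt  : per-site allele strings (kept for VCF round-trips)
    """

    positions: np.ndarray
    alleles: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_samples, n_sites, 2)")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions / alleles length mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise CoordinateError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class GenotypeTable:
    """Diploid biallelic genotype panel with per-sample callable coverage."""

    samples: Tuple[str, ...]
    data: Dict[str, ChromGenotypes]
    coverage: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = tuple(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise IdentifierError("duplicate sample names")
        for chrom, cg in self.data.items():
            if cg.alleles.shape[0] != len(self.samples):
                raise ValueError(f"{chrom}: allele matrix does not match sample count")
        # normalise coverage to merged sorted intervals
        self.coverage = {
            s: {c: merge_intervals(iv) for c, iv in per.items()}
            for s, per in self.coverage.items()
        }

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.data.keys())

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise IdentifierError(f"unknown sample {sample!r}") from None

    def sample_coverage(self, sample: str, chrom: str) -> np.ndarray:
        if sample not in self.samples:
            raise IdentifierError(f"unknown sample {sample!r}")
        return self.coverage.get(sample, {}).get(chrom, np.empty((0, 2), np.int64))

    def coverage_length(self, sample: str) -> int:
        return sum(total_length(iv) for iv in self.coverage.get(sample, {}).values())

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeTable":
        keep = list(keep)
        idx = [self.sample_index(s) for s in keep]
        data = {
            c: ChromGenotypes(cg.positions.copy(), cg.alleles[idx], cg.ref, cg.alt)
            for c, cg in self.data.items()
        }
        cov = {s: self.coverage[s] for s in keep if s in self.coverage}
        return GenotypeTable(tuple(keep), data, cov)


@dataclass(frozen=True)
class WindowGrid:
    """Tiling of chromosomes into fixed-size windows.

    Windows are nonoverlapping by default: window *i* of a chromosome of
    length L is ``[i*W, min((i+1)*W, L))``. A smaller ``step`` yields
    overlapping (sliding) windows of width ``window_size``.
    """

    chrom_lengths: Mapping[str, int]
    window_size: int = 100_000
    step: int | None = None

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.chrom_lengths.keys())

    def _step(self) -> int:
        return self.step if self.step is not None else self.window_size

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise CoordinateError(f"chromosome {chrom!r} not on grid") from None

    def n_windows(self, chrom: str) -> int:
        L = self.chrom_length(chrom)
        step = self._step()
        return max(0, -(-L // step))  # ceil

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of every window on a chromosome."""
        L = self.chrom_length(chrom)
        step = self._step()
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + self.window_size, L)
        return starts, ends

    def window_lengths(self, chrom: str) -> np.ndarray:
        starts, ends = self.window_bounds(chrom)
        return ends - starts
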