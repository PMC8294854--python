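"""Windowed pairwise divergence counting between diploid samples.

For each sample pair and genomic window we count

* ``k`` — the integer number of sequence differences between the pair, and
* ``n`` — the number of allele-sites for which both samples have data,
  i.e. twice the basepairs of the coverage intersection (two alleles per
  covered position; invariant callable positions contribute to ``n`` only).

Diploid comparison rule: each sample is represented by two pseudo-haplotypes
obtained by sorting the alleles at every site (0 before 1, phase being
unavailable in RAD data); hap1 is compared with hap1 and hap2 with hap2, and
``k`` is the summed differences. This keeps ``k`` an integer count out of
``n`` trials, so the ancestry HMM's binomial emissions are well-formed.
Sites where either sample lacks a genotype call but both are covered are
treated as equal (they add to ``n`` through coverage, never to ``k``).

The per-window rate ``k/n`` estimates nucleotide diversity π for
within-population pairs and absolute divergence d_XY for between-population
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GenotypeTable, WindowGrid
from .errors import CoordinateError, IdentifierError, InsufficientDataError
from .intervals import intersect_intervals, window_overlap

PairKey = Tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class PairWindowCounts:
    """Per-window difference counts (k) and compared allele-sites (n) for one pair."""

    pair: PairKey
    k: Dict[str, np.ndarray]
    n: Dict[str, np.ndarray]
    grid: WindowGrid

    def rate(self, chrom: str) -> np.ndarray:
        """Per-window k/n with NaN where n == 0 (no shared data)."""
        n = self.n[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.k[chrom] / n
        return np.where(n > 0, r, np.nan)

    def totals(self) -> Tuple[int, int]:
        K = sum(int(v.sum()) for v in self.k.values())
        N = sum(int(v.sum()) for v in self.n.values())
        return K, N

    def genome_rate(self) -> float:
        K, N = self.totals()
        return K / N if N > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        a, b = self.pair
        for chrom in self.k:
            starts, ends = self.grid.window_bounds(chrom)
            n = self.n[chrom]
            k = self.k[chrom]
            rate = self.rate(chrom)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "window_start": starts,
                        "window_end": ends,
                        "sampleA": a,
                        "sampleB": b,
                        "k": k,
                        "n": n,
                        "rate": rate,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _site_differences(cg, ia: int, ib: int) -> np.ndarray:
    """Per-site integer differences under sorted pseudo-haplotype pairing."""
    a = cg.alleles[ia]
    b = cg.alleles[ib]
    both = (a[:, 0] >= 0) & (b[:, 0] >= 0)
    d = (a[:, 0] != b[:, 0]).astype(np.int64) + (a[:, 1] != b[:, 1])
    d[~both] = 0  # missing genotype with shared coverage counts as equal
    return d


def count_pair_differences(
    table: GenotypeTable, pair: Sequence[str], grid: WindowGrid
) -> PairWindowCounts:
    """Count per-window (k, n) between two diploid samples."""
    a, b = pair
    ia, ib = table.sample_index(a), table.sample_index(b)
    for chrom in table.chroms:
        if chrom not in grid.chrom_lengths:
            raise CoordinateError(f"genotype chromosome {chrom!r} missing from grid")
    k: Dict[str, np.ndarray] = {}
    n: Dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        starts, ends = grid.window_bounds(chrom)
        shared = intersect_intervals(
            table.sample_coverage(a, chrom), table.sample_coverage(b, chrom)
        )
        n[chrom] = 2 * window_overlap(shared, starts, ends)
        if chrom in table.data and table.data[chrom].n_sites:
            cg = table.data[chrom]
            d = _site_differences(cg, ia, ib)
            cum = np.concatenate([[0], np.cumsum(d)])
            lo = np.searchsorted(cg.positions, starts, side="left")
            hi = np.searchsorted(cg.positions, ends, side="left")
            k[chrom] = cum[hi] - cum[lo]
        else:
            k[chrom] = np.zeros(len(starts), dtype=np.int64)
        if np.any(k[chrom] > n[chrom]):
            raise CoordinateError(
                f"{a}/{b} {chrom}: more differences than compared sites; "
                "genotypes fall outside declared coverage"
            )
    return PairWindowCounts(pair_key(a, b), k, n, grid)


def count_all_pairs(
    table: GenotypeTable,
    grid: WindowGrid,
    pairs: Iterable[Sequence[str]] | None = None,
) -> Dict[PairKey, PairWindowCounts]:
    """Counts for a set of pairs (all sample pairs when ``pairs`` is None)."""
    if pairs is None:
        pairs = combinations(table.samples, 2)
    out: Dict[PairKey, PairWindowCounts] = {}
    for p in pairs:
        key = pair_key(*p)
        if key not in out:
            out[key] = count_pair_differences(table, key, grid)
    return out


@dataclass
class WindowedDiversity:
    """Windowed π / d_XY tables plus coverage-weighted genome-wide values."""

    pi: pd.DataFrame  # chrom, window_start, window_end, population, pi
    dxy: pd.DataFrame  # chrom, window_start, window_end, pop_a, pop_b, dxy
    genome_pi: Dict[str, float]
    genome_dxy: Dict[Tuple[str, str], float]


def _mean_pair_rates(counts_list, chrom, n_windows):
    """Mean over pairs of per-window rates, ignoring pairs with n=0 there."""
    rates = np.full((len(counts_list), n_windows), np.nan)
    for i, c in enumerate(counts_list):
        rates[i] = c.rate(chrom)
    have = (~np.isnan(rates)).sum(axis=0)
    total = np.nansum(rates, axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(have > 0, total / np.maximum(have, 1), np.nan)


def windowed_pi_dxy(
    counts: Mapping[PairKey, PairWindowCounts],
    popmap: Mapping[str, str],
    grid: WindowGrid | None = None,
) -> WindowedDiversity:
    """Windowed nucleotide diversity and divergence from pair counts.

    π(window, pop) is the mean of k/n over within-population pairs (pairs
    with no shared data in a window are excluded); d_XY(window, A, B) the
    mean over between-population pairs. Genome-wide values are
    coverage-weighted: Σk/Σn per pair, then averaged over pairs.
    """
    if grid is None:
        grid = next(iter(counts.values())).grid
    pops: Dict[str, list] = {}
    for s, p in popmap.items():
        pops.setdefault(p, []).append(s)

    within: Dict[str, list] = {p: [] for p in pops}
    between: Dict[Tuple[str, str], list] = {}
    for (a, b), c in counts.items():
        pa, pb = popmap.get(a), popmap.get(b)
        if pa is None or pb is None:
            continue
        if pa == pb:
            within[pa].append(c)
        else:
            key = tuple(sorted((pa, pb)))
            between.setdefault(key, []).append(c)

    pi_rows, dxy_rows = [], []
    for pop, lst in within.items():
        if len(pops[pop]) < 2:
            raise InsufficientDataError(
                f"population {pop!r} has <2 samples; pi undefined"
            )
        for chrom in grid.chroms:
            starts, ends = grid.window_bounds(chrom)
            pi_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "window_start": starts,
                        "window_end": ends,
                        "population": pop,
                        "pi": _mean_pair_rates(lst, chrom, len(starts)),
                    }
                )
            )
    for (pa, pb), lst in between.items():
        for chrom in grid.chroms:
            starts, ends = grid.window_bounds(chrom)
            dxy_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "window_start": starts,
                        "window_end": ends,
                        "pop_a": pa,
                        "pop_b": pb,
                        "dxy": _mean_pair_rates(lst, chrom, len(starts)),
                    }
                )
            )

    genome_pi = {
        pop: float(np.mean([c.genome_rate() for c in lst])) if lst else float("nan")
        for pop, lst in within.items()
    }
    genome_dxy = {
        key: float(np.mean([c.genome_rate() for c in lst]))
        for key, lst in between.items()
    }
    empty_pi = pd.DataFrame(
        columns=["chrom", "window_start", "window_end", "population", "pi"]
    )
    empty_dxy = pd.DataFrame(
        columns=["chrom", "window_start", "window_end", "pop_a", "pop_b", "dxy"]
    )
    return WindowedDiversity(
        pi=pd.concat(pi_rows, ignore_index=True) if pi_rows else empty_pi,
        dxy=pd.concat(dxy_rows, ignore_index=True) if dxy_rows else empty_dxy,
        genome_pi=genome_pi,
        genome_dxy=genome_dxy,
    )


def distance_matrix(counts: Mapping[PairKey, PairWindowCounts]) -> pd.DataFrame:
    """Genome-wide per-site difference-rate matrix (Σk/Σn per pair).

    Symmetric with a zero diagonal; a pair with no shared data anywhere is
    NaN (flagged missing, never silently 0).
    """
    samples = sorted({s for key in counts for s in key})
    mat = pd.DataFrame(np.zeros((len(samples), len(samples))), index=samples, columns=samples)
    for a, b in combinations(samples, 2):
        key = pair_key(a, b)
        if key not in counts:
            raise IdentifierError(f"pair {key} missing from counts")
        r = counts[key].genome_rate()
        mat.loc[a, b] = r
        mat.loc[b, a] = r
    return mat


def write_counts_tsv(counts: Mapping[PairKey, PairWindowCounts], path) -> None:
    frames = [c.to_frame() for c in counts.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, grid: WindowGrid) -> Dict[PairKey, PairWindowCounts]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[PairKey, PairWindowCounts] = {}
    for (a, b), sub in df.groupby(["sampleA", "sampleB"]):
        k, n = {}, {}
        for chrom in grid.chroms:
            starts, _ = grid.window_bounds(chrom)
            rows = sub[sub["chrom"] == chrom].set_index("window_start")
            k[chrom] = rows["k"].reindex(starts, fill_value=0).to_numpy(np.int64)
            n[chrom] = rows["n"].reindex(starts, fill_value=0).to_numpy(np.int64)
        out[pair_key(a, b)] = PairWindowCounts(pair_key(a, b), k, n, grid)
    return out
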