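"""Ancestry blocks: extraction, admixture proportions, shared breakpoints, age.

A block is a maximal run of consecutive windows assigned the same donor
(SRC) or heterozygous (HET) ancestry state. Interior runs of MISSING windows
flanked by the same state are bridged into the block (the equivalent of
ghost-shading data gaps from their neighbours); a MISSING run between two
different states belongs to no block. Coordinates snap to window boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import WindowGrid
from .errors import DomainError, InsufficientDataError
from .hmm import HET, MISSING, NAT, SRC, STATE_NAMES, AncestryPath


@dataclass
class AncestryBlock:
    individual: str
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    state: int  # SRC or HET
    n_windows: int
    n_missing_bridged: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]


def _runs(states: np.ndarray):
    """Run-length encode: list of (state, first_idx, last_idx_exclusive)."""
    runs = []
    i = 0
    L = len(states)
    while i < L:
        j = i
        while j < L and states[j] == states[i]:
            j += 1
        runs.append((int(states[i]), i, j))
        i = j
    return runs


def extract_blocks(path: AncestryPath, grid: WindowGrid) -> List[AncestryBlock]:
    """SRC/HET blocks of one decoded chromosome, bridging interior gaps."""
    starts, ends = grid.window_bounds(path.chrom)
    if len(path.states) != len(starts):
        raise InsufficientDataError(
            f"path length {len(path.states)} does not match grid "
            f"({len(starts)} windows on {path.chrom})"
        )
    runs = _runs(path.states)
    blocks: List[AncestryBlock] = []
    i = 0
    while i < len(runs):
        state, a, b = runs[i]
        if state in (SRC, HET):
            n_windows = b - a
            bridged = 0
            last = b
            j = i
            # bridge MISSING runs flanked by the same state
            while (
                j + 2 < len(runs)
                and runs[j + 1][0] == MISSING
                and runs[j + 2][0] == state
            ):
                bridged += runs[j + 1][2] - runs[j + 1][1]
                j += 2
                n_windows += runs[j][2] - runs[j][1]
                last = runs[j][2]
            blocks.append(
                AncestryBlock(
                    individual=path.individual,
                    chrom=path.chrom,
                    start=int(starts[a]),
                    end=int(ends[last - 1]),
                    state=state,
                    n_windows=n_windows,
                    n_missing_bridged=bridged,
                )
            )
            i = j + 1
        else:
            i += 1
    return blocks


def extract_all_blocks(
    paths: Mapping[str, Mapping[str, AncestryPath]] | Mapping[str, AncestryPath],
    grid: WindowGrid,
) -> List[AncestryBlock]:
    """Blocks for {individual: {chrom: path}} or {chrom: path} mappings."""
    blocks: List[AncestryBlock] = []
    for v in paths.values():
        if isinstance(v, AncestryPath):
            blocks.extend(extract_blocks(v, grid))
        else:
            for p in v.values():
                blocks.extend(extract_blocks(p, grid))
    return blocks


def admixture_proportion(
    paths: Mapping[str, AncestryPath] | Iterable[AncestryPath], grid: WindowGrid
) -> float:
    """Donor-genome fraction of one individual.

    (Σ SRC window bp + 0.5 × Σ HET window bp) / Σ non-MISSING window bp — the
    0.5 weight is diploid dosage: a heterozygous-ancestry window carries one
    donor haplotype out of two.
    """
    if isinstance(paths, Mapping):
        paths = paths.values()
    num = 0.0
    den = 0.0
    for p in paths:
        wl = grid.window_lengths(p.chrom)
        if len(p.states) != len(wl):
            raise InsufficientDataError("path does not match grid")
        s = p.states
        num += wl[s == SRC].sum() + 0.5 * wl[s == HET].sum()
        den += wl[s != MISSING].sum()
    if den == 0:
        raise InsufficientDataError("all windows missing; admixture proportion undefined")
    return float(num / den)


def shared_breakpoints(
    blocks: Sequence[AncestryBlock],
    window_size: int,
    tolerance: int = 1,
) -> List[List[str]]:
    """Group block carriers whose block start AND end match within tolerance.

    ``tolerance`` is in windows (default 1, the HMM's resolution). Two blocks
    match when both boundaries differ by at most tolerance × window_size;
    groups are the connected components of this pairwise relation. Returns
    lists of individual names, largest group first.
    """
    n = len(blocks)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tol = tolerance * window_size
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = blocks[i], blocks[j]
            if bi.chrom != bj.chrom or bi.state != bj.state:
                continue
            if abs(bi.start - bj.start) <= tol and abs(bi.end - bj.end) <= tol:
                parent[find(i)] = find(j)
    groups: Dict[int, List[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(blocks[i].individual)
    return sorted(groups.values(), key=len, reverse=True)


def estimate_block_age(x: float, c: float) -> float:
    """Generations since introgression from the surviving block fraction.

    Under proportional erosion, an initially chromosome-spanning donor tract
    retains fraction x(t) = (1 - c)^t after t generations, where c is the
    per-generation proportional loss to recombination. Inverting,

        t = ln(x) / ln(1 - c),

    which is 0 at x = 1 and strictly decreasing in x.
    """
    if not (0.0 < x <= 1.0):
        raise DomainError(f"block fraction x must be in (0, 1], got {x}")
    if not (0.0 < c < 1.0):
        raise DomainError(f"erosion rate c must be in (0, 1), got {c}")
    return math.log(x) / math.log(1.0 - c)


def erosion_rate(r_bp: float, chrom_length_bp: float, kappa: float = 1.0) -> float:
    """Per-generation proportional erosion rate c = r_bp × L × κ.

    r_bp is the per-bp per-generation recombination rate, L the chromosome
    length; κ rescales for map heterogeneity. Clipped away from 1.
    """
    c = r_bp * chrom_length_bp * kappa
    if c <= 0:
        raise DomainError("erosion rate must be positive")
    return min(c, 1.0 - 1e-12)


def blocks_to_bed(blocks: Sequence[AncestryBlock]) -> pd.DataFrame:
    """6-column BED-style frame (name=individual, score=n_missing_bridged)."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "individual": [b.individual for b in blocks],
            "state": [b.state_name for b in blocks],
            "n_missing_bridged": [b.n_missing_bridged for b in blocks],
        }
    )


def summarize_blocks(
    paths: Mapping[str, Mapping[str, AncestryPath]], grid: WindowGrid
) -> pd.DataFrame:
    """Per-individual block count, mean length, and admixture proportion."""
    rows = []
    for ind, per_chrom in paths.items():
        blks = [b for p in per_chrom.values() for b in extract_blocks(p, grid)]
        lengths = [b.length for b in blks]
        rows.append(
            {
                "individual": ind,
                "n_blocks": len(blks),
                "mean_block_length_bp": float(np.mean(lengths)) if lengths else 0.0,
                "admixture_proportion": admixture_proportion(per_chrom, grid),
            }
        )
    return pd.DataFrame(rows)
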