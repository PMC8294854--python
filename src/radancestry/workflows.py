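"""End-to-end convenience workflow: counts -> HMM -> blocks -> mapping.

Glues the pipeline stages together for the common one-donor-panel design;
every stage remains available separately for custom analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .admixmap import genome_scan
from .blocks import AncestryBlock, extract_all_blocks, summarize_blocks
from .containers import GenotypeTable, WindowGrid
from .hmm import AncestryPath, TransitionModel, decode_population
from .pairdiv import PairKey, PairWindowCounts, count_all_pairs


@dataclass
class AncestryAnalysis:
    counts: Dict[PairKey, PairWindowCounts]
    paths: Dict[str, Dict[str, AncestryPath]]
    blocks: List[AncestryBlock]
    summary: pd.DataFrame
    scan: pd.DataFrame | None
    grid: WindowGrid


def analyze_panel(
    table: GenotypeTable,
    popmap: Mapping[str, str],
    focal_pop: str,
    donor_pop: str,
    window_size: int = 100_000,
    chrom_lengths: Mapping[str, int] | None = None,
    phenotypes: Mapping[str, int] | None = None,
    candidates: Sequence[Tuple[str, int, int]] | None = None,
    trans: TransitionModel | None = None,
    min_sites: int = 100,
    aggregate: str = "mean",
) -> AncestryAnalysis:
    """Count pair differences, decode ancestry, extract blocks, optionally scan.

    ``chrom_lengths`` defaults to the extent of the genotype data (last site
    rounded up to a whole window); pass the true lengths when known.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, cg in table.data.items():
            last = int(cg.positions[-1]) + 1 if cg.n_sites else window_size
            for per in table.coverage.values():
                if chrom in per and len(per[chrom]):
                    last = max(last, int(per[chrom][-1, 1]))
            chrom_lengths[chrom] = -(-last // window_size) * window_size
    grid = WindowGrid(chrom_lengths, window_size)

    focal = [s for s in table.samples if popmap.get(s) == focal_pop]
    donors = [s for s in table.samples if popmap.get(s) == donor_pop]
    pairs = list(combinations(donors, 2)) + [(f, d) for f in focal for d in donors]
    counts = count_all_pairs(table, grid, pairs)
    paths = decode_population(
        counts, focal, donors, focal, grid,
        trans=trans, min_sites=min_sites, aggregate=aggregate,
    )
    blocks = extract_all_blocks(paths, grid)
    summary = summarize_blocks(paths, grid)
    scan = None
    if phenotypes is not None:
        scan = genome_scan(paths, phenotypes, grid, candidates=candidates)
    return AncestryAnalysis(
        counts=counts, paths=paths, blocks=blocks, summary=summary, scan=scan, grid=grid
    )
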