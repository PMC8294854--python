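"""Admixture mapping: donor-ancestry carrier status vs. a binary phenotype.

Carrier status at a locus is dominance-coded by default: an individual whose
SRC (homozygous donor) or HET (heterozygous donor) block overlaps the locus
is a carrier, because one donor haplotype suffices to display the dominant
phenotype. Association is a chi-square test of independence on the 2x2
carrier x phenotype table, with the Yates continuity correction on by
default (small sample sizes are the norm in this design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .containers import WindowGrid
from .errors import CoordinateError, DegenerateTableError, InsufficientDataError
from .hmm import HET, MISSING, SRC, AncestryPath
from .blocks import AncestryBlock

NON_CARRIER, HET_CARRIER, HOM_CARRIER = "non-carrier", "het-carrier", "hom-carrier"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = carrier & phenotype+, b = non-carrier & phenotype+,
    c = carrier & phenotype-, d = non-carrier & phenotype-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p: float
    table: ContingencyTable2x2
    corrected: bool
    locus: tuple | None = None


def ancestry_phenotype_test(
    table: ContingencyTable2x2, correction: bool = True
) -> AssociationResult:
    """Chi-square test of independence on a 2x2 table (df = 1).

    With the Yates correction the statistic is
    N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), floored at 0 when
    |ad - bc| <= N/2; without it, N(ad - bc)^2 over the same margins.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise DegenerateTableError("zero row or column margin; test undefined")
    N = table.n
    det = abs(a * d - b * c)
    if correction:
        det = max(det - N / 2.0, 0.0)
    stat = N * det * det / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(stat, 1))
    return AssociationResult(chi2=float(stat), df=1, p=p, table=table, corrected=correction)


def carrier_status(
    blocks: Sequence[AncestryBlock],
    locus: Tuple[str, int, int],
    individuals: Sequence[str],
    grid: WindowGrid | None = None,
) -> Dict[str, str]:
    """Per-individual carrier status at a locus interval (half-open overlap).

    SRC block overlapping the locus => hom-carrier; otherwise HET block =>
    het-carrier; else non-carrier. For dominance-coded testing both carrier
    classes collapse to "carrier".
    """
    chrom, start, end = locus
    if grid is not None and chrom not in grid.chrom_lengths:
        raise CoordinateError(f"locus chromosome {chrom!r} not on grid")
    status = {ind: NON_CARRIER for ind in individuals}
    for blk in blocks:
        if blk.chrom != chrom or blk.individual not in status:
            continue
        if blk.start < end and start < blk.end:  # half-open overlap
            if blk.state == SRC:
                status[blk.individual] = HOM_CARRIER
            elif blk.state == HET and status[blk.individual] != HOM_CARRIER:
                status[blk.individual] = HET_CARRIER
    return status


def build_table(
    status: Mapping[str, str],
    phenotypes: Mapping[str, int],
    coding: str = "dominant",
) -> ContingencyTable2x2:
    """Collapse carrier status and cross-tabulate against a 0/1 phenotype."""
    if coding not in ("dominant", "dosage"):
        raise ValueError("coding must be 'dominant' or 'dosage'")
    a = b = c = d = 0
    for ind, st in status.items():
        if ind not in phenotypes:
            continue
        if coding == "dominant":
            carrier = st != NON_CARRIER
        else:  # dosage collapses hom only; het counts half -> not a 2x2, so
            # dosage coding here means hom-carriers only
            carrier = st == HOM_CARRIER
        phen = int(phenotypes[ind])
        if carrier and phen:
            a += 1
        elif not carrier and phen:
            b += 1
        elif carrier:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def test_locus(
    blocks: Sequence[AncestryBlock],
    locus: Tuple[str, int, int],
    phenotypes: Mapping[str, int],
    individuals: Sequence[str] | None = None,
    correction: bool = True,
    grid: WindowGrid | None = None,
) -> AssociationResult:
    """Carrier status at a locus -> 2x2 table -> chi-square test."""
    if individuals is None:
        individuals = sorted(phenotypes)
    status = carrier_status(blocks, locus, individuals, grid=grid)
    res = ancestry_phenotype_test(build_table(status, phenotypes), correction)
    res.locus = locus
    return res


def genome_scan(
    paths: Mapping[str, Mapping[str, AncestryPath]],
    phenotypes: Mapping[str, int],
    grid: WindowGrid,
    candidates: Sequence[Tuple[str, int, int]] | None = None,
    correction: bool = True,
) -> pd.DataFrame:
    """Window-by-window ancestry/phenotype association scan.

    Tests every window with at least one carrier and one non-carrier among
    phenotyped individuals (individuals MISSING in a window are excluded from
    its table; windows whose sub-table has a zero phenotype margin are
    skipped). Reports the raw p and Benjamini-Hochberg q per scan, and flags
    windows overlapping supplied candidate loci.
    """
    inds = [i for i in paths if i in phenotypes]
    if len(inds) == 0:
        raise InsufficientDataError("no phenotyped individuals with ancestry paths")
    phen = np.array([int(phenotypes[i]) for i in inds])
    if phen.min() == phen.max():
        raise InsufficientDataError("constant phenotype; association undefined")

    rows: List[dict] = []
    for chrom in grid.chroms:
        starts, ends = grid.window_bounds(chrom)
        L = len(starts)
        states = np.full((len(inds), L), MISSING, dtype=np.int8)
        for r, ind in enumerate(inds):
            p = paths[ind].get(chrom)
            if p is not None:
                states[r] = p.states
        carrier = (states == SRC) | (states == HET)
        called = states != MISSING
        for w in range(L):
            ok = called[:, w]
            if not ok.any():
                continue
            cw = carrier[ok, w]
            pw = phen[ok]
            a = int(np.sum(cw & (pw == 1)))
            b = int(np.sum(~cw & (pw == 1)))
            c = int(np.sum(cw & (pw == 0)))
            d = int(np.sum(~cw & (pw == 0)))
            if (a + c) == 0 or (b + d) == 0:  # need >=1 carrier and non-carrier
                continue
            if (a + b) == 0 or (c + d) == 0:  # degenerate phenotype margin here
                continue
            res = ancestry_phenotype_test(ContingencyTable2x2(a, b, c, d), correction)
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": int(starts[w]),
                    "window_end": int(ends[w]),
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "chi2": res.chi2,
                    "p": res.p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        cand = np.zeros(len(df), dtype=bool)
        if candidates:
            for chrom, s, e in candidates:
                cand |= (
                    (df["chrom"] == chrom)
                    & (df["window_start"] < e)
                    & (df["window_end"] > s)
                ).to_numpy()
        df["candidate"] = cand
    else:
        df = pd.DataFrame(
            columns=[
                "chrom", "window_start", "window_end",
                "a", "b", "c", "d", "chi2", "p", "q", "candidate",
            ]
        )
    return df
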