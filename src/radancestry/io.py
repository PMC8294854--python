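"""Readers and writers for the standard text formats the pipeline consumes.

VCF parsing goes through cyvcf2; only biallelic SNPs are kept (multi-allelic
and indel records are dropped with a logged count, as the binomial emission
model assumes biallelic per-site rates). Coverage is BED: either one file per
sample or a single 4-column BED whose name field is the sample. Population
maps and phenotypes are simple TSVs. VCF positions are 1-based at the parser
boundary; everything internal is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import ChromGenotypes, GenotypeTable
from .intervals import in_intervals, merge_intervals

logger = logging.getLogger(__name__)


def read_vcf(path) -> GenotypeTable:
    """Load diploid biallelic genotypes from a plain or bgzipped VCF."""
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    per_chrom: Dict[str, dict] = {}
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        rec = per_chrom.setdefault(v.CHROM, {"pos": [], "gt": [], "ref": [], "alt": []})
        rec["pos"].append(v.POS - 1)  # to 0-based
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int8)
        gts[np.any(gts < 0, axis=1)] = -1
        rec["gt"].append(np.sort(gts, axis=1))
        rec["ref"].append(v.REF)
        rec["alt"].append(v.ALT[0])
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records", n_dropped)
    data = {}
    for chrom, rec in per_chrom.items():
        alleles = np.stack(rec["gt"], axis=1) if rec["gt"] else np.empty((len(samples), 0, 2), np.int8)
        data[chrom] = ChromGenotypes(
            positions=np.array(rec["pos"], dtype=np.int64),
            alleles=alleles,
            ref=np.array(rec["ref"], dtype=object),
            alt=np.array(rec["alt"], dtype=object),
        )
    return GenotypeTable(samples=samples, data=data)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write the panel as an uncompressed VCF (sorted genotype pairs, unphased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in table.data:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for chrom, cg in table.data.items():
            ref = cg.ref if cg.ref is not None else np.full(cg.n_sites, "A", object)
            alt = cg.alt if cg.alt is not None else np.full(cg.n_sites, "T", object)
            for i, pos in enumerate(cg.positions):
                gts = []
                for s in range(len(table.samples)):
                    a, b = cg.alleles[s, i]
                    gts.append("./." if a < 0 else f"{a}/{b}")
                fh.write(
                    f"{chrom}\t{pos + 1}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


def read_coverage_bed(path, sample_column: bool = True) -> Dict[str, Dict[str, np.ndarray]]:
    """4-column BED (chrom, start, end, sample) -> per-sample interval sets."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "sample"][: 4 if sample_column else 3],
        comment="#",
    )
    out: Dict[str, Dict[str, list]] = {}
    if not sample_column:
        df["sample"] = "*"
    for (sample, chrom), sub in df.groupby(["sample", "chrom"]):
        out.setdefault(sample, {})[chrom] = sub[["start", "end"]].to_numpy(np.int64)
    return {
        s: {c: merge_intervals(iv) for c, iv in per.items()} for s, per in out.items()
    }


def write_coverage_bed(coverage: Mapping[str, Mapping[str, np.ndarray]], path) -> None:
    with open(path, "w") as fh:
        for sample in sorted(coverage):
            for chrom in sorted(coverage[sample]):
                for s, e in coverage[sample][chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{sample}\n")


def apply_coverage_mask(table: GenotypeTable) -> int:
    """Set genotypes lying outside the sample's own coverage to missing.

    Enforces the container invariant when VCF and BED come from independent
    sources. Returns the number of genotype calls masked.
    """
    masked = 0
    for chrom, cg in table.data.items():
        for si, sample in enumerate(table.samples):
            cov = table.sample_coverage(sample, chrom)
            called = cg.alleles[si, :, 0] >= 0
            outside = called & ~in_intervals(cov, cg.positions)
            if outside.any():
                cg.alleles[si, outside] = -1
                masked += int(outside.sum())
    return masked


def read_popmap(path) -> pd.DataFrame:
    """TSV ``sample<TAB>population<TAB>species`` -> DataFrame indexed by sample."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "population", "species"],
        comment="#",
    )
    return df.set_index("sample")


def popmap_to_dict(popmap: pd.DataFrame) -> Dict[str, str]:
    return popmap["population"].to_dict()


def read_phenotypes(path) -> Dict[str, int]:
    """TSV ``individual<TAB>phenotype(0/1)``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "phenotype"],
                     comment="#")
    return {str(r.individual): int(r.phenotype) for r in df.itertuples()}


def read_bed_intervals(path) -> Dict[str, np.ndarray]:
    """Plain 3+-column BED -> {chrom: merged (m, 2) intervals}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: Dict[str, list] = {}
    for chrom, sub in df.groupby(0):
        out[str(chrom)] = sub[[1, 2]].to_numpy(np.int64)
    return {c: merge_intervals(iv) for c, iv in out.items()}


def write_bed_intervals(
    intervals: Mapping[str, np.ndarray], path, names: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for row in intervals[chrom]:
                fh.write(f"{chrom}\t{row[0]}\t{row[1]}\n")


def write_paths_tsv(paths, grid, path) -> None:
    """Decoded states as TSV ``individual chrom window_start window_end state``."""
    rows = []
    for ind, per_chrom in paths.items():
        for chrom, p in per_chrom.items():
            starts, ends = grid.window_bounds(chrom)
            for s, e, st in zip(starts, ends, p.state_names()):
                rows.append((ind, chrom, s, e, st))
    pd.DataFrame(
        rows, columns=["individual", "chrom", "window_start", "window_end", "state"]
    ).to_csv(path, sep="\t", index=False)
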