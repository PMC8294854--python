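"""Synthetic two-species RAD-like diploid panels with planted donor tracts.

The generator emulates the structure of a double-digest RAD dataset from a
recently admixed pair of diverged populations: ~12 chromosomes, short
sequenced loci sparsely tiled along each chromosome, per-sample locus
dropout, two populations (a donor species panel and a native focal
population) whose within-population diversities and between-population
divergence are set directly, Mb-scale donor-ancestry tracts planted into
chosen focal individuals, and a dominance-coded binary phenotype controlled
by donor ancestry at a causal locus. Full ground truth is returned for
recovery testing.

Mutation model (star-like, no coalescent): a single root sequence receives
species-ancestor mutations at rate (d - (pi_src + pi_nat)/2) / 2 per branch,
fixed within each species, and each haplotype then receives private
mutations at rate pi_pop / 2. First moments follow: the expected per-site
difference rate between two haplotypes of one population is pi_pop, and
between species it is d. Planted donor tracts replace a focal haplotype
segment with a freshly drawn donor haplotype (species-ancestor donor alleles
plus fresh private mutations at the donor rate). Mutations are placed on
integer positions inside the locus footprint without recurrence.

An optional ``ancestral_poly_rate`` plants unlinked shared polymorphism
(every ingroup haplotype carries the alternate allele independently with a
per-site random frequency). It is off by default so the stated moments hold
exactly; turn it on to give four-taxon site-pattern statistics a nonzero
ABBA+BABA denominator in no-gene-flow scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .containers import ChromGenotypes, GenotypeTable, WindowGrid
from .errors import ConfigError, GridMismatchError
from .hmm import HET, MISSING, SRC, AncestryPath
from .intervals import merge_intervals, window_overlap

DEFAULT_CHROMS = {f"chr{i:02d}": 5_000_000 for i in range(1, 13)}


@dataclass(frozen=True)
class Tract:
    """A planted donor-ancestry segment in one focal individual."""

    chrom: str
    start: int
    length: int
    zygosity: str = "hom"  # 'het': one haplotype replaced; 'hom': both

    def __post_init__(self):
        if self.length <= 0 or self.start < 0:
            raise ConfigError("tract must have positive length and start >= 0")
        if self.zygosity not in ("het", "hom"):
            raise ConfigError("zygosity must be 'het' or 'hom'")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimConfig:
    """Generator parameters. ``seed`` is mandatory; all draws derive from it.

    Defaults follow the study conditions this generator emulates: donor
    within-population diversity pi_src = 4.5e-4 and native pi_nat = 2.3e-4
    (per-site), between-species divergence d = 2.3e-3, 100 kb analysis
    windows, ~200 bp RAD loci at a mean spacing of 3 kb (~20k loci across a
    12 x 5 Mb genome) with 20% per-sample locus dropout (80% completeness).
    """

    seed: int
    chrom_lengths: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    n_donor: int = 6
    n_focal: int = 6
    n_outgroup: int = 0
    pi_src: float = 4.5e-4
    pi_nat: float = 2.3e-4
    d_between: float = 2.3e-3
    tract_plan: Dict[str, List[Tract]] = field(default_factory=dict)
    tracts_per_individual: float = 0.0  # Poisson mean, used when tract_plan empty
    mean_tract_length: float = 1_500_000.0
    tract_zygosity: str = "hom"
    causal_locus: Tuple[str, int, int] | None = None
    locus_length: int = 200
    locus_spacing: int = 3000
    dropout: float = 0.2
    ancestral_poly_rate: float = 0.0

    def __post_init__(self):
        if not (0 < self.pi_src < 1 and 0 < self.pi_nat < 1):
            raise ConfigError("diversities must be in (0, 1)")
        if not (self.d_between > max(self.pi_src, self.pi_nat)):
            raise ConfigError("between-species divergence must exceed both diversities")
        if self.d_between <= (self.pi_src + self.pi_nat) / 2:
            raise ConfigError("d must exceed the mean of the diversities")
        if not (0 <= self.dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        if self.locus_length <= 0 or self.locus_spacing <= self.locus_length:
            raise ConfigError("need locus_spacing > locus_length > 0")
        if self.causal_locus is not None:
            chrom, s, e = self.causal_locus
            if chrom not in self.chrom_lengths or not (0 <= s < e <= self.chrom_lengths[chrom]):
                raise ConfigError("causal locus outside chromosomes")
        for ind, tracts in self.tract_plan.items():
            for t in tracts:
                if t.chrom not in self.chrom_lengths or t.end > self.chrom_lengths[t.chrom]:
                    raise ConfigError(f"tract {t} outside chromosome bounds")

    @property
    def donor_samples(self) -> List[str]:
        return [f"don{i + 1:02d}" for i in range(self.n_donor)]

    @property
    def focal_samples(self) -> List[str]:
        return [f"foc{i + 1:02d}" for i in range(self.n_focal)]

    @property
    def outgroup_samples(self) -> List[str]:
        return [f"out{i + 1:02d}" for i in range(self.n_outgroup)]

    def grid(self, window_size: int = 100_000) -> WindowGrid:
        return WindowGrid(self.chrom_lengths, window_size)


@dataclass
class TruthSet:
    """Ground truth: planted tracts, phenotypes, realized diversity."""

    tracts: Dict[str, List[Tract]]
    phenotypes: Dict[str, int]
    realized: Dict[str, float]

    def tract_intervals(self, individual: str, chrom: str) -> np.ndarray:
        iv = [
            (t.start, t.end)
            for t in self.tracts.get(individual, [])
            if t.chrom == chrom
        ]
        return merge_intervals(np.array(iv, dtype=np.int64).reshape(-1, 2))


@dataclass
class SimResult:
    table: GenotypeTable
    truth: TruthSet
    popmap: Dict[str, str]
    species: Dict[str, str]
    config: SimConfig


def _place_loci(L: int, locus_length: int, spacing: int, rng) -> np.ndarray:
    """RAD loci as disjoint [start, end) intervals with exponential gaps."""
    mean_gap = spacing - locus_length
    n_est = int(3 * L / spacing) + 10
    gaps = rng.exponential(mean_gap, size=n_est)
    starts = np.cumsum(gaps + locus_length) - locus_length
    starts = starts[starts + locus_length <= L].astype(np.int64)
    return np.column_stack([starts, starts + locus_length])


def _resolve_tracts(config: SimConfig, rng) -> Dict[str, List[Tract]]:
    if config.tract_plan:
        return {k: list(v) for k, v in config.tract_plan.items()}
    plan: Dict[str, List[Tract]] = {}
    if config.tracts_per_individual <= 0:
        return plan
    chroms = sorted(config.chrom_lengths)
    for ind in config.focal_samples:
        n = rng.poisson(config.tracts_per_individual)
        tracts = []
        for _ in range(n):
            chrom = chroms[rng.integers(len(chroms))]
            L = config.chrom_lengths[chrom]
            length = max(1, int(rng.exponential(config.mean_tract_length)))
            length = min(length, L)
            start = int(rng.integers(0, L - length + 1))
            tracts.append(Tract(chrom, start, length, config.tract_zygosity))
        if tracts:
            plan[ind] = tracts
    return plan


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate a full synthetic panel; reproducible byte-for-byte from seed."""
    rng = np.random.default_rng(config.seed)
    donors = config.donor_samples
    focals = config.focal_samples
    outgroups = config.outgroup_samples
    samples = donors + focals + outgroups
    n_donor_haps = 2 * len(donors)
    n_ingroup_haps = n_donor_haps + 2 * len(focals)
    n_haps = n_ingroup_haps + 2 * len(outgroups)

    tract_plan = _resolve_tracts(config, rng)
    rate_anc = (config.d_between - (config.pi_src + config.pi_nat) / 2.0) / 2.0

    data: Dict[str, ChromGenotypes] = {}
    coverage: Dict[str, Dict[str, np.ndarray]] = {s: {} for s in samples}
    # hap-frequency accumulators for realized diversity (non-tract focals)
    tractless = [
        f for f in focals if not tract_plan.get(f)
    ]
    acc = {
        "don_num": 0.0, "don_den": 0.0,
        "nat_num": 0.0, "nat_den": 0.0,
        "dxy_num": 0.0, "dxy_den": 0.0,
    }

    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        loci = _place_loci(L, config.locus_length, config.locus_spacing, rng)
        foot = np.concatenate([np.arange(s, e) for s, e in loci]) if len(loci) else np.zeros(0, np.int64)
        F = len(foot)

        # --- mutation counts per class, then one global no-recurrence draw
        n_fix_don = rng.binomial(F, rate_anc)
        n_fix_nat = rng.binomial(F, rate_anc)
        priv_rates = (
            [config.pi_src / 2.0] * n_donor_haps
            + [config.pi_nat / 2.0] * (2 * len(focals))
            + [0.0] * (2 * len(outgroups))
        )
        n_priv = [rng.binomial(F, r) if r > 0 else 0 for r in priv_rates]
        n_poly = rng.binomial(F, config.ancestral_poly_rate) if config.ancestral_poly_rate > 0 else 0
        total = n_fix_don + n_fix_nat + sum(n_priv) + n_poly
        used_idx = rng.choice(F, size=total, replace=False) if total else np.zeros(0, np.int64)
        avail = np.ones(F, dtype=bool)
        avail[used_idx] = False

        cursor = 0

        def take(n):
            nonlocal cursor
            out = used_idx[cursor : cursor + n]
            cursor += n
            return out

        fix_don_idx = take(n_fix_don)
        fix_nat_idx = take(n_fix_nat)
        priv_idx = [take(n) for n in n_priv]
        poly_idx = take(n_poly)
        poly_q = rng.uniform(0.05, 0.95, size=n_poly)

        # fresh donor privates for each tract-replaced haplotype
        tract_specs: List[Tuple[int, int, int, np.ndarray]] = []  # (hap_row, start, end, fresh idx)
        for ind, tracts in sorted(tract_plan.items()):
            si = samples.index(ind)
            for t in tracts:
                if t.chrom != chrom:
                    continue
                hap_offsets = (0,) if t.zygosity == "het" else (0, 1)
                for ho in hap_offsets:
                    in_tract = avail & (foot >= t.start) & (foot < t.end)
                    pool = np.flatnonzero(in_tract)
                    n_new = rng.binomial(len(pool), config.pi_src / 2.0)
                    chosen = rng.choice(pool, size=n_new, replace=False) if n_new else np.zeros(0, np.int64)
                    avail[chosen] = False
                    tract_specs.append((2 * si + ho, t.start, t.end, chosen))

        all_used = np.concatenate(
            [fix_don_idx, fix_nat_idx, *priv_idx, poly_idx]
            + [spec[3] for spec in tract_specs]
        )
        site_foot_idx = np.unique(all_used)
        pos = foot[site_foot_idx]
        order = np.argsort(pos)
        site_foot_idx = site_foot_idx[order]
        pos = pos[order]
        n_sites = len(pos)
        col_of = {int(fi): c for c, fi in enumerate(site_foot_idx)}

        def cols(idx_arr):
            return np.fromiter((col_of[int(i)] for i in idx_arr), dtype=np.int64, count=len(idx_arr))

        hap = np.zeros((n_haps, n_sites), dtype=np.int8)
        fd = cols(fix_don_idx)
        fn = cols(fix_nat_idx)
        hap[:n_donor_haps, fd] = 1
        hap[n_donor_haps:n_ingroup_haps, fn] = 1
        for h, idx_arr in enumerate(priv_idx):
            if len(idx_arr):
                hap[h, cols(idx_arr)] = 1
        if n_poly:
            pc = cols(poly_idx)
            draws = rng.random((n_ingroup_haps, n_poly)) < poly_q[None, :]
            hap[:n_ingroup_haps, pc] = draws.astype(np.int8)

        # realized-diversity accumulators (pre-tract; tracts only touch carriers)
        if len(donors) >= 2:
            j = hap[:n_donor_haps].sum(axis=0)
            H = n_donor_haps
            acc["don_num"] += float(np.sum(2.0 * j * (H - j) / (H * (H - 1))))
            acc["don_den"] += F
        nat_idx = [2 * samples.index(f) + o for f in tractless for o in (0, 1)]
        if len(nat_idx) >= 2:
            j = hap[nat_idx].sum(axis=0)
            H = len(nat_idx)
            acc["nat_num"] += float(np.sum(2.0 * j * (H - j) / (H * (H - 1))))
            acc["nat_den"] += F
        if len(donors) >= 1 and len(nat_idx) >= 1:
            p1 = hap[:n_donor_haps].mean(axis=0)
            p2 = hap[nat_idx].mean(axis=0)
            acc["dxy_num"] += float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)))
            acc["dxy_den"] += F

        # plant tracts: replace the segment with a fresh donor haplotype
        for hrow, t_start, t_end, fresh in tract_specs:
            lo = np.searchsorted(pos, t_start, side="left")
            hi = np.searchsorted(pos, t_end, side="left")
            hap[hrow, lo:hi] = 0
            seg = fd[(pos[fd] >= t_start) & (pos[fd] < t_end)]
            hap[hrow, seg] = 1
            if len(fresh):
                hap[hrow, cols(fresh)] = 1
            if n_poly:
                pc = cols(poly_idx)
                in_seg = (pos[pc] >= t_start) & (pos[pc] < t_end)
                if in_seg.any():
                    hap[hrow, pc[in_seg]] = (
                        rng.random(int(in_seg.sum())) < poly_q[in_seg]
                    ).astype(np.int8)

        # --- coverage: per-sample locus retention
        retained = rng.random((len(samples), len(loci))) >= config.dropout
        for si, s in enumerate(samples):
            coverage[s][chrom] = loci[retained[si]]

        # --- genotypes with dropout-driven missingness
        locus_of_site = np.searchsorted(loci[:, 0], pos, side="right") - 1
        alleles = np.empty((len(samples), n_sites, 2), dtype=np.int8)
        for si in range(len(samples)):
            pair = np.sort(np.stack([hap[2 * si], hap[2 * si + 1]], axis=1), axis=1)
            miss = ~retained[si][locus_of_site]
            pair[miss] = -1
            alleles[si] = pair

        # drop sites with no alternate allele among called genotypes
        called_alt = np.where(alleles >= 0, alleles, 0).sum(axis=(0, 2))
        any_called = np.any(alleles[:, :, 0] >= 0, axis=0)
        keep = (called_alt > 0) & any_called
        data[chrom] = ChromGenotypes(
            positions=pos[keep],
            alleles=alleles[:, keep, :],
            ref=np.full(int(keep.sum()), "A", dtype=object),
            alt=np.full(int(keep.sum()), "T", dtype=object),
        )

    realized = {
        "pi_src": acc["don_num"] / acc["don_den"] if acc["don_den"] else float("nan"),
        "pi_nat": acc["nat_num"] / acc["nat_den"] if acc["nat_den"] else float("nan"),
        "dxy": acc["dxy_num"] / acc["dxy_den"] if acc["dxy_den"] else float("nan"),
    }

    phenotypes = {}
    for f in focals:
        phen = 0
        if config.causal_locus is not None:
            chrom, s, e = config.causal_locus
            for t in tract_plan.get(f, []):
                if t.chrom == chrom and t.start < e and s < t.end:
                    phen = 1  # dominance: het or hom donor ancestry suffices
        phenotypes[f] = phen

    popmap = {s: "DONOR" for s in donors}
    popmap.update({s: "FOCAL" for s in focals})
    popmap.update({s: "OUTGROUP" for s in outgroups})
    species = {s: ("donor" if s in donors else "native" if s in focals else "outgroup") for s in samples}

    table = GenotypeTable(samples=tuple(samples), data=data, coverage=coverage)
    truth = TruthSet(tracts=tract_plan, phenotypes=phenotypes, realized=realized)
    return SimResult(table=table, truth=truth, popmap=popmap, species=species, config=config)


def mg114_scenario(seed: int) -> SimConfig:
    """Preset emulating a polymorphic admixed population.

    15 focal diploids and a 10-diploid donor panel on 12 x 5 Mb chromosomes.
    Six focal individuals carry a breakpoint-identical homozygous 1.6 Mb
    donor tract spanning the causal fruit-color locus on chr03, plus one
    private 0.6 Mb tract elsewhere, giving carriers an expected donor genome
    fraction of (1.6 + 0.6)/60 = 3.7%. Non-carriers have no donor ancestry
    and phenotype 0.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(DEFAULT_CHROMS)
    focals = [f"foc{i + 1:02d}" for i in range(15)]
    carriers = sorted(rng.choice(15, size=6, replace=False).tolist())
    shared = Tract("chr03", 1_900_000, 1_600_000, "hom")
    other_chroms = [c for c in sorted(chrom_lengths) if c != "chr03"]
    plan: Dict[str, List[Tract]] = {}
    for ci in carriers:
        chrom = other_chroms[rng.integers(len(other_chroms))]
        L = chrom_lengths[chrom]
        start = int(rng.integers(0, L - 600_000 + 1))
        plan[focals[ci]] = [shared, Tract(chrom, start, 600_000, "hom")]
    return SimConfig(
        seed=int(rng.integers(2**31 - 1)),
        chrom_lengths=chrom_lengths,
        n_donor=10,
        n_focal=15,
        tract_plan=plan,
        causal_locus=("chr03", 2_500_000, 2_510_000),
    )


@dataclass
class RecoveryReport:
    tp: int
    fp: int
    fn: int
    tn: int
    n_missing: int
    boundary_errors: List[float]

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")


def evaluate_recovery(
    truth: TruthSet,
    paths: Mapping[str, Mapping[str, AncestryPath]],
    grid: WindowGrid,
) -> RecoveryReport:
    """Window-level confusion matrix and per-tract boundary offsets.

    A window counts as truly introgressed when planted tracts (any zygosity)
    cover at least half of it. Predicted positive means a SRC or HET call;
    MISSING windows count as predicted-negative. Boundary offsets compare
    each tract's window-snapped span with the closest predicted block, in
    units of windows.
    """
    tp = fp = fn = tn = n_missing = 0
    boundary: List[float] = []
    W = grid.window_size
    from .blocks import extract_blocks

    for ind, per_chrom in paths.items():
        for chrom, path in per_chrom.items():
            starts, ends = grid.window_bounds(chrom)
            if len(path.states) != len(starts):
                raise GridMismatchError(
                    f"{ind}/{chrom}: path has {len(path.states)} windows, grid {len(starts)}"
                )
            iv = truth.tract_intervals(ind, chrom)
            ov = window_overlap(iv, starts, ends)
            true_pos = ov >= 0.5 * (ends - starts)
            pred_pos = (path.states == SRC) | (path.states == HET)
            n_missing += int(np.sum(path.states == MISSING))
            tp += int(np.sum(true_pos & pred_pos))
            fp += int(np.sum(~true_pos & pred_pos))
            fn += int(np.sum(true_pos & ~pred_pos))
            tn += int(np.sum(~true_pos & ~pred_pos))

            if true_pos.any():
                blks = extract_blocks(path, grid)
                # window-snapped spans of each contiguous truth run
                runs = []
                in_run = False
                for w, t in enumerate(true_pos):
                    if t and not in_run:
                        runs.append([w, w + 1])
                        in_run = True
                    elif t:
                        runs[-1][1] = w + 1
                        in_run = True
                    else:
                        in_run = False
                for w0, w1 in runs:
                    t_start, t_end = starts[w0], ends[w1 - 1]
                    best = None
                    for b in blks:
                        if b.start < t_end and t_start < b.end:
                            err = (abs(b.start - t_start) + abs(b.end - t_end)) / (2.0 * W)
                            best = err if best is None else min(best, err)
                    boundary.append(best if best is not None else float("inf"))
    return RecoveryReport(tp=tp, fp=fp, fn=fn, tn=tn, n_missing=n_missing, boundary_errors=boundary)


def write_dataset(result: SimResult, outdir) -> Dict[str, Path]:
    """Write VCF, coverage BED, truth BED, phenotype/popmap TSVs and a config echo."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "vcf": outdir / "genotypes.vcf",
        "coverage": outdir / "coverage.bed",
        "truth": outdir / "truth_tracts.bed",
        "phenotypes": outdir / "phenotypes.tsv",
        "popmap": outdir / "popmap.tsv",
        "config": outdir / "config.txt",
    }
    _io.write_vcf(result.table, files["vcf"])
    _io.write_coverage_bed(result.table.coverage, files["coverage"])
    with open(files["truth"], "w") as fh:
        for ind in sorted(result.truth.tracts):
            for t in result.truth.tracts[ind]:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{ind}\t{t.zygosity}\n")
    with open(files["phenotypes"], "w") as fh:
        for ind in sorted(result.truth.phenotypes):
            fh.write(f"{ind}\t{result.truth.phenotypes[ind]}\n")
    with open(files["popmap"], "w") as fh:
        for s in result.table.samples:
            fh.write(f"{s}\t{result.popmap[s]}\t{result.species[s]}\n")
    cfg = result.config
    with open(files["config"], "w") as fh:
        fh.write(f"seed={cfg.seed}\n")
        for k in ("n_donor", "n_focal", "n_outgroup", "pi_src", "pi_nat", "d_between",
                  "locus_length", "locus_spacing", "dropout", "ancestral_poly_rate"):
            fh.write(f"{k}={getattr(cfg, k)}\n")
        fh.write(f"chroms={','.join(f'{c}:{l}' for c, l in sorted(cfg.chrom_lengths.items()))}\n")
    return files
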