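"""Population-genetic summaries: S, Watterson's theta, pi, Tajima's D,
folded/projected site-frequency spectra with masking, SFS bootstrap,
four-taxon ABBA-BABA D with block bootstrap, and rescaling of
coalescent-unit demographic estimates into absolute units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

from .containers import GenotypeTable, WindowGrid
from .errors import DomainError, IdentifierError, InsufficientDataError
from .intervals import in_intervals, merge_intervals

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity summaries


@dataclass
class SiteStats:
    """Diversity summary for one sample set.

    Estimators use complete-case sites (every sample in the set called) so
    the sample size n is fixed; per-site values are the dataset-level numbers
    divided by ``seq_length`` when one is supplied. ``tajimas_d`` is NaN with
    ``tajd_defined=False`` when S = 0 — undefined, never silently 0.
    """

    S: int
    theta_w: float
    pi: float
    het_obs: float
    tajimas_d: float
    tajd_defined: bool
    n_haplotypes: int
    n_sites_used: int
    seq_length: int | None = None

    @property
    def theta_w_per_site(self) -> float:
        return self.theta_w / self.seq_length if self.seq_length else float("nan")

    @property
    def pi_per_site(self) -> float:
        return self.pi / self.seq_length if self.seq_length else float("nan")


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _pop_site_counts(table: GenotypeTable, samples: Sequence[str]):
    """(n, derived-count array j, het-genotype count array) over complete sites."""
    idx = [table.sample_index(s) for s in samples]
    n = 2 * len(idx)
    js: List[np.ndarray] = []
    hets: List[np.ndarray] = []
    for cg in table.data.values():
        al = cg.alleles[idx]  # (m, sites, 2)
        complete = np.all(al[:, :, 0] >= 0, axis=0)
        if not complete.any():
            continue
        sub = al[:, complete, :]
        js.append(sub.sum(axis=(0, 2)))
        hets.append((sub[:, :, 0] != sub[:, :, 1]).sum(axis=0))
    if js:
        return n, np.concatenate(js), np.concatenate(hets)
    return n, np.zeros(0, np.int64), np.zeros(0, np.int64)


def site_stats(
    table: GenotypeTable,
    samples: Sequence[str],
    seq_length: int | None = None,
) -> SiteStats:
    """S, Watterson's theta, pi, observed heterozygosity and Tajima's D."""
    if len(samples) < 2:
        raise InsufficientDataError("site_stats needs >= 2 diploid samples")
    n, j, het = _pop_site_counts(table, samples)
    seg = (j > 0) & (j < n)
    S = int(seg.sum())
    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / a1
    jj = j[seg].astype(float)
    pi = float(np.sum(2.0 * jj * (n - jj) / (n * (n - 1))))
    het_obs = float(het.mean() / len(samples)) if len(het) else 0.0
    if S > 0:
        var = e1 * S + e2 * S * (S - 1)
        d = (pi - theta_w) / np.sqrt(var)
        tajd, defined = float(d), True
    else:
        tajd, defined = float("nan"), False
    return SiteStats(
        S=S,
        theta_w=theta_w,
        pi=pi,
        het_obs=het_obs,
        tajimas_d=tajd,
        tajd_defined=defined,
        n_haplotypes=n,
        n_sites_used=len(j),
        seq_length=seq_length,
    )


def windowed_tajimas_d(
    table: GenotypeTable, samples: Sequence[str], grid: WindowGrid
) -> Tuple[float, float, List[float]]:
    """Tajima's D per window; returns (mean, sd, per-window values).

    Windows with no segregating sites are skipped (D undefined there). This
    is the population mean +/- s.d. presentation used for genome-wide D.
    """
    idx = [table.sample_index(s) for s in samples]
    n = 2 * len(idx)
    a1, e1, e2 = _tajima_constants(n)
    vals: List[float] = []
    for chrom in grid.chroms:
        if chrom not in table.data:
            continue
        cg = table.data[chrom]
        al = cg.alleles[idx]
        complete = np.all(al[:, :, 0] >= 0, axis=0)
        j = al.sum(axis=(0, 2))
        starts, ends = grid.window_bounds(chrom)
        for s, e in zip(starts, ends):
            m = complete & (cg.positions >= s) & (cg.positions < e)
            jw = j[m]
            seg = (jw > 0) & (jw < n)
            S = int(seg.sum())
            if S == 0:
                continue
            jj = jw[seg].astype(float)
            pi = float(np.sum(2.0 * jj * (n - jj) / (n * (n - 1))))
            var = e1 * S + e2 * S * (S - 1)
            vals.append((pi - S / a1) / np.sqrt(var))
    if not vals:
        raise InsufficientDataError("no windows with segregating sites")
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0, vals


# ---------------------------------------------------------------------------
# folded SFS


@dataclass
class SFSResult:
    """Folded SFS over minor-allele classes 0..n'/2 at projection size n'."""

    counts: np.ndarray  # float, length n'//2 + 1
    projection: int
    n_sites_masked: int = 0
    n_sites_dropped: int = 0

    def total(self) -> float:
        return float(self.counts.sum())

    def to_dadi_str(self) -> str:
        """dadi-style frequency-spectrum text (folded)."""
        full = np.zeros(self.projection + 1)
        full[: len(self.counts)] = self.counts
        mask = np.zeros(self.projection + 1, dtype=int)
        mask[0] = 1
        mask[self.projection // 2 + 1 :] = 1
        lines = [
            f"{self.projection + 1} folded",
            " ".join(f"{v:.6f}" for v in full),
            " ".join(str(m) for m in mask),
        ]
        return "\n".join(lines) + "\n"


def folded_sfs(
    table: GenotypeTable,
    samples: Sequence[str],
    projection: int | None = None,
    mask: Mapping[str, np.ndarray] | None = None,
) -> SFSResult:
    """Folded SFS with hypergeometric down-projection and interval masking.

    Sites inside the mask are excluded first. A site with m called
    chromosomes and j alternate alleles contributes, for every draw count i,
    its hypergeometric expectation P(i | m, j, n') to the folded class
    min(i, n'-i); sites with m < n' are dropped. Projection therefore
    conserves per-site mass: each retained site contributes total weight 1.
    Without an explicit projection, n' = 2 x samples (complete-case sites
    only, by the same drop rule).
    """
    idx = [table.sample_index(s) for s in samples]
    n_full = 2 * len(idx)
    np_ = projection if projection is not None else n_full
    if np_ % 2 != 0:
        raise DomainError("projection size must be even for a folded spectrum")
    if np_ < 2 or np_ > n_full:
        raise DomainError(f"projection must be in [2, {n_full}]")
    mask = {c: merge_intervals(iv) for c, iv in (mask or {}).items()}

    ms: List[np.ndarray] = []
    js: List[np.ndarray] = []
    n_masked = 0
    for chrom, cg in table.data.items():
        al = cg.alleles[idx]
        called = al[:, :, 0] >= 0
        m = 2 * called.sum(axis=0)
        j = np.where(al >= 0, al, 0).sum(axis=(0, 2))
        keep = np.ones(cg.n_sites, dtype=bool)
        if chrom in mask and len(mask[chrom]):
            inside = in_intervals(mask[chrom], cg.positions)
            n_masked += int(inside.sum())
            keep &= ~inside
        ms.append(m[keep])
        js.append(j[keep])
    m_all = np.concatenate(ms) if ms else np.zeros(0, np.int64)
    j_all = np.concatenate(js) if js else np.zeros(0, np.int64)

    dropped = int(np.sum(m_all < np_))
    ok = m_all >= np_
    m_all, j_all = m_all[ok], j_all[ok]
    counts = np.zeros(np_ // 2 + 1)
    if len(m_all) == 0:
        warnings.warn("no sites have enough called chromosomes for this projection")
        return SFSResult(counts, np_, n_masked, dropped)

    # group sites by (m, j): each unique configuration shares one pmf vector
    cfg, inv = np.unique(np.column_stack([m_all, j_all]), axis=0, return_inverse=True)
    weights = np.bincount(inv, minlength=len(cfg)).astype(float)
    i = np.arange(np_ + 1)
    folded_class = np.minimum(i, np_ - i)
    for (m, j), w in zip(cfg, weights):
        pmf = hypergeom.pmf(i, int(m), int(j), np_)
        np.add.at(counts, folded_class, w * pmf)
    return SFSResult(counts, np_, n_masked, dropped)


def bootstrap_sfs(
    sfs: SFSResult, reps: int, seed: int
) -> List[SFSResult]:
    """Nonparametric SFS bootstrap: multinomial resampling of sites over bins."""
    total = sfs.total()
    if total <= 0:
        raise InsufficientDataError("cannot bootstrap an empty SFS")
    N = int(round(total))
    p = sfs.counts / total
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(N, p, size=reps)
    return [
        SFSResult(d.astype(float), sfs.projection, sfs.n_sites_masked, sfs.n_sites_dropped)
        for d in draws
    ]


# ---------------------------------------------------------------------------
# ABBA-BABA


@dataclass
class DStatResult:
    d: float
    sd: float
    p: float
    n_abba: float
    n_baba: float
    replicates: int
    n_sites_used: int
    n_outgroup_polymorphic: int
    defined: bool = True


def _taxon_freqs(cg, idx):
    """Per-site alternate-allele frequency and called-chromosome count."""
    al = cg.alleles[idx]
    called = (al[:, :, 0] >= 0).sum(axis=0) * 2
    alt = np.where(al >= 0, al, 0).sum(axis=(0, 2))
    with np.errstate(invalid="ignore"):
        freq = alt / called
    return freq, called


def patterson_d(
    table: GenotypeTable,
    p1: Sequence[str],
    p2: Sequence[str],
    p3: Sequence[str],
    outgroup: Sequence[str],
    block_size: int = 1_000_000,
    reps: int = 1000,
    seed: int = 0,
) -> DStatResult:
    """Frequency-weighted four-taxon D with a block bootstrap.

    ABBA = Σ (1-p1) p2 p3 (1-p4), BABA = Σ p1 (1-p2) p3 (1-p4) over biallelic
    sites, p being the derived-allele frequency per taxon. The outgroup's
    major allele is taken as ancestral; sites with a polymorphic outgroup are
    dropped (count reported). D = (ABBA - BABA)/(ABBA + BABA); its s.d. and a
    one-sided p-value come from resampling genomic blocks of ``block_size``
    bp with replacement.
    """
    groups = [
        [table.sample_index(s) for s in grp] for grp in (p1, p2, p3, outgroup)
    ]
    abba_parts, baba_parts, block_ids = [], [], []
    n_poly = 0
    n_used = 0
    for chrom, cg in table.data.items():
        freqs = []
        calleds = []
        for idx in groups:
            f, c = _taxon_freqs(cg, idx)
            freqs.append(f)
            calleds.append(c)
        have = np.all([c > 0 for c in calleds], axis=0)
        f1, f2, f3, f4 = freqs
        out_poly = have & (f4 > 0) & (f4 < 1)
        n_poly += int(out_poly.sum())
        use = have & ~out_poly
        if not use.any():
            continue
        # ancestral = outgroup allele; derived frequency flips where f4 == 1
        flip = f4[use] == 1.0
        d1, d2, d3 = (np.where(flip, 1 - f[use], f[use]) for f in (f1, f2, f3))
        d4 = np.zeros(flip.shape)
        abba = (1 - d1) * d2 * d3 * (1 - d4)
        baba = d1 * (1 - d2) * d3 * (1 - d4)
        abba_parts.append(abba)
        baba_parts.append(baba)
        block_ids.append(
            np.char.add(chrom + ":", (cg.positions[use] // block_size).astype(str))
        )
        n_used += int(use.sum())

    if n_used == 0:
        return DStatResult(float("nan"), float("nan"), float("nan"), 0.0, 0.0, 0, 0, n_poly, False)
    abba = np.concatenate(abba_parts)
    baba = np.concatenate(baba_parts)
    tot_abba, tot_baba = float(abba.sum()), float(baba.sum())
    if tot_abba + tot_baba == 0:
        logger.warning("ABBA + BABA = 0; D undefined")
        return DStatResult(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0, 0, n_used, n_poly, False
        )
    d_obs = (tot_abba - tot_baba) / (tot_abba + tot_baba)

    _, inv = np.unique(np.concatenate(block_ids), return_inverse=True)
    nb = inv.max() + 1
    abba_b = np.bincount(inv, weights=abba, minlength=nb)
    baba_b = np.bincount(inv, weights=baba, minlength=nb)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, nb, size=(reps, nb))
    ra = abba_b[pick].sum(axis=1)
    rb = baba_b[pick].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dd = (ra - rb) / (ra + rb)
    dd = dd[np.isfinite(dd)]
    sd = float(np.std(dd, ddof=1)) if len(dd) > 1 else float("nan")
    if d_obs > 0:
        extreme = int(np.sum(dd <= 0))
    elif d_obs < 0:
        extreme = int(np.sum(dd >= 0))
    else:
        extreme = len(dd)
    p = (extreme + 1) / (len(dd) + 1)
    return DStatResult(
        d=float(d_obs),
        sd=sd,
        p=float(p),
        n_abba=tot_abba,
        n_baba=tot_baba,
        replicates=len(dd),
        n_sites_used=n_used,
        n_outgroup_polymorphic=n_poly,
    )


# ---------------------------------------------------------------------------
# demographic rescaling


@dataclass
class DemographicEstimate:
    """Raw coalescent-unit estimates from a diffusion-based SFS fit.

    theta: population-scaled mutation parameter; nu_b/nu_f relative sizes
    (units of N_ref); t_b/t_f times (units of 2 N_ref generations); f the
    inbreeding coefficient (passed through); mu per-site per-generation
    mutation rate; length callable bp.
    """

    theta: float
    nu_b: float
    nu_f: float
    t_b: float
    t_f: float
    mu: float
    length: float
    f: float = 0.0

    def __post_init__(self):
        for name in ("theta", "nu_b", "nu_f", "t_b", "t_f", "mu", "length"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if not (0.0 <= self.f <= 1.0):
            raise DomainError("inbreeding coefficient f must be in [0, 1]")


@dataclass
class DemographicReport:
    n_ref: float
    n_b: float
    n_f: float
    t_b_gen: float
    t_f_gen: float
    total_bottleneck_gen: float
    f: float


def rescale_demography(est: DemographicEstimate) -> DemographicReport:
    """Convert coalescent-unit estimates to absolute units.

    N_ref = theta / (4 mu L); sizes multiply N_ref; times multiply 2 N_ref.
    """
    n_ref = est.theta / (4.0 * est.mu * est.length)
    t_b = 2.0 * n_ref * est.t_b
    t_f = 2.0 * n_ref * est.t_f
    return DemographicReport(
        n_ref=n_ref,
        n_b=est.nu_b * n_ref,
        n_f=est.nu_f * n_ref,
        t_b_gen=t_b,
        t_f_gen=t_f,
        total_bottleneck_gen=t_b + t_f,
        f=est.f,
    )


def total_bottleneck_time(t_b_gen: float, t_f_gen: float) -> float:
    """Total bottleneck time for inputs already rescaled to generations."""
    if t_b_gen < 0 or t_f_gen < 0:
        raise DomainError("times must be non-negative")
    return t_b_gen + t_f_gen
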