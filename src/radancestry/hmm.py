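"""Three-state local-ancestry HMM over windowed difference counts.

A focal diploid is compared with every member of a donor-species panel; per
100 kb window the difference counts (k) and compared allele-sites (n) are
summed over the focal x panel pairs. If both of the focal individual's
haplotypes in a window descend from the donor species, the per-site rate of
differences to the panel is about the donor's nucleotide diversity π; if
both are native it is about the between-species divergence d_XY; if one of
each ("heterozygous ancestry") it is the midpoint m = (π + d_XY)/2. Each
hidden state therefore emits k ~ Binomial(n, p_state) with

    p_SRC = π(donor panel),  p_HET = m,  p_NAT = d_XY.

Decoding is per chromosome by the Viterbi algorithm in log space. Windows
with fewer than ``min_sites`` compared allele-sites are treated as missing
data: their emission term is log(1) = 0 for every state, so the decoded path
stays continuous through gaps while being determined by the transition model
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .containers import WindowGrid
from .errors import DivergenceError, InsufficientDataError
from .pairdiv import PairKey, PairWindowCounts, pair_key

logger = logging.getLogger(__name__)

# state codes; tie-breaks prefer the higher code (NAT > HET > SRC), which is
# conservative against false introgression calls
SRC, HET, NAT, MISSING = 0, 1, 2, 3
STATE_NAMES = ("SRC", "HET", "NAT", "MISSING")


@dataclass(frozen=True)
class EmissionParams:
    """Binomial success rates of the three ancestry states.

    ``p_het`` is exactly the arithmetic mean of ``p_src`` and ``p_nat``
    unless explicitly overridden.
    """

    p_src: float
    p_nat: float
    p_het: float | None = None

    def __post_init__(self):
        if self.p_het is None:
            object.__setattr__(self, "p_het", (self.p_src + self.p_nat) / 2.0)
        if not (0.0 < self.p_src <= self.p_het <= self.p_nat < 1.0):
            raise ValueError(
                f"require 0 < p_src <= p_het <= p_nat < 1, got "
                f"({self.p_src}, {self.p_het}, {self.p_nat})"
            )

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.p_src, self.p_het, self.p_nat])


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic 3x3 transition matrix and initial distribution."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        init = np.asarray(self.initial, dtype=float)
        if m.shape != (3, 3) or init.shape != (3,):
            raise ValueError("need a 3x3 matrix and length-3 initial distribution")
        if np.any(m < 0) or np.any(init < 0):
            raise ValueError("negative probabilities")
        if np.any(np.abs(m.sum(axis=1) - 1) > 1e-12) or abs(init.sum() - 1) > 1e-12:
            raise ValueError("rows/initial must sum to 1 within 1e-12")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "initial", init)

    @classmethod
    def symmetric(cls, tau: float = 1e-3, tau_het: float | None = None) -> "TransitionModel":
        """Stay with probability 1-τ, switch with τ/2 to each other state.

        τ is per window; the default 1e-3 per 100 kb window corresponds to an
        expected ancestry-block scale of tens of Mb. ``tau_het`` optionally
        gives the HET row its own switch rate.
        """

        def row(i, t):
            r = np.full(3, t / 2.0)
            r[i] = 1.0 - t
            return r

        th = tau if tau_het is None else tau_het
        m = np.vstack([row(0, tau), row(1, th), row(2, tau)])
        return cls(m, np.full(3, 1.0 / 3.0))


@dataclass
class ObservationTrack:
    """Ordered per-window (k_total, n_total) for one chromosome."""

    chrom: str
    k: np.ndarray
    n: np.ndarray
    missing: np.ndarray  # True where n_total < min_sites

    def __post_init__(self):
        if np.any(self.k > self.n):
            raise ValueError("k_total exceeds n_total")


@dataclass
class AncestryPath:
    """Viterbi state sequence of one individual on one chromosome."""

    individual: str
    chrom: str
    states: np.ndarray  # int8 codes, MISSING where the observation was missing
    loglik: float

    def state_names(self) -> list:
        return [STATE_NAMES[s] for s in self.states]


def estimate_emission_params(
    counts: Mapping[PairKey, PairWindowCounts],
    focal: str,
    panel: Sequence[str],
    native_ref: Sequence[str],
    clip: Tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> EmissionParams:
    """Estimate (p_src, p_het, p_nat) from windowed pair rates.

    p_src is the genome-wide median of per-window rates over within-panel
    pairs; p_nat the median over native-reference x panel pairs (the focal
    individual is excluded from the native reference); p_het their mean.
    """
    panel = [s for s in panel if s != focal]
    native_ref = [s for s in native_ref if s != focal]
    if len(panel) < 2:
        raise InsufficientDataError("donor panel needs >= 2 samples")
    if len(native_ref) < 1:
        raise InsufficientDataError("need >= 1 native reference sample besides focal")

    def pooled_rates(pairs):
        vals = []
        for key in pairs:
            c = counts.get(key)
            if c is None:
                raise InsufficientDataError(f"pair {key} missing from counts")
            for chrom in c.k:
                r = c.rate(chrom)
                vals.append(r[~np.isnan(r)])
        pooled = np.concatenate(vals) if vals else np.array([])
        if pooled.size == 0:
            raise InsufficientDataError("no windows with data for rate estimation")
        return pooled

    p_src = float(np.median(pooled_rates([pair_key(a, b) for a, b in combinations(panel, 2)])))
    p_nat = float(
        np.median(
            pooled_rates(
                [pair_key(a, b) for a in native_ref for b in panel if a != b]
            )
        )
    )
    lo, hi = clip
    p_src = float(np.clip(p_src, lo, hi))
    p_nat = float(np.clip(p_nat, lo, hi))
    if p_nat <= p_src:
        raise DivergenceError(
            "populations not diverged enough for ancestry assignment "
            f"(p_nat={p_nat:g} <= p_src={p_src:g})"
        )
    return EmissionParams(p_src=p_src, p_nat=p_nat)


def build_track(
    counts: Mapping[PairKey, PairWindowCounts],
    focal: str,
    panel: Sequence[str],
    chrom: str,
    min_sites: int = 100,
    aggregate: str = "mean",
    max_panel: int | None = None,
) -> ObservationTrack:
    """Aggregate (k, n) over focal x panel pairs in each window.

    ``aggregate="mean"`` (default) divides the summed counts by the number of
    pairs, rounding to integers: the focal individual's differences to the
    donor species are dominated by fixed inter-species sites shared by every
    panel member, so summing across pairs replicates the same observations P
    times and overdisperses k relative to a binomial with the summed n.
    Panel-averaging keeps n at the information content of one diploid-pair
    comparison while still using the whole panel. ``aggregate="sum"`` gives
    the raw pooled counts; ``max_panel`` caps how many panel members are
    used.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    members = [p for p in panel if p != focal]
    if max_panel is not None:
        members = members[:max_panel]
    if not members:
        raise InsufficientDataError("empty panel")
    k = None
    n = None
    for p in members:
        c = counts.get(pair_key(focal, p))
        if c is None:
            raise InsufficientDataError(f"pair {pair_key(focal, p)} missing from counts")
        k = c.k[chrom].astype(np.int64).copy() if k is None else k + c.k[chrom]
        n = c.n[chrom].astype(np.int64).copy() if n is None else n + c.n[chrom]
    if aggregate == "mean":
        P = len(members)
        k = np.rint(k / P).astype(np.int64)
        n = np.rint(n / P).astype(np.int64)
        k = np.minimum(k, n)
    return ObservationTrack(chrom=chrom, k=k, n=n, missing=n < min_sites)


def emission_loglik(k, n, params: EmissionParams) -> np.ndarray:
    """log Binomial(k; n, p_state) for the three states (SRC, HET, NAT).

    Scalar (k, n) gives shape (3,); arrays of length L give (L, 3).
    Windows with n = 0 carry no information: all three log-probabilities
    are 0 (probability 1).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("require 0 <= k <= n")
    scalar = k.ndim == 0
    k2 = np.atleast_1d(k)[:, None]
    n2 = np.atleast_1d(n)[:, None]
    out = binom.logpmf(k2, n2, params.rates[None, :])
    out[np.atleast_1d(n) == 0] = 0.0
    return out[0] if scalar else out


def _viterbi_logemit(logemit: np.ndarray, trans: TransitionModel):
    """Log-space Viterbi on a (L, 3) log-emission matrix.

    Ties are broken toward the higher state code (NAT > HET > SRC) both in
    the backpointers and the terminal argmax.
    """
    L = logemit.shape[0]
    with np.errstate(divide="ignore"):
        log_a = np.log(trans.matrix)
        log_init = np.log(trans.initial)
    score = log_init + logemit[0]
    back = np.zeros((L, 3), dtype=np.int8)
    for t in range(1, L):
        cand = score[:, None] + log_a  # cand[i, j]: from i into j
        # argmax over i with ties to the higher state code
        best = 2 - np.argmax(cand[::-1], axis=0)
        back[t] = best
        score = cand[best, np.arange(3)] + logemit[t]
    last = int(2 - np.argmax(score[::-1]))
    path = np.empty(L, dtype=np.int8)
    path[-1] = last
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(score[last])


def viterbi(
    track: ObservationTrack,
    params: EmissionParams,
    trans: TransitionModel,
    individual: str = "",
) -> AncestryPath:
    """Maximum-likelihood state path for one chromosome, in log space.

    Missing windows contribute a zero emission term for every state, so the
    path remains continuous through them; in the returned path they are
    labelled MISSING.
    """
    L = len(track.k)
    if L == 0:
        logger.warning("empty chromosome %s: returning empty path", track.chrom)
        return AncestryPath(individual, track.chrom, np.empty(0, np.int8), 0.0)
    logemit = emission_loglik(track.k, track.n, params)
    logemit[track.missing] = 0.0
    path, ll = _viterbi_logemit(logemit, trans)
    states = path.copy()
    states[track.missing] = MISSING
    return AncestryPath(individual, track.chrom, states, ll)


def forward_backward(
    track: ObservationTrack, params: EmissionParams, trans: TransitionModel
) -> np.ndarray:
    """Posterior state probabilities (L, 3); optional companion to Viterbi."""
    from scipy.special import logsumexp

    logemit = emission_loglik(track.k, track.n, params)
    logemit[track.missing] = 0.0
    L = logemit.shape[0]
    with np.errstate(divide="ignore"):
        log_a = np.log(trans.matrix)
        log_init = np.log(trans.initial)
    fwd = np.zeros((L, 3))
    fwd[0] = log_init + logemit[0]
    for t in range(1, L):
        fwd[t] = logsumexp(fwd[t - 1][:, None] + log_a, axis=0) + logemit[t]
    bwd = np.zeros((L, 3))
    for t in range(L - 2, -1, -1):
        bwd[t] = logsumexp(log_a + (logemit[t + 1] + bwd[t + 1])[None, :], axis=1)
    post = fwd + bwd
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


def decode_individual(
    counts: Mapping[PairKey, PairWindowCounts],
    focal: str,
    panel: Sequence[str],
    native_ref: Sequence[str],
    grid: WindowGrid,
    trans: TransitionModel | None = None,
    min_sites: int = 100,
    params: EmissionParams | None = None,
    aggregate: str = "mean",
    max_panel: int | None = None,
) -> Dict[str, AncestryPath]:
    """Full per-individual decoding: params -> tracks -> Viterbi per chromosome."""
    if trans is None:
        trans = TransitionModel.symmetric()
    if params is None:
        params = estimate_emission_params(counts, focal, panel, native_ref)
    logger.info(
        "decoding %s: p_src=%.3g p_het=%.3g p_nat=%.3g",
        focal, params.p_src, params.p_het, params.p_nat,
    )
    out: Dict[str, AncestryPath] = {}
    for chrom in grid.chroms:
        track = build_track(
            counts, focal, panel, chrom,
            min_sites=min_sites, aggregate=aggregate, max_panel=max_panel,
        )
        out[chrom] = viterbi(track, params, trans, individual=focal)
    return out


def decode_population(
    counts: Mapping[PairKey, PairWindowCounts],
    focal_samples: Sequence[str],
    panel: Sequence[str],
    native_ref: Sequence[str],
    grid: WindowGrid,
    trans: TransitionModel | None = None,
    min_sites: int = 100,
    shared_params: bool = True,
    aggregate: str = "mean",
    max_panel: int | None = None,
) -> Dict[str, Dict[str, AncestryPath]]:
    """Decode every focal individual against the same donor panel.

    With ``shared_params`` the emission rates are estimated once from the
    panel and native reference (they do not involve any focal individual's
    own observations) and reused across individuals.
    """
    params = None
    if shared_params:
        params = estimate_emission_params(counts, "", panel, native_ref)
    return {
        f: decode_individual(
            counts, f, panel, native_ref, grid, trans, min_sites, params,
            aggregate=aggregate, max_panel=max_panel,
        )
        for f in focal_samples
    }
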