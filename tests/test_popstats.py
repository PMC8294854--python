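"""Diversity statistics, folded SFS, ABBA-BABA D, demographic rescaling."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from radancestry import (
    ChromGenotypes,
    DemographicEstimate,
    GenotypeTable,
    bootstrap_sfs,
    folded_sfs,
    patterson_d,
    rescale_demography,
    site_stats,
    total_bottleneck_time,
)
from radancestry.errors import DomainError, InsufficientDataError


def table_from_haps(haps, positions=None, chrom="chr1", missing=None):
    """Build a diploid table from a (2N, sites) 0/1 haplotype matrix."""
    haps = np.asarray(haps, dtype=np.int8)
    n_samples = haps.shape[0] // 2
    n_sites = haps.shape[1]
    positions = (
        np.arange(10, 10 * (n_sites + 1), 10) if positions is None else np.asarray(positions)
    )
    alleles = np.empty((n_samples, n_sites, 2), dtype=np.int8)
    for s in range(n_samples):
        alleles[s] = np.sort(haps[2 * s : 2 * s + 2].T, axis=1)
    if missing is not None:
        alleles[missing] = -1
    samples = tuple(f"s{i}" for i in range(n_samples))
    return GenotypeTable(
        samples, {chrom: ChromGenotypes(positions, alleles)}, {}
    )


# ---------------------------------------------------------------------------
# site stats


def brute_force_stats(haps):
    """Independent oracle: all-pairs pi, S, theta_W, Tajima's D from scratch."""
    haps = np.asarray(haps)
    n, m = haps.shape
    S = 0
    pi = 0.0
    for j in range(m):
        col = haps[:, j]
        if 0 < col.sum() < n:
            S += 1
        diff = 0
        for i1 in range(n):
            for i2 in range(i1 + 1, n):
                diff += int(col[i1] != col[i2])
        pi += diff / (n * (n - 1) / 2)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = S / a1
    if S == 0:
        return S, theta_w, pi, None
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = (pi - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return S, theta_w, pi, d


def test_watterson_closed_form():
    # 4 haplotypes, 3 segregating sites -> theta_W = 3 / (1 + 1/2 + 1/3)
    haps = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]]
    )
    stats = site_stats(table_from_haps(haps), ["s0", "s1"])
    assert stats.S == 3
    assert stats.theta_w == pytest.approx(3 / (1 + 0.5 + 1 / 3))
    assert stats.theta_w == pytest.approx(1.6364, abs=1e-4)


@pytest.mark.parametrize("seed", range(15))
def test_stats_match_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    n_samples = int(rng.integers(2, 6))
    n_sites = int(rng.integers(3, 21))
    haps = rng.integers(0, 2, size=(2 * n_samples, n_sites))
    table = table_from_haps(haps)
    stats = site_stats(table, [f"s{i}" for i in range(n_samples)])
    S, theta_w, pi, d = brute_force_stats(haps)
    assert stats.S == S
    assert stats.theta_w == pytest.approx(theta_w)
    assert stats.pi == pytest.approx(pi)
    if d is None:
        assert not stats.tajd_defined
    else:
        assert stats.tajimas_d == pytest.approx(d)


def test_monomorphic_input_has_undefined_tajimas_d():
    haps = np.zeros((6, 4), dtype=int)
    haps[:, 1] = 1  # fixed alternate: still not segregating
    stats = site_stats(table_from_haps(haps), ["s0", "s1", "s2"])
    assert stats.S == 0 and stats.theta_w == 0.0
    assert not stats.tajd_defined and np.isnan(stats.tajimas_d)


def test_too_few_samples_rejected():
    with pytest.raises(InsufficientDataError):
        site_stats(table_from_haps(np.zeros((2, 3), int)), ["s0"])


# ---------------------------------------------------------------------------
# folded SFS


def test_singleton_goes_to_class_one():
    haps = np.array([[1], [0], [0], [0]])
    sfs = folded_sfs(table_from_haps(haps), ["s0", "s1"])
    assert sfs.counts.tolist() == [0.0, 1.0, 0.0]


def test_projection_uses_hypergeometric_expectations():
    # one site at 2/4 projected down to n'=2
    haps = np.array([[1], [1], [0], [0]])
    sfs = folded_sfs(table_from_haps(haps), ["s0", "s1"], projection=2)
    expected = np.zeros(2)
    for i in range(3):
        expected[min(i, 2 - i)] += hypergeom.pmf(i, 4, 2, 2)
    assert np.allclose(sfs.counts, expected)
    assert sfs.total() == pytest.approx(1.0)


def test_masked_site_contributes_nothing_and_empty_mask_is_identity():
    haps = np.array([[1, 1], [0, 1], [0, 0], [0, 0]])
    table = table_from_haps(haps, positions=[100, 200])
    full = folded_sfs(table, ["s0", "s1"])
    masked = folded_sfs(table, ["s0", "s1"], mask={"chr1": [(150, 250)]})
    assert masked.n_sites_masked == 1
    assert masked.total() == full.total() - 1
    empty = folded_sfs(table, ["s0", "s1"], mask={"chr1": []})
    assert np.allclose(empty.counts, full.counts)


@pytest.mark.parametrize("seed", range(10))
def test_projection_conserves_per_site_mass(seed):
    """Each retained site contributes total weight 1; dropped sites weight 0."""
    rng = np.random.default_rng(seed)
    n_samples, n_sites = 5, 30
    haps = rng.integers(0, 2, size=(2 * n_samples, n_sites))
    missing = rng.random((n_samples, n_sites)) < 0.3
    table = table_from_haps(haps, missing=missing)
    proj = 4
    sfs = folded_sfs(table, [f"s{i}" for i in range(n_samples)], projection=proj)
    assert sfs.total() + sfs.n_sites_dropped == pytest.approx(n_sites)
    assert np.all(sfs.counts >= 0)


def test_odd_projection_rejected():
    haps = np.array([[1], [0], [0], [0]])
    with pytest.raises(DomainError):
        folded_sfs(table_from_haps(haps), ["s0", "s1"], projection=3)


class TestBootstrapSFS:
    def setup_method(self):
        haps = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        self.sfs = folded_sfs(table_from_haps(haps), ["s0", "s1"])

    def test_deterministic_given_seed(self):
        r1 = bootstrap_sfs(self.sfs, reps=1, seed=7)[0]
        r2 = bootstrap_sfs(self.sfs, reps=1, seed=7)[0]
        assert np.array_equal(r1.counts, r2.counts)

    def test_total_preserved_and_mean_close(self):
        reps = bootstrap_sfs(self.sfs, reps=1000, seed=3)
        totals = {r.total() for r in reps}
        assert totals == {self.sfs.total()}
        mean = np.mean([r.counts for r in reps], axis=0)
        assert np.allclose(mean, self.sfs.counts, atol=0.1)

    def test_single_bin_sfs_replicates_identically(self):
        from radancestry import SFSResult

        single = SFSResult(np.array([0.0, 5.0]), projection=2)
        for r in bootstrap_sfs(single, reps=5, seed=1):
            assert np.array_equal(r.counts, single.counts)

    def test_empty_sfs_rejected(self):
        from radancestry import SFSResult

        with pytest.raises(InsufficientDataError):
            bootstrap_sfs(SFSResult(np.zeros(3), projection=4), reps=2, seed=0)


# ---------------------------------------------------------------------------
# ABBA-BABA


def four_taxon_table(patterns):
    """One homozygous diploid per taxon; patterns are (p1, p2, p3, out) rows."""
    rows = []
    for pat in patterns:
        rows.append([pat[0]] * 2 + [pat[1]] * 2 + [pat[2]] * 2 + [pat[3]] * 2)
    haps = np.array(rows).T  # (8 haps, sites)
    return table_from_haps(haps)


def test_d_from_known_site_patterns():
    # 9 ABBA sites and 1 BABA site -> D = (9 - 1) / (9 + 1) = 0.8
    table = four_taxon_table([(0, 1, 1, 0)] * 9 + [(1, 0, 1, 0)])
    res = patterson_d(table, ["s0"], ["s1"], ["s2"], ["s3"], reps=100, seed=1)
    assert res.d == pytest.approx(0.8)
    assert res.n_abba == pytest.approx(9.0) and res.n_baba == pytest.approx(1.0)


def test_equal_pattern_counts_give_zero():
    table = four_taxon_table([(0, 1, 1, 0)] * 5 + [(1, 0, 1, 0)] * 5)
    res = patterson_d(table, ["s0"], ["s1"], ["s2"], ["s3"], reps=50, seed=1)
    assert res.d == pytest.approx(0.0)


def test_antisymmetric_under_p1_p2_swap():
    rng = np.random.default_rng(4)
    haps = rng.integers(0, 2, size=(8, 60))
    haps[6:8] = 0  # fixed outgroup
    table = table_from_haps(haps)
    d12 = patterson_d(table, ["s0"], ["s1"], ["s2"], ["s3"], reps=10, seed=1).d
    d21 = patterson_d(table, ["s1"], ["s0"], ["s2"], ["s3"], reps=10, seed=1).d
    assert d12 == pytest.approx(-d21)


def test_polymorphic_outgroup_sites_dropped():
    table = four_taxon_table([(0, 1, 1, 0)] * 4)
    res = patterson_d(table, ["s0"], ["s1"], ["s2"], ["s3"], reps=10, seed=0)
    assert res.n_outgroup_polymorphic == 0
    # now make the outgroup heterozygous at the first site
    t2 = four_taxon_table([(0, 1, 1, 0)] * 4)
    cg = t2.data["chr1"]
    cg.alleles[3, 0] = [0, 1]  # outgroup het at first site
    res2 = patterson_d(t2, ["s0"], ["s1"], ["s2"], ["s3"], reps=10, seed=0)
    assert res2.n_outgroup_polymorphic == 1
    assert res2.n_abba == pytest.approx(3.0)


def test_no_informative_sites_flagged_undefined():
    table = four_taxon_table([(1, 1, 0, 0)] * 3)  # no ABBA or BABA weight
    res = patterson_d(table, ["s0"], ["s1"], ["s2"], ["s3"], reps=10, seed=0)
    assert not res.defined and np.isnan(res.d)


class TestDOnSimulatedPanels:
    """Simulation checks: no gene flow -> D near 0; planted flow -> D > 0."""

    @staticmethod
    def _sim(seed, with_flow):
        from itertools import combinations
        from radancestry import SimConfig, Tract, simulate_dataset

        plan = {}
        if with_flow:
            # donor tracts planted into the P2 half of the focal population
            plan = {
                f"foc{i:02d}": [
                    Tract("chr01", 200_000, 1_200_000, "hom"),
                    Tract("chr02", 500_000, 1_000_000, "hom"),
                ]
                for i in (5, 6, 7, 8)
            }
        cfg = SimConfig(
            seed=seed,
            chrom_lengths={f"chr{i:02d}": 2_000_000 for i in (1, 2, 3)},
            n_donor=4,
            n_focal=8,
            n_outgroup=1,
            ancestral_poly_rate=3e-4,
            tract_plan=plan,
        )
        res = simulate_dataset(cfg)
        p1 = cfg.focal_samples[:4]
        p2 = cfg.focal_samples[4:]
        return res.table, p1, p2, cfg.donor_samples, cfg.outgroup_samples

    def test_no_gene_flow_d_within_three_sd(self):
        hits = 0
        for seed in range(20):
            table, p1, p2, p3, out = self._sim(100 + seed, with_flow=False)
            res = patterson_d(table, p1, p2, p3, out, block_size=500_000,
                              reps=200, seed=seed)
            if abs(res.d) < 3 * res.sd:
                hits += 1
        assert hits >= 18  # >= 95% of seeds minus one-seed slack

    def test_planted_flow_gives_positive_significant_d(self):
        ok = 0
        for seed in range(20):
            table, p1, p2, p3, out = self._sim(300 + seed, with_flow=True)
            res = patterson_d(table, p1, p2, p3, out, block_size=500_000,
                              reps=200, seed=seed)
            if res.d > 0 and res.p < 0.05:
                ok += 1
        assert ok >= 18  # >= 90% of seeds


# ---------------------------------------------------------------------------
# demographic rescaling


def test_reference_size_from_theta():
    est = DemographicEstimate(
        theta=68.40, nu_b=0.186, nu_f=13.72, t_b=0.164, t_f=0.179,
        mu=1e-8, length=5_806_952,
    )
    rep = rescale_demography(est)
    assert rep.n_ref == pytest.approx(68.40 / (4 * 1e-8 * 5_806_952))
    assert rep.n_ref == pytest.approx(294.5, abs=0.1)
    assert rep.n_b == pytest.approx(0.186 * rep.n_ref)
    assert rep.total_bottleneck_gen == pytest.approx(2 * rep.n_ref * (0.164 + 0.179))


def test_unit_size_ratio_is_identity():
    est = DemographicEstimate(
        theta=10.0, nu_b=1.0, nu_f=1.0, t_b=0.5, t_f=0.5, mu=1e-8, length=1e6
    )
    rep = rescale_demography(est)
    assert rep.n_b == pytest.approx(rep.n_ref)


def test_total_bottleneck_time_sums_rescaled_inputs():
    assert total_bottleneck_time(96.52, 105.14) == pytest.approx(201.66)
    with pytest.raises(DomainError):
        total_bottleneck_time(-1.0, 5.0)


def test_nonpositive_inputs_rejected():
    with pytest.raises(DomainError):
        DemographicEstimate(theta=0, nu_b=1, nu_f=1, t_b=1, t_f=1, mu=1e-8, length=1e6)
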