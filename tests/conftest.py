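import numpy as np
import pytest

from radancestry import ChromGenotypes, GenotypeTable, WindowGrid


def make_table(samples, chrom_lengths, sites, coverage):
    """Small-table builder for hand-written cases.

    sites: {chrom: (positions, {sample: [(a, b) | None per site]})}
    coverage: {sample: {chrom: [(start, end), ...]}}
    """
    data = {}
    for chrom, (positions, gts) in sites.items():
        n_sites = len(positions)
        alleles = np.full((len(samples), n_sites, 2), -1, dtype=np.int8)
        for si, s in enumerate(samples):
            for j, g in enumerate(gts.get(s, [None] * n_sites)):
                if g is not None:
                    alleles[si, j] = sorted(g)
        data[chrom] = ChromGenotypes(np.array(positions, dtype=np.int64), alleles)
    cov = {
        s: {c: np.array(iv, dtype=np.int64).reshape(-1, 2) for c, iv in per.items()}
        for s, per in coverage.items()
    }
    return GenotypeTable(tuple(samples), data, cov)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def grid_100kb():
    return WindowGrid({"chr1": 1_000_000}, window_size=100_000)


def random_small_table(rng, n_samples=4, n_sites=10, L=100_000, chrom="chr1"):
    """Random complete-ish table with random coverage, for oracle checks."""
    positions = np.sort(rng.choice(L, size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(n_samples, n_sites, 2)).astype(np.int8)
    missing = rng.random((n_samples, n_sites)) < 0.15
    alleles = np.sort(alleles, axis=2)
    alleles[missing] = -1
    samples = tuple(f"s{i}" for i in range(n_samples))
    cov = {}
    for s in samples:
        n_iv = rng.integers(1, 4)
        bounds = np.sort(rng.choice(L + 1, size=2 * n_iv, replace=False))
        cov[s] = {chrom: bounds.reshape(-1, 2)}
    # enforce the container invariant: called genotypes lie inside coverage
    table = GenotypeTable(
        samples,
        {chrom: ChromGenotypes(positions, alleles)},
        cov,
    )
    from radancestry.intervals import in_intervals

    cg = table.data[chrom]
    for si, s in enumerate(samples):
        outside = ~in_intervals(table.sample_coverage(s, chrom), cg.positions)
        cg.alleles[si, outside] = -1
    return table
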