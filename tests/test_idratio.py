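import numpy as np
import pytest

from extremecc import (
    ClumpIndex,
    ContractError,
    GenotypeMatrix,
    ParameterError,
    SimParams,
    clump,
    count_id,
    log2_id,
    permute_null,
    simulate_cohort,
    z_and_p,
)
from extremecc.simulate import add_ld_duplicate

from conftest import make_gm


# ----------------------------------------------------------------------
# clumping


def brute_force_clump(dosages, chrom, pos, p, r2_max=0.1, window=1_000_000):
    """Independent O(m^2) clumping oracle with an explicit r^2 matrix."""
    m = len(p)
    d = dosages.astype(float)
    r2 = np.corrcoef(d.T) ** 2
    order = sorted(range(m), key=lambda j: (p[j], chrom[j], pos[j]))
    removed = set()
    kept = []
    for j in order:
        if j in removed:
            continue
        kept.append(j)
        for k in range(m):
            if k != j and chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= window:
                if r2[j, k] > r2_max:
                    removed.add(k)
    return sorted(kept)


def _common_gm(n=300, m=30, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(np.int8)
    return make_gm(d, pos=(np.arange(m) + 1) * 10_000), rng


def test_independent_variants_all_retained():
    gm, rng = _common_gm()
    idx = ClumpIndex.build(gm)
    p = rng.uniform(size=gm.n_variants)
    assert len(clump(p, idx)) == gm.n_variants


def test_duplicated_pair_keeps_stronger():
    gm, rng = _common_gm(seed=3)
    gm2 = add_ld_duplicate(gm, "v0", "dup", flip_prob=0.0, rng=rng, pos_offset=5_500)
    p = np.full(gm2.n_variants, 0.5)
    p[0], p[-1] = 1e-5, 1e-3
    idx = ClumpIndex.build(gm2)
    kept = clump(p, idx)
    assert 0 in kept and (gm2.n_variants - 1) not in kept


def test_clump_matches_brute_force_oracle():
    """50-variant toy with planted r^2 blocks equals exhaustive clumping."""
    gm, rng = _common_gm(n=400, m=40, seed=11)
    for i, src in enumerate(["v1", "v5", "v5", "v20"]):
        gm = add_ld_duplicate(gm, src, f"dup{i}", flip_prob=0.05, rng=rng,
                              pos_offset=15_000 + 7_000 * i)
    p = rng.uniform(size=gm.n_variants)
    idx = ClumpIndex.build(gm)
    kept = clump(p, idx).tolist()
    oracle = brute_force_clump(
        gm.dosages, gm.variants["chrom"].to_numpy(), gm.variants["pos"].to_numpy(), p
    )
    assert kept == oracle


def test_clump_invariant_to_row_order():
    gm, rng = _common_gm(n=200, m=25, seed=5)
    gm = add_ld_duplicate(gm, "v2", "dupA", flip_prob=0.0, rng=rng, pos_offset=4_500)
    p = rng.uniform(size=gm.n_variants)
    kept_ids = set(gm.variant_ids[clump(p, ClumpIndex.build(gm))])

    perm = rng.permutation(gm.n_variants)
    gm_shuf = GenotypeMatrix(gm.sample_ids, gm.dosages[:, perm],
                             gm.variants.iloc[perm].reset_index(drop=True))
    kept_ids_shuf = set(gm_shuf.variant_ids[clump(p[perm], ClumpIndex.build(gm_shuf))])
    assert kept_ids == kept_ids_shuf


def test_empty_input_empty_output():
    gm, _ = _common_gm(m=5)
    idx = ClumpIndex.build(gm)
    assert len(clump(np.full(5, np.nan), idx)) == 0


# ----------------------------------------------------------------------
# counting


def test_count_directions_and_boundaries():
    maf = np.array([0.005, 0.01, 0.011, 0.3])
    beta = np.array([0.1, -0.2, 0.0, 0.4])
    p = np.array([0.005, 0.0005, 0.001, 0.5])
    cells = count_id(maf, beta, p)
    assert cells[((0.0, 0.01), 0.01)] == (2, 1, 1)
    # maf exactly 0.01 belongs to the (0,0.01] bin only
    assert cells[((0.0, 0.01), 0.001)] == (1, 0, 1)
    assert cells[((0.01, 0.05), 0.01)] == (1, 0, 0)  # beta=0: counted, no direction
    assert cells[((0.15, 0.5), 0.01)] == (0, 0, 0)   # p=0.5 fails threshold


def test_all_positive_betas_give_zero_decreasers():
    rng = np.random.default_rng(0)
    maf = rng.uniform(0.001, 0.5, 50)
    beta = np.abs(rng.normal(size=50))
    p = rng.uniform(0, 0.02, 50)
    cells = count_id(maf, beta, p)
    assert all(D == 0 for (_, _, D) in cells.values())


def test_count_matches_independent_tally():
    rng = np.random.default_rng(9)
    maf = rng.uniform(0.0001, 0.5, 100)
    beta = rng.normal(size=100)
    p = rng.uniform(size=100)
    cells = count_id(maf, beta, p)
    for (lo, hi), t in cells:
        n = I = D = 0
        for j in range(100):
            if lo < maf[j] <= hi and p[j] < t:
                n += 1
                I += beta[j] > 0
                D += beta[j] < 0
        assert cells[((lo, hi), t)] == (n, I, D)


def test_unoriented_input_rejected():
    with pytest.raises(ContractError):
        count_id(np.array([0.7]), np.array([0.1]), np.array([0.001]))


# ----------------------------------------------------------------------
# log2 and Z


def test_log2_integer_ratios():
    assert log2_id(8, 1) == (pytest.approx(3.0), False)
    assert log2_id(6, 1) == (pytest.approx(2.585, abs=5e-4), False)
    assert log2_id(1, 2) == (pytest.approx(-1.0), False)
    assert log2_id(5, 5) == (pytest.approx(0.0), False)


def test_log2_continuity_correction_and_undefined():
    val, corrected = log2_id(3, 0)
    assert corrected and val == pytest.approx(np.log2(3.5 / 0.5))
    with pytest.raises(ParameterError):
        log2_id(0, 0)


def test_z_from_printed_table_rows():
    """Z-scores recompute from (obs_log2, mu, sigma) triples of the published
    I/D table to the printed 3-dp precision."""
    assert z_and_p(2.585, 1.035, 1.222)[0] == pytest.approx(1.268, abs=5e-4)
    assert z_and_p(0.000, 0.209, 0.510)[0] == pytest.approx(-0.410, abs=5e-4)
    assert z_and_p(-1.000, 0.307, 1.211)[0] == pytest.approx(-1.079, abs=5e-4)


def test_p_from_z_chi2_one_df():
    assert z_and_p(-2.668, 0.0, 1.0)[1] == pytest.approx(0.008, abs=5e-4)
    assert z_and_p(0.0, 0.0, 1.0)[1] == pytest.approx(1.0)
    with pytest.raises(ParameterError):
        z_and_p(1.0, 0.0, 0.0)


# ----------------------------------------------------------------------
# permutation null


def test_permutation_preserves_case_count_and_is_deterministic():
    params = SimParams(n_cases=100, n_controls=150, n_variants=300, n_genes=30,
                       h2_liability=0.0, n_causal=0, selection_quantile=0.5, seed=6)
    c = simulate_cohort(params, case_mode="pool")
    a = permute_null(c.genotypes, c.phenotypes, 20, np.random.default_rng(5))
    b = permute_null(c.genotypes, c.phenotypes, 20, np.random.default_rng(5))
    for cell, v in a.log2_vectors.items():
        assert np.array_equal(v, b.log2_vectors[cell])
        np.testing.assert_equal(a.mu[cell], b.mu[cell])
        np.testing.assert_equal(a.sigma[cell], b.sigma[cell])
        assert len(v) + a.n_dropped[cell] == 20
    with pytest.raises(ParameterError):
        permute_null(c.genotypes, c.phenotypes, 1, np.random.default_rng(0))
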