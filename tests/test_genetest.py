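import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from extremecc import (
    ContractError,
    ParameterError,
    SimParams,
    burden_test,
    gene_bonferroni_threshold,
    group_variants,
    kernel_test,
    optimal_combination,
    score_test,
    simulate_cohort,
)
from extremecc.genetest import _GeneEngine, _minor_dosages, liu_mixture_sf

from conftest import binary_pheno, make_gm


# ----------------------------------------------------------------------
# grouping


def test_scheme_class_predicates():
    gm = make_gm(
        np.array([[0, 1, 0], [1, 0, 1], [0, 0, 0], [0, 1, 0]] * 10, dtype=np.int8),
        fclass=["NonSynonymous", "StopGain", "Synonymous"],
    )
    g = group_variants(gm, "SG_ESS", rare_maf_max=0.3)
    assert list(gm.variant_ids[g.groups["G1"]]) == ["v1"]
    g2 = group_variants(gm, "SG_ESS_NS", rare_maf_max=0.3)
    assert list(gm.variant_ids[g2.groups["G1"]]) == ["v0", "v1"]


def test_pp2_scheme_requires_damaging_for_ns_only():
    gm = make_gm(
        np.array([[0, 1, 1], [1, 0, 0], [0, 0, 0], [0, 0, 0]] * 10, dtype=np.int8),
        fclass=["NonSynonymous", "NonSynonymous", "StopGain"],
        damaging=[False, True, False],
    )
    g = group_variants(gm, "SG_ESS_PP2", rare_maf_max=0.2)
    # NS needs the damaging flag; StopGain qualifies regardless
    assert list(gm.variant_ids[g.groups["G1"]]) == ["v1", "v2"]


def test_maf_bound_excludes_common_variants():
    d = np.zeros((100, 2), dtype=np.int8)
    d[:4, 0] = 1   # maf 0.02
    d[:1, 1] = 1   # maf 0.005
    gm = make_gm(d, fclass=["StopGain", "StopGain"])
    g = group_variants(gm, "SG_ESS", rare_maf_max=0.01)
    assert list(gm.variant_ids[g.groups["G1"]]) == ["v1"]


def test_unknown_scheme_rejected():
    gm = make_gm(np.zeros((4, 1), dtype=np.int8))
    with pytest.raises(ParameterError):
        group_variants(gm, "NOT_A_SCHEME")


def test_grouping_matches_brute_force_recount():
    params = SimParams(n_cases=50, n_controls=150, n_variants=600, n_genes=60,
                       h2_liability=0.1, n_causal=30, selection_quantile=0.1, seed=13)
    gm = simulate_cohort(params).genotypes
    g = group_variants(gm, "SG_ESS_NS", rare_maf_max=0.01)
    maf = gm.maf()
    classes = {"StopGain", "EssentialSpliceSite", "NonSynonymous"}
    expected = {}
    for j in range(gm.n_variants):
        row = gm.variants.iloc[j]
        if row.functional_class in classes and 0 < maf[j] < 0.01:
            expected.setdefault(row.gene, []).append(j)
    got = {k: sorted(v.tolist()) for k, v in g.groups.items()}
    assert got == {k: sorted(v) for k, v in expected.items()}
    # every excluded gene really has no qualifying variant
    assert set(g.excluded["gene"]).isdisjoint(expected)


# ----------------------------------------------------------------------
# burden


def _toy_gene(n=200, m=4, seed=0, maf=0.02):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    gm = make_gm(d, fclass=["StopGain"] * m)
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return gm, binary_pheno(y)


def test_single_variant_burden_equals_score_test():
    gm, pheno = _toy_gene(m=1, seed=3)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.1)
    _, _, p_b, _ = burden_test(gm, grouping, "G1", pheno)
    _, _, p_s, _ = score_test(gm.dosages[:, 0], pheno.status)
    assert p_b == pytest.approx(p_s, rel=1e-12)


def test_disjoint_carriers_collapse_to_sum():
    d = np.zeros((6, 2), dtype=np.int8)
    d[0, 0] = 1
    d[1, 1] = 2
    gm = make_gm(d, fclass=["StopGain", "StopGain"])
    assert np.array_equal(_minor_dosages(gm, np.array([0, 1])).sum(axis=1),
                          d.sum(axis=1).astype(float))


def test_burden_p_within_permutation_bracket():
    """Burden p on a 100-sample toy gene sits inside the exact
    label-permutation bracket."""
    gm, pheno = _toy_gene(n=100, m=5, seed=7, maf=0.06)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.2)
    _, _, p_b, _ = burden_test(gm, grouping, "G1", pheno)
    count = _minor_dosages(gm, grouping.groups["G1"]).sum(axis=1)
    cc = count - count.mean()
    y = pheno.status
    obs = abs((y - y.mean()) @ cc)
    rng = np.random.default_rng(1)
    perms = np.array([rng.permutation(y) for _ in range(100_000)])
    r = np.abs(perms @ cc)
    lo, hi = np.mean(r > obs + 1e-9), np.mean(r >= obs - 1e-9)
    assert lo - 0.02 <= p_b <= hi + 0.02


def test_zero_carriers_not_testable():
    d = np.zeros((20, 1), dtype=np.int8)
    gm = make_gm(d, fclass=["StopGain"])
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.1)
    assert "G1" in grouping.excluded["gene"].tolist()


# ----------------------------------------------------------------------
# kernel


def test_single_variant_kernel_equals_score_test():
    """One qualifying variant: the chi-square mixture collapses to one term."""
    gm, pheno = _toy_gene(m=1, seed=5)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.1)
    _, p_k = kernel_test(gm, grouping, "G1", pheno)
    _, _, p_s, _ = score_test(gm.dosages[:, 0], pheno.status)
    assert p_k == pytest.approx(p_s, rel=1e-9)


def test_kernel_weight_scale_invariance():
    gm, pheno = _toy_gene(n=150, m=4, seed=9, maf=0.05)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.2)
    w = np.array([1.0, 2.0, 0.5, 1.5])
    _, p1 = kernel_test(gm, grouping, "G1", pheno, weights_spec=w)
    _, p2 = kernel_test(gm, grouping, "G1", pheno, weights_spec=2 * w)
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_kernel_p_matches_permutation_oracle():
    """5-variant toy gene, n=200: mixture p within 30% relative of a
    phenotype-permutation p."""
    gm, pheno = _toy_gene(n=200, m=5, seed=21, maf=0.08)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.2)
    q_obs, p_k = kernel_test(gm, grouping, "G1", pheno)
    eng = _GeneEngine.build(gm, grouping, "G1", pheno, None, "beta:1,25")
    rng = np.random.default_rng(3)
    y = pheno.status
    n_perm = 100_000
    qs = np.empty(n_perm)
    for i in range(n_perm):
        yp = y[rng.permutation(len(y))]
        ryp = yp - yp.mean()
        S = eng.G_resid.T @ ryp
        qs[i] = np.sum(eng.w**2 * S**2)
    p_perm = np.mean(qs >= q_obs)
    assert p_k == pytest.approx(p_perm, rel=0.30, abs=0.01)


def test_liu_single_eigenvalue_exact():
    from scipy.stats import chi2 as chi2_dist
    assert liu_mixture_sf(5.0, np.array([2.0])) == pytest.approx(
        float(chi2_dist.sf(2.5, 1)), rel=1e-12
    )


# ----------------------------------------------------------------------
# optimal combination


def test_rho_endpoints_recover_component_tests():
    gm, pheno = _toy_gene(n=150, m=4, seed=2, maf=0.05)
    grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.2)
    p0, rho0 = optimal_combination(gm, grouping, "G1", pheno, rho_grid=[0.0])
    _, p_k = kernel_test(gm, grouping, "G1", pheno)
    assert rho0 == 0.0 and p0 == pytest.approx(p_k, rel=1e-9)
    p1, rho1 = optimal_combination(gm, grouping, "G1", pheno, rho_grid=[1.0])
    # rho=1 is the weighted-score burden axis
    _, _, p_b, _ = burden_test(gm, grouping, "G1", pheno, weights="beta:1,25")
    assert rho1 == 1.0 and p1 == pytest.approx(p_b, rel=1e-9)
    with pytest.raises(ParameterError):
        optimal_combination(gm, grouping, "G1", pheno, rho_grid=[])


def test_shared_sign_effects_favor_burden_axis():
    """When every causal allele pushes the same way, the burden end of the
    grid wins more often than the kernel end."""
    rng = np.random.default_rng(77)
    sel_burden = sel_kernel = 0
    for rep in range(200):
        n, m = 150, 6
        d = rng.binomial(2, 0.05, size=(n, m)).astype(np.int8)
        score = d.sum(axis=1) * 0.6 + rng.normal(size=n)
        y = (score > np.median(score)).astype(float)
        gm = make_gm(d, fclass=["StopGain"] * m)
        pheno = binary_pheno(y)
        grouping = group_variants(gm, "SG_ESS", rare_maf_max=0.2)
        if "G1" not in grouping.groups:
            continue
        try:
            _, rho = optimal_combination(gm, grouping, "G1", pheno,
                                         n_perm=10, rng=rng)
        except ContractError:
            continue
        sel_burden += rho == 1.0
        sel_kernel += rho == 0.0
    assert sel_burden > sel_kernel


def test_null_gene_pvalues_uniform():
    """Burden and kernel p-values are uniformly calibrated under the
    simulator null (>=2000 genes aggregated over replicates).

    Collapsed rare-allele counts make the statistic a lattice, so uniformity
    is asserted on tail fractions at several thresholds (within binomial
    error) and on the mean implied chi-square, rather than a continuous-KS
    statistic that any discrete test fails by construction.
    """
    bp, kp = [], []
    for rep in range(5):
        params = SimParams(
            n_cases=300, n_controls=300, n_variants=2500, n_genes=500,
            maf_weights={"rare": 0.8, "low": 0.1, "common": 0.1},
            h2_liability=0.0, n_causal=0, selection_quantile=0.5, seed=500 + rep,
        )
        c = simulate_cohort(params, case_mode="pool")
        gm, pheno = c.genotypes, c.phenotypes
        grouping = group_variants(gm, "SG_ESS_NS", rare_maf_max=0.01)
        for gene in grouping.groups:
            try:
                _, _, p_b, _ = burden_test(gm, grouping, gene, pheno)
                _, p_k = kernel_test(gm, grouping, gene, pheno)
            except ContractError:
                continue
            bp.append(p_b)
            kp.append(p_k)
    bp, kp = np.array(bp), np.array(kp)
    m = len(bp)
    assert m >= 2000
    for t in (0.01, 0.05, 0.1, 0.5):
        band = 3.5 * np.sqrt(t * (1 - t) / m) + 0.005
        assert abs(np.mean(bp < t) - t) < band
        assert abs(np.mean(kp < t) - t) < band
    assert abs(np.mean(chi2_dist.isf(bp, 1)) - 1.0) < 0.1
    assert abs(np.mean(chi2_dist.isf(kp, 1)) - 1.0) < 0.1


def test_bonferroni_threshold():
    assert gene_bonferroni_threshold(1000) == pytest.approx(5e-5)
    with pytest.raises(ParameterError):
        gene_bonferroni_threshold(0)
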