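import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from layersel import censorcv, datasets, siremodel
from layersel.censorcv import (
    accuracy_from_path,
    censoring_tradeoff,
    censoring_tradeoff_from_phenos,
    expected_accuracy,
    fold_correlation,
    make_folds,
    pooled_correlation,
    rank_with_censoring,
    sire_observed_rank,
)


# ---------------------------------------------------------------------------
# censoring trade-off


def test_bd_line_censoring_at_372_days():
    out = censoring_tradeoff(datasets.bd_batches(372.0), 372.0)
    assert out.n_total == 16_032
    assert out.n_alive_at_day == 6_447
    assert out.n_retained == 10_910
    assert round(out.pct_censored) == 40
    assert round(out.pct_data_lost) == 32


def test_b1_line_censoring_at_395_days():
    out = censoring_tradeoff(datasets.b1_batches(395.0), 395.0)
    assert out.n_total == 24_956
    assert out.n_alive_at_day == 13_526
    assert out.n_retained == 19_975
    assert round(out.pct_censored) == 54
    assert round(out.pct_data_lost) == 20


def test_day_before_every_batch_end_loses_nothing():
    out = censoring_tradeoff(datasets.b1_batches(372.0), 372.0)
    assert out.pct_data_lost == 0.0


def test_day_beyond_all_batches_flagged():
    tab = datasets.bd_batches(372.0).assign(n_alive_at_day=0)
    with pytest.warns(UserWarning, match="100% data lost"):
        out = censoring_tradeoff(tab, 9999.0)
    assert out.all_batches_lost and out.pct_data_lost == 100.0


def test_tradeoff_matches_direct_row_counting(tiny_pop):
    _, _, phenos = tiny_pop
    ends = {b: d for b, d in [("b1", 360.0), ("b2", 400.0), ("b3", 420.0)]}
    out = censoring_tradeoff_from_phenos(phenos, ends, 400.0)
    df = phenos.df
    expect_alive = int(((df["survival_days"] >= 400.0)
                        & df["batch"].isin(["b2", "b3"])).sum())
    assert out.n_alive_at_day == expect_alive
    assert out.n_total == len(df)
    assert out.n_retained == int(df["batch"].isin(["b2", "b3"]).sum())


# ---------------------------------------------------------------------------
# folds


def test_fold_sizes_for_207_sires():
    folds = make_folds(np.arange(1, 208), k=5, seed=3)
    sizes = sorted(folds.value_counts().tolist(), reverse=True)
    assert sizes == [42, 42, 41, 41, 41]


def test_folds_partition_and_determinism():
    ids = np.arange(100, 160)
    f1 = make_folds(ids, 5, seed=9)
    f2 = make_folds(ids, 5, seed=9)
    pd.testing.assert_series_equal(f1, f2)
    assert set(f1.index) == set(ids)
    assert f1.index.is_unique
    with pytest.raises(ValueError):
        make_folds(ids, 61, seed=0)
    with pytest.raises(ValueError):
        make_folds([], 2, seed=0)


# ---------------------------------------------------------------------------
# censored ranking


def test_rank_with_censoring_examples():
    ranks = rank_with_censoring([10.0, 30.0, 20.0, 0.0, 0.0],
                                [False, False, False, True, True])
    np.testing.assert_allclose(ranks, [1, 3, 2, 4.5, 4.5])
    np.testing.assert_allclose(rank_with_censoring([5.0, 1.0, 3.0], [False] * 3),
                               [3, 1, 2])


def test_all_censored_warns_and_ties_everything():
    with pytest.warns(UserWarning, match="all records censored"):
        ranks = rank_with_censoring([372.0] * 4, [True] * 4)
    assert (ranks == 2.5).all()


def test_ties_get_average_ranks_and_are_stable():
    r1 = rank_with_censoring([10.0, 10.0, 5.0], [False] * 3)
    np.testing.assert_allclose(r1, [2.5, 2.5, 1])
    r2 = rank_with_censoring([10.0, 10.0, 5.0], [False] * 3)
    np.testing.assert_allclose(r1, r2)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    vals=st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=30),
    data=st.data(),
)
def test_rank_vector_is_valid_tied_ranking(vals, data):
    cens = data.draw(st.lists(st.booleans(), min_size=len(vals), max_size=len(vals)))
    if all(cens):
        with pytest.warns(UserWarning):
            ranks = rank_with_censoring(vals, cens)
    else:
        ranks = rank_with_censoring(vals, cens)
    n = len(vals)
    assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
    # every censored record sits above every non-censored one
    if any(cens) and not all(cens):
        assert ranks[np.array(cens)].min() > ranks[~np.array(cens)].max()


def test_sire_observed_rank():
    ranks = np.array([1.0, 5.0, 2.0, 4.0])
    sires = np.array([7, 7, 8, 9])
    out = sire_observed_rank(ranks, sires)
    assert out.loc[7] == 3.0 and out.loc[8] == 2.0 and out.loc[9] == 4.0


# ---------------------------------------------------------------------------
# correlations


def test_fold_correlation_formula_and_oracle(rng):
    # perfectly concordant: r = 1, SE = 0
    r, se = fold_correlation([1, 2, 3, 4], [10, 20, 30, 40])
    assert r == pytest.approx(1.0) and se == pytest.approx(0.0)
    # SE = (1-r^2)/sqrt(n) at r ~ 0 and n = 25 is 0.2
    for _ in range(10):
        a, b = rng.normal(size=25), rng.normal(size=25)
        r, se = fold_correlation(a, b)
        assert r == pytest.approx(spearmanr(a, b).statistic, abs=1e-10)
        assert se == pytest.approx((1 - r**2) / 5.0)
    with pytest.raises(ValueError):
        fold_correlation([1, 2], [2, 1])
    with pytest.raises(ValueError, match="zero-variance"):
        fold_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pooled_correlation_properties(rng):
    folds = [(rng.normal(size=20), rng.normal(size=20)) for _ in range(3)]
    base = pooled_correlation(folds)
    shifted = [(p + 100 * i, o - 50 * i) for i, (p, o) in enumerate(folds)]
    assert pooled_correlation(shifted) == pytest.approx(base)
    scaled = [(3.0 * p, 3.0 * o) for p, o in folds]
    assert pooled_correlation(scaled) == pytest.approx(base)
    with pytest.raises(ValueError):
        pooled_correlation(folds[:1])


def test_pooled_correlation_equals_fixed_effect_residual_oracle(rng):
    """Pooled correlation == residual correlation after regressing both
    variables on validation-set dummies (least-squares oracle)."""
    folds = [(rng.normal(i, 1, 15), rng.normal(-i, 1, 15)) for i in range(3)]
    pooled = pooled_correlation(folds)
    x = np.concatenate([p for p, _ in folds])
    y = np.concatenate([o for _, o in folds])
    D = np.zeros((45, 3))
    for i in range(3):
        D[15 * i : 15 * (i + 1), i] = 1.0
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    assert pooled == pytest.approx(np.corrcoef(rx, ry)[0, 1])


def test_homogeneous_folds_pool_to_common_correlation(rng):
    rho = 0.6
    folds = []
    for _ in range(4):
        z = rng.normal(size=(2, 500))
        x = z[0]
        y = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        folds.append((x, y))
    assert pooled_correlation(folds) == pytest.approx(rho, abs=0.06)


# ---------------------------------------------------------------------------
# path-coefficient accuracy and expected accuracy


def test_path_coefficient_accuracies_for_both_lines():
    assert round(accuracy_from_path(0.35, np.sqrt(0.36)), 2) == 0.58
    assert round(accuracy_from_path(0.27, np.sqrt(0.53)), 2) == 0.37
    assert accuracy_from_path(0.5, 0.5) == 1.0
    with pytest.warns(UserWarning, match="clipped"):
        assert accuracy_from_path(0.9, 0.5) == 1.0
    with pytest.raises(ValueError):
        accuracy_from_path(0.3, 0.0)


def test_expected_accuracy_printed_values():
    assert round(expected_accuracy(0.8 * 207, 0.36, 799.0), 2) == 0.26
    assert round(expected_accuracy(0.8 * 242, 0.53, 1020.0), 2) == 0.30


def test_expected_accuracy_limits():
    assert expected_accuracy(100, 0.5, 1e12) < 1e-4
    assert expected_accuracy(1e12, 0.5, 100.0) > 0.999
    with pytest.raises(ValueError):
        expected_accuracy(0, 0.5, 100)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    Np=st.floats(1, 1e4), r2=st.floats(0.01, 1.0), Me=st.floats(1, 1e5),
    f=st.floats(1.01, 3.0),
)
def test_expected_accuracy_monotonicity(Np, r2, Me, f):
    base = expected_accuracy(Np, r2, Me)
    assert expected_accuracy(Np * f, r2, Me) >= base
    assert expected_accuracy(Np, min(r2 * f, 1.0), Me) >= base
    assert expected_accuracy(Np, r2, Me * f) <= base


# ---------------------------------------------------------------------------
# cross-validation orchestration


def test_crossvalidation_reports_consistent_bookkeeping(tiny_pop):
    ped, geno, phenos = tiny_pop
    vc = siremodel.VarianceComponents(675.0, 1403.0, 10350.0)
    stats = censorcv.run_crossvalidation(
        phenos, geno, ped, method="pedigree", k=4, seed=2, var_components=vc
    )
    assert stats.fraction_censored == pytest.approx(phenos.df["censored"].mean())
    assert sum(stats.fold_n) == phenos.df["sire_id"].nunique()
    assert len(stats.fold_correlations) == 4
    assert all(se > 0 for se in stats.fold_se)


def test_zero_heritability_gives_null_accuracy():
    from layersel import relmat, simdata
    from layersel.config import SimConfig

    pooled = []
    for seed in range(4):
        cfg = SimConfig(n_generations=1, n_sires_per_gen=50, dams_per_sire=4,
                        daughters_per_dam=5, n_snps=60, sigma2_u=0.0,
                        prop_sires_genotyped=1.0,
                        batch_defs=[("b1", 430.0), ("b2", 460.0)], seed=600 + seed)
        ped = simdata.simulate_pedigree(cfg)
        geno = simdata.simulate_genotypes(ped, cfg)
        ph = simdata.simulate_survival(ped, cfg)
        vc = siremodel.VarianceComponents(200.0, 1403.0, 10350.0)
        stats = censorcv.run_crossvalidation(
            ph, geno, ped, method="ssgblup", k=5, seed=seed, var_components=vc
        )
        pooled.append(stats.pooled_corr)
    # mean pooled correlation indistinguishable from zero (SE ~ 1/sqrt(50)/2)
    assert abs(np.mean(pooled)) < 3 * (1 / np.sqrt(50)) / 2
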