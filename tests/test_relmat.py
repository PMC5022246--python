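import numpy as np
import pytest

from layersel import relmat, simdata
from layersel.config import QCThresholds, SimConfig
from layersel.simdata import GenotypeMatrix

from conftest import kinship_oracle, make_pedigree


# ---------------------------------------------------------------------------
# quality control


def _geno(X, ids=None):
    X = np.asarray(X, dtype=np.int8)
    ids = np.arange(1, X.shape[0] + 1) if ids is None else ids
    snps = np.array([f"s{j}" for j in range(X.shape[1])])
    return GenotypeMatrix(ids, snps, X)


def test_maf_exactly_two_percent_is_excluded():
    # 50 animals, one heterozygote and one missing-free column: MAF = 1/50 = 0.02
    X = np.zeros((50, 2), dtype=np.int8)
    X[0, 0] = 2  # p = 2/100 = 0.02 -> excluded ("2% or less")
    X[:25, 1] = 2  # p = 0.5 -> retained
    out, report = relmat.qc_filter(_geno(X))
    assert list(out.snp_ids) == ["s1"]
    assert report.set_index("filter").loc["maf", "n_removed"] == 1


def test_monomorphic_snp_excluded():
    X = np.zeros((20, 2), dtype=np.int8)
    X[:10, 1] = 2
    out, _ = relmat.qc_filter(_geno(X))
    assert list(out.snp_ids) == ["s1"]


def test_planted_failures_counted_per_filter(rng):
    """100 SNPs with 10 planted failures per filter -> report (10,10,10), 70 kept."""
    n = 60
    X = rng.binomial(2, 0.5, size=(n, 100)).astype(np.int8)
    X[:, 90:] = np.where(rng.binomial(2, 0.5, (n, 10)) > 0, 1, 1)  # all het: HWE fails
    for j in range(10):  # call rate 80% < 90%
        X[: int(0.2 * n), j] = GenotypeMatrix.MISSING
    X[:, 10:20] = 0  # monomorphic: MAF fails
    thr = QCThresholds(max_hwe_chisq=30.0)  # all-het chi2 = n = 60 > 30
    out, report = relmat.qc_filter(_geno(X), thr)
    counts = report.set_index("filter")["n_removed"]
    assert (counts.loc[["call_rate", "maf", "hwe"]] == 10).all()
    assert out.n_snps == 70
    # brute-force re-evaluation of the three rules, in order
    keep = np.ones(100, dtype=bool)
    cr = (X != GenotypeMatrix.MISSING).mean(axis=0)
    keep &= cr >= 0.9
    for j in np.flatnonzero(keep):
        x = X[:, j][X[:, j] != GenotypeMatrix.MISSING]
        p = x.mean() / 2
        if min(p, 1 - p) <= 0.02:
            keep[j] = False
    assert keep.sum() == 80  # HWE handled by construction (only all-het cols fail)


def test_qc_idempotent(rng):
    X = rng.binomial(2, rng.uniform(0.05, 0.5, 50), size=(40, 50)).astype(np.int8)
    X[rng.random(X.shape) < 0.05] = GenotypeMatrix.MISSING
    once, _ = relmat.qc_filter(_geno(X))
    twice, rep2 = relmat.qc_filter(once)
    assert (twice.X == once.X).all()
    assert rep2.set_index("filter")["n_removed"].loc[["call_rate", "maf", "hwe"]].sum() == 0


def test_all_snps_removed_raises():
    X = np.zeros((10, 3), dtype=np.int8)
    with pytest.raises(relmat.AllSNPsRemoved):
        relmat.qc_filter(_geno(X))


# ---------------------------------------------------------------------------
# pedigree relationship matrix


def test_textbook_relationships():
    # founders 1,2,3; full sibs 4,5; paternal half sib 6
    ped = make_pedigree([
        (1, 0, 0, 1, "M"), (2, 0, 0, 1, "F"), (3, 0, 0, 1, "F"),
        (4, 1, 2, 2, "M"), (5, 1, 2, 2, "F"), (6, 1, 3, 2, "F"),
    ])
    A = relmat.build_A(ped)
    assert A[0, 0] == 1.0 and A[0, 1] == 0.0  # unrelated founders -> identity
    assert A[0, 3] == 0.5  # parent-offspring
    assert A[3, 4] == 0.5  # full sibs
    assert A[3, 5] == 0.25  # half sibs


def test_full_sib_mating_gives_inbred_diagonal():
    ped = make_pedigree([
        (1, 0, 0, 1, "M"), (2, 0, 0, 1, "F"),
        (3, 1, 2, 2, "M"), (4, 1, 2, 2, "F"),
        (5, 3, 4, 3, "M"),
    ])
    A = relmat.build_A(ped)
    assert A[4, 4] == pytest.approx(1.25)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_tabular_matches_coancestry_oracle_on_small_pedigrees(seed):
    """Random pedigrees of <= 8 animals: tabular A equals recursive kinship."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(1, 9):
        if a <= 3 or rng.random() < 0.3:
            rows.append((a, 0, 0, 1, "M" if a % 2 else "F"))
        else:
            s = int(rng.integers(1, a))
            d = int(rng.integers(1, a))
            rows.append((a, s, d, 2, "M" if a % 2 else "F"))
    ped = make_pedigree(rows)
    A = relmat.build_A(ped)
    np.testing.assert_allclose(A, kinship_oracle(ped), atol=1e-12)


def test_henderson_inverse_matches_dense_inverse(tiny_pop):
    ped, _, _ = tiny_pop
    A = relmat.build_A(ped)
    np.testing.assert_allclose(relmat.A_inverse(ped, A), np.linalg.inv(A), atol=1e-8)


def test_cyclic_pedigree_rejected():
    import pandas as pd

    df = pd.DataFrame(
        {"animal": [1, 2], "sire": [2, 1], "dam": [0, 0],
         "generation": [1, 1], "sex": ["M", "M"]}
    )
    with pytest.raises(ValueError):
        simdata.Pedigree(df)


# ---------------------------------------------------------------------------
# genomic relationship matrix


def test_vanraden_hand_example():
    # observed p = (0.5, 0.5): Z = [[-1,1],[1,-1]], denominator 2*(0.25+0.25)=1
    G = relmat.build_G(_geno([[0, 2], [2, 0]]))
    np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])


def test_identical_rows_share_diagonal_and_offdiagonal():
    G = relmat.build_G(_geno([[0, 2, 1], [0, 2, 1], [2, 0, 1]]))
    assert G[0, 0] == pytest.approx(G[1, 1])
    assert G[0, 1] == pytest.approx(G[0, 0])


def test_monomorphic_only_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        relmat.build_G(_geno([[2, 2], [2, 2]]))


def test_mean_diagonal_near_one_for_founders():
    cfg = SimConfig(n_generations=1, n_sires_per_gen=300, dams_per_sire=1,
                    daughters_per_dam=5, n_snps=500, prop_sires_genotyped=1.0, seed=13)
    ped = simdata.simulate_pedigree(cfg)
    G = relmat.build_G(simdata.simulate_genotypes(ped, cfg))
    d = np.diag(G)
    assert abs(d.mean() - 1.0) < 3 * d.std() / np.sqrt(d.size)
    # and G is PSD
    assert np.linalg.eigvalsh(G).min() > -1e-8


# ---------------------------------------------------------------------------
# single-step blending


def _small_system(seed=0, n_geno=3):
    rng = np.random.default_rng(seed)
    ped = make_pedigree([
        (1, 0, 0, 1, "M"), (2, 0, 0, 1, "F"), (3, 0, 0, 1, "F"),
        (4, 1, 2, 2, "M"), (5, 1, 3, 2, "M"), (6, 1, 2, 2, "M"),
    ])
    A = relmat.build_A(ped)
    gidx = np.array([3, 4, 5])[:n_geno]
    A22 = A[np.ix_(gidx, gidx)]
    E = rng.normal(0, 0.15, size=(n_geno, n_geno))
    G = A22 + E @ E.T  # a PD perturbation of A22
    return ped, A, A22, G, gidx


@pytest.mark.parametrize("convention", ["as_printed", "complement"])
def test_blended_inverse_matches_dense_assembled_H(convention):
    """H^-1 from the block formula equals inv(H) with H assembled densely."""
    ped, A, A22, G, gidx = _small_system()
    alpha = 0.95
    beta = 2 - alpha if convention == "as_printed" else 1 - alpha
    Gw = alpha * G + beta * A22
    n = A.shape[0]
    rest = np.setdiff1d(np.arange(n), gidx)
    order = np.concatenate([rest, gidx])
    Ao = A[np.ix_(order, order)]
    n1 = len(rest)
    A11, A12, A21 = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, :n1]
    Ai22 = np.linalg.inv(A22)
    D = Gw - A22
    H = np.block([
        [A11 + A12 @ Ai22 @ D @ Ai22 @ A21, A12 @ Ai22 @ Gw],
        [Gw @ Ai22 @ A21, Gw],
    ])
    H_inv_dense = np.linalg.inv(H)
    got = relmat.blend_H_inverse(np.linalg.inv(A), A22, G, gidx, alpha, convention)
    got_o = got[np.ix_(order, order)]
    np.testing.assert_allclose(got_o, H_inv_dense, atol=1e-8)


def test_g_equal_a22_complement_alpha_one_recovers_A_inverse():
    ped, A, A22, G, gidx = _small_system()
    got = relmat.blend_H_inverse(np.linalg.inv(A), A22, A22, gidx, 1.0, "complement")
    np.testing.assert_allclose(got, np.linalg.inv(A), atol=1e-10)


def test_g_equal_a22_printed_convention_keeps_shrinkage_term():
    """With beta = 2 - alpha the blend is 2*A22 even when G = A22, so the
    augmentation is -(1/2) A22^-1, not zero."""
    ped, A, A22, G, gidx = _small_system()
    got = relmat.blend_H_inverse(np.linalg.inv(A), A22, A22, gidx, 0.95, "as_printed")
    expected = np.linalg.inv(A).copy()
    expected[np.ix_(gidx, gidx)] += np.linalg.inv(2 * A22) - np.linalg.inv(A22)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_singular_blend_rejected():
    ped, A, A22, G, gidx = _small_system()
    bad = np.zeros_like(A22)
    with pytest.raises(np.linalg.LinAlgError, match="lower alpha"):
        relmat.blend_H_inverse(np.linalg.inv(A), A22 * 0, bad, gidx, 0.95)


# ---------------------------------------------------------------------------
# LD summaries


def test_var_offdiag_identity_and_hand_set():
    assert relmat.var_offdiag(np.eye(4)) == 0.0
    M = np.zeros((3, 3))
    M[0, 1] = M[1, 0] = 0.0
    M[0, 2] = M[2, 0] = 0.25
    M[1, 2] = M[2, 1] = 0.5
    assert relmat.var_offdiag(M) == pytest.approx(np.var([0.0, 0.25, 0.5], ddof=1))
    with pytest.raises(ValueError):
        relmat.var_offdiag(np.eye(1))


def test_me_two_point_difference():
    d = 0.05
    A22 = np.eye(4)
    D = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    vals = np.array([d, -d, d, -d, d, -d])
    D[iu] = vals
    D = D + D.T
    arch = relmat.compute_Me(A22 + D, A22)
    assert arch.var_G_minus_A22 == pytest.approx(np.var(vals, ddof=1))
    assert arch.Me == pytest.approx(1.0 / np.var(vals, ddof=1))


def test_me_infinite_when_no_ld_signal():
    arch = relmat.compute_Me(np.eye(5), np.eye(5))
    assert np.isinf(arch.Me)


def test_me_finite_positive_on_simulated_sires(tiny_pop):
    ped, geno, _ = tiny_pop
    A = relmat.build_A(ped)
    A22 = relmat.subset_A(A, ped, geno.ids)
    arch = relmat.compute_Me(relmat.build_G(geno), A22)
    assert 0 < arch.Me < np.inf
    assert arch.var_offdiag_A >= 0
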