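"""Censoring bookkeeping, censored-rank cross-validation and EBV accuracy.

Survival records of hens still alive at a batch's endpoint are censored, so
EBV validation cannot correlate predictions with raw phenotypes.  Instead,
fixed-effect-corrected phenotypes are ranked with all censored records placed
(at their common mean rank) above the highest non-censored rank, a sire's
observed rank is the mean rank of its daughters, and the accuracy of sire EBV
is obtained from the path-coefficient identity

    rho(A, Ahat) = rho(Ahat, Pbar_off) / rho(A, Pbar_off),

dividing the cross-validation correlation by the accuracy of progeny testing
sqrt(sigma2_u / sigma2_pbar).  The module also evaluates the expected genomic
accuracy sqrt(Np r^2 / (Np r^2 + Me)) from reference-population size,
reference reliability and the effective number of chromosome segments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import relmat, siremodel
from .simdata import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "CensoringTradeoff",
    "censoring_tradeoff",
    "make_folds",
    "rank_with_censoring",
    "sire_observed_rank",
    "fold_correlation",
    "pooled_correlation",
    "accuracy_from_path",
    "expected_accuracy",
    "run_crossvalidation",
    "AccuracyStats",
]


@dataclass
class CensoringTradeoff:
    """Consequences of one candidate common censoring day.

    Batches that end before the candidate day cannot be included (their hens
    are "data lost"); hens still alive at the day, over all batches, are the
    censored fraction of the full dataset.
    """

    candidate_day: float
    n_total: int
    n_retained: int
    n_alive_at_day: int
    all_batches_lost: bool = False

    @property
    def pct_censored(self) -> float:
        return 100.0 * self.n_alive_at_day / self.n_total

    @property
    def pct_data_lost(self) -> float:
        return 100.0 * (self.n_total - self.n_retained) / self.n_total


def censoring_tradeoff(batches: pd.DataFrame, candidate_day: float) -> CensoringTradeoff:
    """Evaluate a common censoring day against per-batch survival summaries.

    ``batches`` needs one row per batch with columns ``n_ind`` (hens),
    ``end_day`` (the batch's own endpoint) and ``n_alive_at_day`` (hens still
    alive at ``candidate_day``; 0 for batches that ended before it).
    """
    need = {"n_ind", "end_day", "n_alive_at_day"}
    if not need.issubset(batches.columns):
        raise ValueError(f"batch table must have columns {sorted(need)}")
    n_total = int(batches["n_ind"].sum())
    reached = batches["end_day"] >= candidate_day
    n_retained = int(batches.loc[reached, "n_ind"].sum())
    n_alive = int(batches["n_alive_at_day"].sum())
    out = CensoringTradeoff(
        candidate_day=candidate_day,
        n_total=n_total,
        n_retained=n_retained,
        n_alive_at_day=n_alive,
        all_batches_lost=not bool(reached.any()),
    )
    if out.all_batches_lost:
        warnings.warn(
            f"candidate day {candidate_day} is beyond every batch end: 100% data lost",
            UserWarning,
        )
    return out


def censoring_tradeoff_from_phenos(
    phenos: PhenotypeTable, batch_ends: dict, candidate_day: float
) -> CensoringTradeoff:
    """Same trade-off computed by direct row counting on a phenotype table."""
    df = phenos.df
    rows = []
    for batch, g in df.groupby("batch"):
        end = batch_ends[batch]
        alive = int(((g["survival_days"] >= candidate_day) & (end >= candidate_day)).sum())
        rows.append({"batch": batch, "n_ind": len(g), "end_day": end, "n_alive_at_day": alive})
    return censoring_tradeoff(pd.DataFrame(rows), candidate_day)


def make_folds(ids, k: int, seed: int) -> pd.Series:
    """Near-equal random partition of ``ids`` into ``k`` mutually exclusive
    validation sets; deterministic under ``seed``."""
    ids = np.asarray(ids)
    if len(ids) == 0:
        raise ValueError("empty id list")
    if k < 2 or k > len(ids):
        raise ValueError("need 2 <= k <= number of ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return pd.Series(assignment, index=pd.Index(ids, name="sire_id"), name="fold")


def rank_with_censoring(corrected: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Rank corrected phenotypes, censored records above all others.

    Non-censored records get average ranks 1..m ascending in survival;
    every censored record gets the mean of ranks m+1..n (assigning random
    ranks above the top and replacing them by their mean collapses to this
    deterministically).  The output is a valid tied-rank vector: its sum is
    n(n+1)/2.
    """
    corrected = np.asarray(corrected, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    n = len(corrected)
    ranks = np.empty(n)
    m = int((~censored).sum())
    if m == 0:
        warnings.warn("all records censored: every rank is the common mean", UserWarning)
        ranks[:] = (n + 1) / 2.0
        return ranks
    ranks[~censored] = rankdata(corrected[~censored], method="average")
    ranks[censored] = m + (n - m + 1) / 2.0
    return ranks


def sire_observed_rank(ranks: np.ndarray, sire_ids: np.ndarray) -> pd.Series:
    """Mean observed daughter rank per sire."""
    s = pd.Series(np.asarray(ranks, dtype=float)).groupby(np.asarray(sire_ids)).mean()
    s.index.name = "sire_id"
    return s.rename("observed_rank")


def fold_correlation(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation and its standard error (1 - r^2)/sqrt(n).

    Computed as the Pearson correlation of average-tie ranks.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(predicted)
    if n < 3:
        raise ValueError("need at least 3 sires per fold")
    rp, ro = rankdata(predicted), rankdata(observed)
    if np.std(rp) == 0 or np.std(ro) == 0:
        raise ValueError("zero-variance rank vector: correlation undefined")
    r = float(np.corrcoef(rp, ro)[0, 1])
    return r, (1.0 - r**2) / np.sqrt(n)


def pooled_correlation(per_fold: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Correlation of within-fold-centred predicted and observed ranks.

    Equals the residual correlation of a bivariate model with validation set
    as the only fixed effect (homogeneous residual covariance), pooled over
    all sires; folds with fewer than two sires are excluded.
    """
    if len(per_fold) < 2:
        raise ValueError("need at least two folds")
    xs, ys = [], []
    for pred, obs in per_fold:
        pred, obs = np.asarray(pred, dtype=float), np.asarray(obs, dtype=float)
        if len(pred) < 2:
            continue
        xs.append(pred - pred.mean())
        ys.append(obs - obs.mean())
    x, y = np.concatenate(xs), np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_from_path(pooled: float, progeny_accuracy: float) -> float:
    """EBV accuracy rho(A, Ahat) = rho(Ahat, Pbar) / rho(A, Pbar)."""
    if not (0 < progeny_accuracy <= 1):
        raise ValueError("progeny accuracy must be in (0, 1]")
    acc = pooled / progeny_accuracy
    if acc > 1:
        warnings.warn(f"path-coefficient accuracy {acc:.3f} > 1 clipped to 1", UserWarning)
        acc = 1.0
    return float(acc)


def expected_accuracy(Np: float, r2: float, Me: float) -> float:
    """Expected genomic accuracy sqrt(Np r^2 / (Np r^2 + Me)).

    ``Np`` is the number of (progeny-tested) records in the reference
    population, ``r2`` the reliability of one such record, and ``Me`` the
    effective number of independently segregating chromosome segments.
    """
    if min(Np, r2, Me) <= 0:
        raise ValueError("all inputs must be positive")
    return float(np.sqrt(Np * r2 / (Np * r2 + Me)))


@dataclass
class AccuracyStats:
    """Cross-validation summary: per-fold correlations, pooled correlation,
    progeny-test accuracy and the resulting EBV accuracy."""

    fold_correlations: list[float]
    fold_se: list[float]
    fold_n: list[int]
    pooled_corr: float
    progeny_accuracy: float
    ebv_accuracy: float
    method: str
    scenario: str
    fraction_censored: float
    extras: dict = field(default_factory=dict)

    @property
    def mean_fold_corr(self) -> float:
        return float(np.mean(self.fold_correlations))


def run_crossvalidation(
    phenos: PhenotypeTable,
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    scenario: str = "geno_only",
    method: str = "ssgblup",
    k: int = 5,
    seed: int = 1,
    var_components: siremodel.VarianceComponents | None = None,
    alpha: float = 0.95,
    beta_convention: str = "as_printed",
) -> AccuracyStats:
    """Censored-rank cross-validation of sire EBV.

    Folds partition the genotyped sires; each fold's sires form the
    validation set and their daughters' records are removed from the training
    data (scenario ``geno_only`` also drops the daughters of non-genotyped
    sires from training; ``geno_plus_ungeno`` keeps them).  Per fold, sire
    EBV are predicted by pedigree-BLUP or ssGBLUP and correlated (Spearman)
    with the mean corrected-and-censoring-ranked daughter phenotype; the
    pooled correlation divided by the progeny-test accuracy gives the EBV
    accuracy.
    """
    if scenario not in ("geno_only", "geno_plus_ungeno"):
        raise ValueError("scenario must be 'geno_only' or 'geno_plus_ungeno'")
    df = phenos.df
    geno_sires = np.asarray(genotypes.ids)
    # validation requires daughter records: fold over genotyped sires with them
    cv_sires = geno_sires[np.isin(geno_sires, df["sire_id"].unique())]
    if len(cv_sires) < k:
        raise ValueError("fewer genotyped sires with daughters than folds")

    # fixed-effect correction and censored ranking on the full data
    _, corrected, _ = siremodel.fit_fixed_effects(phenos)
    ranks = rank_with_censoring(corrected.to_numpy(), df["censored"].to_numpy())
    observed = sire_observed_rank(ranks, df["sire_id"].to_numpy())

    # relationship matrices
    A = relmat.build_A(pedigree)
    A_inv = relmat.A_inverse(pedigree, A)
    animal_ids = pedigree.animals
    if method == "ssgblup":
        A22 = relmat.subset_A(A, pedigree, geno_sires)
        G = relmat.build_G(genotypes)
        K_inv = relmat.blend_H_inverse(
            A_inv, A22, G, geno_sires - 1, alpha=alpha, beta_convention=beta_convention
        )
    else:
        K_inv = A_inv

    if var_components is None:
        fit_all = siremodel.fit_sire_model(
            phenos, K_inv=K_inv, animal_ids=animal_ids, method=method
        )
        var_components = fit_all.vc

    # progeny-test accuracy from the full data
    progeny_means = df.groupby("sire_id")["survival_days"].mean()
    vc = siremodel.derive_params(var_components, progeny_means)
    rho_progeny = np.sqrt(min(vc.sigma2_u / vc.sigma2_pbar, 1.0))

    folds = make_folds(cv_sires, k, seed)
    per_fold, rs, ses, ns = [], [], [], []
    for f in range(k):
        val_sires = folds.index[folds == f].to_numpy()
        train_mask = ~df["sire_id"].isin(val_sires)
        if scenario == "geno_only":
            train_mask &= df["sire_id"].isin(geno_sires)
        train = PhenotypeTable(df[train_mask].reset_index(drop=True))
        try:
            fit = siremodel.fit_sire_model(
                train,
                K_inv=K_inv,
                animal_ids=animal_ids,
                method=method,
                var_components=var_components,
            )
        except Exception as err:  # propagate with fold context
            raise RuntimeError(f"fold {f} failed: {err}") from err
        pred = fit.ebv.loc[val_sires].to_numpy()
        obs = observed.loc[val_sires].to_numpy()
        r, se = fold_correlation(pred, obs)
        per_fold.append((rankdata(pred), rankdata(obs)))
        rs.append(r)
        ses.append(se)
        ns.append(len(val_sires))

    pooled = pooled_correlation(per_fold)
    acc = accuracy_from_path(max(pooled, 0.0), rho_progeny) if pooled > 0 else pooled / rho_progeny
    return AccuracyStats(
        fold_correlations=rs,
        fold_se=ses,
        fold_n=ns,
        pooled_corr=pooled,
        progeny_accuracy=float(rho_progeny),
        ebv_accuracy=float(acc),
        method=method,
        scenario=scenario,
        fraction_censored=phenos.fraction_censored(),
    )
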