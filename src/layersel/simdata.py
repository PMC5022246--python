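"""Synthetic populations with the structure the survival analysis assumes.

The generator produces (i) a multi-generation pedigree of breeding males and
females, (ii) gene-dropped SNP genotypes for a subset of the sires, and
(iii) survival records on paternal half-sib daughters housed five to a cage,
with batch-specific censoring.  The phenotypic model is the generative
direction of the sire model used downstream:

    y = mu + batch + cross + house_row_level + u_sire + c_cage + e,

where ``u_sire`` is the total sire effect (direct plus indirect genetic
effects are not separated; the cage design identifies only their sum), with
variance ``sigma2_u``, cage effects with variance ``sigma2_c`` and residuals
with variance ``sigma2_e``.

Under the default ``snp`` architecture, sire effects are sums of additive
effects at the simulated loci, so they are transmitted through the actual
gene-dropped alleles and genomic relationships among sires are informative
about their effects.  The ``infinitesimal`` mode transmits effects through
the pedigree only (half-parental plus a Mendelian-sampling deviation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, UNKNOWN_PARENT

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "PhenotypeTable",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_survival",
]

# independent, reproducible random streams derived from the root seed
_STREAM_PEDIGREE = 11
_STREAM_GENEDROP = 12
_STREAM_GENOSUBSET = 13
_STREAM_SURVIVAL = 14
_STREAM_EFFECTS = 15


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class Pedigree:
    """Animal/sire/dam triples, parents-first, with generation and sex.

    IDs are 1-based consecutive integers; ``0`` codes an unknown parent.
    """

    df: pd.DataFrame  # columns: animal, sire, dam, generation, sex

    def __post_init__(self) -> None:
        need = {"animal", "sire", "dam", "generation", "sex"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"pedigree frame must have columns {sorted(need)}")
        a = self.df["animal"].to_numpy()
        for col in ("sire", "dam"):
            p = self.df[col].to_numpy()
            known = p != UNKNOWN_PARENT
            if np.any(p[known] >= a[known]):
                raise ValueError("parents must precede offspring (no animal its own ancestor)")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy()

    def sires(self, generation: int | None = None) -> np.ndarray:
        m = self.df["sex"] == "M"
        if generation is not None:
            m &= self.df["generation"] == generation
        return self.df.loc[m, "animal"].to_numpy()

    def parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based parent indices, -1 for unknown, assuming dense 1..n IDs."""
        s = self.df["sire"].to_numpy() - 1
        d = self.df["dam"].to_numpy() - 1
        return s, d


@dataclass
class GenotypeMatrix:
    """0/1/2 allele counts for an ordered list of animals; ``-1`` = missing."""

    ids: np.ndarray
    snp_ids: np.ndarray
    X: np.ndarray  # shape (n_animals, n_snps), int8

    MISSING = -1

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match id lists")
        ok = np.isin(self.X, [self.MISSING, 0, 1, 2])
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2} or missing (-1)")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Observed allele frequency per SNP, ignoring missing calls."""
        X = np.ma.masked_equal(self.X, self.MISSING)
        return np.asarray(X.mean(axis=0) / 2.0)

    def call_rate(self) -> np.ndarray:
        return (self.X != self.MISSING).mean(axis=0)


@dataclass
class PhenotypeTable:
    """One row per hen: survival days, censoring flag, design factors, sire."""

    df: pd.DataFrame
    true_sire_effects: pd.Series | None = field(default=None, repr=False)

    REQUIRED = (
        "hen_id",
        "survival_days",
        "censored",
        "batch",
        "cross",
        "house_row_level",
        "cage_id",
        "sire_id",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
        if (self.df["survival_days"] <= 0).any():
            raise ValueError("survival_days must be positive")
        per_cage = self.df.groupby("cage_id")[["sire_id", "cross"]].nunique()
        if (per_cage > 1).any().any():
            raise ValueError("each cage must hold a single sire's daughters of one cross")

    @property
    def n(self) -> int:
        return len(self.df)

    def fraction_censored(self) -> float:
        return float(self.df["censored"].mean())


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Nested-mating pedigree: each sire mated to ``dams_per_sire`` dams.

    Generation 1 animals are founders with unknown parents.  In later
    generations each new sire and each new dam is the offspring of a
    (sire, dam) couple drawn from the previous generation's matings, so every
    non-founder has both parents identified and parents precede offspring.
    """
    rng = _rng(config.seed, _STREAM_PEDIGREE)
    S, D = config.n_sires_per_gen, config.n_sires_per_gen * config.dams_per_sire
    rows: list[tuple[int, int, int, int, str]] = []
    nxt = 1
    prev_couples: np.ndarray | None = None  # (n_couples, 2) of (sire, dam)
    for g in range(1, config.n_generations + 1):
        males = np.arange(nxt, nxt + S)
        nxt += S
        females = np.arange(nxt, nxt + D)
        nxt += D
        if prev_couples is None:
            for a in males:
                rows.append((a, UNKNOWN_PARENT, UNKNOWN_PARENT, g, "M"))
            for a in females:
                rows.append((a, UNKNOWN_PARENT, UNKNOWN_PARENT, g, "F"))
        else:
            pick = rng.integers(0, len(prev_couples), size=S + D)
            parents = prev_couples[pick]
            for a, (s, d) in zip(males, parents[:S]):
                rows.append((a, int(s), int(d), g, "M"))
            for a, (s, d) in zip(females, parents[S:]):
                rows.append((a, int(s), int(d), g, "F"))
        prev_couples = np.column_stack(
            [np.repeat(males, config.dams_per_sire), females]
        )
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])
    return Pedigree(df)


def _gene_drop(pedigree: Pedigree, config: SimConfig, rng: np.random.Generator):
    """Drop alleles through the pedigree; returns (haplotypes, founder freqs).

    Founder alleles are Bernoulli draws at per-SNP frequencies sampled
    uniformly in [maf_low, maf_high]; each descendant receives one allele per
    parent, picked at random per locus (free recombination between loci, so
    linkage disequilibrium among the simulated sires arises from drift and
    family structure only).
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    n, m = pedigree.n, config.n_snps
    p0 = rng.uniform(config.maf_low, config.maf_high, size=m)
    H = np.zeros((n, 2, m), dtype=np.int8)
    sire_ix, dam_ix = pedigree.parent_arrays()
    for i in range(n):
        for k, par in enumerate((sire_ix[i], dam_ix[i])):
            if par < 0:
                H[i, k] = rng.random(m) < p0
            else:
                which = rng.integers(0, 2, size=m)
                H[i, k] = H[par, which, np.arange(m)]
    return H, p0


def genotyped_sire_ids(pedigree: Pedigree, config: SimConfig) -> np.ndarray:
    """The declared genotyped subset: a seed-deterministic random fraction
    ``prop_sires_genotyped`` of all sires."""
    rng = _rng(config.seed, _STREAM_GENOSUBSET)
    sires = pedigree.sires()
    k = max(1, int(round(config.prop_sires_genotyped * len(sires))))
    return np.sort(rng.choice(sires, size=k, replace=False))


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Genotypes (0/1/2) of the genotyped sires from a single gene drop."""
    rng = _rng(config.seed, _STREAM_GENEDROP)
    H, _ = _gene_drop(pedigree, config, rng)
    ids = genotyped_sire_ids(pedigree, config)
    X = H.sum(axis=1, dtype=np.int8)[ids - 1]
    snp_ids = np.array([f"snp{j + 1}" for j in range(config.n_snps)])
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, X=X)


def _true_effects(pedigree: Pedigree, config: SimConfig) -> np.ndarray:
    """Total sire effects u for every pedigree animal (variance sigma2_u)."""
    rng = _rng(config.seed, _STREAM_GENEDROP)
    if config.architecture == "snp":
        H, p0 = _gene_drop(pedigree, config, rng)
        erng = _rng(config.seed, _STREAM_EFFECTS)
        denom = np.sum(2.0 * p0 * (1.0 - p0))
        w = erng.normal(0.0, np.sqrt(config.sigma2_u / denom), size=config.n_snps)
        dosage = H.sum(axis=1).astype(float)
        return (dosage - 2.0 * p0) @ w
    # infinitesimal: half-parental average plus Mendelian deviation
    erng = _rng(config.seed, _STREAM_EFFECTS)
    u = np.zeros(pedigree.n)
    sire_ix, dam_ix = pedigree.parent_arrays()
    for i in range(pedigree.n):
        if sire_ix[i] < 0 and dam_ix[i] < 0:
            u[i] = erng.normal(0.0, np.sqrt(config.sigma2_u))
        else:
            mid = 0.0
            mend = config.sigma2_u
            if sire_ix[i] >= 0:
                mid += 0.5 * u[sire_ix[i]]
                mend -= 0.25 * config.sigma2_u
            if dam_ix[i] >= 0:
                mid += 0.5 * u[dam_ix[i]]
                mend -= 0.25 * config.sigma2_u
            u[i] = mid + erng.normal(0.0, np.sqrt(mend))
    return u


def simulate_survival(pedigree: Pedigree, config: SimConfig) -> PhenotypeTable:
    """Daughter survival records for the final-generation sires.

    Each sire's ``dams_per_sire * daughters_per_dam`` daughters are chunked
    into cages of exactly ``cage_size`` birds (all paternal half-sibs of one
    cross).  Every cage is assigned to a batch; records exceeding the batch's
    endpoint are truncated there and flagged censored.
    """
    per_sire = config.dams_per_sire * config.daughters_per_dam
    if config.strict_cages and per_sire % config.cage_size != 0:
        raise ValueError(
            f"{per_sire} daughters per sire cannot fill cages of {config.cage_size}; "
            "adjust counts or disable strict_cages (under-filled cages are dropped)"
        )
    rng = _rng(config.seed, _STREAM_SURVIVAL)
    u_all = _true_effects(pedigree, config)
    last_gen = int(pedigree.df["generation"].max())
    sires = pedigree.sires(last_gen)

    batches = list(config.batch_defs)
    eff = {
        "batch": rng.normal(0.0, config.fixed_effect_sds.get("batch", 0.0), len(batches)),
        "cross": rng.normal(0.0, config.fixed_effect_sds.get("cross", 0.0), config.n_crosses),
        "house_row_level": rng.normal(
            0.0, config.fixed_effect_sds.get("house_row_level", 0.0), config.n_locations
        ),
    }

    n_cages_per_sire = per_sire // config.cage_size
    rows = []
    hen = 1
    cage = 0
    for s in sires:
        u_s = u_all[s - 1]
        cross = int(rng.integers(0, config.n_crosses))
        for _ in range(n_cages_per_sire):
            cage += 1
            b = int(rng.integers(0, len(batches)))
            batch_id, end_day = batches[b]
            loc = int(rng.integers(0, config.n_locations))
            c_eff = rng.normal(0.0, np.sqrt(config.sigma2_c))
            mu_cage = (
                config.mu
                + eff["batch"][b]
                + eff["cross"][cross]
                + eff["house_row_level"][loc]
                + u_s
                + c_eff
            )
            e = rng.normal(0.0, np.sqrt(config.sigma2_e), size=config.cage_size)
            y_true = mu_cage + e
            censored = y_true >= end_day
            y = np.where(censored, end_day, y_true)
            y = np.maximum(y, 1.0)
            for j in range(config.cage_size):
                rows.append(
                    (
                        hen,
                        float(y[j]),
                        bool(censored[j]),
                        batch_id,
                        f"cross{cross + 1}",
                        f"loc{loc + 1}",
                        f"cage{cage}",
                        int(s),
                    )
                )
                hen += 1
    df = pd.DataFrame(rows, columns=list(PhenotypeTable.REQUIRED))
    true_u = pd.Series(u_all[sires - 1], index=pd.Index(sires, name="sire_id"), name="u")
    return PhenotypeTable(df, true_sire_effects=true_u)
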