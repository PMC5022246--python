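"""Sire-model REML and BLUP for censored survival time.

The model is

    y = X b + W c + Z u + e,

with fixed batch, cross and house-row-level effects, random cage effects
c ~ N(0, I sigma2_c), random sire effects u ~ N(0, K sigma2_u) with K the
pedigree (A) or blended (H) relationship matrix over *all* pedigree animals,
and residuals e ~ N(0, I sigma2_e).  Censored records enter at their
censoring-day value, mirroring the linear-model treatment of the analysis
this package reimplements.  Because cages hold paternal half-sibs only, the
sire effect is the total sire effect (direct plus indirect genetic effects).

Variance components are estimated by average-information REML with EM
fallback, both driven by Henderson's mixed-model equations; the restricted
log-likelihood is evaluated through the standard MME determinant identity and
is unit-tested against a direct dense-V evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .simdata import PhenotypeTable

__all__ = [
    "VarianceComponents",
    "SireModelFit",
    "fit_fixed_effects",
    "fit_sire_model",
    "reml_loglik_dense",
    "derive_params",
    "progeny_test_accuracy",
]

_FACTORS = ("batch", "cross", "house_row_level")


@dataclass
class VarianceComponents:
    """REML estimates (days^2) with approximate standard errors.

    ``sigma2_AT = 4 * sigma2_u`` is the total additive genetic variance;
    ``sigma2_P`` is the phenotypic variance ``sigma2_u + sigma2_c + sigma2_e``
    (the convention the published Table-5 values obey numerically;
    ``sigma2_P_footnote`` carries the 4*sigma2_u alternative); ``T2`` is
    ``sigma2_AT / sigma2_P``; ``sigma2_pbar`` the among-sire variance of
    daughter phenotype means.
    """

    sigma2_u: float
    sigma2_c: float
    sigma2_e: float
    se: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)
    sigma2_pbar: float | None = None
    se_sigma2_pbar: float | None = None
    n_sires_pbar: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma2_u, self.sigma2_c, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def sigma2_AT(self) -> float:
        return 4.0 * self.sigma2_u

    @property
    def sigma2_P(self) -> float:
        return self.sigma2_u + self.sigma2_c + self.sigma2_e

    @property
    def sigma2_P_footnote(self) -> float:
        return self.sigma2_AT + self.sigma2_c + self.sigma2_e

    @property
    def T2(self) -> float:
        return self.sigma2_AT / self.sigma2_P


@dataclass
class SireModelFit:
    vc: VarianceComponents
    ebv: pd.Series  # EBV for every animal in K, ancestors included
    pev: pd.Series  # prediction-error variance per animal
    loglik: float
    n_iter: int
    converged: bool
    method: str
    steps: list = field(default_factory=list)


def fit_fixed_effects(phenos: PhenotypeTable):
    """Least-squares fit of the fixed factors only; residuals are the
    corrected phenotypes used by the censored-rank cross-validation.

    Factors with a single observed level are dropped (intercept-only in the
    degenerate case, so residuals are deviations from the mean).  Returns
    (effects, residuals, anova_table) where the ANOVA table holds type-II
    F tests per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = phenos.df
    terms = [f"C({f})" for f in _FACTORS if df[f].nunique() >= 2]
    formula = "survival_days ~ " + (" + ".join(terms) if terms else "1")
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2) if terms else None
    effects = fit.params
    residuals = pd.Series(fit.resid.to_numpy(), index=df.index, name="corrected")
    return effects, residuals, anova


def _design(phenos: PhenotypeTable, animal_ids: np.ndarray):
    """Full-rank fixed design X, cage index, and sire index into animal_ids."""
    df = phenos.df
    parts = [np.ones((len(df), 1))]
    for f in _FACTORS:
        if df[f].nunique() >= 2:
            d = pd.get_dummies(df[f], drop_first=True, dtype=float)
            parts.append(d.to_numpy())
    X = np.hstack(parts)
    # reference-level dummies can still be collinear in small/unbalanced
    # designs; keep an independent column subset (pivoted QR)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    if rank < X.shape[1]:
        X = X[:, np.sort(piv[:rank])]
    cage_codes, _ = pd.factorize(df["cage_id"], sort=True)
    id_pos = {int(a): i for i, a in enumerate(animal_ids)}
    try:
        sire_ix = np.array([id_pos[int(s)] for s in df["sire_id"]])
    except KeyError as err:
        raise ValueError(f"sire {err} not covered by the relationship matrix") from None
    return X, cage_codes, sire_ix


class _MME:
    """Mixed-model equations for one (sigma2_u, sigma2_c, sigma2_e) point."""

    def __init__(self, X, cage, sire_ix, y, K_inv, logdet_K):
        self.n, self.p = X.shape
        self.qc = int(cage.max()) + 1
        self.qu = K_inv.shape[0]
        self.X, self.cage, self.sire_ix, self.y = X, cage, sire_ix, y
        self.K_inv, self.logdet_K = K_inv, logdet_K
        # data crossproducts, computed once
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.WtW = np.bincount(cage, minlength=self.qc).astype(float)
        self.Wty = np.bincount(cage, weights=y, minlength=self.qc)
        self.ZtZ = np.bincount(sire_ix, minlength=self.qu).astype(float)
        self.Zty = np.bincount(sire_ix, weights=y, minlength=self.qu)
        self.XtW = np.zeros((self.p, self.qc))
        self.XtZ = np.zeros((self.p, self.qu))
        for j in range(self.p):
            self.XtW[j] = np.bincount(cage, weights=X[:, j], minlength=self.qc)
            self.XtZ[j] = np.bincount(sire_ix, weights=X[:, j], minlength=self.qu)
        self.WtZ = np.zeros((self.qc, self.qu))
        np.add.at(self.WtZ, (cage, sire_ix), 1.0)
        self.yty = float(y @ y)

    def assemble(self, s2u, s2c, s2e):
        p, qc, qu = self.p, self.qc, self.qu
        dim = p + qc + qu
        M = np.zeros((dim, dim))
        M[:p, :p] = self.XtX
        M[:p, p : p + qc] = self.XtW
        M[p : p + qc, :p] = self.XtW.T
        M[:p, p + qc :] = self.XtZ
        M[p + qc :, :p] = self.XtZ.T
        M[p : p + qc, p + qc :] = self.WtZ
        M[p + qc :, p : p + qc] = self.WtZ.T
        M[p : p + qc, p : p + qc] = np.diag(self.WtW + s2e / s2c)
        M[p + qc :, p + qc :] = np.diag(self.ZtZ) + (s2e / s2u) * self.K_inv
        rhs = np.concatenate([self.Xty, self.Wty, self.Zty])
        return M, rhs

    def solve_point(self, s2u, s2c, s2e, want_inverse=False):
        """Solve the MME and return everything REML needs at this point."""
        M, rhs = self.assemble(s2u, s2c, s2e)
        cf = sla.cho_factor(M, lower=True, check_finite=False)
        sol = sla.cho_solve(cf, rhs, check_finite=False)
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ypy = (self.yty - sol @ rhs) / s2e
        n, p, qc, qu = self.n, self.p, self.qc, self.qu
        m2ll = (
            (n - p - qc - qu) * np.log(s2e)
            + qc * np.log(s2c)
            + qu * np.log(s2u)
            + self.logdet_K
            + logdet_M
            + ypy
        )
        out = {
            "m2ll": m2ll,
            "loglik": -0.5 * (m2ll + (n - p) * np.log(2 * np.pi)),
            "sol": sol,
            "ypy": ypy,
            "cf": cf,
        }
        if want_inverse:
            Minv = sla.cho_solve(cf, np.eye(M.shape[0]), check_finite=False)
            out["Ccc_diag_sum"] = float(np.trace(Minv[p : p + qc, p : p + qc]))
            out["Cuu"] = Minv[p + qc :, p + qc :]
        return out

    def fitted_parts(self, sol):
        p, qc = self.p, self.qc
        b, c, u = sol[:p], sol[p : p + qc], sol[p + qc :]
        resid = self.y - self.X @ b - c[self.cage] - u[self.sire_ix]
        return b, c, u, resid


def reml_loglik_dense(X, cage, sire_ix, y, K, s2u, s2c, s2e):
    """Restricted log-likelihood by direct dense-V evaluation (small n only).

    Independent of the MME identity; used as the oracle in tests.
    """
    n = len(y)
    W = np.zeros((n, int(cage.max()) + 1))
    W[np.arange(n), cage] = 1.0
    Z = np.zeros((n, K.shape[0]))
    Z[np.arange(n), sire_ix] = 1.0
    V = s2u * Z @ K @ Z.T + s2c * W @ W.T + s2e * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    b = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ b
    m2ll = (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + float(r @ Vinv @ y)
    )
    return -0.5 * (m2ll + (n - X.shape[1]) * np.log(2 * np.pi))


def _pv(mme: _MME, cf, v, s2e):
    """P v for an arbitrary vector, via an MME solve with v as data."""
    rhs = np.concatenate(
        [
            mme.X.T @ v,
            np.bincount(mme.cage, weights=v, minlength=mme.qc),
            np.bincount(mme.sire_ix, weights=v, minlength=mme.qu),
        ]
    )
    sol = sla.cho_solve(cf, rhs, check_finite=False)
    b, c, u = sol[: mme.p], sol[mme.p : mme.p + mme.qc], sol[mme.p + mme.qc :]
    return (v - mme.X @ b - c[mme.cage] - u[mme.sire_ix]) / s2e


def fit_sire_model(
    phenos: PhenotypeTable,
    K: np.ndarray | None = None,
    method: str = "pedigree",
    *,
    K_inv: np.ndarray | None = None,
    animal_ids: np.ndarray,
    var_components: VarianceComponents | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> SireModelFit:
    """Fit the sire model by AI-REML (EM fallback) or BLUP-only.

    ``K`` (or its inverse ``K_inv``; pass the blended H^-1 directly for
    method='ssgblup') must cover every animal in ``animal_ids``, ancestors
    without daughters included; phenotyped hens map to their sire's row.  If
    ``var_components`` is given the components are held fixed and a single
    BLUP solve is performed.  A component pinned at the zero boundary is
    floored at a tiny positive value and flagged in ``vc.boundary`` rather
    than silently zeroed.
    """
    if method not in ("pedigree", "ssgblup"):
        raise ValueError("method must be 'pedigree' or 'ssgblup'")
    if K_inv is None:
        if K is None:
            raise ValueError("supply K or K_inv")
        sign, logdet_K = np.linalg.slogdet(K)
        if sign <= 0:
            raise np.linalg.LinAlgError("K is not positive definite")
        K_inv = np.linalg.inv(K)
    else:
        sign, logdet_Kinv = np.linalg.slogdet(K_inv)
        if sign <= 0:
            raise np.linalg.LinAlgError("K_inv is not positive definite")
        logdet_K = -logdet_Kinv
    animal_ids = np.asarray(animal_ids)
    X, cage, sire_ix = _design(phenos, animal_ids)
    y = phenos.df["survival_days"].to_numpy(dtype=float)
    mme = _MME(X, cage, sire_ix, y, K_inv, logdet_K)

    vary = float(np.var(y, ddof=1))
    floor = max(1e-8 * vary, 1e-10)

    if var_components is not None:
        th = np.array(
            [var_components.sigma2_u, var_components.sigma2_c, var_components.sigma2_e]
        )
        th = np.maximum(th, floor)
        pt = mme.solve_point(*th, want_inverse=True)
        vc = var_components
        return _finish(mme, th, pt, vc, animal_ids, 0, True, method, [])

    th = np.array([vary / 3.0, vary / 3.0, vary / 3.0])  # phenotypic-variance thirds
    pt = mme.solve_point(*th, want_inverse=True)
    steps = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, AI = _derivatives(mme, th, pt)
        # average-information update with EM fallback and step halving
        try:
            delta = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            delta = None
        new_th, new_pt, kind = None, None, "em"
        if delta is not None:
            cand = th + delta
            for _ in range(5):
                if np.all(cand > 0):
                    cand_pt = mme.solve_point(*np.maximum(cand, floor), want_inverse=True)
                    if cand_pt["m2ll"] <= pt["m2ll"] + 1e-10:
                        new_th, new_pt, kind = np.maximum(cand, floor), cand_pt, "ai"
                        break
                cand = th + (cand - th) / 2.0
        if new_th is None:
            new_th = _em_step(mme, th, pt)
            new_th = np.maximum(new_th, floor)
            new_pt = mme.solve_point(*new_th, want_inverse=True)
        rel = abs(new_pt["m2ll"] - pt["m2ll"]) / (abs(pt["m2ll"]) + 1.0)
        steps.append((kind, *new_th, -0.5 * new_pt["m2ll"]))
        th, pt = new_th, new_pt
        if rel < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"REML did not converge in {max_iter} rounds", RuntimeWarning)

    grad, AI = _derivatives(mme, th, pt)
    se = {}
    try:
        cov = np.linalg.inv(AI)
        d = np.diag(cov)
        se = {
            "sigma2_u": float(np.sqrt(max(d[0], 0.0))),
            "sigma2_c": float(np.sqrt(max(d[1], 0.0))),
            "sigma2_e": float(np.sqrt(max(d[2], 0.0))),
        }
    except np.linalg.LinAlgError:
        pass
    boundary = {
        name: bool(val <= 2 * floor)
        for name, val in zip(("sigma2_u", "sigma2_c", "sigma2_e"), th)
    }
    vc = VarianceComponents(*th, se=se, boundary=boundary)
    return _finish(mme, th, pt, vc, animal_ids, it, converged, method, steps)


def _em_step(mme: _MME, th, pt):
    s2u, s2c, s2e = th
    _, c, u, resid = mme.fitted_parts(pt["sol"])
    tr_kinv_cuu = float(np.sum(mme.K_inv * pt["Cuu"]))
    new_u = (u @ mme.K_inv @ u + s2e * tr_kinv_cuu) / mme.qu
    new_c = (c @ c + s2e * pt["Ccc_diag_sum"]) / mme.qc
    new_e = pt["ypy"] * s2e / (mme.n - mme.p)
    return np.array([new_u, new_c, new_e])


def _derivatives(mme: _MME, th, pt):
    """REML gradient and average-information matrix at the current point."""
    s2u, s2c, s2e = th
    _, c, u, resid = mme.fitted_parts(pt["sol"])
    # working variates V_i P y
    f_u = u[mme.sire_ix] / s2u
    f_c = c[mme.cage] / s2c
    f_e = resid / s2e
    # quadratic terms y'P V_i P y
    q_u = u @ mme.K_inv @ u / s2u**2
    q_c = c @ c / s2c**2
    q_e = resid @ resid / s2e**2
    # traces via MME identities
    tr_kinv_cuu = float(np.sum(mme.K_inv * pt["Cuu"]))
    tr_pvu = (mme.qu - (s2e / s2u) * tr_kinv_cuu) / s2u
    tr_pvc = (mme.qc - (s2e / s2c) * pt["Ccc_diag_sum"]) / s2c
    tr_p = (mme.n - mme.p - s2u * tr_pvu - s2c * tr_pvc) / s2e
    grad = -0.5 * np.array([tr_pvu - q_u, tr_pvc - q_c, tr_p - q_e])
    fs = [f_u, f_c, f_e]
    pfs = [_pv(mme, pt["cf"], f, s2e) for f in fs]
    AI = 0.5 * np.array([[fi @ pfj for pfj in pfs] for fi in fs])
    return grad, AI


def _finish(mme, th, pt, vc, animal_ids, n_iter, converged, method, steps):
    _, _, u, _ = mme.fitted_parts(pt["sol"])
    pev = np.diag(pt["Cuu"]) * th[2]
    idx = pd.Index(animal_ids, name="animal")
    return SireModelFit(
        vc=vc,
        ebv=pd.Series(u, index=idx, name="ebv"),
        pev=pd.Series(pev, index=idx, name="pev"),
        loglik=float(pt["loglik"]),
        n_iter=n_iter,
        converged=converged,
        method=method,
        steps=steps,
    )


def derive_params(vc: VarianceComponents, progeny_means: pd.Series | None = None) -> VarianceComponents:
    """Attach the derived genetic parameters to a set of components.

    ``progeny_means`` are per-sire mean daughter phenotypes; their among-sire
    variance sigma2_pbar gets the standard error sigma2_pbar * sqrt(2/(n-1)).
    """
    if progeny_means is not None:
        n = len(progeny_means)
        if n < 2:
            raise ValueError("need at least two sires for sigma2_pbar")
        vc.sigma2_pbar = float(np.var(progeny_means.to_numpy(), ddof=1))
        vc.se_sigma2_pbar = vc.sigma2_pbar * np.sqrt(2.0 / (n - 1))
        vc.n_sires_pbar = n
    return vc


def progeny_test_accuracy(vc: VarianceComponents) -> float:
    """Accuracy of progeny testing, sqrt(sigma2_u / sigma2_pbar): the
    correlation between a sire's total breeding value and its progeny mean."""
    if not vc.sigma2_pbar or vc.sigma2_pbar <= 0:
        raise ValueError("sigma2_pbar not available or non-positive")
    if vc.sigma2_u > vc.sigma2_pbar:
        raise ValueError(
            "sigma2_u exceeds sigma2_pbar; implied accuracy > 1 is impossible"
        )
    return float(np.sqrt(vc.sigma2_u / vc.sigma2_pbar))
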