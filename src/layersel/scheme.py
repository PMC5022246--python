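"""Deterministic comparison of traditional and genomic breeding schemes.

A selection-index engine in the SelAction tradition: candidates of each sex
carry a set of information sources (parent-average EBV, a progeny-group mean,
an own marker record modelled as a fully heritable correlated pseudo-trait),
index weights solve b = P^-1 g, and the recursion is iterated to the Bulmer
equilibrium, where directional selection has depleted the between-family
genetic variance.  From the equilibrium the engine predicts response to
selection per generation and per year, and the rate of inbreeding under
truncation selection from the variance of family size, with family-size
(co)variances driven by the probability that sibs are co-selected (bivariate
normal orthant probabilities of their correlated indices).

The progeny group of a progeny-tested sire is modelled with its real
structure: ``progeny_dams`` full-sib daughter families, each family sharing
one cage, so the progeny mean carries dam-family and cage common-environment
covariance in addition to the sire's own contribution.

The three-step calibration mirrors how a marker pseudo-trait is anchored to
cross-validation results: (1) the parent-average accuracy rho_PA of the
traditional scheme in an unselected population, (2) a genomic target accuracy
rho_GS = rho_PA times the observed accuracy ratio, (3) the genetic
correlation r_g between marker information and survival that gives a
candidate with a progeny-tested father plus an own marker record exactly that
accuracy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .config import SchemeConfig, TraitParams, genomic_scheme

__all__ = [
    "selection_intensity",
    "build_index",
    "pa_accuracy_unselected",
    "bulmer_equilibrium",
    "predict_response",
    "predict_inbreeding",
    "solve_rg",
    "calibration_pipeline",
    "simulate_scheme",
    "SchemeOutputs",
    "CalibrationResult",
    "genomic_scheme",
]


def selection_intensity(p: float) -> tuple[float, float]:
    """Selection intensity i = phi(x)/p and variance-reduction factor
    k = i(i - x) for truncation of the upper fraction ``p`` of a standard
    normal (infinite population size)."""
    if not (0 < p <= 1):
        raise ValueError("selected proportion must be in (0, 1]")
    if p == 1.0:
        return 0.0, 0.0
    x = stats.norm.isf(p)
    i = stats.norm.pdf(x) / p
    return float(i), float(i * (i - x))


def _truncation_point(p: float) -> float:
    return -np.inf if p == 1.0 else float(stats.norm.isf(p))


@dataclass
class _State:
    """Per-generation state of the single-trait pseudo-BLUP recursion."""

    sigma2_A: float  # genetic variance among candidates, pre-selection
    var_I: dict = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    acc2: dict = field(default_factory=lambda: {"M": 0.0, "F": 0.0})


def _progeny_mean_var(scheme: SchemeConfig, traits: TraitParams, sigma2_A: float,
                      sigma2_A_mates: float) -> float:
    """Variance among sires of a progeny-group daughter mean.

    The group is ``progeny_dams`` full-sib families of equal size, one cage
    per family: sire term sigma2_A/4, dam term (sigma2_A_mates/4)/n_dams,
    Mendelian term (sigma2_A0/2)/n, cage term sigma2_c/n_dams and residual
    environment (sigma2_P - sigma2_A0 - sigma2_c)/n.
    """
    n = scheme.progeny_group_size
    nd = scheme.progeny_dams
    s2A0 = traits.sigma2_A
    s2env = traits.sigma2_P - s2A0 - traits.sigma2_cage
    return (
        0.25 * sigma2_A
        + 0.25 * sigma2_A_mates / nd
        + 0.5 * s2A0 / n
        + traits.sigma2_cage / nd
        + s2env / n
    )


def _sources(sex: str, scheme: SchemeConfig, traits: TraitParams, state: _State,
             k: dict) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Index source covariance matrix P and source-BV covariances g for a
    candidate of ``sex`` given the current recursion state."""
    names = list(scheme.male_sources if sex == "M" else scheme.female_sources)
    if "own_marker" in names:
        raise ValueError("marker sources are handled by the two-trait engine")
    v_pa = 0.25 * (
        (1 - k["M"]) * state.var_I["M"] + (1 - k["F"]) * state.var_I["F"]
    )
    s2A = state.sigma2_A
    mates_var = (1 - k["F"] * state.acc2["F"]) * s2A
    vals = {}
    for nm in names:
        if nm == "parent_average":
            vals[nm] = (v_pa, v_pa)  # (variance, cov with own BV)
        elif nm == "progeny_mean":
            vals[nm] = (_progeny_mean_var(scheme, traits, s2A, mates_var), 0.5 * s2A)
        elif nm == "own_phenotype":
            s2env = traits.sigma2_P - traits.sigma2_A
            vals[nm] = (s2A + s2env, s2A)
        else:  # pragma: no cover
            raise ValueError(nm)
    m = len(names)
    P = np.zeros((m, m))
    g = np.zeros(m)
    for a, nm in enumerate(names):
        P[a, a], g[a] = vals[nm]
    # cross-covariances between sources
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            if a >= b:
                continue
            pair = {na, nb}
            if pair == {"parent_average", "progeny_mean"}:
                c = 0.5 * v_pa  # cov(PA, A/2)
            elif pair == {"parent_average", "own_phenotype"}:
                c = v_pa
            elif pair == {"progeny_mean", "own_phenotype"}:
                c = 0.5 * s2A
            else:
                c = 0.0
            P[a, b] = P[b, a] = c
    return names, P, g


def _solve_index(P: np.ndarray, g: np.ndarray, sigma2_A: float) -> np.ndarray:
    """Index weights; information-free sources (zero variance, e.g. the parent
    average before any ancestor carries an EBV) get weight zero."""
    keep = np.diag(P) > 1e-12 * sigma2_A
    b = np.zeros_like(g)
    if keep.any():
        sub = np.ix_(keep, keep)
        b[keep] = np.linalg.solve(P[sub], g[keep])
    return b


def build_index(sex: str, scheme: SchemeConfig, traits: TraitParams,
                state: _State | None = None) -> tuple[np.ndarray, float]:
    """Selection-index weights b = P^-1 g and accuracy sqrt(b'g / sigma2_A)
    for one sex; with no state, the unselected base population (no pedigree
    information accumulated yet)."""
    state = state or _State(sigma2_A=traits.sigma2_A)
    _, P, g = _sources(sex, scheme, traits, state, {"M": 0.0, "F": 0.0})
    if (np.diag(P) > 0).all() and np.linalg.cond(P) > 1e12:
        raise np.linalg.LinAlgError("singular source covariance matrix P")
    b = _solve_index(P, g, state.sigma2_A)
    acc2 = float(b @ g) / state.sigma2_A
    return b, float(np.sqrt(max(acc2, 0.0)))


@dataclass
class SchemeOutputs:
    """Equilibrium accuracies, genetic variance, response and inbreeding."""

    accuracy_male: float
    accuracy_female: float
    sigma2_A_eq: float
    i_male: float
    i_female: float
    k_male: float
    k_female: float
    response_per_gen: float | None = None
    response_per_year: float | None = None
    deltaF_per_gen_pct: float | None = None
    deltaF_per_year_pct: float | None = None
    var_I: dict = field(default_factory=dict)
    genetic_cov: np.ndarray | None = None
    index_weights: dict = field(default_factory=dict)
    n_iter: int = 0


def _iterate_single_trait(scheme: SchemeConfig, traits: TraitParams, selected: bool,
                          tol: float = 1e-10, max_iter: int = 1000):
    """Fixed point of the single-trait recursion (traditional scheme)."""
    if selected:
        i_m, k_m = selection_intensity(scheme.p_male)
        i_f, k_f = selection_intensity(scheme.p_female)
    else:
        i_m = i_f = k_m = k_f = 0.0
    k = {"M": k_m, "F": k_f}
    st = _State(sigma2_A=traits.sigma2_A)
    weights = {}
    it = 0
    for it in range(1, max_iter + 1):
        new = _State(sigma2_A=st.sigma2_A)
        for sex in ("M", "F"):
            _, P, g = _sources(sex, scheme, traits, st, k)
            b = _solve_index(P, g, st.sigma2_A)
            vi = float(b @ g)
            new.var_I[sex] = vi
            new.acc2[sex] = vi / st.sigma2_A
            weights[sex] = b
        new.sigma2_A = (
            0.5 * traits.sigma2_A
            + 0.25 * (1 - k["M"] * new.acc2["M"]) * st.sigma2_A
            + 0.25 * (1 - k["F"] * new.acc2["F"]) * st.sigma2_A
        )
        delta = max(
            abs(new.sigma2_A - st.sigma2_A) / traits.sigma2_A,
            abs(new.var_I["M"] - st.var_I["M"]) / traits.sigma2_A,
            abs(new.var_I["F"] - st.var_I["F"]) / traits.sigma2_A,
        )
        st = new
        if delta < tol:
            break
    else:
        raise RuntimeError("pseudo-BLUP recursion did not converge")
    out = SchemeOutputs(
        accuracy_male=float(np.sqrt(st.acc2["M"])),
        accuracy_female=float(np.sqrt(st.acc2["F"])),
        sigma2_A_eq=st.sigma2_A,
        i_male=i_m,
        i_female=i_f,
        k_male=k["M"],
        k_female=k["F"],
        var_I=dict(st.var_I),
        index_weights=weights,
        n_iter=it,
    )
    return out, st, k


def _iterate_two_trait(scheme: SchemeConfig, traits: TraitParams, selected: bool,
                       tol: float = 1e-10, max_iter: int = 1000):
    """Bulmer recursion of the 2x2 genetic covariance matrix (survival,
    marker) when both sexes are selected on their own marker record."""
    if traits.r_g is None:
        raise ValueError("traits.r_g must be set for the genomic scheme")
    s2A = traits.sigma2_A
    s2Am = traits.r_g**2 * s2A  # marker BV variance; h2_marker = 1
    C0 = np.array(
        [[s2A, traits.r_g * np.sqrt(s2A * s2Am)], [traits.r_g * np.sqrt(s2A * s2Am), s2Am]]
    )
    if selected:
        i_m, k_m = selection_intensity(scheme.p_male)
        i_f, k_f = selection_intensity(scheme.p_female)
    else:
        i_m = i_f = k_m = k_f = 0.0
    C = C0.copy()
    sel = np.array([0.0, 1.0])  # index = own marker record (no residual)
    it = 0
    for it in range(1, max_iter + 1):
        c = C @ sel  # cov(index, BV vector)
        vI = float(sel @ C @ sel)
        shrink = np.outer(c, c) / vI
        Cm = C - k_m * shrink
        Cf = C - k_f * shrink
        Cn = 0.5 * C0 + 0.25 * Cm + 0.25 * Cf
        delta = np.max(np.abs(Cn - C)) / s2A
        C = Cn
        if delta < tol:
            break
    else:
        raise RuntimeError("two-trait Bulmer recursion did not converge")
    r_eq = float(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]))
    out = SchemeOutputs(
        accuracy_male=r_eq,
        accuracy_female=r_eq,
        sigma2_A_eq=float(C[0, 0]),
        i_male=i_m,
        i_female=i_f,
        k_male=k_m,
        k_female=k_f,
        var_I={"M": float(C[1, 1]), "F": float(C[1, 1])},
        genetic_cov=C,
        n_iter=it,
    )
    return out, C


def _is_genomic(scheme: SchemeConfig) -> bool:
    return "own_marker" in scheme.male_sources or "own_marker" in scheme.female_sources


def pa_accuracy_unselected(scheme: SchemeConfig, traits: TraitParams) -> float:
    """Accuracy of the parent-average EBV in an unselected population
    (selected proportions 100% in both sexes), iterated to its fixed point.

    With the traditional information sources this is also the accuracy of a
    female candidate, whose only information is the parent average.
    """
    out, st, _ = _iterate_single_trait(scheme, traits, selected=False)
    v_pa = 0.25 * (st.var_I["M"] + st.var_I["F"])
    return float(np.sqrt(v_pa / st.sigma2_A))


def bulmer_equilibrium(scheme: SchemeConfig, traits: TraitParams) -> SchemeOutputs:
    """Equilibrium accuracies and genetic variance under recurrent selection."""
    if _is_genomic(scheme):
        out, _ = _iterate_two_trait(scheme, traits, selected=True)
    else:
        out, _, _ = _iterate_single_trait(scheme, traits, selected=True)
    return out


def predict_response(scheme: SchemeConfig, traits: TraitParams,
                     equilibrium: SchemeOutputs | None = None) -> SchemeOutputs:
    """Response to selection at the Bulmer equilibrium.

    R per generation = sigma_A_eq (i_m r_m + i_f r_f)/2; per year, divided by
    the mean generation interval in years.
    """
    out = equilibrium or bulmer_equilibrium(scheme, traits)
    sd = np.sqrt(out.sigma2_A_eq)
    out.response_per_gen = float(
        0.5 * (out.i_male * out.accuracy_male + out.i_female * out.accuracy_female) * sd
    )
    out.response_per_year = out.response_per_gen / scheme.mean_L_years
    return out


# ---------------------------------------------------------------------------
# rate of inbreeding


def _orthant(x1: float, x2: float, rho: float) -> float:
    """P(Z1 > x1, Z2 > x2) for standard bivariate normal with correlation rho."""
    rho = float(np.clip(rho, -0.9999, 0.9999))
    if np.isinf(x1) or np.isinf(x2):
        return 0.0
    return float(
        stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([-x1, -x2])
    )


def _sib_index_correlations(scheme: SchemeConfig, traits: TraitParams):
    """Correlations between the index values of full sibs and paternal half
    sibs, for every sex pair, at the Bulmer equilibrium."""
    if _is_genomic(scheme):
        out, C = _iterate_two_trait(scheme, traits, selected=True)
        vI = float(C[1, 1])
        between_m = 0.25 * (1 - out.k_male) * vI
        between_f = 0.25 * (1 - out.k_female) * vI
        fs = (between_m + between_f) / vI
        hs = between_m / vI
        rho = {("M", "M"): (fs, hs), ("M", "F"): (fs, hs), ("F", "F"): (fs, hs)}
        return rho, out
    out, st, k = _iterate_single_trait(scheme, traits, selected=True)
    v_pa = 0.25 * ((1 - k["M"]) * st.var_I["M"] + (1 - k["F"]) * st.var_I["F"])
    half_sire = 0.25 * (1 - k["M"]) * st.var_I["M"]  # shared sire-EBV part of PA
    bf_m = 0.25 * (1 - k["M"] * st.acc2["M"]) * st.sigma2_A  # between-family BV (sire)
    bf_f = 0.25 * (1 - k["F"] * st.acc2["F"]) * st.sigma2_A

    def cov_sources(na: str, nb: str, rel: str) -> float:
        full = rel == "FS"
        bv_cov = (bf_m + bf_f) if full else bf_m  # sibs' BV covariance
        if na == "parent_average" and nb == "parent_average":
            return v_pa if full else half_sire
        if {na, nb} == {"parent_average", "progeny_mean"}:
            return 0.5 * (v_pa if full else half_sire)
        if {na, nb} == {"parent_average", "own_phenotype"}:
            return v_pa if full else half_sire
        if {na, nb} == {"progeny_mean", "own_phenotype"}:
            return 0.5 * bv_cov
        if na == "own_phenotype" and nb == "own_phenotype":
            return bv_cov  # environments independent across sibs
        # progeny_mean x progeny_mean: quarter of the sibs' BV covariance
        return 0.25 * bv_cov

    bw = {}
    names = {}
    for sex in ("M", "F"):
        nm, P, g = _sources(sex, scheme, traits, st, k)
        bw[sex] = _solve_index(P, g, st.sigma2_A)
        names[sex] = nm
    rho = {}
    for sa, sb in (("M", "M"), ("M", "F"), ("F", "F")):
        pair = {}
        for rel in ("FS", "HS"):
            cov = 0.0
            for a, na in enumerate(names[sa]):
                for b, nb in enumerate(names[sb]):
                    cov += bw[sa][a] * bw[sb][b] * cov_sources(na, nb, rel)
            denom = np.sqrt(st.var_I[sa] * st.var_I[sb])
            pair[rel] = cov / denom
        rho[(sa, sb)] = (pair["FS"], pair["HS"])
    return rho, out


def predict_inbreeding(scheme: SchemeConfig, traits: TraitParams,
                       equilibrium: SchemeOutputs | None = None) -> SchemeOutputs:
    """Rate of inbreeding per generation under truncation selection.

    Computed as Delta F = 1/(2 Ne) with Ne from the variance of family size
    (Hill's unequal-sex formula).  The variance of the number of selected
    offspring per sire and per dam is evaluated from pairwise co-selection
    probabilities of sib indices (bivariate-normal orthant probabilities at
    the structural selected proportions), so truncation on family-correlated
    indices inflates Delta F above the random-selection baseline
    1/(8 Nm) + 1/(8 Nf).  Persistence of selective advantage over later
    generations is not modelled, which makes the prediction conservative for
    schemes with very strong family co-selection.
    """
    rho, out = _sib_index_correlations(scheme, traits)
    if equilibrium is not None:
        out = equilibrium
    M, F = scheme.n_sires, scheme.n_dams
    mo, fo = scheme.male_offspring_per_dam, scheme.female_offspring_per_dam
    d = scheme.dams_per_sire
    n_cand_m = M * d * mo
    n_cand_f = M * d * fo
    p_m = M / n_cand_m
    p_f = F / n_cand_f
    x_m, x_f = _truncation_point(p_m), _truncation_point(p_f)

    def pair_cov(sexes: tuple[str, str], rel: str) -> float:
        key = sexes if sexes in rho else (sexes[1], sexes[0])
        r_fs, r_hs = rho[key]
        r = r_fs if rel == "FS" else r_hs
        xa = x_m if sexes[0] == "M" else x_f
        xb = x_m if sexes[1] == "M" else x_f
        pa = p_m if sexes[0] == "M" else p_f
        pb = p_m if sexes[1] == "M" else p_f
        if r >= 0.9999:  # identical indices: co-selection is certain
            return min(pa, pb) - pa * pb
        return _orthant(xa, xb, r) - pa * pb

    # per-sire family-size moments (d dams, mo/fo offspring of each sex per dam)
    def sire_moments():
        n_m, n_f = d * mo, d * fo
        fs_mm, hs_mm = d * mo * (mo - 1), n_m * (n_m - 1) - d * mo * (mo - 1)
        fs_ff, hs_ff = d * fo * (fo - 1), n_f * (n_f - 1) - d * fo * (fo - 1)
        fs_mf, hs_mf = d * mo * fo, n_m * n_f - d * mo * fo
        v_mm = n_m * p_m * (1 - p_m) + fs_mm * pair_cov(("M", "M"), "FS") + hs_mm * pair_cov(("M", "M"), "HS")
        v_ff = n_f * p_f * (1 - p_f) + fs_ff * pair_cov(("F", "F"), "FS") + hs_ff * pair_cov(("F", "F"), "HS")
        c_mf = fs_mf * pair_cov(("M", "F"), "FS") + hs_mf * pair_cov(("M", "F"), "HS")
        return v_mm, v_ff, c_mf

    def dam_moments():
        v_mm = mo * p_m * (1 - p_m) + mo * (mo - 1) * pair_cov(("M", "M"), "FS")
        v_ff = fo * p_f * (1 - p_f) + fo * (fo - 1) * pair_cov(("F", "F"), "FS")
        c_mf = mo * fo * pair_cov(("M", "F"), "FS")
        return v_mm, v_ff, c_mf

    s_mm, s_mf, s_mmf = sire_moments()
    d_fm, d_ff, d_fmf = dam_moments()
    inv_ne = (1.0 / (16 * M)) * (
        2 + s_mm + 2 * (M / F) * s_mmf + (M / F) ** 2 * s_mf
    ) + (1.0 / (16 * F)) * (
        (F / M) ** 2 * d_fm + 2 * (F / M) * d_fmf + 2 + d_ff
    )
    dF = 0.5 * inv_ne
    if not (0 < dF < 1):
        warnings.warn(f"rate of inbreeding {dF:.4f} outside (0,1)", UserWarning)
    out.deltaF_per_gen_pct = 100.0 * dF
    out.deltaF_per_year_pct = 100.0 * dF / scheme.mean_L_years
    return out


# ---------------------------------------------------------------------------
# the three-step r_g calibration


def _candidate_accuracy_with_marker(r_g: float, q_father: float, traits: TraitParams) -> float:
    """Unselected accuracy of a candidate with a progeny-tested father
    (EBV reliability ``q_father``) and an own marker record, as a function of
    the marker-survival genetic correlation."""
    s2A = traits.sigma2_A
    s2Am = r_g**2 * s2A
    P = np.array(
        [
            [q_father * s2A, 0.5 * q_father * r_g**2 * s2A],
            [0.5 * q_father * r_g**2 * s2A, max(s2Am, 1e-12 * s2A)],
        ]
    )
    g = np.array([0.5 * q_father * s2A, r_g**2 * s2A])
    b = np.linalg.solve(P, g)
    return float(np.sqrt(max(b @ g, 0.0) / s2A))


def solve_rg(target_accuracy: float, scheme: SchemeConfig, traits: TraitParams,
             tol: float = 1e-4) -> float:
    """Bisection on r_g until the two-trait unselected candidate accuracy
    (progeny-tested father plus own marker record) reaches the target."""
    if not (0 < target_accuracy < 1):
        raise ValueError("target accuracy must be in (0, 1)")
    out, st, _ = _iterate_single_trait(scheme, traits, selected=False)
    q_father = st.acc2["M"]
    lo, hi = 0.0, 0.999999
    if _candidate_accuracy_with_marker(hi, q_father, traits) < target_accuracy:
        raise ValueError("target accuracy unreachable even with r_g ~ 1")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _candidate_accuracy_with_marker(mid, q_father, traits) < target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class CalibrationResult:
    rho_PA: float
    rho_GS: float
    r_g: float
    traditional: SchemeOutputs
    genomic: SchemeOutputs
    accuracy_ratio: float


def calibration_pipeline(
    cv_accuracy_ratio: float,
    traditional: SchemeConfig | None = None,
    traits: TraitParams | None = None,
    genomic: SchemeConfig | None = None,
    pa_precision: int | None = 2,
) -> CalibrationResult:
    """Full chain: rho_PA -> rho_GS = rho_PA * ratio -> r_g -> predictions.

    ``pa_precision`` rounds rho_PA before applying the cross-validation
    accuracy ratio, matching the two-decimal precision at which the ratio
    itself is known; pass None to use full precision.
    """
    if cv_accuracy_ratio <= 0:
        raise ValueError("accuracy ratio must be positive")
    traditional = traditional or SchemeConfig()
    traits = traits or TraitParams()
    genomic = genomic or genomic_scheme()
    rho_pa = pa_accuracy_unselected(traditional, traits)
    rho_used = round(rho_pa, pa_precision) if pa_precision is not None else rho_pa
    rho_gs = rho_used * cv_accuracy_ratio
    r_g = solve_rg(rho_gs, traditional, traits)
    traits_gs = replace(traits, r_g=r_g)
    trad_out = predict_inbreeding(
        traditional, traits, predict_response(traditional, traits)
    )
    gs_out = predict_inbreeding(
        genomic, traits_gs, predict_response(genomic, traits_gs)
    )
    return CalibrationResult(
        rho_PA=float(rho_pa),
        rho_GS=float(rho_gs),
        r_g=float(r_g),
        traditional=trad_out,
        genomic=gs_out,
        accuracy_ratio=cv_accuracy_ratio,
    )


# ---------------------------------------------------------------------------
# stochastic cross-check


def simulate_scheme(
    scheme: SchemeConfig,
    traits: TraitParams,
    n_generations: int = 8,
    seed: int = 1,
    track_inbreeding: bool = True,
):
    """Stochastic truncation-selection counterpart of the engine.

    Supports candidates selected on an own record (``own_marker`` or
    ``own_phenotype``); progeny-testing schemes are covered by the
    deterministic engine only.  Returns per-generation mean survival breeding
    values, mean inbreeding coefficients, and the realized response per
    generation over the post-Bulmer phase.
    """
    src = set(scheme.male_sources) | set(scheme.female_sources)
    if not src <= {"own_marker", "own_phenotype"}:
        raise NotImplementedError("stochastic check supports own-record selection only")
    rng = np.random.default_rng(seed)
    s2A = traits.sigma2_A
    if "own_marker" in src:
        s2Am = traits.r_g**2 * s2A
        C0 = np.array(
            [[s2A, traits.r_g * np.sqrt(s2A * s2Am)],
             [traits.r_g * np.sqrt(s2A * s2Am), s2Am]]
        )
        env_sd = 0.0
        crit = 1  # select on marker BV
    else:
        C0 = np.array([[s2A, 0.0], [0.0, 1e-12]])
        env_sd = np.sqrt(traits.sigma2_P - s2A)
        crit = 0
    M, F = scheme.n_sires, scheme.n_dams
    d = scheme.dams_per_sire
    mo, fo = scheme.male_offspring_per_dam, scheme.female_offspring_per_dam
    n_cm, n_cf = M * d * mo, M * d * fo

    chol0 = np.linalg.cholesky(C0 + 1e-9 * np.eye(2) * s2A)
    bv_m = (chol0 @ rng.standard_normal((2, n_cm))).T
    bv_f = (chol0 @ rng.standard_normal((2, n_cf))).T
    ped: list[tuple[int, int]] = [(-1, -1)] * (n_cm + n_cf)
    id_m = np.arange(n_cm)
    id_f = np.arange(n_cm, n_cm + n_cf)
    mean_bv, mean_F = [], []
    kin: dict[tuple[int, int], float] = {}

    def kinship(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in kin:
            return kin[key]
        if a == b:
            val = 0.5 * (1 + kinship(*ped[a]))
        else:
            hi, lo_ = (a, b) if a > b else (b, a)
            s, dd = ped[hi]
            val = 0.5 * (kinship(lo_, s) + kinship(lo_, dd))
        kin[key] = val
        return val

    chol_mend = None
    for _ in range(n_generations):
        idx_m = bv_m[:, crit] + env_sd * rng.standard_normal(len(bv_m))
        idx_f = bv_f[:, crit] + env_sd * rng.standard_normal(len(bv_f))
        sires = np.argsort(idx_m)[::-1][:M]
        dams = np.argsort(idx_f)[::-1][:F]
        sire_ids, dam_ids = id_m[sires], id_f[dams]
        sire_bv, dam_bv = bv_m[sires], bv_f[dams]
        # hierarchical matings, random union of the selected parents
        mate = rng.permutation(np.resize(np.arange(F), M * d))
        s_of_mating = np.repeat(np.arange(M), d)
        if chol_mend is None:
            chol_mend = np.linalg.cholesky(0.5 * C0 + 1e-9 * np.eye(2) * s2A)
        new_bv, new_ped = [], []
        for m_ix, f_ix in zip(s_of_mating, mate):
            mid = 0.5 * (sire_bv[m_ix] + dam_bv[f_ix])
            n_off = mo + fo
            mend = (chol_mend @ rng.standard_normal((2, n_off))).T
            new_bv.append(mid + mend)
            new_ped.extend([(int(sire_ids[m_ix]), int(dam_ids[f_ix]))] * n_off)
        all_bv = np.vstack(new_bv)
        start = len(ped)
        ped.extend(new_ped)
        ids = np.arange(start, start + len(new_ped))
        # first mo of each dam's brood male, next fo female
        sel_m = np.concatenate(
            [np.arange(j * (mo + fo), j * (mo + fo) + mo) for j in range(M * d)]
        )
        sel_f = np.setdiff1d(np.arange(len(all_bv)), sel_m)
        bv_m, bv_f = all_bv[sel_m], all_bv[sel_f]
        id_m, id_f = ids[sel_m], ids[sel_f]
        mean_bv.append(float(all_bv[:, 0].mean()))
        if track_inbreeding:
            sample = ids[:: max(1, len(ids) // 60)]
            fvals = [kinship(*ped[int(a)]) for a in sample]
            mean_F.append(float(np.mean(fvals)))
    resp = np.diff(mean_bv)
    return {
        "mean_bv": np.array(mean_bv),
        "mean_F": np.array(mean_F) if track_inbreeding else None,
        "response_per_gen_eq": float(np.mean(resp[2:])) if len(resp) > 2 else float("nan"),
    }
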