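"""Published summary inputs for the two brown-layer sire lines (B1, BD).

These are the printed batch survival summaries and pedigree-REML variance
components for the two commercial lines of brown laying hens with intact
beaks that motivate this package.  They are *inputs* for worked examples and
desk-scale checks (censoring trade-offs, progeny-test reliabilities, expected
genomic accuracies); the underlying individual records are proprietary and
are emulated by :mod:`layersel.simdata` instead.
"""
from __future__ import annotations

import pandas as pd

from .siremodel import VarianceComponents

__all__ = [
    "b1_batches",
    "bd_batches",
    "b1_variance_components",
    "bd_variance_components",
    "LINE_INFO",
]

# genotyped/total sires and the LD summary Me = 1/var(G - A22) per line,
# plus the common censoring day each line's analysis adopted
LINE_INFO = {
    "B1": {"n_sires": 509, "n_genotyped": 207, "Me": 799.0, "var_offdiag_A": 0.00091,
           "censor_day": 395.0},
    "BD": {"n_sires": 284, "n_genotyped": 242, "Me": 1020.0, "var_offdiag_A": 0.00077,
           "censor_day": 372.0},
}


def b1_batches(candidate_day: float = 395.0) -> pd.DataFrame:
    """Batch summaries for line B1: hens per batch, the batch's own endpoint,
    and hens still alive at ``candidate_day`` (only 372, 395, 414, 419 and
    421 days are tabulated)."""
    alive = {
        372.0: [3241, 3783, 4181, 3503, 2675],
        395.0: [3129, 3711, 4070, 0, 2616],
        414.0: [3055, 3644, 3933, 0, 0],
        419.0: [3027, 3617, 0, 0, 0],
        421.0: [0, 3617, 0, 0, 0],
    }
    if candidate_day not in alive:
        raise KeyError(f"no tabulated counts at day {candidate_day}")
    return pd.DataFrame(
        {
            "batch": ["2008102", "200961", "201124", "201182", "2012102"],
            "n_ind": [5397, 5228, 5692, 4981, 3658],
            # endpoints bracketed by the tabulated columns in which each
            # batch still has survivors
            "end_day": [420.0, 421.0, 415.0, 385.0, 400.0],
            "n_alive_at_day": alive[candidate_day],
        }
    )


def bd_batches(candidate_day: float = 372.0) -> pd.DataFrame:
    """Batch summaries for line BD (columns tabulated at 351, 372, 413 days)."""
    alive = {
        351.0: [2461, 2694, 3772],
        372.0: [0, 2774, 3673],
        413.0: [0, 0, 3540],
    }
    if candidate_day not in alive:
        raise KeyError(f"no tabulated counts at day {candidate_day}")
    return pd.DataFrame(
        {
            "batch": ["201042", "201182", "200919"],
            "n_ind": [5122, 4525, 6385],
            "end_day": [360.0, 400.0, 413.0],
            "n_alive_at_day": alive[candidate_day],
        }
    )


def b1_variance_components() -> VarianceComponents:
    """Pedigree-REML estimates for line B1 (sigma2_u = sigma2_AT / 4)."""
    vc = VarianceComponents(sigma2_u=1912.0 / 4.0, sigma2_c=1084.0, sigma2_e=8885.0)
    vc.sigma2_pbar = 1327.0
    vc.n_sires_pbar = 509
    return vc


def bd_variance_components() -> VarianceComponents:
    """Pedigree-REML estimates for line BD."""
    vc = VarianceComponents(sigma2_u=2700.0 / 4.0, sigma2_c=1403.0, sigma2_e=10350.0)
    vc.sigma2_pbar = 1280.0
    vc.n_sires_pbar = 284
    return vc
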