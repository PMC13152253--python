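"""Maternal-specific effect partitioning and blood-count derivation.

Maternal and fetal genomes are correlated (each child shares half of each
parent's alleles), so an unadjusted GWAS of maternal genotype on a pregnancy
trait absorbs half of the fetal effect and vice versa. The weighted linear
model (WLM) inverts that contamination at the summary-statistic level:

    beta_maternal_adj = (4/3) * beta_maternal_unadj - (2/3) * beta_fetal_unadj

which recovers the true maternal effect exactly when the unadjusted pair is
(bm + bf/2, bf + bm/2). The symmetric fetal adjustment is provided for
completeness. SE propagation uses the quadratic form for a linear
combination of two possibly correlated estimates; the between-GWAS overlap
correlation defaults to 0 (independent samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_WM, _WF = 4.0 / 3.0, 2.0 / 3.0


@dataclass
class DuoEffectPair:
    """Per-variant unadjusted maternal and fetal GWAS effects.

    ``beta_maternal_unadj`` is the effect of maternal genotype on the
    offspring trait; ``beta_fetal_unadj`` the effect of own genotype on own
    trait. ``overlap_correlation`` is the sampling correlation between the
    two estimates induced by overlapping samples.
    """

    beta_maternal_unadj: np.ndarray
    se_maternal_unadj: np.ndarray
    beta_fetal_unadj: np.ndarray
    se_fetal_unadj: np.ndarray
    overlap_correlation: float = 0.0

    def __post_init__(self):
        for name in ("beta_maternal_unadj", "se_maternal_unadj", "beta_fetal_unadj", "se_fetal_unadj"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.se_maternal_unadj <= 0) or np.any(self.se_fetal_unadj <= 0):
            raise ValueError("standard errors must be positive")
        if not -1.0 <= self.overlap_correlation <= 1.0:
            raise ValueError("overlap_correlation must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(np.atleast_1d(self.beta_maternal_unadj))


@dataclass
class AdjustedMaternalEffect:
    beta_adj: np.ndarray
    se_adj: np.ndarray


def wlm_adjust_maternal(beta_maternal_unadj, beta_fetal_unadj):
    """Maternal-specific effect: (4/3)*beta_maternal - (2/3)*beta_fetal."""
    return _WM * np.asarray(beta_maternal_unadj, float) - _WF * np.asarray(beta_fetal_unadj, float)


def wlm_adjust_fetal(beta_fetal_unadj, beta_maternal_unadj):
    """Symmetric fetal-specific effect: (4/3)*beta_fetal - (2/3)*beta_maternal."""
    return _WM * np.asarray(beta_fetal_unadj, float) - _WF * np.asarray(beta_maternal_unadj, float)


def wlm_se(se_maternal, se_fetal, overlap_correlation: float = 0.0):
    """SE of the WLM-adjusted maternal effect.

    Variance of (4/3)X - (2/3)Y with corr(X, Y) = ``overlap_correlation``:
    (4/3)^2 se_m^2 + (2/3)^2 se_f^2 - 2*(4/3)*(2/3)*rho*se_m*se_f.
    """
    se_m = np.asarray(se_maternal, float)
    se_f = np.asarray(se_fetal, float)
    if not -1.0 <= overlap_correlation <= 1.0:
        raise ValueError("overlap_correlation must lie in [-1, 1]")
    var = (_WM * se_m) ** 2 + (_WF * se_f) ** 2 - 2 * _WM * _WF * overlap_correlation * se_m * se_f
    if np.any(var <= 0):
        raise ValueError("non-positive adjusted variance; check SEs and overlap correlation")
    return np.sqrt(var)


def adjust_duo(pair: DuoEffectPair) -> AdjustedMaternalEffect:
    """Apply the WLM point-estimate transform and SE propagation to a duo set."""
    return AdjustedMaternalEffect(
        beta_adj=wlm_adjust_maternal(pair.beta_maternal_unadj, pair.beta_fetal_unadj),
        se_adj=wlm_se(pair.se_maternal_unadj, pair.se_fetal_unadj, pair.overlap_correlation),
    )


def derive_absolute_count(cell_percent, wbc_total):
    """Absolute blood count from a WBC percentage: percent * WBC total / 100."""
    cell_percent = np.asarray(cell_percent, float)
    wbc_total = np.asarray(wbc_total, float)
    if np.any(cell_percent < 0) or np.any(cell_percent > 100):
        raise ValueError("cell_percent must lie in [0, 100]")
    if np.any(wbc_total <= 0):
        raise ValueError("wbc_total must be positive")
    return cell_percent * wbc_total / 100.0
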