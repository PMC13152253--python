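"""Two-step MR mediation: gatekeeping, indirect/direct effects, SEs.

For an exposure -> mediator -> outcome triple, three causal estimates are
obtained by two-sample MR (IVW multiplicative random effects at each step):

* total  — exposure on outcome (the univariate causal effect),
* a      — exposure on mediator,
* b      — mediator on outcome (using the mediator's own instruments).

The indirect (mediated) effect is the product a*b with the delta-method SE
sqrt(b^2 SE_a^2 + a^2 SE_b^2 + SE_a^2 SE_b^2); the direct effect is
total - indirect with SE sqrt(SE_total^2 + SE_indirect^2) (difference of two
estimates). Mediation is only assessed when each of the three step effects
is nominally causal (p < alpha, default 0.05) — a deliberately liberal gate
that limits the number of mediation analyses performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .estimators import IVWEstimator, _two_sided_normal_p
from .sumstats import SummaryStatSet, clump_greedy, harmonize_pair, select_genome_wide

#: Human-readable names of the three gated causal steps, in gate order.
STEP_NAMES = ("exposure->outcome", "exposure->mediator", "mediator->outcome")


@dataclass
class StepEstimates:
    """The three step-wise IVW estimates feeding the mediation arithmetic."""

    a: float
    se_a: float
    b: float
    se_b: float
    total: float
    se_total: float
    step_pvalues: tuple  # (p_total, p_a, p_b), matching STEP_NAMES


@dataclass
class MediationResult:
    assessed: bool
    steps: StepEstimates | None = None
    failing_steps: tuple = ()
    indirect: float | None = None
    se_indirect: float | None = None
    p_indirect: float | None = None
    direct: float | None = None
    se_direct: float | None = None
    p_direct: float | None = None
    proportion_mediated: float | None = None
    n_snps_per_step: tuple | None = None


def mediation_gate(step_pvalues, alpha: float = 0.05) -> bool:
    """True iff every step p-value is strictly below ``alpha``."""
    pvals = tuple(step_pvalues)
    if len(pvals) != 3:
        raise ValueError("expected exactly three step p-values")
    return all(p < alpha for p in pvals)


def indirect_effect(a: float, se_a: float, b: float, se_b: float):
    """Product-of-coefficients indirect effect with delta-method SE."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    indirect = a * b
    se = sqrt(b**2 * se_a**2 + a**2 * se_b**2 + se_a**2 * se_b**2)
    p = _two_sided_normal_p(indirect / se) if se > 0 else 1.0
    return indirect, se, p


def direct_effect(total: float, se_total: float, indirect: float, se_indirect: float):
    """Direct effect total - indirect; SE by the difference-of-estimates rule."""
    if se_total < 0 or se_indirect < 0:
        raise ValueError("standard errors must be non-negative")
    direct = total - indirect
    se = sqrt(se_total**2 + se_indirect**2)
    p = _two_sided_normal_p(direct / se) if se > 0 else 1.0
    return direct, se, p


def mediate_steps(steps: StepEstimates, gate_alpha: float = 0.05,
                  report_proportion: bool = False) -> MediationResult:
    """Apply the gate and, when passed, the mediation arithmetic to step
    estimates (however obtained)."""
    if not mediation_gate(steps.step_pvalues, gate_alpha):
        failing = tuple(
            name for name, p in zip(STEP_NAMES, steps.step_pvalues) if not p < gate_alpha
        )
        return MediationResult(assessed=False, steps=steps, failing_steps=failing)

    indirect, se_ind, p_ind = indirect_effect(steps.a, steps.se_a, steps.b, steps.se_b)
    direct, se_dir, p_dir = direct_effect(steps.total, steps.se_total, indirect, se_ind)
    proportion = None
    if report_proportion and steps.total != 0 and np.sign(indirect) == np.sign(steps.total):
        proportion = indirect / steps.total
    return MediationResult(
        assessed=True,
        steps=steps,
        indirect=indirect,
        se_indirect=se_ind,
        p_indirect=p_ind,
        direct=direct,
        se_direct=se_dir,
        p_direct=p_dir,
        proportion_mediated=proportion,
    )


def _step_ivw(instrument_set: SummaryStatSet, outcome_set: SummaryStatSet,
              palindrome_eaf_band) -> tuple[IVWEstimator, int]:
    h = harmonize_pair(instrument_set, outcome_set, palindrome_eaf_band)
    return IVWEstimator().fit(h), len(h)


def run_two_step(
    exposure: SummaryStatSet,
    mediator: SummaryStatSet,
    outcome: SummaryStatSet,
    *,
    ld=None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    window_kb: float = 10_000.0,
    gate_alpha: float = 0.05,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    instruments: dict | None = None,
    report_proportion: bool = False,
) -> MediationResult:
    """Run the full two-step MR for one exposure-mediator-outcome triple.

    Instruments for the exposure steps are the exposure's genome-wide
    significant, clumped variants; the mediator->outcome step uses the
    mediator's own instruments selected the same way. ``instruments`` may
    supply pre-selected variant-id lists per role
    (``{"exposure": [...], "mediator": [...]}``), bypassing selection —
    useful when instruments were curated externally or, in simulation, are
    known by design. Clumping runs only when an LD table is supplied.
    """
    instruments = instruments or {}

    def _select(sset: SummaryStatSet, role: str) -> SummaryStatSet:
        if role in instruments:
            ids = set(instruments[role])
            return sset.subset(sset.records["variant_id"].isin(ids))
        sel = select_genome_wide(sset, p_threshold)
        if ld is not None:
            sel = clump_greedy(sel, ld, clump_r2, window_kb)
        return sel

    exp_instruments = _select(exposure, "exposure")
    med_instruments = _select(mediator, "mediator")

    total_fit, n_total = _step_ivw(exp_instruments, outcome, palindrome_eaf_band)
    a_fit, n_a = _step_ivw(exp_instruments, mediator, palindrome_eaf_band)
    b_fit, n_b = _step_ivw(med_instruments, outcome, palindrome_eaf_band)

    steps = StepEstimates(
        a=a_fit.estimate_, se_a=a_fit.se_,
        b=b_fit.estimate_, se_b=b_fit.se_,
        total=total_fit.estimate_, se_total=total_fit.se_,
        step_pvalues=(total_fit.pvalue_, a_fit.pvalue_, b_fit.pvalue_),
    )
    result = mediate_steps(steps, gate_alpha, report_proportion)
    result.n_snps_per_step = (n_total, n_a, n_b)
    return result
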