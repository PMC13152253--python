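"""Synthetic GWAS summary statistics with known causal structure.

Summary statistics are simulated directly (no individual-level genotypes):
the pipeline consumes only summary data, so direct simulation makes the
ground truth exact and generation fast.

The mediation study draws a panel of biallelic SNPs in two blocks:

* exposure instruments with true effects gamma_j on the exposure, drawn
  centred-normal and scaled so the block explains a stated heritability;
* mediator instruments with effects delta_j on the mediator directly (the
  mediator's own genetic architecture, independent of the exposure).

Causal structure: the exposure affects the mediator (``a_effect``) and the
outcome directly (``theta_direct``); the mediator affects the outcome
(``b_effect``). Hence per SNP, the true outcome association is
(theta_direct + a*b) * gamma_j + b * delta_j + alpha_j, with alpha_j a
horizontally pleiotropic direct effect (none / balanced around zero /
directional around ``pleiotropy_mean``). Observed betas add sampling noise
with SE = 1/sqrt(2 p (1-p) N), the standard GWAS approximation for a
standardised trait; binary outcomes are generated on the log-odds scale with
the SE inflated by 1/sqrt(v(1-v)) for case fraction v.

Allele labels include configured, exactly-counted fractions of palindromic
(A/T, G/C) variants and of records whose effect/other alleles are swapped in
the mediator and outcome sets, so harmonization is exercised end to end.

The duo study emulates correlated maternal/fetal GWASs: with allele-sharing
coefficient 1/2, the unadjusted estimates are the contaminated mixtures
(bm + bf/2, bf + bm/2) plus (optionally correlated) sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import DuoEffectPair
from .sumstats import LDPairTable, SummaryStatSet

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic two-step MR study.

    Defaults mirror the scale of the source GWASs the pipeline is designed
    for: a ~700k-sample exposure GWAS with ~500 instruments, a ~408k-sample
    mediator GWAS, and a ~270k-sample outcome GWAS. ``h2_exposure`` /
    ``h2_mediator`` are the trait-variance fractions explained by each
    instrument block and set the instrument strength (per-SNP F is roughly
    h2/n_snps * N).
    """

    n_snps: int = 500                 # exposure-instrument block size
    n_mediator_snps: int = 500        # mediator-instrument block size
    n_exposure: int = 700_000
    n_mediator: int = 408_112
    n_outcome: int = 270_000
    maf_range: tuple = (0.05, 0.45)
    h2_exposure: float = 0.04
    h2_mediator: float = 0.15
    theta_direct: float = 0.0
    a_effect: float = 0.0
    b_effect: float = 0.0
    pleiotropy_mode: str = "none"     # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    binary_outcome: bool = False
    case_fraction: float = 0.117      # matches a 15,200/115,007 case-control mix
    palindromic_fraction: float = 0.10
    swapped_fraction: float = 0.20
    ld_block_size: int = 1
    within_block_r2: float = 0.95
    # duo-study settings
    maternal_effect_sd: float = 0.05
    fetal_effect_sd: float = 0.05
    n_duo_maternal: int = 270_002
    n_duo_fetal: int = 423_683
    overlap_correlation: float = 0.0
    seed: int = 20240401

    def validate(self) -> None:
        if min(self.n_snps, self.n_exposure, self.n_mediator, self.n_outcome) <= 0:
            raise ValueError("counts and sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        for frac in (self.palindromic_fraction, self.swapped_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("allele-label fractions must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Generating parameters paired with the realized per-SNP effects."""

    config: SimulationConfig
    variant_ids: list
    gamma: np.ndarray        # per-SNP effect on the exposure
    delta: np.ndarray        # per-SNP direct effect on the mediator
    alpha: np.ndarray        # per-SNP pleiotropic direct effect on the outcome
    maf: np.ndarray
    roles: list              # 'exposure_instrument' | 'mediator_instrument'
    seed: int = 0
    exposure_instrument_ids: list = field(default_factory=list)
    mediator_instrument_ids: list = field(default_factory=list)

    @property
    def total_effect(self) -> float:
        c = self.config
        return c.theta_direct + c.a_effect * c.b_effect


def _layout(m: int, block_size: int):
    """Chromosome/position layout: LD blocks of ``block_size`` adjacent SNPs
    10 kb apart within a block; blocks 50,000 kb apart (beyond any clumping
    window) cycling over 22 chromosomes."""
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for j in range(m):
        block, offset = divmod(j, block_size)
        chrom[j] = str(block % 22 + 1)
        pos[j] = 1_000_000 + (block // 22) * 50_000_000 + offset * 10_000
    return chrom, pos


def _alleles(m: int, n_palindromic: int, rng: np.random.Generator):
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    palin_idx = rng.choice(m, size=n_palindromic, replace=False) if n_palindromic else np.array([], int)
    is_palin = np.zeros(m, bool)
    is_palin[palin_idx] = True
    for j in range(m):
        if is_palin[j]:
            pair = ("A", "T") if rng.random() < 0.5 else ("C", "G")
            ea[j], oa[j] = pair if rng.random() < 0.5 else pair[::-1]
        else:
            ea[j], oa[j] = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
    return ea, oa, is_palin


def _records(variant_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    from scipy import stats

    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": n,
        }
    )


def _swap_records(df: pd.DataFrame, swap_mask: np.ndarray) -> pd.DataFrame:
    """Report the swapped subset with effect/other alleles exchanged (beta
    negated, eaf mirrored) — the same association, differently coded."""
    df = df.copy()
    ea = df["effect_allele"].to_numpy(object).copy()
    oa = df["other_allele"].to_numpy(object).copy()
    ea[swap_mask], oa[swap_mask] = oa[swap_mask].copy(), ea[swap_mask].copy()
    df["effect_allele"], df["other_allele"] = ea, oa
    df.loc[swap_mask, "beta"] *= -1.0
    df.loc[swap_mask, "eaf"] = 1.0 - df.loc[swap_mask, "eaf"]
    return df


def simulate_mediation_study(config: SimulationConfig) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, SimulationTruth]:
    """Simulate exposure, mediator and outcome summary statistics.

    Returns the three :class:`SummaryStatSet` (every set covers the full SNP
    panel, as real GWASs would) plus the :class:`SimulationTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_e, n_m = config.n_snps, config.n_mediator_snps
    m = n_e + n_m

    maf = rng.uniform(*config.maf_range, m)
    var_per_allele = 2.0 * maf * (1.0 - maf)

    gamma = np.zeros(m)
    gamma[:n_e] = rng.normal(0.0, np.sqrt(config.h2_exposure / (n_e * var_per_allele[:n_e])))
    delta = np.zeros(m)
    if n_m:
        delta[n_e:] = rng.normal(0.0, np.sqrt(config.h2_mediator / (n_m * var_per_allele[n_e:])))

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, m)
    else:
        # "directional" is only meaningful relative to the trait-increasing
        # allele: applied in the raw (arbitrary) coding, a non-zero mean
        # would cancel over the symmetric instrument-effect signs. Orient
        # each pleiotropic effect by the sign of the SNP's instrument effect.
        orientation = np.where(np.sign(gamma + delta) == 0, 1.0, np.sign(gamma + delta))
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, m) * orientation

    se_exp = 1.0 / np.sqrt(var_per_allele * config.n_exposure)
    se_med = 1.0 / np.sqrt(var_per_allele * config.n_mediator)
    se_out = 1.0 / np.sqrt(var_per_allele * config.n_outcome)
    if config.binary_outcome:
        se_out = se_out / np.sqrt(config.case_fraction * (1.0 - config.case_fraction))

    beta_exp = gamma + rng.standard_normal(m) * se_exp
    true_med = config.a_effect * gamma + delta
    beta_med = true_med + rng.standard_normal(m) * se_med
    true_out = (config.theta_direct + config.a_effect * config.b_effect) * gamma + config.b_effect * delta + alpha
    beta_out = true_out + rng.standard_normal(m) * se_out

    variant_ids = [f"rs{j + 1}" for j in range(m)]
    chrom, pos = _layout(m, config.ld_block_size)
    n_palin = round(config.palindromic_fraction * m)
    ea, oa, _ = _alleles(m, n_palin, rng)

    exp_df = _records(variant_ids, chrom, pos, ea, oa, maf, beta_exp, se_exp, config.n_exposure)
    med_df = _records(variant_ids, chrom, pos, ea, oa, maf, beta_med, se_med, config.n_mediator)
    out_df = _records(variant_ids, chrom, pos, ea, oa, maf, beta_out, se_out,
                      config.n_outcome)

    n_swap = round(config.swapped_fraction * m)
    swap_mask = np.zeros(m, bool)
    if n_swap:
        swap_mask[rng.choice(m, size=n_swap, replace=False)] = True
    med_df = _swap_records(med_df, swap_mask)
    out_df = _swap_records(out_df, swap_mask)

    outcome_scale = "log_odds" if config.binary_outcome else "sd"
    truth = SimulationTruth(
        config=config,
        variant_ids=variant_ids,
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        maf=maf,
        roles=["exposure_instrument"] * n_e + ["mediator_instrument"] * n_m,
        seed=config.seed,
        exposure_instrument_ids=variant_ids[:n_e],
        mediator_instrument_ids=variant_ids[n_e:],
    )
    return (
        SummaryStatSet("exposure", exp_df, "sd"),
        SummaryStatSet("mediator", med_df, "sd"),
        SummaryStatSet("outcome", out_df, outcome_scale),
        truth,
    )


def simulate_duo_study(
    config: SimulationConfig,
    beta_maternal=None,
    beta_fetal=None,
    noise: bool = True,
) -> tuple[DuoEffectPair, dict]:
    """Simulate unadjusted maternal/fetal duo GWAS effect pairs.

    True maternal and fetal effects are drawn independently (or supplied);
    the unadjusted estimates are the allele-sharing mixtures
    (bm + bf/2, bf + bm/2) plus bivariate-normal sampling noise with the
    configured between-GWAS ``overlap_correlation``. ``noise=False`` gives
    the exact contaminated values (useful for recovery identities).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    maf = rng.uniform(*config.maf_range, n)
    var_per_allele = 2.0 * maf * (1.0 - maf)
    se_m = 1.0 / np.sqrt(var_per_allele * config.n_duo_maternal)
    se_f = 1.0 / np.sqrt(var_per_allele * config.n_duo_fetal)

    bm = np.broadcast_to(np.asarray(
        beta_maternal if beta_maternal is not None
        else rng.normal(0.0, config.maternal_effect_sd, n), float), (n,)).copy()
    bf = np.broadcast_to(np.asarray(
        beta_fetal if beta_fetal is not None
        else rng.normal(0.0, config.fetal_effect_sd, n), float), (n,)).copy()

    unadj_m = bm + 0.5 * bf
    unadj_f = bf + 0.5 * bm
    if noise:
        rho = config.overlap_correlation
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        unadj_m = unadj_m + se_m * z1
        unadj_f = unadj_f + se_f * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    pair = DuoEffectPair(
        beta_maternal_unadj=unadj_m,
        se_maternal_unadj=se_m,
        beta_fetal_unadj=unadj_f,
        se_fetal_unadj=se_f,
        overlap_correlation=config.overlap_correlation,
    )
    truth = {"beta_maternal": bm, "beta_fetal": bf, "maf": maf, "seed": config.seed}
    return pair, truth


def block_ld_table(truth: SimulationTruth) -> LDPairTable:
    """Block-diagonal LD implied by the layout: every within-block pair has
    the configured r2, cross-block pairs are absent (r2 = 0)."""
    cfg = truth.config
    ld = LDPairTable()
    bs = cfg.ld_block_size
    ids = truth.variant_ids
    for start in range(0, len(ids), bs):
        block = ids[start:start + bs]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.add(block[i], block[j], cfg.within_block_r2)
    return ld


def write_fixture_bundle(outdir, config: SimulationConfig) -> dict:
    """Write a complete, re-readable study fixture to ``outdir``.

    Emits exposure/mediator/outcome TSVs, the block-diagonal LD table and a
    JSON truth file; returns {name: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, truth = simulate_mediation_study(config)

    paths = {}
    for name, sset in (("exposure", exposure), ("mediator", mediator), ("outcome", outcome)):
        path = outdir / f"{name}.tsv"
        sset.to_tsv(path)
        paths[name] = path

    ld_path = outdir / "ld.tsv"
    block_ld_table(truth).to_tsv(ld_path)
    paths["ld"] = ld_path

    truth_path = outdir / "truth.json"
    payload = {
        "config": asdict(truth.config),
        "seed": truth.seed,
        "total_effect": truth.total_effect,
        "variant_ids": truth.variant_ids,
        "gamma": truth.gamma.tolist(),
        "delta": truth.delta.tolist(),
        "alpha": truth.alpha.tolist(),
        "maf": truth.maf.tolist(),
        "roles": truth.roles,
        "exposure_instrument_ids": truth.exposure_instrument_ids,
        "mediator_instrument_ids": truth.mediator_instrument_ids,
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    paths["truth"] = truth_path
    return paths
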