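"""Analysis-graph orchestration: panels for every pair, gated mediation,
multiple-testing flags, and report tables.

A run is described by a declarative YAML document naming one exposure, one
or more mediators and one or more outcomes (dataset path + scale each,
outcomes optionally as an unpartitioned maternal/fetal duo to be
WLM-adjusted on load), an optional LD table, and thresholds whose defaults
are the conventional ones: instrument p < 5e-8, clump r2 = 0.001 within a
10,000 kb window, mediation gate alpha = 0.05, Bonferroni m = 7.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import partition
from .estimators import DEFAULT_BOOT, DEFAULT_SEED, beta_to_or, run_method_panel
from .mediation import STEP_NAMES, mediate_steps, StepEstimates
from .sumstats import (
    LDPairTable,
    SummaryStatSet,
    clump_greedy,
    harmonize_pair,
    read_summary_stats,
    select_genome_wide,
)


@dataclass
class TraitSpec:
    """One dataset in the analysis graph."""

    label: str
    path: str | None = None
    scale: str = "sd"
    #: optional duo partitioning: {"maternal_path": ..., "fetal_path": ...,
    #: "overlap_correlation": 0.0}; when set, the maternal-specific effect is
    #: derived on load via the WLM. Already-partitioned inputs use ``path``.
    duo: dict | None = None

    def load(self) -> SummaryStatSet:
        if self.duo is None:
            if self.path is None:
                raise ValueError(f"{self.label}: either path or duo must be given")
            return read_summary_stats(self.path, scale=self.scale, trait_label=self.label)
        maternal = read_summary_stats(self.duo["maternal_path"], scale=self.scale,
                                      trait_label=f"{self.label}_maternal_unadj")
        fetal = read_summary_stats(self.duo["fetal_path"], scale=self.scale,
                                   trait_label=f"{self.label}_fetal_unadj")
        rho = float(self.duo.get("overlap_correlation", 0.0))
        merged = maternal.records.merge(fetal.records, on="variant_id", suffixes=("_m", "_f"))
        if len(merged) == 0:
            raise ValueError(f"{self.label}: maternal and fetal duo files share no variants")
        beta = partition.wlm_adjust_maternal(merged["beta_m"], merged["beta_f"])
        se = partition.wlm_se(merged["se_m"], merged["se_f"], rho)
        from scipy import stats

        records = pd.DataFrame(
            {
                "variant_id": merged["variant_id"],
                "chromosome": merged["chromosome_m"],
                "position": merged["position_m"],
                "effect_allele": merged["effect_allele_m"],
                "other_allele": merged["other_allele_m"],
                "eaf": merged["eaf_m"],
                "beta": beta,
                "se": se,
                "pvalue": np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0),
                "n": merged["n_m"],
            }
        )
        return SummaryStatSet(self.label, records, self.scale)


@dataclass
class RunConfig:
    exposure: TraitSpec
    mediators: list
    outcomes: list
    ld_path: str | None = None
    instrument_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    gate_alpha: float = 0.05
    bonferroni_m: int = 7
    palindrome_eaf_band: tuple = (0.42, 0.58)
    n_boot: int = DEFAULT_BOOT
    seed: int = DEFAULT_SEED
    output_dir: str | None = None

    def __post_init__(self):
        if not self.mediators or not self.outcomes:
            raise ValueError("at least one mediator and one outcome are required")
        if not 0 < self.instrument_p < 1 or not 0 < self.gate_alpha < 1:
            raise ValueError("thresholds out of range")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        thresholds = doc.get("thresholds", {})
        return cls(
            exposure=TraitSpec(**doc["exposure"]),
            mediators=[TraitSpec(**spec) for spec in doc.get("mediators", [])],
            outcomes=[TraitSpec(**spec) for spec in doc.get("outcomes", [])],
            ld_path=doc.get("ld"),
            instrument_p=float(thresholds.get("instrument_p", 5e-8)),
            clump_r2=float(thresholds.get("clump_r2", 0.001)),
            clump_window_kb=float(thresholds.get("clump_window_kb", 10_000.0)),
            gate_alpha=float(thresholds.get("gate_alpha", 0.05)),
            bonferroni_m=int(thresholds.get("bonferroni_m", 7)),
            n_boot=int(doc.get("bootstrap", {}).get("n_boot", DEFAULT_BOOT)),
            seed=int(doc.get("seed", DEFAULT_SEED)),
            output_dir=doc.get("output_dir"),
        )


@dataclass
class AnalysisReport:
    panel: pd.DataFrame
    mediation: pd.DataFrame
    log: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def apply_bonferroni(pvalues, m: int) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level 0.05/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(pvalues, float) < 0.05 / m


def _select_instruments(sset, ld, cfg, log):
    selected = select_genome_wide(sset, cfg.instrument_p)
    log.append(f"{sset.trait_label}: {len(sset)} variants, {len(selected)} at p<{cfg.instrument_p:g}")
    if ld is not None and len(selected):
        clumped = clump_greedy(selected, ld, cfg.clump_r2, cfg.clump_window_kb)
        log.append(f"{sset.trait_label}: {len(clumped)} index SNPs after clumping")
        return clumped
    return selected


def _panel_for_pair(instruments, outcome_set, cfg, log):
    h = harmonize_pair(instruments, outcome_set, cfg.palindrome_eaf_band)
    log.append(
        f"{instruments.trait_label}->{outcome_set.trait_label}: {len(h)} harmonized "
        f"({h.n_dropped_palindromic} palindromic, {h.n_dropped_missing} incompatible dropped)"
    )
    return run_method_panel(h, n_boot=cfg.n_boot, seed=cfg.seed)


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis graph.

    Runs selection -> clump -> harmonize -> estimator panel for every
    exposure->outcome, exposure->mediator and mediator->outcome pair, then
    two-step mediation for each triple whose three step IVW p-values pass
    the gate. Bonferroni flags are attached to the pregnancy-outcome
    analyses (pairs whose outcome is in the outcomes list).
    """
    log: list[str] = []
    ld = LDPairTable.from_tsv(config.ld_path) if config.ld_path else None

    exposure = config.exposure.load()
    mediators = [spec.load() for spec in config.mediators]
    outcomes = [spec.load() for spec in config.outcomes]

    exp_instr = _select_instruments(exposure, ld, config, log)
    med_instr = {m.trait_label: _select_instruments(m, ld, config, log) for m in mediators}

    panels = {}
    frames = []
    for out_set in outcomes:
        panels[(exposure.trait_label, out_set.trait_label)] = _panel_for_pair(exp_instr, out_set, config, log)
    for med_set in mediators:
        panels[(exposure.trait_label, med_set.trait_label)] = _panel_for_pair(exp_instr, med_set, config, log)
        for out_set in outcomes:
            panels[(med_set.trait_label, out_set.trait_label)] = _panel_for_pair(
                med_instr[med_set.trait_label], out_set, config, log
            )
    outcome_labels = {o.trait_label for o in outcomes}
    for report in panels.values():
        frame = report.to_frame()
        corrected = report.outcome_label in outcome_labels
        frame["bonferroni_m"] = config.bonferroni_m if corrected else 1
        frame["significant"] = apply_bonferroni(
            frame["pvalue"], config.bonferroni_m if corrected else 1
        )
        frames.append(frame)
    panel_df = pd.concat(frames, ignore_index=True)

    mediation_rows = []
    for med_set in mediators:
        for out_set in outcomes:
            total = panels[(exposure.trait_label, out_set.trait_label)].results.get("ivw_mre")
            a_res = panels[(exposure.trait_label, med_set.trait_label)].results.get("ivw_mre")
            b_res = panels[(med_set.trait_label, out_set.trait_label)].results.get("ivw_mre")
            if total is None or a_res is None or b_res is None:
                log.append(f"mediation {med_set.trait_label}/{out_set.trait_label}: skipped (missing IVW)")
                continue
            steps = StepEstimates(
                a=a_res.beta, se_a=a_res.se, b=b_res.beta, se_b=b_res.se,
                total=total.beta, se_total=total.se,
                step_pvalues=(total.pvalue, a_res.pvalue, b_res.pvalue),
            )
            result = mediate_steps(steps, config.gate_alpha)
            row = {
                "exposure": exposure.trait_label,
                "mediator": med_set.trait_label,
                "outcome": out_set.trait_label,
                "assessed": result.assessed,
                "failing_steps": ";".join(result.failing_steps),
                "total": steps.total, "se_total": steps.se_total,
                "a": steps.a, "se_a": steps.se_a,
                "b": steps.b, "se_b": steps.se_b,
                "indirect": result.indirect, "se_indirect": result.se_indirect,
                "p_indirect": result.p_indirect,
                "direct": result.direct, "se_direct": result.se_direct,
                "p_direct": result.p_direct,
            }
            mediation_rows.append(row)
            gate = "passed" if result.assessed else f"failed at {result.failing_steps}"
            log.append(f"mediation {med_set.trait_label}/{out_set.trait_label}: gate {gate} "
                       f"(step p-values {[f'{p:.3g}' for p in steps.step_pvalues]}, order {STEP_NAMES})")
    mediation_df = pd.DataFrame(
        mediation_rows,
        columns=["exposure", "mediator", "outcome", "assessed", "failing_steps",
                 "total", "se_total", "a", "se_a", "b", "se_b",
                 "indirect", "se_indirect", "p_indirect",
                 "direct", "se_direct", "p_direct"],
    )

    summary = {
        "seed": config.seed,
        "thresholds": {
            "instrument_p": config.instrument_p,
            "clump_r2": config.clump_r2,
            "clump_window_kb": config.clump_window_kb,
            "gate_alpha": config.gate_alpha,
            "bonferroni_m": config.bonferroni_m,
            "bonferroni_threshold": 0.05 / config.bonferroni_m,
        },
        "n_pairs": len(panels),
        "n_mediation_assessed": int(mediation_df["assessed"].sum()) if len(mediation_df) else 0,
    }
    report = AnalysisReport(panel=panel_df, mediation=mediation_df, log=log, summary=summary)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        panel_df.to_csv(outdir / "panel.tsv", sep="\t", index=False, float_format="%.10g")
        mediation_df.to_csv(outdir / "mediation.tsv", sep="\t", index=False, float_format="%.10g")
        forest_data(report).to_csv(outdir / "forest.tsv", sep="\t", index=False, float_format="%.10g")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return report


def forest_data(report: AnalysisReport) -> pd.DataFrame:
    """Plot-ready per-(pair, method) table: estimate and 95% CI on the
    reporting scale (odds ratios for log-odds outcomes)."""
    if len(report.panel) == 0:
        raise ValueError("empty report")
    rows = []
    for rec in report.panel.itertuples(index=False):
        if rec.scale == "log_odds":
            est, lo, hi = beta_to_or(rec.beta, rec.se, rec.scale)
            unit = "odds_ratio"
        else:
            est, lo, hi = rec.beta, rec.ci_low, rec.ci_high
            unit = rec.scale
        rows.append(
            {
                "exposure": rec.exposure, "outcome": rec.outcome, "method": rec.method,
                "n_snps": rec.n_snps, "estimate": est, "ci_low": lo, "ci_high": hi,
                "unit": unit, "pvalue": rec.pvalue,
            }
        )
    return pd.DataFrame(rows)
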