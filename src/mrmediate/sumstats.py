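"""Reading, filtering, clumping and harmonizing GWAS summary statistics.

The unit of data is a :class:`SummaryStatSet`: one GWAS's per-variant
association records (variant id, alleles, effect-allele frequency, beta, SE,
p-value, sample size) on a declared scale. Instrument preparation follows the
standard two-sample MR workflow: genome-wide significance filtering, greedy
LD clumping to approximately independent index SNPs, and allele harmonization
of an exposure/outcome pair into a :class:`HarmonizedInstrumentSet` ready for
the estimator panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ALLELES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Allele pairs that are their own strand complement (ambiguous strand).
PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: Canonical column name -> accepted aliases (case-insensitive) in input TSVs.
COLUMN_ALIASES = {
    "variant_id": ["variant_id", "snp", "rsid", "rs_id", "variant", "markername", "id"],
    "chromosome": ["chromosome", "chr", "chrom", "#chrom"],
    "position": ["position", "pos", "bp", "base_pair_location"],
    "effect_allele": ["effect_allele", "ea", "a1", "allele1", "alt"],
    "other_allele": ["other_allele", "oa", "a2", "allele2", "nea", "non_effect_allele", "ref"],
    "eaf": ["eaf", "effect_allele_frequency", "freq", "af", "maf"],
    "beta": ["beta", "b", "effect", "effect_size"],
    "se": ["se", "standard_error", "stderr", "sebeta"],
    "pvalue": ["pvalue", "p", "pval", "p_value"],
    "n": ["n", "sample_size", "samplesize", "n_total"],
}

MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
CANONICAL_COLUMNS = list(COLUMN_ALIASES)

SCALES = ("sd", "log_odds", "z_score")


@dataclass
class SummaryStatSet:
    """One GWAS's per-variant association records.

    ``records`` is a DataFrame with the canonical columns (``variant_id``,
    ``chromosome``, ``position``, ``effect_allele``, ``other_allele``,
    ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``); optional columns may hold
    NaN. ``scale`` records the unit the betas are on: ``sd`` for standardised
    continuous traits, ``log_odds`` for binary outcomes, ``z_score`` for
    standardised-Z partitioned statistics.
    """

    trait_label: str
    records: pd.DataFrame
    scale: str = "sd"
    n_dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> pd.Series:
        return self.records["variant_id"]

    def subset(self, mask) -> "SummaryStatSet":
        return SummaryStatSet(self.trait_label, self.records[mask].reset_index(drop=True), self.scale)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _resolve_columns(columns) -> dict:
    """Map canonical names to the actual header names present in the file."""
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def read_summary_stats(path, scale: str = "sd", trait_label: str | None = None) -> SummaryStatSet:
    """Read a tab-separated GWAS summary-statistics file.

    Rows violating the record invariants (non-ACGT or identical alleles,
    se <= 0, p outside (0, 1], missing beta) are dropped and counted in the
    returned set's ``n_dropped`` tally. Missing a mandatory column or ending
    with zero valid rows is fatal.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    resolved = _resolve_columns(raw.columns)
    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    df = pd.DataFrame(index=raw.index)
    for canonical in CANONICAL_COLUMNS:
        if canonical in resolved:
            df[canonical] = raw[resolved[canonical]]
        else:
            df[canonical] = np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str).where(df["chromosome"].notna())
    for col in ("position", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    tally: dict[str, int] = {}

    def _drop(mask, reason):
        n = int(mask.sum())
        if n:
            tally[reason] = tally.get(reason, 0) + n
        return df[~mask]

    df = _drop(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES), "invalid_allele")
    df = _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    df = _drop(df["beta"].isna(), "missing_beta")
    df = _drop(df["se"].isna() | (df["se"] <= 0), "nonpositive_se")
    df = _drop(df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1), "invalid_pvalue")
    df = _drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "invalid_eaf")
    df = _drop(df.duplicated("variant_id", keep="first"), "duplicate_variant_id")

    if len(df) == 0:
        raise ValueError(f"{path}: no valid rows after filtering ({tally})")
    out = SummaryStatSet(trait_label or path.stem, df.reset_index(drop=True), scale)
    out.n_dropped = tally
    return out


def select_genome_wide(sset: SummaryStatSet, p_threshold: float = 5e-8) -> SummaryStatSet:
    """Keep records with p < ``p_threshold`` (strict), preserving input order."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    kept = sset.subset(sset.records["pvalue"] < p_threshold)
    if len(kept) == 0:
        warnings.warn(f"{sset.trait_label}: no variants below p < {p_threshold:g}", stacklevel=2)
    return kept


class LDPairTable:
    """Sparse long-format pairwise LD (variant_id_a, variant_id_b, r2).

    Lookups are symmetric; self-pairs return 1; absent pairs return 0
    (sparse tables typically omit pairs below the reporting threshold).
    """

    def __init__(self, pairs: pd.DataFrame | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._ids: set[str] = set()
        if pairs is not None:
            for a, b, r2 in pairs[["variant_id_a", "variant_id_b", "r2"]].itertuples(index=False):
                self.add(str(a), str(b), float(r2))

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        key = (a, b) if a <= b else (b, a)
        self._r2[key] = r2
        self._ids.update((a, b))

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    @property
    def ids(self) -> set[str]:
        return set(self._ids)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LDPairTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def clump_greedy(
    sset: SummaryStatSet,
    ld: LDPairTable | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryStatSet:
    """Greedy p-value clumping to approximately independent index SNPs.

    Candidates are visited by ascending p-value; a candidate is removed when
    an already-kept variant on the same chromosome lies within
    ``window_kb`` kilobases AND has r2 above ``r2_threshold`` with it. A
    missing LD pair within the window is treated as r2 = 0 (kept).
    """
    df = sset.records
    if df["position"].isna().any() or df["chromosome"].isna().any():
        raise ValueError("clumping requires chromosome and position for every variant")
    ld = ld or LDPairTable()
    unknown = ld.ids - set(df["variant_id"])
    if unknown:
        warnings.warn(f"LD table references {len(unknown)} unknown variant id(s); ignored", stacklevel=2)

    order = df.sort_values(["pvalue", "variant_id"], kind="mergesort").index
    window_bp = window_kb * 1000.0
    kept: list[int] = []
    for idx in order:
        cand = df.loc[idx]
        removed = False
        for kidx in kept:
            k = df.loc[kidx]
            if k["chromosome"] == cand["chromosome"] and abs(k["position"] - cand["position"]) <= window_bp:
                if ld.get(cand["variant_id"], k["variant_id"]) > r2_threshold:
                    removed = True
                    break
        if not removed:
            kept.append(idx)
    return sset.subset(df.index.isin(kept))


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned (beta_exposure, beta_outcome) pairs ready for MR.

    ``table`` columns: variant_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome (and eaf_exposure for audit). ``scale`` is copied from the
    outcome set and drives odds-ratio conversion downstream.
    """

    exposure_label: str
    outcome_label: str
    table: pd.DataFrame
    scale: str = "sd"
    n_dropped_palindromic: int = 0
    n_dropped_missing: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.table["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.table["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, exposure_label="exposure", outcome_label="outcome", scale="sd"):
        return cls(exposure_label, outcome_label, pd.read_csv(path, sep="\t"), scale)


def _orientation(ea_exp, oa_exp, ea_out, oa_out):
    """Classify outcome allele labels relative to exposure labels.

    Returns 'same', 'swapped' or None (incompatible even after taking the
    reverse-strand complement of the outcome alleles).
    """
    if (ea_out, oa_out) == (ea_exp, oa_exp):
        return "same"
    if (ea_out, oa_out) == (oa_exp, ea_exp):
        return "swapped"
    ea_c, oa_c = COMPLEMENT[ea_out], COMPLEMENT[oa_out]
    if (ea_c, oa_c) == (ea_exp, oa_exp):
        return "same"
    if (ea_c, oa_c) == (oa_exp, ea_exp):
        return "swapped"
    return None


def harmonize_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstrumentSet:
    """Align an exposure/outcome pair of summary-stat sets on shared variants.

    Variants are intersected on id; outcome betas are sign-flipped (and eaf
    mirrored) where the outcome's effect allele is the exposure's other
    allele, allowing for reverse-strand reporting. Palindromic (A/T, G/C)
    variants are resolved by allele frequency: dropped when the exposure eaf
    is missing or inside ``palindrome_eaf_band``, otherwise oriented so the
    minor/major side agrees between studies. Variants with incompatible
    alleles, or with beta_exposure exactly 0 (undefined Wald ratio), are
    dropped and counted.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize_pair requires non-empty exposure and outcome sets")
    lo, hi = palindrome_eaf_band
    merged = exposure.records.merge(
        outcome.records, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )

    rows = []
    n_palin = 0
    n_missing = 0
    for rec in merged.itertuples(index=False):
        orient = _orientation(rec.effect_allele_exp, rec.other_allele_exp,
                              rec.effect_allele_out, rec.other_allele_out)
        if orient is None:
            n_missing += 1
            continue
        flip = orient == "swapped"
        if frozenset((rec.effect_allele_exp, rec.other_allele_exp)) in PALINDROMIC_PAIRS:
            eaf_exp = rec.eaf_exp
            if pd.isna(eaf_exp) or lo <= eaf_exp <= hi:
                n_palin += 1
                continue
            # allele labels carry no strand information here; trust frequency
            if not pd.isna(rec.eaf_out):
                eaf_out_aligned = 1.0 - rec.eaf_out if flip else rec.eaf_out
                if (eaf_exp - 0.5) * (eaf_out_aligned - 0.5) < 0:
                    flip = not flip
        beta_out = -rec.beta_out if flip else rec.beta_out
        if rec.beta_exp == 0:
            n_missing += 1
            continue
        rows.append((rec.variant_id, rec.beta_exp, rec.se_exp, beta_out, rec.se_out, rec.eaf_exp))

    if not rows:
        raise ValueError("no variants survived harmonization")
    table = pd.DataFrame(
        rows, columns=["variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "eaf_exposure"]
    )
    return HarmonizedInstrumentSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        table=table,
        scale=outcome.scale,
        n_dropped_palindromic=n_palin,
        n_dropped_missing=n_missing,
    )


def mean_f_statistic(h: HarmonizedInstrumentSet) -> float:
    """Mean instrument-strength F statistic, mean over SNPs of (beta/se)^2."""
    if len(h) == 0:
        raise ValueError("mean_f_statistic requires at least one instrument")
    return float(np.mean((h.beta_exposure / h.se_exposure) ** 2))
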