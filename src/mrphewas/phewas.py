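"""Phenome-wide scan orchestration.

Filtering of the phenotype manifest, Bonferroni control at alpha / Np,
per-phenotype per-stratum MR estimation, LDL-c-anchored relative-effect
scaling, and the sex-difference / replication z-tests.
"""
from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from scipy import special

from .estimators import (
    EstimatorError,
    MREstimate,
    ORResult,
    estimate_auto,
    linear_beta_to_or,
)
from .sumstats import (
    HarmonizationError,
    InstrumentSet,
    PhenotypeRecord,
    SummaryAssociation,
    SumstatsError,
    harmonize,
)


class PhewasError(ValueError):
    pass


@dataclass(frozen=True)
class PhewasConfig:
    """Scan configuration; defaults follow the UK-Biobank-style inclusion
    rules (>= 100 cases for binary traits, n >= 10,000 for quantitative
    traits, external-cause ICD chapter Z excluded)."""

    min_cases_binary: int = 100
    min_n_quantitative: int = 10000
    excluded_icd_range: tuple[str, str] = ("Z00", "Z99")
    excluded_subcategories: tuple[str, ...] = ()
    alpha: float = 0.05
    strata: tuple[str, ...] = ("both", "men", "women")
    anchor_phenotype_id: str | None = None
    palindrome_eaf_window: float = 0.08

    def __post_init__(self):
        if self.min_cases_binary < 1:
            raise PhewasError("min_cases_binary must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise PhewasError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_icd_range"] = list(self.excluded_icd_range)
        d["excluded_subcategories"] = list(self.excluded_subcategories)
        d["strata"] = list(self.strata)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhewasConfig":
        kw = dict(d)
        for key in ("excluded_icd_range", "excluded_subcategories", "strata"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)


# ---------------------------------------------------------------------------
# Manifest filtering

_ICD_RE = re.compile(r"([A-Z])(\d{1,3})")


def _icd_in_range(code: str, lo: str, hi: str) -> bool:
    m, ml, mh = _ICD_RE.match(code), _ICD_RE.match(lo), _ICD_RE.match(hi)
    if m is None or ml is None or mh is None:
        return False
    key = (m.group(1), int(m.group(2)))
    return (ml.group(1), int(ml.group(2))) <= key <= (mh.group(1), int(mh.group(2)))


@dataclass(frozen=True, slots=True)
class Exclusion:
    phenotype_id: str
    reason: str  # first matching rule
    detail: str


def filter_phenotypes(
    manifest: Sequence[PhenotypeRecord], config: PhewasConfig
) -> tuple[list[PhenotypeRecord], list[Exclusion]]:
    """Apply the inclusion rules in a fixed order, recording the first
    matching reason for every dropped row.

    Order: duplicates, binary case-count floor, quantitative sample-size
    floor, ICD coding rules (missing main code, excluded code range),
    excluded subcategories.  Np is the number of kept rows.
    """
    kept: list[PhenotypeRecord] = []
    ledger: list[Exclusion] = []
    seen: set[str] = set()
    lo, hi = config.excluded_icd_range
    excluded_cats = set(config.excluded_subcategories)
    for rec in manifest:
        reason = detail = None
        if rec.duplicate_of is not None or rec.phenotype_id in seen:
            reason, detail = "duplicate", rec.duplicate_of or rec.phenotype_id
        elif rec.trait_type == "binary" and rec.n_cases < config.min_cases_binary:
            reason, detail = "min_cases", f"{rec.n_cases} < {config.min_cases_binary}"
        elif rec.trait_type in ("continuous", "ordered") and (
            rec.n < config.min_n_quantitative
        ):
            reason, detail = "min_n", f"{rec.n} < {config.min_n_quantitative}"
        elif rec.icd_based and rec.icd_code is None:
            reason, detail = "no_main_icd", "ICD-coded phenotype without a main code"
        elif rec.icd_code is not None and _icd_in_range(rec.icd_code, lo, hi):
            reason, detail = "icd_excluded_range", f"{rec.icd_code} in {lo}-{hi}"
        elif rec.category in excluded_cats:
            reason, detail = "excluded_subcategory", rec.category
        if reason is None:
            kept.append(rec)
            seen.add(rec.phenotype_id)
        else:
            ledger.append(Exclusion(rec.phenotype_id, reason, detail))
    return kept, ledger


@dataclass(frozen=True, slots=True)
class BonferroniThreshold:
    threshold: float
    threshold_2sf: float
    np_tested: int
    alpha: float


def bonferroni_threshold(np_tested: int, alpha: float = 0.05) -> BonferroniThreshold:
    """Family-wise significance level alpha / Np, reported at full precision
    and rounded to 2 significant figures for display."""
    if np_tested < 1:
        raise PhewasError("np_tested must be >= 1")
    t = alpha / np_tested
    return BonferroniThreshold(
        threshold=t,
        threshold_2sf=float(f"{t:.1e}"),
        np_tested=np_tested,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# z-tests


def sexdiff_ztest(
    beta_m: float, se_m: float, beta_w: float, se_w: float
) -> tuple[float, float]:
    """Two-sided z-test for a difference between men's and women's estimates:
    z = (beta_m - beta_w) / sqrt(se_m^2 + se_w^2)."""
    if se_m <= 0 or se_w <= 0:
        raise PhewasError("standard errors must be positive")
    z = (beta_m - beta_w) / math.hypot(se_m, se_w)
    return z, 2.0 * float(special.ndtr(-abs(z)))


def compare_replication(
    primary: MREstimate, replication: MREstimate
) -> tuple[float, float]:
    """Two-sided z-test comparing a primary estimate with its replication."""
    return sexdiff_ztest(
        primary.beta_hat, primary.se_hat, replication.beta_hat, replication.se_hat
    )


# ---------------------------------------------------------------------------
# Result rows and anchor scaling


@dataclass(slots=True)
class PhewasResultRow:
    target: str
    phenotype_id: str
    category: str
    trait_type: str
    stratum: str
    estimate: MREstimate
    or_result: ORResult | None = None
    scaled_beta: float | None = None
    neglog10_p: float = 0.0
    significant: bool = False
    sexdiff_z: float | None = None
    sexdiff_p: float | None = None


def scale_to_anchor(
    rows: Iterable[PhewasResultRow], anchor_id: str
) -> list[PhewasResultRow]:
    """Fill ``scaled_beta`` = beta / |beta of the anchor phenotype| within
    each (target, stratum).

    With LDL-c as the anchor this is the relative-effect-on-LDL-c scale: the
    anchor row itself becomes sign(beta_anchor) * 1.  Strata without an
    anchor estimate keep scaled_beta undefined.
    """
    rows = list(rows)
    anchors: dict[tuple[str, str], float] = {}
    for r in rows:
        if r.phenotype_id == anchor_id and r.estimate.beta_hat != 0:
            anchors[(r.target, r.stratum)] = abs(r.estimate.beta_hat)
    for r in rows:
        denom = anchors.get((r.target, r.stratum))
        r.scaled_beta = None if denom is None else r.estimate.beta_hat / denom
    return rows


# ---------------------------------------------------------------------------
# Scan


class SumstatsStore(Protocol):
    """Anything that yields outcome associations per phenotype x stratum."""

    def get(
        self, phenotype_id: str, stratum: str
    ) -> list[SummaryAssociation] | None: ...


class InMemoryStore(dict):
    """Mapping (phenotype_id, stratum) -> list[SummaryAssociation]."""

    def get(self, phenotype_id, stratum=None):  # type: ignore[override]
        if stratum is None:
            return super().get(phenotype_id)
        return super().get((phenotype_id, stratum))


class DirectoryStore:
    """Reads ``<dir>/<phenotype_id>.<stratum>.tsv`` on demand."""

    def __init__(self, directory):
        from pathlib import Path

        self.directory = Path(directory)

    def get(self, phenotype_id, stratum):
        from .sumstats import read_sumstats

        path = self.directory / f"{phenotype_id}.{stratum}.tsv"
        if not path.exists():
            return None
        return read_sumstats(path, stratum=stratum)


@dataclass
class PhewasSummary:
    np_tested: int
    threshold: BonferroniThreshold
    n_significant_rows: int
    n_significant_phenotypes: int  # distinct (target, phenotype) with any hit
    category_counts: dict[tuple[str, str], int]  # (target, category) -> hits
    exclusions: list[Exclusion]
    skipped: list[tuple[str, str, str]]  # (phenotype, stratum, reason)
    sexdiff: dict[tuple[str, str], tuple[float, float]]  # (target, pheno) -> (z, p)


def _estimate_one(
    instruments: InstrumentSet,
    outcomes_by_variant: Mapping[str, SummaryAssociation],
    palindrome_eaf_window: float,
) -> tuple[MREstimate | None, str | None]:
    """Harmonize each instrument to its outcome record and estimate.

    Returns (estimate, None) or (None, reason) when no usable variant
    survives harmonization.
    """
    kept_exp: list[SummaryAssociation] = []
    kept_out: list[SummaryAssociation] = []
    kept_ids: list[str] = []
    for member in instruments.members:
        out = outcomes_by_variant.get(member.variant_id)
        if out is None:
            continue
        try:
            _, out_h = harmonize(member, out, palindrome_eaf_window)
        except HarmonizationError:
            continue
        kept_exp.append(member)
        kept_out.append(out_h)
        kept_ids.append(member.variant_id)
    if not kept_ids:
        return None, "no_usable_variants"
    subset = (
        instruments
        if len(kept_ids) == len(instruments)
        else instruments.subset(kept_ids)
    )
    try:
        return estimate_auto(subset, kept_out), None
    except EstimatorError as exc:
        return None, f"estimator_error: {exc}"


def run_phewas(
    manifest: Sequence[PhenotypeRecord],
    store: SumstatsStore,
    instruments_by_target: Mapping[str, InstrumentSet],
    config: PhewasConfig | None = None,
) -> tuple[list[PhewasResultRow], PhewasSummary]:
    """Scan every target against every kept phenotype in every stratum.

    For each cell: harmonize, estimate (Wald / IVW dispatch), convert binary
    traits to odds ratios for presentation, and flag significance of the
    linear-scale p at alpha / Np.  Missing stratum files are skipped with a
    ledger entry, never silently.
    """
    config = config or PhewasConfig()
    kept, exclusions = filter_phenotypes(manifest, config)
    if not kept:
        raise PhewasError("no phenotypes survive filtering")
    thr = bonferroni_threshold(len(kept), config.alpha)

    rows: list[PhewasResultRow] = []
    skipped: list[tuple[str, str, str]] = []
    by_pheno: dict[tuple[str, str], dict[str, PhewasResultRow]] = {}
    for target, instruments in instruments_by_target.items():
        for rec in kept:
            for stratum in config.strata:
                outcomes = store.get(rec.phenotype_id, stratum)
                if outcomes is None:
                    skipped.append((rec.phenotype_id, stratum, "missing_stratum"))
                    continue
                est, why = _estimate_one(
                    instruments,
                    {o.variant_id: o for o in outcomes},
                    config.palindrome_eaf_window,
                )
                if est is None:
                    skipped.append((rec.phenotype_id, stratum, why))
                    continue
                or_result = None
                if rec.trait_type == "binary" and rec.case_fraction is not None:
                    or_result = linear_beta_to_or(est, rec.case_fraction)
                row = PhewasResultRow(
                    target=target,
                    phenotype_id=rec.phenotype_id,
                    category=rec.category,
                    trait_type=rec.trait_type,
                    stratum=stratum,
                    estimate=est,
                    or_result=or_result,
                    neglog10_p=est.neglog10_p,
                    significant=est.pval < thr.threshold,
                )
                rows.append(row)
                by_pheno.setdefault((target, rec.phenotype_id), {})[stratum] = row

    sexdiff: dict[tuple[str, str], tuple[float, float]] = {}
    for key, per_stratum in by_pheno.items():
        men, women = per_stratum.get("men"), per_stratum.get("women")
        if men is None or women is None:
            continue
        z, p = sexdiff_ztest(
            men.estimate.beta_hat,
            men.estimate.se_hat,
            women.estimate.beta_hat,
            women.estimate.se_hat,
        )
        sexdiff[key] = (z, p)
        for row in per_stratum.values():
            row.sexdiff_z, row.sexdiff_p = z, p

    if config.anchor_phenotype_id is not None:
        rows = scale_to_anchor(rows, config.anchor_phenotype_id)

    category_counts: dict[tuple[str, str], int] = {}
    hit_phenotypes: set[tuple[str, str]] = set()
    n_sig_rows = 0
    for r in rows:
        if r.significant:
            n_sig_rows += 1
            if (r.target, r.phenotype_id) not in hit_phenotypes:
                hit_phenotypes.add((r.target, r.phenotype_id))
                key = (r.target, r.category)
                category_counts[key] = category_counts.get(key, 0) + 1

    summary = PhewasSummary(
        np_tested=len(kept),
        threshold=thr,
        n_significant_rows=n_sig_rows,
        n_significant_phenotypes=len(hit_phenotypes),
        category_counts=category_counts,
        exclusions=exclusions,
        skipped=skipped,
        sexdiff=sexdiff,
    )
    return rows, summary


def manhattan_table(rows: Sequence[PhewasResultRow]) -> list[dict]:
    """Category-ordered (target, category, phenotype, stratum, -log10 p)
    records for Manhattan-style plotting or tabulation."""
    ordered = sorted(
        rows, key=lambda r: (r.target, r.category, r.phenotype_id, r.stratum)
    )
    return [
        {
            "target": r.target,
            "category": r.category,
            "phenotype_id": r.phenotype_id,
            "stratum": r.stratum,
            "neglog10_p": r.neglog10_p,
            "significant": r.significant,
        }
        for r in ordered
    ]
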