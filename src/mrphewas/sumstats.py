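"""GWAS summary-statistic records, TSV I/O, allele harmonization and LD pruning.

The objects here are the building blocks of two-sample Mendelian randomization:
per-variant association records (variant -> exposure, variant -> outcome), the
instrument sets that proxy a drug target, and the phenotype manifest rows a
phenome-wide scan iterates over.  Everything is identified by rsID; genomic
coordinates are out of scope.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

log = logging.getLogger(__name__)

STRATA = ("both", "men", "women")
_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_LN10 = math.log(10.0)
_LN2 = math.log(2.0)


class SumstatsError(ValueError):
    """Malformed summary-statistic input."""


class HarmonizationError(SumstatsError):
    """A variant that cannot be aligned between exposure and outcome.

    Attributes
    ----------
    variant_id : str
    reason : str
        Machine-readable reason code: ``allele_mismatch``,
        ``palindromic_ambiguous`` or ``palindromic_no_eaf``.
    """

    def __init__(self, variant_id: str, reason: str, message: str):
        super().__init__(message)
        self.variant_id = variant_id
        self.reason = reason


@dataclass(frozen=True, slots=True)
class SummaryAssociation:
    """One variant x phenotype x stratum association.

    ``beta`` is the per-allele effect of ``effect_allele``: SD units for
    continuous traits, linear-probability units for binary traits fit with
    linear regression.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float | None = None
    eaf: float | None = None
    n: int | None = None
    n_cases: int | None = None
    stratum: str = "both"

    def __post_init__(self):
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise SumstatsError(
                f"{self.variant_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise SumstatsError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise SumstatsError(f"{self.variant_id}: pval outside (0, 1]: {self.pval}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SumstatsError(f"{self.variant_id}: eaf outside [0, 1]: {self.eaf}")
        if self.n is not None and self.n < 1:
            raise SumstatsError(f"{self.variant_id}: n must be >= 1")
        if self.n_cases is not None:
            if self.n is None or not (0 < self.n_cases < self.n):
                raise SumstatsError(f"{self.variant_id}: need 0 < n_cases < n")
        if self.stratum not in STRATA:
            raise SumstatsError(f"{self.variant_id}: unknown stratum {self.stratum!r}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def pval_from_z(self) -> float:
        """Two-sided normal p implied by beta/se."""
        return 2.0 * float(special.ndtr(-abs(self.z)))

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class InstrumentSet:
    """Variants proxying a drug target (or a polygenic score) on the exposure.

    ``correlation`` is the signed pairwise LD correlation matrix rho (not
    r-squared), aligned row-for-row with ``members``; ``None`` means the
    instruments are treated as independent.
    """

    target_label: str
    members: tuple[SummaryAssociation, ...]
    correlation: np.ndarray | None = None
    r2_prune_threshold: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if not (0.0 < self.r2_prune_threshold <= 1.0):
            raise SumstatsError("r2_prune_threshold must be in (0, 1]")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            object.__setattr__(self, "correlation", r)
            j = len(self.members)
            if r.shape != (j, j):
                raise SumstatsError(
                    f"correlation shape {r.shape} does not match {j} members"
                )
            if not np.allclose(r, r.T, atol=1e-10):
                raise SumstatsError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-10):
                raise SumstatsError("correlation diagonal must be 1")
            if np.any(np.abs(r) > 1.0 + 1e-12):
                raise SumstatsError("correlation entries must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.members)

    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]

    def subset(self, variant_ids: Sequence[str]) -> "InstrumentSet":
        """Restrict to the given variants, keeping their order and the
        matching correlation sub-matrix."""
        index = {m.variant_id: i for i, m in enumerate(self.members)}
        idx = [index[v] for v in variant_ids]
        corr = None
        if self.correlation is not None:
            corr = self.correlation[np.ix_(idx, idx)]
        return InstrumentSet(
            target_label=self.target_label,
            members=tuple(self.members[i] for i in idx),
            correlation=corr,
            r2_prune_threshold=self.r2_prune_threshold,
        )


@dataclass(frozen=True, slots=True)
class PhenotypeRecord:
    """One phenome-manifest row: what the trait is and whether it has the
    power/coding required for inclusion in the scan."""

    phenotype_id: str
    label: str
    category: str
    trait_type: str  # binary | ordered | continuous
    n: int
    n_cases: int | None = None
    icd_code: str | None = None
    duplicate_of: str | None = None
    icd_based: bool = False

    def __post_init__(self):
        if self.trait_type not in ("binary", "ordered", "continuous"):
            raise SumstatsError(
                f"{self.phenotype_id}: trait_type must be binary/ordered/continuous"
            )
        if self.trait_type == "binary" and self.n_cases is None:
            raise SumstatsError(f"{self.phenotype_id}: binary trait needs n_cases")
        if self.n_cases is not None and not (0 < self.n_cases < self.n):
            raise SumstatsError(f"{self.phenotype_id}: need 0 < n_cases < n")
        if self.icd_code is not None and not re.fullmatch(
            r"[A-Z]\d+(\.\d+)?", self.icd_code
        ):
            raise SumstatsError(
                f"{self.phenotype_id}: icd_code {self.icd_code!r} not letter+digits"
            )

    @property
    def case_fraction(self) -> float | None:
        if self.n_cases is None:
            return None
        return self.n_cases / self.n


# ---------------------------------------------------------------------------
# TSV I/O

#: Default column-name synonyms, Neale-lab dialect first.
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "variant", "snp", "rsid", "rsids", "id", "markername"),
    "effect_allele": ("effect_allele", "alt", "a1", "ea", "allele1"),
    "other_allele": ("other_allele", "ref", "a2", "oa", "nea", "allele2", "allele0"),
    "eaf": ("eaf", "minor_af", "af", "effect_allele_frequency", "freq", "maf"),
    "beta": ("beta", "b", "effect", "est"),
    "se": ("se", "standard_error", "sebeta", "stderr"),
    "pval": ("pval", "p", "p_value", "pvalue", "p_val"),
    "log10_pval": ("log10_pval", "log10p", "logp"),
    "neglog10_pval": ("neglog10_pval", "neglog10p", "mlog10p", "lp"),
    "n": ("n", "n_complete_samples", "sample_size", "nsamples"),
    "n_cases": ("n_cases", "ncase", "ncases", "cases"),
}

_REQUIRED = ("variant_id", "effect_allele", "other_allele", "beta", "se")
_NUMERIC = ("eaf", "beta", "se", "pval", "log10_pval", "neglog10_pval", "n", "n_cases")
# float64 min subnormal; p-values that underflow are clamped here, the exact
# tail mass survives in the log10 p column
_TINY_P = 5e-324


def _resolve_columns(
    header: Sequence[str], synonyms: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    out: dict[str, str] = {}
    for canonical, names in synonyms.items():
        for name in names:
            if name in lower:
                out[canonical] = lower[name]
                break
    return out


def read_sumstats(
    path: str | Path,
    stratum: str = "both",
    synonyms: Mapping[str, tuple[str, ...]] | None = None,
) -> list[SummaryAssociation]:
    """Read a tab-separated summary-statistic file (gzip allowed).

    Rows missing beta or se are dropped and counted in the log; a value that
    is present but not numeric raises with the offending line number.
    """
    path = Path(path)
    syn = dict(COLUMN_SYNONYMS)
    if synonyms:
        syn.update(synonyms)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(df.columns, syn)
    for canonical in _REQUIRED:
        if canonical not in cols:
            raise SumstatsError(
                f"{path}: required column {canonical!r} missing "
                f"(accepted names: {', '.join(syn[canonical])})"
            )

    numeric: dict[str, pd.Series] = {}
    for canonical in _NUMERIC:
        if canonical not in cols:
            continue
        raw = df[cols[canonical]]
        values = []
        for i, v in enumerate(raw):
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "NA":
                values.append(math.nan)
                continue
            try:
                values.append(float(v))  # exact round-trip parse
            except ValueError:
                raise SumstatsError(
                    f"{path}: unparseable {canonical} value {v!r} on line {i + 2}"
                ) from None
        numeric[canonical] = pd.Series(values, index=raw.index)

    droppable = numeric["beta"].isna() | numeric["se"].isna()
    n_dropped = int(droppable.sum())
    if n_dropped:
        log.info("%s: dropped %d row(s) missing beta or se", path, n_dropped)

    records: list[SummaryAssociation] = []
    for i in range(len(df)):
        if droppable.iloc[i]:
            continue

        def num(key, cast=float):
            v = numeric.get(key)
            if v is None or pd.isna(v.iloc[i]):
                return None
            return cast(v.iloc[i])

        pval = num("pval")
        log10p = num("log10_pval")
        if log10p is None:
            neg = num("neglog10_pval")
            if neg is not None:
                log10p = -neg
        if pval is None and log10p is not None:
            pval = max(10.0 ** log10p, _TINY_P)
        elif pval is not None and pval == 0.0:
            pval = _TINY_P
        records.append(
            SummaryAssociation(
                variant_id=str(df[cols["variant_id"]].iloc[i]),
                effect_allele=str(df[cols["effect_allele"]].iloc[i]).upper(),
                other_allele=str(df[cols["other_allele"]].iloc[i]).upper(),
                beta=num("beta"),
                se=num("se"),
                pval=pval,
                eaf=num("eaf"),
                n=num("n", int),
                n_cases=num("n_cases", int),
                stratum=stratum,
            )
        )
    return records


_WRITE_COLS = (
    "variant_id", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pval", "n", "n_cases",
)


def write_sumstats(records: Iterable[SummaryAssociation], path: str | Path) -> None:
    """Write records as a canonical tab-separated table (NA for missing)."""
    rows = [
        {c: getattr(r, c) for c in _WRITE_COLS}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(_WRITE_COLS))
    for c in ("n", "n_cases"):
        df[c] = df[c].astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_instruments(
    path: str | Path,
    correlation_path: str | Path | None = None,
    target_label: str | None = None,
    r2_prune_threshold: float = 0.01,
) -> InstrumentSet:
    """Read an instrument-definition TSV (exposure associations), optionally
    with a square correlation TSV whose header row/column are variant ids."""
    members = read_sumstats(path)
    corr = None
    if correlation_path is not None:
        cm = pd.read_csv(correlation_path, sep="\t", index_col=0, comment="#")
        order = [m.variant_id for m in members]
        missing = [v for v in order if v not in cm.index or v not in cm.columns]
        if missing:
            raise SumstatsError(
                f"{correlation_path}: variants missing from matrix: {missing}"
            )
        corr = cm.loc[order, order].to_numpy(dtype=float)
    if target_label is None:
        target_label = Path(path).stem
    return InstrumentSet(
        target_label=target_label,
        members=tuple(members),
        correlation=corr,
        r2_prune_threshold=r2_prune_threshold,
    )


def write_correlation(inst: InstrumentSet, path: str | Path) -> None:
    if inst.correlation is None:
        raise SumstatsError("instrument set has no correlation matrix")
    ids = inst.variant_ids()
    pd.DataFrame(inst.correlation, index=ids, columns=ids).to_csv(path, sep="\t")


_MANIFEST_COLS = (
    "phenotype_id", "label", "category", "trait_type", "n",
    "n_cases", "icd_code", "duplicate_of", "icd_based",
)


def read_manifest(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype-manifest TSV (columns as written by
    :func:`write_manifest`; missing optional values as NA)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("phenotype_id", "label", "category", "trait_type", "n"):
        if col not in df.columns:
            raise SumstatsError(f"{path}: required manifest column {col!r} missing")
    records = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) or v == "NA" else v

        records.append(
            PhenotypeRecord(
                phenotype_id=row["phenotype_id"],
                label=row["label"],
                category=row["category"],
                trait_type=row["trait_type"],
                n=int(float(row["n"])),
                n_cases=None if get("n_cases") is None else int(float(get("n_cases"))),
                icd_code=get("icd_code"),
                duplicate_of=get("duplicate_of"),
                icd_based=str(get("icd_based")).lower() in ("true", "1"),
            )
        )
    return records


def write_manifest(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _MANIFEST_COLS} for r in records],
        columns=list(_MANIFEST_COLS),
    )
    df["n_cases"] = df["n_cases"].astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonization


def _swap(rec: SummaryAssociation) -> SummaryAssociation:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _complement(rec: SummaryAssociation) -> SummaryAssociation:
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def harmonize(
    exposure: SummaryAssociation,
    outcome: SummaryAssociation,
    palindrome_eaf_window: float = 0.08,
) -> tuple[SummaryAssociation, SummaryAssociation]:
    """Express the outcome association for the exposure's effect allele.

    Allele-label swaps negate the outcome beta (and flip eaf); strand
    complements are resolved before the swap rule.  Palindromic variants
    (A/T, C/G) are aligned by allele frequency: both eafs must fall outside
    ``0.5 +/- palindrome_eaf_window`` and on the same side, otherwise the
    variant is dropped (`HarmonizationError` with a reason code).
    """
    if exposure.variant_id != outcome.variant_id:
        raise SumstatsError(
            f"variant mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    vid = exposure.variant_id

    if exposure.is_palindromic():
        if {outcome.effect_allele, outcome.other_allele} != {ea, oa}:
            raise HarmonizationError(
                vid, "allele_mismatch",
                f"{vid}: outcome alleles {outcome.effect_allele}/"
                f"{outcome.other_allele} irreconcilable with palindromic {ea}/{oa}",
            )
        out = outcome if outcome.effect_allele == ea else _swap(outcome)
        if exposure.eaf is None or out.eaf is None:
            raise HarmonizationError(
                vid, "palindromic_no_eaf",
                f"{vid}: palindromic variant without eaf on both sides",
            )
        w = palindrome_eaf_window
        d_exp, d_out = exposure.eaf - 0.5, out.eaf - 0.5
        if abs(d_exp) <= w or abs(d_out) <= w or d_exp * d_out < 0:
            raise HarmonizationError(
                vid, "palindromic_ambiguous",
                f"{vid}: palindromic variant with ambiguous eafs "
                f"({exposure.eaf}, {out.eaf}, window {w})",
            )
        return exposure, out

    if (outcome.effect_allele, outcome.other_allele) == (ea, oa):
        return exposure, outcome
    if (outcome.effect_allele, outcome.other_allele) == (oa, ea):
        return exposure, _swap(outcome)
    flipped = _complement(outcome)
    if (flipped.effect_allele, flipped.other_allele) == (ea, oa):
        return exposure, flipped
    if (flipped.effect_allele, flipped.other_allele) == (oa, ea):
        return exposure, _swap(flipped)
    raise HarmonizationError(
        vid, "allele_mismatch",
        f"{vid}: outcome alleles {outcome.effect_allele}/{outcome.other_allele} "
        f"irreconcilable with exposure {ea}/{oa} even after strand complement",
    )


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(instruments: InstrumentSet) -> InstrumentSet:
    """Greedy r^2 pruning in ascending exposure p-value order.

    A variant is kept iff its squared correlation with every already-kept
    variant is below the set's ``r2_prune_threshold``.  Ties in p are broken
    lexicographically on variant id; output preserves the kept (greedy) order.
    """
    if instruments.correlation is None:
        raise SumstatsError(
            "ld_prune requires a correlation matrix; to run without pruning, "
            "skip the call explicitly rather than passing correlation=None"
        )
    members = instruments.members
    pvals = [
        m.pval if m.pval is not None else m.pval_from_z() for m in members
    ]
    order = sorted(range(len(members)), key=lambda i: (pvals[i], members[i].variant_id))
    r2 = np.asarray(instruments.correlation) ** 2
    thr = instruments.r2_prune_threshold
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] < thr for j in kept):
            kept.append(i)
    return instruments.subset([members[i].variant_id for i in kept])


# ---------------------------------------------------------------------------
# SE recovery from printed beta/p pairs


def se_from_beta_p(
    beta: float, pval: float | None = None, *, log10_pval: float | None = None
) -> float:
    """Recover a standard error from a beta and its two-sided p-value.

    Returns ``|beta| / z`` with z the upper p/2 standard-normal quantile.
    ``log10_pval`` (log10 of p, a negative number) supports p-values below
    double underflow, as printed in published tables (p ~ 1e-324).
    """
    if beta == 0:
        raise SumstatsError("se_from_beta_p undefined for beta = 0")
    if log10_pval is not None:
        if log10_pval >= 0:
            raise SumstatsError("log10_pval must be negative (p < 1)")
        log_half_p = log10_pval * _LN10 - _LN2
        z = -float(special.ndtri_exp(log_half_p))
    else:
        if pval is None:
            raise SumstatsError("need pval or log10_pval")
        if not (0.0 < pval < 1.0):
            raise SumstatsError(f"pval must be in (0, 1), got {pval}")
        z = -float(special.ndtri_exp(math.log(pval / 2.0)))
    return abs(beta) / z
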