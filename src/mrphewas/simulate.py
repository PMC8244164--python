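"""Seeded generator of two-sample MR summary statistics and phenome fixtures.

The generator encodes the statistical model the estimators assume: fixed
(conditioned-on) instrument-exposure betas, outcome betas
``theta * beta_exp + alpha + eps`` with directional pleiotropy
``alpha ~ N(mu_a, sigma_a^2)`` and noise ``eps`` correlated within LD blocks,
sex-specific causal effects per stratum, and linear-probability betas for
binary traits at a stated case fraction (``theta_linear = logOR * k(1-k)``).

Standard errors are driven by GWAS sample size and allele frequency:
``se = 1/sqrt(2 p (1-p) n)`` for a standardised continuous trait and
``sqrt(k(1-k))`` times that for a binary trait fit by linear regression.

Default sample sizes mirror a UK-Biobank-scale phenome (about 360k
participants overall, 167k men, 194k women) with an external exposure GWAS
of 300k; the default instrument regimes are J = 1 (a single drug-target
variant), J = 6 correlated variants in one gene region, and J = 56
independent genome-wide variants for the exposure score.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .phewas import InMemoryStore, PhewasConfig
from .sumstats import InstrumentSet, PhenotypeRecord, SummaryAssociation

_STRATUM_KEY = {"both": 11, "men": 12, "women": 13}
_TYPE_KEY = {"continuous": 21, "binary": 22, "ordered": 23}
#: substream tags, kept distinct so panel and noise never collide
_PANEL_TAG = 1000001
_NOISE_TAG = 2000002


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters for one simulated trait.

    ``theta`` is the true causal effect of the exposure on the trait per
    stratum (for binary traits, interpreted as a log odds ratio and emitted
    on the linear-probability scale).  ``ld_blocks`` is a tuple of
    ``(block_size, within_block_rho)`` pairs summing to ``n_instruments``;
    ``None`` means independent instruments.
    """

    target_label: str = "HMGCR-statins"
    n_instruments: int = 56
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    theta: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.0, "men": 0.0, "women": 0.0}
    )
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_beta_scale: float = 0.06
    n_exposure: int = 300_000
    n_outcome: Mapping[str, int] = field(
        default_factory=lambda: {"both": 360_000, "men": 167_000, "women": 194_000}
    )
    case_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_instruments < 1:
            raise SimulationError("n_instruments must be >= 1")
        if self.ld_blocks is not None:
            sizes = [b[0] for b in self.ld_blocks]
            if sum(sizes) != self.n_instruments:
                raise SimulationError(
                    f"ld_blocks sizes {sizes} do not sum to J={self.n_instruments}"
                )
            if any(not (abs(b[1]) < 1.0) for b in self.ld_blocks):
                raise SimulationError("within-block correlation must satisfy |rho| < 1")
        if self.pleiotropy_sd < 0:
            raise SimulationError("pleiotropy_sd must be >= 0")
        if not (0.0 < self.case_fraction < 1.0):
            raise SimulationError("case_fraction must be in (0, 1)")
        for s, n in self.n_outcome.items():
            if self.case_fraction * n < 1 or self.case_fraction * n >= n:
                raise SimulationError(f"impossible case_fraction/n for stratum {s}")


@functools.lru_cache(maxsize=64)
def _block_correlation(
    ld_blocks: tuple[tuple[int, float], ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Block-diagonal correlation matrix and its Cholesky factor."""
    blocks = []
    for size, rho in ld_blocks:
        b = np.full((size, size), rho)
        np.fill_diagonal(b, 1.0)
        blocks.append(b)
    j = sum(size for size, _ in ld_blocks)
    r = np.zeros((j, j))
    at = 0
    for b in blocks:
        k = b.shape[0]
        r[at : at + k, at : at + k] = b
        at += k
    return r, np.linalg.cholesky(r)


@dataclass(frozen=True, slots=True)
class _Panel:
    """The conditioned-on instrument panel: fixed across replicates."""

    variant_ids: tuple[str, ...]
    eaf: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    correlation: np.ndarray | None
    chol: np.ndarray | None


def _panel_key(truth: SyntheticTruth) -> tuple:
    return (
        truth.seed,
        truth.n_instruments,
        truth.ld_blocks,
        truth.exposure_beta_scale,
        truth.n_exposure,
    )


@functools.lru_cache(maxsize=256)
def _build_panel(key: tuple) -> _Panel:
    seed, j, ld_blocks, scale, n_exposure = key
    rng = np.random.default_rng([seed, _PANEL_TAG])
    eaf = rng.uniform(0.1, 0.9, size=j)
    mag = rng.uniform(0.6, 1.4, size=j) * scale
    sign = rng.choice([-1.0, 1.0], size=j)
    beta_exp = sign * mag
    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_exposure)
    if ld_blocks is None:
        corr = chol = None
    else:
        corr, chol = _block_correlation(ld_blocks)
    ids = tuple(f"rs{100000 + i}" for i in range(j))
    return _Panel(ids, eaf, beta_exp, se_exp, corr, chol)


_TWO_PHI = None  # placeholder to keep module namespace tidy


def _p_from_z(z: np.ndarray) -> np.ndarray:
    from scipy import special

    p = 2.0 * special.ndtr(-np.abs(z))
    return np.maximum(p, 5e-324)


def instrument_panel(truth: SyntheticTruth) -> InstrumentSet:
    """The exposure-side instrument set implied by the truth (deterministic
    in ``truth.seed``)."""
    panel = _build_panel(_panel_key(truth))
    z = panel.beta_exp / panel.se_exp
    pvals = _p_from_z(z)
    members = tuple(
        SummaryAssociation(
            variant_id=panel.variant_ids[i],
            effect_allele="A",
            other_allele="G",
            beta=float(panel.beta_exp[i]),
            se=float(panel.se_exp[i]),
            pval=float(pvals[i]),
            eaf=float(panel.eaf[i]),
            n=truth.n_exposure,
        )
        for i in range(truth.n_instruments)
    )
    return InstrumentSet(
        target_label=truth.target_label,
        members=members,
        correlation=panel.correlation,
    )


def simulate_pair(
    truth: SyntheticTruth,
    trait_type: str = "continuous",
    stratum: str = "both",
    rng: np.random.Generator | None = None,
) -> tuple[InstrumentSet, list[SummaryAssociation]]:
    """Draw one (instrument set, outcome associations) pair.

    The instrument panel is fixed by ``truth.seed``; only the outcome noise,
    pleiotropy draws and LD-correlated errors come from ``rng`` (derived
    deterministically from the seed, trait type and stratum when not given).
    """
    if trait_type not in _TYPE_KEY:
        raise SimulationError(f"unknown trait_type {trait_type!r}")
    if stratum not in _STRATUM_KEY:
        raise SimulationError(f"unknown stratum {stratum!r}")
    if rng is None:
        rng = np.random.default_rng(
            [truth.seed, _NOISE_TAG, _STRATUM_KEY[stratum], _TYPE_KEY[trait_type]]
        )
    panel = _build_panel(_panel_key(truth))
    j = truth.n_instruments
    n_out = truth.n_outcome[stratum]
    theta = float(truth.theta.get(stratum, 0.0))
    k = truth.case_fraction

    se_out = 1.0 / np.sqrt(2.0 * panel.eaf * (1.0 - panel.eaf) * n_out)
    n_cases = None
    if trait_type == "binary":
        theta = theta * k * (1.0 - k)  # logOR -> linear-probability scale
        se_out = se_out * np.sqrt(k * (1.0 - k))
        n_cases = int(round(k * n_out))

    if truth.pleiotropy_mean != 0.0 or truth.pleiotropy_sd != 0.0:
        # directional with respect to the exposure-increasing allele: the
        # Egger intercept is defined after orienting exposure betas positive
        alpha = np.sign(panel.beta_exp) * rng.normal(
            truth.pleiotropy_mean, truth.pleiotropy_sd, size=j
        )
    else:
        alpha = np.zeros(j)
    z = rng.standard_normal(j)
    eps = (panel.chol @ z if panel.chol is not None else z) * se_out
    beta_out = theta * panel.beta_exp + alpha + eps
    pvals = _p_from_z(beta_out / se_out)

    outcomes = [
        SummaryAssociation(
            variant_id=panel.variant_ids[i],
            effect_allele="A",
            other_allele="G",
            beta=float(beta_out[i]),
            se=float(se_out[i]),
            pval=float(pvals[i]),
            eaf=float(panel.eaf[i]),
            n=n_out,
            n_cases=n_cases,
            stratum=stratum,
        )
        for i in range(j)
    ]
    return instrument_panel(truth), outcomes


# ---------------------------------------------------------------------------
# Phenome fixture

_CATEGORIES = (
    "Blood biochemistry",
    "Blood count",
    "Endocrine",
    "Circulatory",
    "Anthropometry",
    "Respiratory",
)
_NULL_TYPES = ("continuous", "binary", "ordered")

ANCHOR_ID = "ldl_c"
SEXDIFF_ID = "shbg_like"


@dataclass
class PhewasFixture:
    manifest: list[PhenotypeRecord]
    store: InMemoryStore
    truth_table: list[dict]  # non-null phenotypes with theta per stratum
    instruments: InstrumentSet
    config: PhewasConfig
    template: SyntheticTruth
    seed: int


def _engineered_drop_rows(n: int) -> list[PhenotypeRecord]:
    """Manifest rows that each trip exactly one exclusion rule."""
    return [
        PhenotypeRecord(
            "drop_duplicate", "duplicate of the anchor", "Blood biochemistry",
            "continuous", n, duplicate_of=ANCHOR_ID,
        ),
        PhenotypeRecord(
            "drop_min_cases", "rare binary outcome", "Circulatory",
            "binary", n, n_cases=99, icd_code="I99", icd_based=True,
        ),
        PhenotypeRecord(
            "drop_min_n", "small quantitative trait", "Anthropometry",
            "continuous", 9_999,
        ),
        PhenotypeRecord(
            "drop_no_main_icd", "ICD-coded without main code", "Circulatory",
            "binary", n, n_cases=500, icd_based=True,
        ),
        PhenotypeRecord(
            "drop_external_cause", "external-cause admission", "Circulatory",
            "binary", n, n_cases=500, icd_code="Z51", icd_based=True,
        ),
        PhenotypeRecord(
            "drop_subcategory", "family history item", "Family history",
            "binary", n, n_cases=5_000,
        ),
    ]


def simulate_phewas_fixture(
    n_phenotypes: int = 50,
    n_signals: int = 5,
    template: SyntheticTruth | None = None,
    seed: int = 0,
    include_sexdiff_signal: bool = True,
    global_null: bool = False,
    strata: Sequence[str] = ("both", "men", "women"),
) -> PhewasFixture:
    """Build a phenome-scan fixture with known ground truth.

    Emits a manifest spanning trait types and categories (plus engineered
    rows tripping each filter rule once), per-stratum summary statistics for
    every kept phenotype, an LDL-c anchor trait with theta = -1 in every
    stratum (the statin-mimic convention), and — unless disabled — one
    women-only signal (theta_women = -0.25, theta_men = 0) exercising the
    sex-difference test.  True signals have |theta| >= 0.5 on the
    anchor-scaled scale; everything else is null.

    ``seed`` drives per-phenotype noise substreams; the instrument panel is
    fixed by ``template.seed``, so replicate fixtures share instruments.
    """
    template = template or SyntheticTruth()
    if n_signals > n_phenotypes - 1:
        raise SimulationError("need n_signals <= n_phenotypes - 1 (anchor included)")
    n_both = template.n_outcome["both"]
    k = template.case_fraction

    # --- phenotype plan: (id, label, category, trait_type, theta-by-stratum)
    plan: list[tuple[str, str, str, str, dict[str, float]]] = []
    anchor_theta = 0.0 if global_null else -1.0
    plan.append(
        (
            ANCHOR_ID, "LDL cholesterol (SD)", "Blood biochemistry", "continuous",
            {s: anchor_theta for s in ("both", "men", "women")},
        )
    )
    if n_signals > 0 and not global_null:
        mags = np.linspace(0.5, 1.0, n_signals)
        for i in range(n_signals):
            theta = float(mags[i]) * (-1.0 if i % 2 == 0 else 1.0)
            plan.append(
                (
                    f"signal_{i:03d}", f"true signal {i}",
                    _CATEGORIES[(i + 1) % len(_CATEGORIES)], "continuous",
                    {s: theta for s in ("both", "men", "women")},
                )
            )
    use_sexdiff = include_sexdiff_signal and not global_null
    if use_sexdiff:
        plan.append(
            (
                SEXDIFF_ID, "women-only serum trait", "Endocrine", "continuous",
                {"both": -0.125, "men": 0.0, "women": -0.25},
            )
        )
    i_null = 0
    while len(plan) < n_phenotypes:
        ttype = _NULL_TYPES[i_null % len(_NULL_TYPES)]
        plan.append(
            (
                f"null_{i_null:03d}", f"null trait {i_null}",
                _CATEGORIES[i_null % len(_CATEGORIES)], ttype,
                {s: 0.0 for s in ("both", "men", "women")},
            )
        )
        i_null += 1

    manifest: list[PhenotypeRecord] = []
    store = InMemoryStore()
    truth_rows: list[dict] = []
    for idx, (pid, label, category, ttype, theta) in enumerate(plan):
        n_cases = int(round(k * n_both)) if ttype == "binary" else None
        icd = f"I{10 + idx % 80:02d}" if ttype == "binary" else None
        manifest.append(
            PhenotypeRecord(
                pid, label, category, ttype, n_both,
                n_cases=n_cases, icd_code=icd, icd_based=ttype == "binary",
            )
        )
        truth = replace(template, theta=theta)
        for stratum in strata:
            rng = np.random.default_rng(
                [seed, _NOISE_TAG, idx, _STRATUM_KEY[stratum]]
            )
            _, outcomes = simulate_pair(truth, ttype, stratum, rng=rng)
            store[(pid, stratum)] = outcomes
        if any(v != 0.0 for v in theta.values()):
            truth_rows.append(
                {
                    "phenotype_id": pid,
                    "theta_both": theta["both"],
                    "theta_men": theta["men"],
                    "theta_women": theta["women"],
                }
            )
    manifest.extend(_engineered_drop_rows(n_both))

    config = PhewasConfig(
        excluded_subcategories=("Family history",),
        strata=tuple(strata),
        anchor_phenotype_id=ANCHOR_ID,
    )
    return PhewasFixture(
        manifest=manifest,
        store=store,
        truth_table=truth_rows,
        instruments=instrument_panel(template),
        config=config,
        template=template,
        seed=seed,
    )
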