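"""Result serialization and publication-style comparison tables.

All tables are tab-separated, UTF-8, period decimals, ``NA`` for missing.
P-values are printed in scientific notation with 3 significant digits; the
full-precision tail mass is preserved in the ``neglog10_p`` column (relevant
once p underflows a double).  Every table carries a header comment naming the
run hash so outputs are traceable to a configuration and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .phewas import Exclusion, PhewasResultRow, PhewasSummary, manhattan_table


@dataclass
class RunManifest:
    """Provenance of one pipeline run.

    The config hash covers configuration, seeds and input digests — not
    timestamps — so identical inputs give identical hashes and identical
    output bytes.
    """

    config: Mapping = field(default_factory=dict)
    seed: int | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    started: str | None = None
    finished: str | None = None
    ledger_counts: dict[str, int] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "config": dict(self.config),
                "seed": self.seed,
                "inputs": self.input_digests,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def header_line(self) -> str:
        return f"# mrphewas/{__version__} run={self.config_hash[:16]}"

    @staticmethod
    def digest_file(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()


_P_COLS = ("pval", "egger_intercept_p", "sexdiff_p")

RESULT_COLUMNS = (
    "target", "phenotype_id", "category", "trait_type", "stratum",
    "method", "n_snps", "beta", "se", "ci_low", "ci_high", "pval",
    "neglog10_p", "phi", "q", "egger_intercept", "egger_intercept_p",
    "or", "or_ci_low", "or_ci_high", "scaled_beta", "significant",
    "sexdiff_z", "sexdiff_p",
)


def results_to_frame(rows: Sequence[PhewasResultRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        e = r.estimate
        out.append(
            {
                "target": r.target,
                "phenotype_id": r.phenotype_id,
                "category": r.category,
                "trait_type": r.trait_type,
                "stratum": r.stratum,
                "method": e.method,
                "n_snps": e.n_snps,
                "beta": e.beta_hat,
                "se": e.se_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "neglog10_p": r.neglog10_p,
                "phi": e.dispersion_phi,
                "q": e.heterogeneity_q,
                "egger_intercept": e.egger_intercept,
                "egger_intercept_p": e.egger_intercept_p,
                "or": None if r.or_result is None else r.or_result.odds_ratio,
                "or_ci_low": None if r.or_result is None else r.or_result.ci_low,
                "or_ci_high": None if r.or_result is None else r.or_result.ci_high,
                "scaled_beta": r.scaled_beta,
                "significant": r.significant,
                "sexdiff_z": r.sexdiff_z,
                "sexdiff_p": r.sexdiff_p,
            }
        )
    return pd.DataFrame(out, columns=list(RESULT_COLUMNS))


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    run: RunManifest | None = None,
) -> None:
    """Write a TSV with the run-hash header comment and the fixed dialect."""
    df = df.copy()
    for col in df.columns:
        if col in _P_COLS:
            df[col] = df[col].map(
                lambda v: None if pd.isna(v) else f"{v:.2e}"
            )
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if run is not None:
            fh.write(run.header_line() + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def exclusions_to_frame(exclusions: Sequence[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(e) for e in exclusions],
        columns=["phenotype_id", "reason", "detail"],
    )


def category_counts_to_frame(summary: PhewasSummary) -> pd.DataFrame:
    rows = [
        {"target": t, "category": c, "significant_phenotypes": n}
        for (t, c), n in sorted(summary.category_counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["target", "category", "significant_phenotypes"]
    )


def manhattan_to_frame(rows: Sequence[PhewasResultRow]) -> pd.DataFrame:
    return pd.DataFrame(
        manhattan_table(rows),
        columns=[
            "target", "category", "phenotype_id", "stratum",
            "neglog10_p", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# Wide comparison table (per-target per-stratum scaled effects + sexdiff p)


def build_table1_analogue(rows: Sequence[PhewasResultRow]) -> pd.DataFrame:
    """Wide comparison table across >= 2 targets.

    One row per phenotype; per target and stratum the anchor-scaled beta and
    p-value, plus the men-vs-women z-test p per target.  A phenotype missing
    for some target leaves blank (NA) cells.
    """
    long = results_to_frame(rows)
    return build_table1_from_frame(long)


def build_table1_from_frame(long: pd.DataFrame) -> pd.DataFrame:
    import logging

    phenos = list(dict.fromkeys(long["phenotype_id"]))
    targets = list(dict.fromkeys(long["target"]))
    strata = list(dict.fromkeys(long["stratum"]))
    indexed = long.set_index(["target", "phenotype_id", "stratum"]).sort_index()
    out_rows = []
    for pid in phenos:
        row: dict = {"phenotype_id": pid}
        for t in targets:
            sexdiff = None
            for s in strata:
                try:
                    cell = indexed.loc[(t, pid, s)]
                except KeyError:
                    logging.getLogger(__name__).warning(
                        "phenotype %s missing for target %s stratum %s", pid, t, s
                    )
                    row[f"{t}|{s}|scaled_beta"] = None
                    row[f"{t}|{s}|pval"] = None
                    continue
                if isinstance(cell, pd.DataFrame):
                    cell = cell.iloc[0]
                row[f"{t}|{s}|scaled_beta"] = cell["scaled_beta"]
                row[f"{t}|{s}|pval"] = cell["pval"]
                if cell.get("sexdiff_p") is not None and not pd.isna(
                    cell.get("sexdiff_p")
                ):
                    sexdiff = cell["sexdiff_p"]
            row[f"{t}|sexdiff_p"] = sexdiff
        out_rows.append(row)
    return pd.DataFrame(out_rows)
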