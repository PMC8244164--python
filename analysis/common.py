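"""Shared design of the analysis runs: instrument regimes and fixture seeds.

The three regimes mirror the three ways a lipid-lowering target is proxied:
one lead variant, a handful of correlated variants in the target gene
region, and a genome-wide independent score for the exposure itself.  The
phenome plan (which phenotypes carry which true effects) is identical across
regimes; only the instrument panel differs.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mrphewas import SyntheticTruth, simulate_phewas_fixture  # noqa: E402

SEED = 20240917

REGIMES = {
    "lead_snp": dict(target_label="HMGCR-rs12916-style", n_instruments=1,
                     ld_blocks=None, seed=101),
    "region6": dict(target_label="HMGCR-region-proxies", n_instruments=6,
                    ld_blocks=((6, 0.5),), seed=102),
    "score56": dict(target_label="LDL-c-score", n_instruments=56,
                    ld_blocks=None, seed=103),
}

N_PHENOTYPES = 50
N_SIGNALS = 5


def template(regime: str) -> SyntheticTruth:
    return SyntheticTruth(**REGIMES[regime])


def build_fixture(regime: str):
    return simulate_phewas_fixture(
        n_phenotypes=N_PHENOTYPES,
        n_signals=N_SIGNALS,
        template=template(regime),
        seed=SEED,
    )
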