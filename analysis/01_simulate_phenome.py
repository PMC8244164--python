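"""Generate the synthetic phenome used by the downstream analyses.

Builds a 50-phenotype, three-stratum phenome with known ground truth under
three instrument regimes — a single drug-target variant (J=1), six correlated
variants in one gene region (J=6, within-block rho 0.5), and 56 independent
exposure-score variants — plus engineered manifest rows that each trip one
exclusion rule.  The full per-phenotype summary-statistic files go to
scratch/fixture_<regime>/ (bulky, regenerable); the small manifest, truth
table and instrument definitions are copied under results/.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from mrphewas import write_manifest, write_sumstats  # noqa: E402
from mrphewas.sumstats import write_correlation  # noqa: E402

sys.path.insert(0, str(ROOT / "analysis"))
from common import REGIMES, SEED, build_fixture  # noqa: E402


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in REGIMES:
        fx = build_fixture(name)
        out = ROOT / "scratch" / f"fixture_{name}"
        (out / "sumstats").mkdir(parents=True, exist_ok=True)
        write_manifest(fx.manifest, out / "manifest.tsv")
        write_sumstats(fx.instruments.members, out / "instruments.tsv")
        if fx.instruments.correlation is not None:
            write_correlation(fx.instruments, out / "correlation.tsv")
        for (pid, stratum), records in sorted(fx.store.items()):
            write_sumstats(records, out / "sumstats" / f"{pid}.{stratum}.tsv")
        print(
            f"[{name}] J={len(fx.instruments)}: {len(fx.manifest)} manifest rows "
            f"({len(fx.truth_table)} non-null), {len(fx.store)} sumstat files "
            f"-> {out}"
        )

    # small, human-readable copies of the shared design
    fx = build_fixture("score56")
    write_manifest(fx.manifest, results / "phenome_manifest.tsv")
    pd.DataFrame(
        fx.truth_table,
        columns=["phenotype_id", "theta_both", "theta_men", "theta_women"],
    ).to_csv(results / "phenome_truth.tsv", sep="\t", index=False)
    print(f"seed {SEED}; manifest and truth table copied to {results}")


if __name__ == "__main__":
    main()
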