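#!/usr/bin/env python
"""Reproduce the summary-statistic MR results from the printed per-SNP table.

Loads the packaged 7-SNP instrument table (exposure betas for log2-CRP and
per-allele hazard differences for overall and CRC-specific mortality),
recovers the outcome standard errors from the printed p-values, and runs all
five estimators for the main analysis and the sensitivity analysis that
drops the lipid-associated APOE variant rs429358.

Writes results/mr_summary_statistics.tsv and a scatter of per-SNP effects
with the fitted IVW and Egger lines under results/figures/.
"""

from pathlib import Path

import pandas as pd

from crpmr import mr
from crpmr.datamodel import load_table1_fixture
from crpmr.pipeline import plot_instruments

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_table1_fixture()
    rows = mr.mr_summary(table, outcomes=("overall", "cause_specific"),
                         exclusions=[(), ("rs429358",)], n_boot=10_000, seed=1)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "mr_summary_statistics.tsv", sep="\t", index=False)

    print("Hazard difference per 1,000 person-years per doubling of CRP")
    for _, r in df.iterrows():
        print(f"  {r['analysis']:>20} {r['outcome']:>14} {r['method']:>16}: "
              f"{r['estimate']:6.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f}) "
              f"p={r['p']:.3f}")

    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    for outcome in ("overall", "cause_specific"):
        plot_instruments(table, outcome, figdir / f"scatter_{outcome}.png")

    ivw_main = df.query("analysis=='main' and outcome=='overall' and method=='IVW'")
    print(f"\nHeadline: genetically predicted CRP shows no association with "
          f"overall mortality (IVW {ivw_main['estimate'].iloc[0]:.2f} per "
          f"1,000 PY per doubling; CI crosses zero).")


if __name__ == "__main__":
    main()
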