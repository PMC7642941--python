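#!/usr/bin/env python
"""Benjamini-Hochberg correction and the three-criteria decision rule.

Per trait, the null p-values (proportion of h2 and LR, t-method by default)
and the paired predictive-ability p-value are BH-adjusted across pathways at
a 10% FDR; a pair is flagged when all three adjusted p-values pass. Writes
results/report/ (master, flagged-only and diagnostics tables).
"""

import pandas as pd

from common import CONFIG, RESULTS

from pathpartblup import write_report  # noqa: E402
from pathpartblup.pipeline import stage_decision_report  # noqa: E402


def main() -> int:
    pvals = pd.read_csv(RESULTS / "null_pvalues.tsv", sep="\t")
    cv = pd.read_csv(RESULTS / "cv_summary.tsv", sep="\t")
    diag = pd.read_csv(RESULTS / "kinship_diagnostics.tsv", sep="\t")
    verdicts = stage_decision_report(pvals, cv, CONFIG)
    paths = write_report(verdicts, RESULTS / "report", diagnostics=diag)
    cols = ["trait", "pathway", "observed_proportion", "p_proportion_adj",
            "p_lr_adj", "p_predictive_adj", "delta_r", "verdict"]
    print(verdicts[cols].round(4).to_string(index=False))
    flagged = verdicts.loc[verdicts["flagged"]]
    print(f"\n{len(flagged)} trait-pathway pair(s) flagged "
          f"(all three BH-adjusted p <= {CONFIG.fdr}) -> {paths['flagged']}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
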