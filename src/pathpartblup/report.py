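"""FDR correction and the three-criteria pathway decision rule.

A trait-pathway pair is flagged as a pathway of interest when, after
Benjamini-Hochberg adjustment across the trait's pathways at a 10% FDR, all
three criteria pass: (1) proportion of genomic heritability larger than the
random-gene-group null, (2) likelihood-ratio model-fit gain larger than the
null, (3) MultiBLUP predictive ability greater than GBLUP. Pairs whose
MultiBLUP gain in predictive ability exceeds 5% get an extra annotation tier.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


class ReportError(ValueError):
    """Raised for malformed decision inputs."""


P_COLUMNS = ["p_proportion", "p_lr", "p_predictive"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with NaN passthrough."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        vals = p[ok]
        if np.any((vals < 0) | (vals > 1)):
            raise ReportError("p-values must lie in [0, 1]")
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def flag_pathways(results: pd.DataFrame, fdr: float = 0.10,
                  delta_r_tier: float = 0.05) -> pd.DataFrame:
    """Apply BH per trait across pathways and the three-criteria rule.

    ``results`` needs one row per trait-pathway with columns ``trait``,
    ``pathway`` and raw p-values ``p_proportion``, ``p_lr``, ``p_predictive``
    (plus any metric columns, carried through). Adds ``<p>_adj`` columns, a
    per-criterion pass column, ``flagged`` (all three adjusted p <= fdr),
    ``verdict`` ("flagged" / "not_flagged" / "incomplete") and
    ``high_delta_r`` marking pairs with delta_r > ``delta_r_tier``.
    """
    missing = [c for c in ["trait", "pathway", *P_COLUMNS] if c not in results.columns]
    if missing:
        raise ReportError(f"results table lacks columns {missing}")
    out = results.copy()
    for col in P_COLUMNS:
        out[f"{col}_adj"] = np.nan
    for _, idx in out.groupby("trait").groups.items():
        for col in P_COLUMNS:
            out.loc[idx, f"{col}_adj"] = bh_adjust(out.loc[idx, col].to_numpy())
    for col in P_COLUMNS:
        out[f"{col}_pass"] = out[f"{col}_adj"] <= fdr
    complete = out[[f"{c}_adj" for c in P_COLUMNS]].notna().all(axis=1)
    out["flagged"] = complete & out[[f"{c}_pass" for c in P_COLUMNS]].all(axis=1)
    out["verdict"] = np.where(
        ~complete, "incomplete", np.where(out["flagged"], "flagged", "not_flagged")
    )
    if "delta_r" in out.columns:
        out["high_delta_r"] = out["delta_r"] > delta_r_tier
    return out


def write_report(
    verdicts: pd.DataFrame,
    outdir: str | Path,
    diagnostics: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write the master, flagged-only and diagnostics tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    master = outdir / "results_master.tsv"
    verdicts.to_csv(master, sep="\t", index=False)
    paths["master"] = str(master)
    flagged = outdir / "results_flagged.tsv"
    sel = (
        verdicts.loc[verdicts["flagged"]]
        if "flagged" in verdicts.columns
        else verdicts.iloc[0:0]
    )
    sel.to_csv(flagged, sep="\t", index=False)
    paths["flagged"] = str(flagged)
    if diagnostics is not None:
        diag = outdir / "diagnostics.tsv"
        diagnostics.to_csv(diag, sep="\t", index=False)
        paths["diagnostics"] = str(diag)
    return paths
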