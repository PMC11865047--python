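"""Decoy-referenced confidence filtering of per-protein p-values.

Mass-spectrometry protein identifications arrive as per-sample p-values
(the chance that the peptide spectrum matches arise at random) together
with decoy entries drawn from the null.  A target protein is kept when its
log p-value is at least ``factor``-fold lower (more negative) than the log
p-value of the sample's best-scoring decoy.  The multiplicative reading of
"factor-fold lower log p" is the default because it is invariant to the
base of the logarithm; an additive variant (subtract ``factor`` log10
units) is exposed as a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mucinsig")

COLUMNS = ("protein_id", "p_value", "decoy", "sample_id")


@dataclass
class ProteinTable:
    """Rows: protein id, p-value in (0, 1], decoy flag, sample id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"protein table missing columns {missing}")
        p = self.table["p_value"]
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in (0, 1]; "
                             "p = 0 rows are malformed")
        decoys = self.table.groupby("sample_id")["decoy"].sum()
        if (decoys < 1).any():
            bad = decoys.index[decoys < 1].tolist()
            raise ValueError(f"samples without decoy rows: {bad}")

    @classmethod
    def read_tsv(cls, path) -> "ProteinTable":
        t = pd.read_csv(path, sep="\t")
        t["decoy"] = t["decoy"].astype(bool)
        return cls(t)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def decoy_confidence_filter(table: ProteinTable, factor: float = 2.0,
                            mode: str = "multiplicative") -> dict:
    """Per-sample confident target set referenced to the top decoy.

    With the default multiplicative rule a target is kept iff
    log10(p_target) <= factor * log10(p_top_decoy), i.e. its |log10 p| is at
    least ``factor``-fold larger than the best decoy's; equality at the
    threshold keeps the protein.  ``mode='additive'`` keeps targets with
    log10(p) <= log10(p_top_decoy) - factor.  Returns per-sample kept
    protein ids and the computed p-value threshold.
    """
    if factor <= 1 and mode == "multiplicative":
        raise ValueError("multiplicative factor must exceed 1")
    out: dict[str, dict] = {}
    for sample, sub in table.table.groupby("sample_id"):
        decoys = sub[sub["decoy"]]
        targets = sub[~sub["decoy"]]
        top_decoy_p = float(decoys["p_value"].min())
        log_top = np.log10(top_decoy_p)
        if mode == "multiplicative":
            log_threshold = factor * log_top
        elif mode == "additive":
            log_threshold = log_top - factor
        else:
            raise ValueError("mode must be 'multiplicative' or 'additive'")
        keep = np.log10(targets["p_value"].to_numpy()) <= log_threshold
        kept = targets.loc[keep, "protein_id"].tolist()
        out[sample] = {"kept": kept,
                       "n_kept": len(kept),
                       "top_decoy_p": top_decoy_p,
                       "p_threshold": float(10.0 ** log_threshold)}
        logger.info("sample %s: %d/%d targets confident "
                    "(top decoy p=%.3g, threshold p=%.3g)",
                    sample, len(kept), len(targets),
                    top_decoy_p, 10.0 ** log_threshold)
    return out
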