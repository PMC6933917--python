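"""Which strains drive which co-expression modules.

Per module, a one-way ANOVA of the eigengene across strains (BH-adjusted
across modules), followed by Tukey HSD contrasts of each mutant strain
against the control for ANOVA-significant modules. A strain is a "driver"
of a module when both tests pass at the chosen alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SampleMetadata
from .stats import adjust_bh, one_way_anova, tukey_hsd

log = logging.getLogger(__name__)


@dataclass
class DriverTable:
    """Module-level ANOVA results and per-(module, strain) Tukey contrasts."""

    module_table: pd.DataFrame   # module, F, p, padj
    contrast_table: pd.DataFrame  # module, strain, diff, tukey_p, driver

    def drivers(self) -> dict[str, list[str]]:
        """Module -> list of driver strains (possibly empty)."""
        out: dict[str, list[str]] = {m: [] for m in self.module_table["module"]}
        hit = self.contrast_table[self.contrast_table["driver"]]
        for m, s in zip(hit["module"], hit["strain"]):
            out[m].append(s)
        return out


def associate_strains(
    eigengenes: pd.DataFrame,
    meta: SampleMetadata,
    alpha: float = 0.05,
    all_pairs: bool = False,
    tukey_bh: bool = False,
) -> DriverTable:
    """Eigengene-vs-strain association scan.

    ``eigengenes`` is module x sample. Strains with a single sample are
    excluded from the Tukey stage with a warning (the ANOVA keeps them).
    With ``all_pairs=True`` every strain pair is reported, not only the
    contrasts against the control. ``tukey_bh=True`` additionally applies
    BH across all reported Tukey contrasts before the driver call (the
    stricter reading of "reported p-values were BH-adjusted").
    """
    samples = eigengenes.columns.tolist()
    missing = [s for s in samples if s not in meta.table.index]
    if missing:
        raise ValueError(f"eigengene samples missing from metadata: {missing}")
    strains = meta.table.loc[samples, "strain"].to_numpy()
    if len(np.unique(strains)) < 2:
        raise ValueError("need >= 2 strains including the control")
    if meta.control not in strains:
        raise ValueError(f"control strain {meta.control!r} absent from samples")

    counts = pd.Series(strains).value_counts()
    tukey_ok = set(counts.index[counts >= 2])
    dropped = sorted(set(counts.index) - tukey_ok)
    if dropped:
        log.warning("strains excluded from Tukey (single sample): %s", dropped)

    anova_rows = []
    for module in eigengenes.index:
        res = one_way_anova(eigengenes.loc[module].to_numpy(), strains)
        anova_rows.append({"module": module, "F": res.statistic, "p": res.p})
    module_table = pd.DataFrame(anova_rows)
    module_table["padj"] = adjust_bh(module_table["p"].to_numpy())

    contrast_rows = []
    mask = np.isin(strains, list(tukey_ok))
    for _, row in module_table.iterrows():
        module = row["module"]
        if not row["padj"] < alpha:
            continue
        values = eigengenes.loc[module].to_numpy()[mask]
        pairs = tukey_hsd(values, strains[mask])
        for pr in pairs:
            if not all_pairs and meta.control not in (pr.group1, pr.group2):
                continue
            strain = pr.group2 if pr.group1 == meta.control else pr.group1
            other = pr.group1 if pr.group1 != strain else pr.group2
            diff = pr.diff if pr.group1 == strain else -pr.diff
            contrast_rows.append(
                {"module": module, "strain": strain, "versus": other,
                 "diff": diff, "tukey_p": pr.p,
                 "driver": bool(pr.p < alpha and other == meta.control)}
            )
    contrast_table = pd.DataFrame(
        contrast_rows,
        columns=["module", "strain", "versus", "diff", "tukey_p", "driver"],
    )
    contrast_table["driver"] = contrast_table["driver"].astype(bool)
    if tukey_bh and len(contrast_table):
        adj = adjust_bh(contrast_table["tukey_p"].to_numpy())
        contrast_table["tukey_padj"] = adj
        contrast_table["driver"] = contrast_table["driver"] & (adj < alpha)
    return DriverTable(module_table, contrast_table)
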