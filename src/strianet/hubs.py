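"""Hub-gene identification and conservation in the least preserved module.

A hub is a module gene whose expression has absolute Pearson correlation
with the module eigengene (its kME) at or above a threshold, 0.9 by
default.  Hubs are identified separately per condition, with the case-side
eigengene recomputed on case data for the mapped module so that hub loss
reflects case connectivity rather than a projection of the control
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DegSets
from .network import module_eigengene

__all__ = ["identify_hubs", "hub_conservation", "hub_deg_overlap", "HubReport"]


def identify_hubs(
    expr: pd.DataFrame,
    module_genes,
    threshold: float = 0.9,
    me: np.ndarray | None = None,
) -> set[str]:
    """Module genes with |cor(expression, module eigengene)| >= threshold.

    The eigengene is computed from ``expr`` restricted to the module
    unless supplied.  Constant genes are excluded.
    """
    module_genes = pd.Index(module_genes)
    if len(module_genes) == 0:
        raise ValueError("module must contain at least one gene")
    sub = expr.loc[module_genes]
    if me is None:
        me, _ = module_eigengene(expr, module_genes)
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    mu = x.mean(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd == 0, 1.0, sd)[:, None]
    mz = (me - me.mean()) / (me.std() or 1.0)
    k = (z @ mz) / x.shape[1]
    is_hub = (np.abs(k) >= threshold) & (sd > 0)
    return set(module_genes[is_hub])


def hub_conservation(
    hubs_control: set[str], hubs_case: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(exclusive_control, shared, exclusive_case) hub partition."""
    shared = hubs_control & hubs_case
    return hubs_control - shared, shared, hubs_case - shared


@dataclass
class HubReport:
    module: int
    hubs_control: set[str]
    hubs_case: set[str]
    exclusive_control: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)
    exclusive_case: set[str] = field(default_factory=set)

    @classmethod
    def build(cls, module: int, hubs_control: set[str], hubs_case: set[str]):
        excl_c, shared, excl_o = hub_conservation(hubs_control, hubs_case)
        return cls(
            module=module,
            hubs_control=hubs_control,
            hubs_case=hubs_case,
            exclusive_control=excl_c,
            shared=shared,
            exclusive_case=excl_o,
        )

    def counts(self) -> dict[str, int]:
        return {
            "exclusive_control": len(self.exclusive_control),
            "shared": len(self.shared),
            "exclusive_case": len(self.exclusive_case),
        }


def hub_deg_overlap(
    report: HubReport, module_genes, degs: DegSets
) -> pd.DataFrame:
    """Module genes in the relaxed DEG set, annotated with per-condition
    hub status."""
    module_genes = pd.Index(module_genes)
    overlap = sorted(set(module_genes) & degs.relaxed)
    rows = [
        {
            "gene": g,
            "hub_in_control": g in report.hubs_control,
            "hub_in_case": g in report.hubs_case,
        }
        for g in overlap
    ]
    return pd.DataFrame(rows, columns=["gene", "hub_in_control", "hub_in_case"])
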