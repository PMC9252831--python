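"""Data behind the two standard visualisations, plus minimal rendering.

The tested artifact is the plot *data*: an enrichment-plot table (one dot
per regulator) and cumulative-distribution (CD) groups.  CD plots are the
field's standard read-out of miRNA activity: the signal distribution of a
regulator's targets, split by best site type (or score, or simple
target/non-target membership), shifts left of the "no site" curve when the
regulator is active, ideally with a dose-response ordering across site
types.  Rendering to an axes object is a thin optional layer on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .targets import CANONICAL_SITE_TYPES, TargetCollection

log = logging.getLogger(__name__)

__all__ = ["CDGroup", "enrichment_plot_data", "cd_plot_data", "plot_cd", "plot_enrichment"]

NO_SITE = "no site"


@dataclass
class CDGroup:
    """One empirical CDF: unique sorted values and cumulative fractions."""

    label: str
    values: np.ndarray  # unique, ascending
    ecdf_y: np.ndarray  # strictly increasing, ends at exactly 1
    n: int  # group size (members, including ties)

    @property
    def median(self) -> float:
        """Group median read off the ECDF (lower median for even sizes)."""
        return float(self.values[np.searchsorted(self.ecdf_y, 0.5)])

    @classmethod
    def from_values(cls, label: str, values: np.ndarray) -> "CDGroup":
        v = np.sort(np.asarray(values, dtype=float))
        uniq, counts = np.unique(v, return_counts=True)
        y = np.cumsum(counts) / len(v)
        y[-1] = 1.0
        return cls(label=label, values=uniq, ecdf_y=y, n=len(v))


def enrichment_plot_data(
    results: pd.DataFrame,
    expr: Mapping[str, float] | None = None,
    sig_alpha: float = 0.05,
    family_members: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """One row per regulator: x = signed enrichment, y = -log10(p), dot size
    = number of significantly downregulated targets, colour = expression of
    the regulator's top-expressed member (NA without an expression table).

    ``family_members`` maps a family-level regulator id to its member
    miRNAs so the top-expressed member can be looked up; a regulator id
    present directly in ``expr`` is used as its own member.
    """
    out = pd.DataFrame(
        {
            "regulator": results["regulator"],
            "enrichment": results["enrichment"],
            "neg_log10_p": -np.log10(results["pvalue"]),
            "size": results["n_selected_targets"],
            "significant": results["fdr"] < sig_alpha,
        }
    )
    colour = np.full(len(out), np.nan)
    if expr is not None:
        for i, reg in enumerate(out["regulator"]):
            members = [reg]
            if family_members and reg in family_members:
                members = list(family_members[reg]) + [reg]
            vals = [expr[m] for m in members if m in expr]
            if vals:
                colour[i] = max(vals)
    out["colour"] = colour
    return out


def cd_plot_data(
    signal: pd.Series,
    tc: TargetCollection,
    regulator: str,
    split: str = "sitetype",
    score_quantile: float = 0.5,
) -> list[CDGroup]:
    """CD groups for one regulator, partitioning the whole universe.

    split="sitetype": targets grouped by best canonical site type (8mer,
    7mer-m8, 7mer-A1); features without a canonical 7/8mer site — including
    non-targets — form the "no site" group.
    split="score": targets split at the ``score_quantile`` of repression
    magnitude into "high score" / "low score", plus "no site".
    split="target": simply targets vs non-targets.
    Empty groups are omitted (logged).  Groups always partition the
    universe (the signal's feature index).
    """
    if split not in ("sitetype", "score", "target"):
        raise ValueError("split must be 'sitetype', 'score' or 'target'")
    if regulator not in set(tc.regulator_index):
        raise ValueError(f"unknown regulator '{regulator}'")
    universe = signal.index
    rec = tc.records
    rec = rec[(rec["regulator"] == regulator) & rec["feature"].isin(universe)]
    rec = rec.set_index("feature")
    groups: dict[str, pd.Index] = {}
    if split == "target":
        tgt = universe.intersection(rec.index)
        groups["targets"] = tgt
        groups["non-targets"] = universe.difference(tgt)
    elif split == "sitetype":
        if rec["site_type"].isna().all() and len(rec):
            raise ValueError("collection has no site_type annotation")
        assigned = pd.Index([])
        for st in CANONICAL_SITE_TYPES:
            members = rec.index[rec["site_type"] == st]
            groups[st] = members
            assigned = assigned.union(members)
        groups[NO_SITE] = universe.difference(assigned)
    else:
        if rec["score"].isna().all() and len(rec):
            raise ValueError("collection has no scores")
        mag = -rec["score"].dropna()
        thr = mag.quantile(score_quantile) if len(mag) else np.nan
        hi = mag.index[mag >= thr] if len(mag) else pd.Index([])
        lo = mag.index[mag < thr] if len(mag) else pd.Index([])
        groups["high score"] = pd.Index(hi)
        groups["low score"] = pd.Index(lo)
        groups[NO_SITE] = universe.difference(pd.Index(hi).union(lo))
    out = []
    for label, members in groups.items():
        if len(members) == 0:
            log.info("cd_plot_data: omitting empty group '%s'", label)
            continue
        out.append(CDGroup.from_values(label, signal.loc[members].to_numpy()))
    return out


def cd_groups_to_frame(groups: Sequence[CDGroup]) -> pd.DataFrame:
    """Long-format CD data for CSV export."""
    return pd.concat(
        [
            pd.DataFrame({"group": g.label, "value": g.values, "ecdf": g.ecdf_y, "n": g.n})
            for g in groups
        ],
        ignore_index=True,
    )


# -- optional rendering ------------------------------------------------------


def plot_cd(groups: Sequence[CDGroup], ax=None, xlabel: str = "signal"):
    """Step-plot the CD groups (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in groups:
        ax.step(g.values, g.ecdf_y, where="post", label=f"{g.label} (n={g.n})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    return ax


def plot_enrichment(data: pd.DataFrame, ax=None, sig_alpha: float = 0.05):
    """Scatter of enrichment vs significance, dot size = selected targets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    size = 10 + 3 * data["size"].fillna(0)
    colours = data["colour"]
    sc = ax.scatter(
        data["enrichment"],
        data["neg_log10_p"],
        s=size,
        c=colours.fillna(colours.median() if colours.notna().any() else 0.0),
        cmap="viridis",
        alpha=0.8,
    )
    ax.set_xlabel("enrichment (log2 odds)")
    ax.set_ylabel("-log10 p-value")
    if colours.notna().any():
        ax.figure.colorbar(sc, ax=ax, label="miRNA expression")
    return ax
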