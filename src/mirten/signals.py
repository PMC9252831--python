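"""Differential-expression inputs and derived test signals.

The continuous tests consume a per-feature statistic ("signal") derived from
a differential-expression analysis (DEA): the sign of the fold change times
-log10(FDR).  This tracks logFC for well-measured genes while damping noisy
fold changes.  Binary tests consume a selected set / universe pair, by
default the significantly downregulated genes (the gain-of-function
convention: extra miRNA pushes its targets down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .targets import CollectionError, TargetCollection

log = logging.getLogger(__name__)

__all__ = [
    "DEAError",
    "GeneSetPair",
    "read_dea",
    "validate_dea",
    "compute_signal",
    "derive_sets",
    "map_ids",
    "restrict_background",
    "filter_regulators",
]


class DEAError(ValueError):
    """Raised for unusable differential-expression input."""


@dataclass(frozen=True)
class GeneSetPair:
    """A selected feature set and the universe it was drawn from."""

    selected: frozenset
    universe: frozenset

    def __post_init__(self):
        if not self.universe:
            raise DEAError("universe must be non-empty")
        if not self.selected <= self.universe:
            raise DEAError("selected set must be a subset of the universe")


# Column-name dialects of the common DE tools (edgeR, DESeq2, limma).
_DEA_ALIASES = {
    "logFC": ("logfc", "log2foldchange", "log2fc"),
    "pvalue": ("pvalue", "p.value", "p_value", "pval", "p"),
    "fdr": ("fdr", "padj", "adj.p.val", "qvalue", "q_value"),
    "mean_expr": ("logcpm", "basemean", "aveexpr", "mean_expr", "avgexpr"),
    "feature": ("feature", "gene", "gene_id", "genes", "symbol", "id", "transcript"),
}


def read_dea(path) -> pd.DataFrame:
    """Read a DEA table exported by edgeR / DESeq2 / limma or similar.

    Returns a frame with normalised columns ``feature``, ``logFC``,
    ``pvalue``, ``fdr`` and (when present) ``mean_expr``.  An unnamed first
    column is treated as row names holding feature ids.  Rows with missing
    logFC or FDR are dropped (count logged); duplicated feature ids keep the
    row with the smallest FDR.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    first = df.columns[0]
    if first.startswith("Unnamed") or first == "":
        df = df.rename(columns={first: "feature"})
    rename = {}
    for canon, aliases in _DEA_ALIASES.items():
        for c in df.columns:
            if c.lower() in aliases or c == canon:
                rename[c] = canon
                break
    df = df.rename(columns=rename)
    if "logFC" not in df.columns:
        raise DEAError(
            "no recognizable log-fold-change column; accepted: logFC, log2FoldChange, log2FC"
        )
    if "feature" not in df.columns:
        raise DEAError("no recognizable feature-id column (feature/gene/symbol/id or row names)")
    if "fdr" not in df.columns:
        raise DEAError("no recognizable FDR column; accepted: FDR, padj, adj.P.Val, qvalue")
    keep = ["feature", "logFC", "pvalue", "fdr"] + (
        ["mean_expr"] if "mean_expr" in df.columns else []
    )
    if "pvalue" not in df.columns:
        df["pvalue"] = df["fdr"]
    df = df[keep].copy()
    df["feature"] = df["feature"].astype(str)
    for c in keep[1:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["logFC", "fdr"])
    if len(df) < n0:
        log.info("dropped %d row(s) with missing logFC or FDR", n0 - len(df))
    ndup = df.duplicated("feature").sum()
    if ndup:
        log.info("resolving %d duplicated feature id(s) by smallest FDR", ndup)
        df = df.sort_values("fdr", kind="stable").drop_duplicates("feature")
    return validate_dea(df.reset_index(drop=True))


def validate_dea(dea: pd.DataFrame) -> pd.DataFrame:
    """Range-check a normalised DEA frame and return it unchanged."""
    for col in ("feature", "logFC", "pvalue", "fdr"):
        if col not in dea.columns:
            raise DEAError(f"DEA table lacks required column '{col}'")
    if dea["feature"].duplicated().any():
        raise DEAError("DEA table has duplicated feature ids")
    for col in ("pvalue", "fdr"):
        vals = dea[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise DEAError(f"column '{col}' outside [0, 1]")
    return dea


def compute_signal(dea: pd.DataFrame) -> pd.Series:
    """Per-feature signal s = sign(logFC) * -log10(FDR).

    An FDR of exactly 0 is floored to half the smallest positive FDR in the
    table, which avoids infinities while preserving rank order.
    """
    if dea.empty:
        raise DEAError("empty DEA table")
    fdr = dea["fdr"].to_numpy(dtype=float).copy()
    pos = fdr[fdr > 0]
    if pos.size == 0:
        raise DEAError("all FDR values are zero; cannot derive a finite signal")
    fdr[fdr == 0] = pos.min() / 2.0
    s = np.sign(dea["logFC"].to_numpy(dtype=float)) * (-np.log10(fdr))
    if not s.any():
        log.warning("all FDR values are 1: signal is identically zero")
    out = pd.Series(s, index=pd.Index(dea["feature"], name="feature"), name="signal")
    out.attrs["derivation"] = "sign(logFC) * -log10(FDR)"
    return out


def derive_sets(
    dea: pd.DataFrame, alpha: float = 0.05, direction: str = "down", use: str = "fdr"
) -> GeneSetPair:
    """Selected = features significant at ``alpha`` and changing in
    ``direction`` (down | up | both); universe = all features in the DEA.

    Significance is judged on the FDR by default; ``use="pvalue"`` selects
    on the unadjusted p-value instead, which keeps the set non-empty in
    weak-signal settings where nothing survives multiple-testing correction
    (the selection then reads as "nominally downregulated genes").
    """
    if not 0 < alpha < 1:
        raise DEAError("alpha must be in (0, 1)")
    if direction not in ("down", "up", "both"):
        raise DEAError("direction must be down, up or both")
    if use not in ("fdr", "pvalue"):
        raise DEAError("use must be 'fdr' or 'pvalue'")
    sig = dea[use] < alpha
    if direction == "down":
        sig &= dea["logFC"] < 0
    elif direction == "up":
        sig &= dea["logFC"] > 0
    selected = frozenset(dea.loc[sig, "feature"])
    if not selected:
        raise DEAError(
            f"no feature passes FDR < {alpha} ({direction}); "
            "loosen alpha or use a continuous test"
        )
    return GeneSetPair(selected=selected, universe=frozenset(dea["feature"]))


def map_ids(
    features: Iterable[str], mapping: Mapping[str, str] | pd.DataFrame, on_missing: str = "keep"
) -> list[str]:
    """Translate feature ids through a 2-column mapping table.

    Unmapped ids are kept or dropped per ``on_missing``; many-to-one
    collisions resolve to the first occurrence.  Lossy mapping is logged,
    never fatal.
    """
    if on_missing not in ("keep", "drop"):
        raise ValueError("on_missing must be 'keep' or 'drop'")
    if isinstance(mapping, pd.DataFrame):
        src, dst = mapping.columns[:2]
        mapping = dict(
            zip(mapping[src].astype(str), mapping[dst].astype(str))
        )
    out, missing = [], 0
    for f in features:
        if f in mapping:
            out.append(mapping[f])
        elif on_missing == "keep":
            out.append(f)
            missing += 1
        else:
            missing += 1
    if missing:
        log.info("%d feature id(s) had no mapping (%s)", missing, on_missing)
    ncoll = len(out) - len(dict.fromkeys(out))
    if ncoll:
        log.info("%d many-to-one collision(s) after mapping", ncoll)
    return out


def restrict_background(
    dea: pd.DataFrame, top_n: int | None = None, custom: Iterable[str] | None = None
) -> pd.DataFrame:
    """Limit the DEA (hence the test universe) to a background set.

    ``custom`` wins when given; otherwise the ``top_n`` highest-expressed
    features by ``mean_expr`` are kept, ties at the boundary broken by
    feature id for determinism.
    """
    if custom is not None:
        return dea[dea["feature"].isin(set(custom))].reset_index(drop=True)
    if top_n is None:
        return dea
    if "mean_expr" not in dea.columns:
        raise DEAError("top-N background restriction requires a mean-expression column")
    ranked = dea.sort_values(
        ["mean_expr", "feature"], ascending=[False, True], kind="stable"
    )
    return ranked.head(top_n).sort_index().reset_index(drop=True)


def filter_regulators(
    tc: TargetCollection,
    expr: Mapping[str, float] | Iterable[str],
    min_expr: float = 0.0,
    family_map: Mapping[str, str] | None = None,
) -> TargetCollection:
    """Keep only regulators expressed in the tissue of interest.

    ``expr`` is either a miRNA → expression mapping (kept if ≥ ``min_expr``)
    or a plain id list.  For a family-level collection pass ``family_map``
    (miRNA → family); a family passes if any member passes.
    """
    if isinstance(expr, Mapping):
        passing = {m for m, v in expr.items() if v >= min_expr}
    else:
        passing = set(expr)
    if family_map is not None:
        passing |= {family_map[m] for m in passing if m in family_map}
    keep = [r for r in tc.regulator_index if r in passing]
    if not keep:
        raise CollectionError("no regulator passes the expression filter")
    from dataclasses import replace

    kept = tc.records[tc.records["regulator"].isin(keep)].reset_index(drop=True)
    return replace(tc, records=kept, regulator_index=pd.Index(keep, name="regulator"))
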