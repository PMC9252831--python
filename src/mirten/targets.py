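"""Binding-site collections: data model, readers, family aggregation and
universe restriction.

A :class:`TargetCollection` stores, for one annotation source, the predicted
(or validated) interactions between post-transcriptional regulators (miRNAs,
miRNA families, or RBPs) and features (genes or transcripts).  Each stored
record carries the number of binding sites on the feature, a repression score
and optionally the strongest ("best") canonical site type.  Scores follow the
TargetScan context++ convention internally: more negative means stronger
predicted repression.  Sources that report positive strengths can be flipped
at read time via ``score_sign``.

Non-targets are absent rather than stored as zero rows; every record has at
least one site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SITE_TYPES",
    "CANONICAL_SITE_TYPES",
    "CollectionError",
    "TargetCollection",
    "read_long_collection",
    "write_long_collection",
    "read_gmt",
    "read_targetscan",
    "TARGETSCAN_DIALECT",
    "aggregate_families",
    "restrict_to_universe",
]

#: Allowed site-type vocabulary, strongest first.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "other", "none")

#: Canonical seed-match types (a feature whose best site is none of these is
#: treated as having "no site" in CD plots).
CANONICAL_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

# Larger = stronger predicted repression for the best-site-type merge rule.
_SITE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "other": 1, "none": 0}

_RECORD_COLUMNS = ["regulator", "feature", "sites", "score", "site_type"]


class CollectionError(ValueError):
    """Raised for malformed or inconsistent collection inputs."""


@dataclass
class TargetCollection:
    """A set of regulator→feature interaction records plus feature metadata.

    Parameters
    ----------
    records
        Long-format frame with columns ``regulator``, ``feature``, ``sites``
        (int ≥ 1), ``score`` (float, NaN when the source has no score) and
        ``site_type`` (one of :data:`SITE_TYPES` or NaN).  At most one row per
        (regulator, feature) pair.
    feature_meta
        Frame indexed by feature id; the only recognised column is
        ``utr_length`` (3'UTR length in nucleotides), required by the
        UTR-length-corrected site test.
    regulator_index
        All regulators the collection knows about, including ones whose
        records were removed by universe restriction.  Keeping them lets
        downstream result tables report such regulators as untestable
        instead of silently dropping them.
    """

    records: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["utr_length"]))
    level: str = "gene"
    regulator_level: str = "mirna"
    species_tag: str = ""
    regulator_index: pd.Index | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("regulator", "feature") if c not in df.columns]
        if missing:
            raise CollectionError(f"records lack mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        if "sites" not in df.columns:
            df["sites"] = 1
        if "score" not in df.columns:
            df["score"] = np.nan
        if "site_type" not in df.columns:
            df["site_type"] = None
        df["sites"] = df["sites"].astype(np.int64)
        if (df["sites"] < 1).any():
            raise CollectionError("every stored record must have sites >= 1")
        bad = df["site_type"].dropna()
        bad = bad[~bad.isin(SITE_TYPES)]
        if len(bad):
            raise CollectionError(f"unknown site_type value(s): {sorted(bad.unique())}")
        if df.duplicated(["regulator", "feature"]).any():
            raise CollectionError("at most one record per (regulator, feature) pair")
        self.records = df[_RECORD_COLUMNS].reset_index(drop=True)
        self._mat_cache: dict = {}
        if self.regulator_index is None:
            self.regulator_index = pd.Index(sorted(df["regulator"].unique()), name="regulator")
        if not isinstance(self.feature_meta, pd.DataFrame):
            self.feature_meta = pd.DataFrame(
                {"utr_length": pd.Series(dict(self.feature_meta), dtype=float)}
            )

    # -- basic introspection -------------------------------------------------

    @property
    def regulators(self) -> pd.Index:
        return self.regulator_index

    @property
    def features(self) -> pd.Index:
        return pd.Index(self.records["feature"].unique(), name="feature")

    @property
    def has_scores(self) -> bool:
        return bool(self.records["score"].notna().any())

    def n_records(self) -> int:
        return len(self.records)

    def target_set(self, regulator: str) -> set[str]:
        return set(self.records.loc[self.records["regulator"] == regulator, "feature"])

    def utr_lengths(self, features: Iterable[str]) -> pd.Series:
        """UTR lengths for ``features``; raises naming any feature without one."""
        feats = pd.Index(features)
        if "utr_length" not in self.feature_meta.columns:
            raise CollectionError(f"no utr_length metadata; missing for e.g. {list(feats[:5])}")
        lens = self.feature_meta["utr_length"].reindex(feats)
        missing = feats[lens.isna().to_numpy()]
        if len(missing):
            raise CollectionError(
                f"utr_length missing for {len(missing)} feature(s), e.g. {list(missing[:5])}"
            )
        return lens

    # -- dense matrices used by the vectorised tests -------------------------

    def matrices(self, universe: Iterable[str]) -> tuple[pd.Index, pd.Index, np.ndarray, np.ndarray]:
        """Dense feature × regulator matrices of site counts and scores.

        Returns ``(features, regulators, sites, scores)`` where non-target
        entries are 0 in both matrices and a missing score on a target is 0
        in ``scores`` (it then contributes no weight to score-based tests).
        Results are cached per universe; callers must not mutate them.
        """
        feats = pd.Index(pd.unique(pd.Index(universe)), name="feature")
        key = hash(tuple(feats))
        if key in self._mat_cache:
            return self._mat_cache[key]
        regs = self.regulator_index
        fpos = pd.Series(np.arange(len(feats)), index=feats)
        rpos = pd.Series(np.arange(len(regs)), index=regs)
        rec = self.records[self.records["feature"].isin(feats)]
        i = fpos[rec["feature"]].to_numpy()
        j = rpos[rec["regulator"]].to_numpy()
        sites = np.zeros((len(feats), len(regs)))
        scores = np.zeros((len(feats), len(regs)))
        sites[i, j] = rec["sites"].to_numpy(dtype=float)
        scores[i, j] = np.nan_to_num(rec["score"].to_numpy(dtype=float))
        if len(self._mat_cache) > 4:
            self._mat_cache.clear()
        self._mat_cache[key] = (feats, regs, sites, scores)
        return feats, regs, sites, scores


def _strongest_site_type(values: pd.Series):
    vals = values.dropna()
    if vals.empty:
        return None
    return max(vals, key=lambda v: _SITE_RANK.get(v, -1))


def _merge_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate (regulator, feature) rows: sum sites, keep the most
    negative score and the strongest site type."""
    if not df.duplicated(["regulator", "feature"]).any():
        return df
    agg = df.groupby(["regulator", "feature"], sort=False).agg(
        sites=("sites", "sum"),
        score=("score", "min"),
        site_type=("site_type", _strongest_site_type),
    )
    return agg.reset_index()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LONG_ALIASES = {
    "regulator": ("regulator", "mirna", "mir", "set", "family"),
    "feature": ("feature", "gene", "gene_id", "symbol", "transcript", "target"),
    "sites": ("sites", "n_sites", "nsites", "sitecount"),
    "score": ("score", "context_score", "repression_score"),
    "site_type": ("site_type", "sitetype", "best_site", "best_site_type"),
    "utr_length": ("utr_length", "utr_len", "utr.length", "length"),
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_long_collection(
    path,
    column_map: Mapping[str, str] | None = None,
    score_sign: int = 1,
    level: str = "gene",
    regulator_level: str = "mirna",
    species_tag: str = "",
) -> TargetCollection:
    """Read a long-format (one interaction per row) TSV/CSV collection.

    ``column_map`` maps canonical names (regulator, feature, sites, score,
    site_type, utr_length) to the file's column headers; common aliases are
    recognised automatically.  ``score_sign=-1`` flips sources that report
    positive strengths into the internal more-negative-is-stronger
    orientation.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _LONG_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] not in df.columns:
                raise CollectionError(f"mapped column '{column_map[canon]}' (for '{canon}') not in file")
            resolved[canon] = column_map[canon]
            continue
        for a in aliases:
            if a in cols:
                resolved[canon] = cols[a]
                break
    for mandatory in ("regulator", "feature"):
        if mandatory not in resolved:
            raise CollectionError(
                f"missing mandatory column '{mandatory}' "
                f"(accepted aliases: {', '.join(_LONG_ALIASES[mandatory])})"
            )
    out = pd.DataFrame(
        {
            "regulator": df[resolved["regulator"]].astype(str),
            "feature": df[resolved["feature"]].astype(str),
        }
    )
    out["sites"] = df[resolved["sites"]] if "sites" in resolved else 1
    out["score"] = (
        score_sign * pd.to_numeric(df[resolved["score"]], errors="coerce")
        if "score" in resolved
        else np.nan
    )
    out["site_type"] = df[resolved["site_type"]] if "site_type" in resolved else None
    out = _merge_duplicates(out)
    meta = pd.DataFrame(columns=["utr_length"])
    if "utr_length" in resolved:
        lens = pd.to_numeric(df[resolved["utr_length"]], errors="coerce")
        meta = (
            pd.DataFrame({"feature": df[resolved["feature"]].astype(str), "utr_length": lens})
            .dropna()
            .groupby("feature")["utr_length"]
            .max()
            .to_frame()
        )
    return TargetCollection(
        out, feature_meta=meta, level=level, regulator_level=regulator_level, species_tag=species_tag
    )


def write_long_collection(tc: TargetCollection, path) -> None:
    """Write the collection in the long TSV dialect read_long_collection reads."""
    df = tc.records.copy()
    if "utr_length" in tc.feature_meta.columns and len(tc.feature_meta):
        df = df.merge(
            tc.feature_meta["utr_length"].rename_axis("feature").reset_index(),
            on="feature",
            how="left",
        )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> TargetCollection:
    """Read a GMT gene-set file; each set becomes a regulator with unit sites
    and no score (so the collection supports set/site tests only)."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CollectionError(f"GMT parse error at line {lineno}: fewer than 3 fields")
            name, _desc, *members = parts
            for m in dict.fromkeys(m for m in members if m):  # dedup, keep order
                rows.append((name, m))
    if not rows:
        raise CollectionError("empty GMT file: no gene sets found")
    df = pd.DataFrame(rows, columns=["regulator", "feature"])
    return TargetCollection(df)


#: Default column map for TargetScan "summary counts"-style tables.
TARGETSCAN_DIALECT = {
    "regulator": "miR Family",
    "feature": "Gene Symbol",
    "conserved_sites": "Total num conserved sites",
    "nonconserved_sites": "Total num nonconserved sites",
    "score": "Cumulative weighted context++ score",
}


def read_targetscan(
    path,
    conserved_only: bool = False,
    dialect: Mapping[str, str] | None = None,
    species_tag: str = "",
) -> TargetCollection:
    """Read a TargetScan summary-style table (family-level annotation).

    Site counts come from the conserved (+ non-conserved unless
    ``conserved_only``) site-count columns; rows left with zero sites are
    dropped.  The score column defaults to the cumulative weighted context++
    score and can be switched via ``dialect``.
    """
    d = dict(TARGETSCAN_DIALECT)
    if dialect:
        d.update(dialect)
    df = _read_table(path)
    missing = [v for k, v in d.items() if v not in df.columns]
    if missing:
        raise CollectionError(
            "unrecognized TargetScan dialect; expected columns "
            f"{sorted(d.values())}, missing {missing}. Present: {list(df.columns)}"
        )
    cons = pd.to_numeric(df[d["conserved_sites"]], errors="coerce").fillna(0).astype(int)
    noncons = pd.to_numeric(df[d["nonconserved_sites"]], errors="coerce").fillna(0).astype(int)
    sites = cons if conserved_only else cons + noncons
    out = pd.DataFrame(
        {
            "regulator": df[d["regulator"]].astype(str),
            "feature": df[d["feature"]].astype(str),
            "sites": sites,
            "score": pd.to_numeric(df[d["score"]], errors="coerce"),
        }
    )
    out = out[out["sites"] >= 1]
    if out.empty:
        raise CollectionError("no records left after site filtering")
    out = _merge_duplicates(out)
    return TargetCollection(out, regulator_level="family", species_tag=species_tag)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def aggregate_families(tc: TargetCollection, family_map: Mapping[str, str]) -> TargetCollection:
    """Regroup a miRNA-level collection by family.

    Per (family, feature): sites = max over members, score = most negative
    over members, site_type = strongest over members — a family's strongest
    member prediction, not additive evidence.
    """
    if tc.regulator_level != "mirna":
        raise CollectionError("collection is not at individual-miRNA level")
    regs = tc.records["regulator"].unique()
    unmapped = [r for r in regs if r not in family_map]
    if unmapped:
        raise CollectionError(f"miRNA(s) missing from family map: {sorted(unmapped)}")
    df = tc.records.copy()
    df["regulator"] = df["regulator"].map(dict(family_map))
    agg = (
        df.groupby(["regulator", "feature"], sort=False)
        .agg(
            sites=("sites", "max"),
            score=("score", "min"),
            site_type=("site_type", _strongest_site_type),
        )
        .reset_index()
    )
    all_fams = pd.Index(
        sorted({family_map[r] for r in tc.regulator_index if r in family_map}), name="regulator"
    )
    return replace(tc, records=agg, regulator_level="family", regulator_index=all_fams)


def restrict_to_universe(tc: TargetCollection, universe: Iterable[str]) -> TargetCollection:
    """Drop records whose feature is outside ``universe``.

    Regulators left without records stay in ``regulator_index`` so the test
    layer reports them as untestable (p = NA) instead of dropping them.
    """
    uni = set(universe)
    if not uni:
        raise CollectionError("universe must be non-empty")
    kept = tc.records[tc.records["feature"].isin(uni)].reset_index(drop=True)
    if kept.empty:
        log.warning("universe is disjoint from the collection: all regulators are now empty")
    meta = tc.feature_meta
    if len(meta):
        meta = meta[meta.index.isin(uni)]
    return replace(tc, records=kept, feature_meta=meta, regulator_index=tc.regulator_index)
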