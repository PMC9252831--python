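"""Benchmark protocol for comparing enrichment tests.

Perturbation datasets with a known causal regulator are made progressively
harder by "scrambling": swapping the full DE statistics of a fraction of the
true regulator's targets with those of random non-targets.  Each test is
then scored by the rank of the true regulator (ascending p), whether it was
discovered at a nominal FDR threshold, and how many other regulators were
falsely discovered.  Performance should degrade steadily with the scramble
fraction; how gracefully is what separates the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import TestConfig, run_enrichment
from .targets import TargetCollection

log = logging.getLogger(__name__)

__all__ = ["BenchmarkRecord", "scramble_dea", "evaluate_run", "run_benchmark", "summarize"]

_STAT_COLS = ("logFC", "pvalue", "fdr", "mean_expr")


@dataclass(frozen=True)
class BenchmarkRecord:
    """One (dataset, test, scramble fraction, seed) evaluation."""

    dataset: str
    test: str
    scramble_fraction: float
    seed: int
    rank_true: int
    discovered: bool
    n_fp: int
    error: str | None = None


def scramble_dea(
    dea: pd.DataFrame, true_targets: Iterable[str], fraction: float, seed: int
) -> pd.DataFrame:
    """Swap the DE statistics of a random fraction of true targets with
    those of as many random non-targets; feature ids stay in place, so the
    multiset of statistic rows is exactly preserved."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 2])  # stream disjoint from the simulators'
    feats = dea["feature"].to_numpy()
    tmask = np.isin(feats, np.asarray(list(true_targets)))
    tgt_idx = np.nonzero(tmask)[0]
    non_idx = np.nonzero(~tmask)[0]
    k = int(round(fraction * len(tgt_idx)))
    if k == 0:
        return dea.copy()
    if k > len(non_idx):
        raise ValueError(f"not enough non-targets ({len(non_idx)}) to pair {k} swaps")
    pick_t = rng.choice(tgt_idx, size=k, replace=False)
    pick_n = rng.choice(non_idx, size=k, replace=False)
    out = dea.copy()
    cols = [c for c in _STAT_COLS if c in out.columns]
    block_t = out.iloc[pick_t][cols].to_numpy()
    out.iloc[pick_t, [out.columns.get_loc(c) for c in cols]] = out.iloc[pick_n][cols].to_numpy()
    out.iloc[pick_n, [out.columns.get_loc(c) for c in cols]] = block_t
    return out


def _true_ids(true_regulator: str, family_map: Mapping[str, str] | None) -> set[str]:
    ids = {true_regulator}
    if family_map:
        fam = family_map.get(true_regulator)
        if fam is not None:
            ids.add(fam)
            ids |= {m for m, f in family_map.items() if f == fam}
    return ids


def evaluate_run(
    results: pd.DataFrame,
    true_regulator: str,
    family_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    dataset: str = "",
    test: str = "",
    scramble_fraction: float = 0.0,
    seed: int = 0,
) -> BenchmarkRecord:
    """Score one result table against the known causal regulator.

    Any member of the true regulator's family (when a family map is given)
    counts as a true positive, because family-level annotations cannot
    distinguish members.  An untestable true regulator (p = NA) ranks after
    every testable one.
    """
    truth = _true_ids(true_regulator, family_map)
    if not set(results["regulator"]) & truth:
        raise ValueError(f"true regulator '{true_regulator}' absent from results")
    testable = results[results["pvalue"].notna()].copy()
    testable["_abs_enr"] = testable["enrichment"].abs()
    testable["_abs_stat"] = testable["statistic"].abs()
    # ties on p (e.g. permutation p floors) break by effect size, then id
    ranked = testable.sort_values(
        ["pvalue", "_abs_enr", "_abs_stat", "regulator"],
        ascending=[True, False, False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    is_true = ranked["regulator"].isin(truth).to_numpy()
    if is_true.any():
        rank_true = int(np.nonzero(is_true)[0][0]) + 1
        true_rows = ranked[is_true]
        discovered = bool((true_rows["fdr"] < alpha).any())
    else:
        rank_true = len(ranked) + 1
        discovered = False
    fp = ranked[~is_true]
    n_fp = int((fp["fdr"] < alpha).sum())
    return BenchmarkRecord(
        dataset=dataset,
        test=test,
        scramble_fraction=scramble_fraction,
        seed=seed,
        rank_true=rank_true,
        discovered=discovered,
        n_fp=n_fp,
    )


def run_benchmark(
    datasets: Sequence[tuple[pd.DataFrame, str]],
    tc: TargetCollection,
    tests: Sequence[str],
    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    seeds: Sequence[int] = (0,),
    cfg: TestConfig | None = None,
    family_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full-factorial benchmark: datasets × scramble fractions × seeds × tests.

    Returns one row per run with the BenchmarkRecord fields; individual run
    failures are recorded in the ``error`` column, never fatal.  Deterministic
    given the seed grid.
    """
    if not (len(datasets) and len(tests) and len(fractions) and len(seeds)):
        raise ValueError("datasets, tests, fractions and seeds must all be non-empty")
    cfg = cfg or TestConfig()
    rows = []
    for di, (dea, true_reg) in enumerate(datasets):
        true_targets = tc.target_set(true_reg)
        for frac in fractions:
            for seed in seeds:
                scrambled = scramble_dea(dea, true_targets, frac, seed)
                for test in tests:
                    ident = dict(
                        dataset=f"d{di}", test=test, scramble_fraction=frac, seed=seed
                    )
                    try:
                        res = run_enrichment(
                            scrambled, tc, test, dc_replace(cfg, seed=seed)
                        )
                        rec = evaluate_run(
                            res, true_reg, family_map, alpha=alpha, **ident
                        )
                    except Exception as exc:  # recorded per-row, not fatal
                        log.warning("benchmark run failed (%s): %s", ident, exc)
                        rec = BenchmarkRecord(
                            **ident, rank_true=-1, discovered=False, n_fp=0, error=str(exc)
                        )
                    rows.append(rec)
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize(records: pd.DataFrame, pooled_fdr: bool = False) -> pd.DataFrame:
    """Per (test, scramble fraction) summary: mean rank of the true
    regulator, sensitivity (fraction of runs discovering it) and empirical
    FDR.

    Empirical FDR defaults to the mean over runs of FP/(FP+TP) (with 0/0
    counted as 0); ``pooled_fdr`` pools counts over runs instead.
    """
    ok = records[records["error"].isna()].copy()
    ok["tp"] = ok["discovered"].astype(int)

    def _agg(g: pd.DataFrame) -> pd.Series:
        if pooled_fdr:
            denom = max(1, int(g["n_fp"].sum() + g["tp"].sum()))
            fdr = g["n_fp"].sum() / denom
        else:
            fdr = (g["n_fp"] / np.maximum(1, g["n_fp"] + g["tp"])).mean()
        return pd.Series(
            {
                "mean_rank_true": g["rank_true"].mean(),
                "sensitivity": g["discovered"].mean(),
                "empirical_fdr": fdr,
                "n_runs": len(g),
            }
        )

    out = (
        ok.groupby(["test", "scramble_fraction"])[ok.columns]
        .apply(_agg)
        .reset_index()
    )
    return out
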