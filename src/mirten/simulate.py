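"""Seeded generator of synthetic target collections and miRNA-perturbation
differential-expression tables.

The generator emulates the statistical structure the enrichment tests assume
about real annotation sources and mimic-transfection experiments:

* 3'UTR lengths are log-normal (median ~1 kb), and a regulator's expected
  site count on a feature scales with UTR length — the bias the
  length-corrected site test exists to remove.
* Site counts are Poisson with a per-regulator rate, so target sets differ
  in size; best site types follow the canonical 8mer < 7mer-m8 < 7mer-A1
  frequency ordering, and repression scores strengthen (grow more negative)
  with site count and site-type strength plus exponential noise.
* A perturbation shifts each feature's expected logFC by the summed
  repression scores of the active regulators; observed logFCs add Gaussian
  noise with known SD, and p-values come from the matching z-test, so null
  p-values are uniform by construction — which is what type-I-error
  calibration checks require.
* Optional "twin" regulators share a configurable fraction of a source
  regulator's targets, mimicking same-seed miRNA family members, to
  exercise the additive-regression disentanglement test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import adjust_bh
from .targets import TargetCollection
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["SimTruth", "simulate_collection", "simulate_dea"]

_SITE_TYPE_P = {"8mer": 0.2, "7mer-m8": 0.5, "7mer-A1": 0.3}
_TAU = {"8mer": 1.5, "7mer-m8": 1.0, "7mer-A1": 0.6}


@dataclass
class SimTruth:
    """Ground truth of a simulated perturbation experiment.

    ``active`` maps regulator id -> effect multiplier beta (beta > 0 pushes
    that regulator's targets down, since scores are negative).  Together
    with the seed it fully determines the generated DEA.
    """

    active: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    n_genes: int = 5000
    n_regulators: int = 50
    twin_pairs: Sequence[tuple[str, str, float]] = ()
    seed: int = 0

    def to_json(self, path) -> None:
        d = asdict(self)
        d["active"] = dict(self.active)
        d["twin_pairs"] = [list(t) for t in self.twin_pairs]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_collection(
    n_genes: int = 5000,
    n_regulators: int = 50,
    twin_pairs: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
) -> TargetCollection:
    """Generate a synthetic binding-site collection.

    ``twin_pairs`` entries are (source regulator, twin name, target-overlap
    fraction): the twin copies the source's records and re-draws the
    non-shared fraction of its targets onto features the source does not
    target.  Every record has sites >= 1 and a negative score.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if n_regulators < 2:
        raise ValueError("n_regulators must be >= 2")
    # distinct sub-stream per operation: the DEA generator must not replay
    # the bit stream that decided targethood, or noise correlates with it
    rng = np.random.default_rng([seed, 0])
    feats = np.array([f"g{i:05d}" for i in range(1, n_genes + 1)])
    regs = [f"mir-{i}" for i in range(1, n_regulators + 1)]
    L = rng.lognormal(mean=np.log(1000.0), sigma=0.6, size=n_genes)
    rel_len = L / L.mean()
    types = np.array(list(_SITE_TYPE_P))
    type_p = np.array(list(_SITE_TYPE_P.values()))
    tau = np.array([_TAU[t] for t in types])
    frames = []
    for m in regs:
        lam = rng.uniform(0.05, 0.25)
        sites = rng.poisson(lam * rel_len)
        idx = np.nonzero(sites)[0]
        ti = rng.choice(len(types), size=len(idx), p=type_p)
        score = -(
            0.05 + 0.12 * sites[idx] * tau[ti] + rng.exponential(0.05, size=len(idx))
        )
        frames.append(
            pd.DataFrame(
                {
                    "regulator": m,
                    "feature": feats[idx],
                    "sites": sites[idx],
                    "score": score,
                    "site_type": types[ti],
                }
            )
        )
    rec = pd.concat(frames, ignore_index=True)
    for src, twin, overlap in twin_pairs:
        if not 0 <= overlap <= 1:
            raise ValueError("twin overlap must be in [0, 1]")
        block = rec[rec["regulator"] == src]
        if block.empty:
            raise ValueError(f"twin source '{src}' has no records")
        k = len(block)
        n_keep = int(round(overlap * k))
        perm = rng.permutation(k)
        moved = block.iloc[perm[n_keep:]].copy()
        kept = block.iloc[perm[:n_keep]].copy()
        free = np.setdiff1d(feats, block["feature"].to_numpy())
        if len(free) < len(moved):
            raise ValueError(
                f"cannot place twin '{twin}': only {len(free)} free features "
                f"for {len(moved)} resampled targets"
            )
        moved["feature"] = rng.choice(free, size=len(moved), replace=False)
        new = pd.concat([kept, moved], ignore_index=True)
        new["regulator"] = twin
        rec = pd.concat([rec, new], ignore_index=True)
    meta = pd.DataFrame({"utr_length": L}, index=pd.Index(feats, name="feature"))
    return TargetCollection(
        rec.reset_index(drop=True), feature_meta=meta, species_tag="synthetic"
    )


def simulate_dea(tc: TargetCollection, truth: SimTruth) -> pd.DataFrame:
    """Simulate a perturbation DEA over all features of the collection.

    Expected logFC mu_i = sum over active regulators of beta * score_mi
    (zero for non-targets); observed logFC = mu + N(0, noise_sd); p-values
    are the exact z-test with the known SD, FDR is Benjamini-Hochberg and
    mean expression is uniform and independent of everything else.
    """
    missing = [m for m in truth.active if m not in set(tc.regulator_index)]
    if missing:
        raise ValueError(f"active regulator(s) not in collection: {missing}")
    rng = np.random.default_rng([truth.seed, 1])
    feats = tc.feature_meta.index if len(tc.feature_meta) else tc.features
    fidx, regs, _, scores = tc.matrices(feats)
    mu = np.zeros(len(fidx))
    for m, beta in truth.active.items():
        mu += beta * scores[:, list(regs).index(m)]
    logfc = mu + rng.normal(0.0, truth.noise_sd, size=len(fidx))
    if truth.noise_sd > 0:
        pvals = 2.0 * stats.norm.sf(np.abs(logfc) / truth.noise_sd)
    else:
        pvals = np.where(logfc == 0, 1.0, 0.0)
    dea = pd.DataFrame(
        {
            "feature": np.asarray(fidx),
            "logFC": logfc,
            "pvalue": pvals,
            "fdr": adjust_bh(pvals),
            "mean_expr": rng.uniform(0.0, 15.0, size=len(fidx)),
        }
    )
    return dea
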