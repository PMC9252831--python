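"""The enrichment-test compendium.

Twelve statistics for ranking post-transcriptional regulators by their likely
involvement in a transcriptional signature, divided by input type:

binary (selected set vs universe)
    ``overlap`` (gene-level hypergeometric ORA), ``siteoverlap`` (site-level
    hypergeometric, counting binding sites rather than genes) and
    ``woverlap`` (site-level ORA correcting for 3'UTR length).

continuous (per-feature signal from a DEA)
    ``ks`` / ``mw`` (two-sample rank tests of targets vs non-targets),
    ``modsites`` / ``modscore`` (per-regulator linear regression of the
    signal on site counts / repression scores), ``ebayes`` (the score
    regression with empirical-Bayes moderated t-statistics), ``lmadd``
    (forward additive joint regression that requires each extra regulator to
    carry signal conditional on the stronger ones), ``areamir``
    (score-weighted analytic rank enrichment, a z-statistic), ``regmir``
    (lasso selection followed by OLS testing) and ``gsea`` (weighted
    running-sum enrichment with gene-label permutation p-values).

All tests emit a uniform result table with one row per regulator of the
collection: untestable regulators (no targets in the universe, degenerate
predictors, out-of-bounds set sizes) get p = NA and are excluded from BH
correction but keep their row, so result indices are stable across inputs.

Direction convention: p-values are two-sided and the statistic's sign
carries the direction.  Scores are negative for predicted repression, the
default signal is sign(logFC)·-log10(FDR), so a regulator that is *active*
in a gain-of-function design shows a positive regression slope on score, a
negative rank/aREA/GSEA statistic and a positive (log-odds) enrichment of
its targets among downregulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, ndtri, polygamma
from statsmodels.stats.multitest import multipletests

from .signals import DEAError, GeneSetPair, compute_signal, derive_sets, validate_dea
from .targets import TargetCollection

log = logging.getLogger(__name__)

__all__ = [
    "TestConfig",
    "BINARY_TESTS",
    "CONTINUOUS_TESTS",
    "ALL_TESTS",
    "test_overlap",
    "test_siteoverlap",
    "test_woverlap",
    "test_rank",
    "test_linreg",
    "test_ebayes",
    "test_lmadd",
    "test_areamir",
    "test_regmir",
    "test_gsea",
    "adjust_bh",
    "run_enrichment",
    "write_results",
]

P_FLOOR = 1e-300

# Signal value below which a target counts as "significantly downregulated"
# for the n_selected_targets column: with the default signal derivation
# s < log10(0.05) is exactly (FDR < 0.05 and logFC < 0).
_SIG_SIGNAL = np.log10(0.05)

RESULT_COLUMNS = [
    "regulator",
    "n_targets",
    "n_selected_targets",
    "statistic",
    "enrichment",
    "pvalue",
    "fdr",
    "selected",
]

BINARY_TESTS = ("overlap", "siteoverlap", "woverlap")
CONTINUOUS_TESTS = (
    "ks",
    "mw",
    "modsites",
    "modscore",
    "ebayes",
    "lmadd",
    "areamir",
    "regmir",
    "gsea",
)
ALL_TESTS = BINARY_TESTS + CONTINUOUS_TESTS


@dataclass
class TestConfig:
    """Tuning knobs shared by the dispatcher and the selection-based tests."""

    __test__ = False  # not a pytest class despite the name

    alpha_add: float = 0.05  # entry threshold for lmadd's forward selection
    max_terms: int = 10  # cap on lmadd model size
    nperm: int = 1000  # GSEA gene-label permutations
    cv_folds: int = 10  # regmir cross-validation folds
    lambda_rule: str = "1se"  # regmir penalty choice: "1se" or "min"
    seed: int = 0
    # how binary tests derive their selected set from a DEA input
    sel_alpha: float = 0.05
    sel_direction: str = "down"
    sel_use: str = "fdr"

    def __post_init__(self):
        if not 0 < self.alpha_add < 1:
            raise ValueError("alpha_add must be in (0, 1)")
        if not 0 < self.sel_alpha < 1:
            raise ValueError("sel_alpha must be in (0, 1)")
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")


def _clip_p(p):
    return np.clip(p, P_FLOOR, 1.0)


def _frame(regs, n_targets, n_sel, statistic, enrichment, pvalue, selected=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "regulator": np.asarray(regs),
            "n_targets": np.asarray(n_targets, dtype=float),
            "n_selected_targets": np.asarray(n_sel, dtype=float),
            "statistic": np.asarray(statistic, dtype=float),
            "enrichment": np.asarray(enrichment, dtype=float),
            "pvalue": np.asarray(pvalue, dtype=float),
            "fdr": np.nan,
            "selected": pd.array(
                [None] * len(regs) if selected is None else selected, dtype="boolean"
            ),
        }
    )
    return df


def _log2_odds(a, b, c, d):
    """Haldane-corrected log2 odds ratio of the 2x2 table [[a, b], [c, d]]."""
    return np.log2(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))


# ---------------------------------------------------------------------------
# binary (set-based) tests
# ---------------------------------------------------------------------------


def _set_inputs(sets: GeneSetPair, tc: TargetCollection):
    universe = pd.Index(sorted(sets.universe))
    # matrices() itself drops records outside the universe
    feats, regs, sites, scores = tc.matrices(universe)
    sel_mask = np.asarray([f in sets.selected for f in feats])
    return tc, feats, regs, sites, scores, sel_mask


def test_overlap(sets: GeneSetPair, tc: TargetCollection) -> pd.DataFrame:
    """Gene-level over-representation of targets in the selected set.

    One-sided hypergeometric upper tail: with N universe genes, K targets of
    the regulator, n selected genes and a selected targets,
    p = P(X >= a), X ~ Hypergeom(N, K, n).  The statistic is the
    Haldane-corrected log2 odds ratio of the 2x2 table.
    """
    _, feats, regs, sites, _, sel = _set_inputs(sets, tc)
    N, n = len(feats), int(sel.sum())
    tgt = sites > 0
    K = tgt.sum(axis=0)
    a = (tgt & sel[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = _clip_p(stats.hypergeom.sf(a - 1, N, K, n))
    lor = _log2_odds(a, K - a, n - a, N - K - n + a)
    untestable = K == 0
    p = np.where(untestable, np.nan, p)
    lor = np.where(untestable, np.nan, lor)
    return _frame(regs, K, a, lor, lor, p)


def test_siteoverlap(sets: GeneSetPair, tc: TargetCollection) -> pd.DataFrame:
    """Site-level over-representation: ORA counting binding sites, so that a
    regulator hitting a target through several sites gets more weight.

    Population = all (regulator, feature, site) units on universe features
    (S in total, S_m for regulator m); draws = the S_sel site units lying on
    selected features; observed = a, the regulator's sites on selected
    features; p = upper tail of Hypergeom(S, S_m, S_sel) at a.
    """
    _, feats, regs, sites, _, sel = _set_inputs(sets, tc)
    S = sites.sum()
    S_m = sites.sum(axis=0)
    S_sel = sites[sel].sum()
    a = sites[sel].sum(axis=0)
    n_tsel = ((sites > 0) & sel[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = _clip_p(stats.hypergeom.sf(a - 1, int(S), S_m.astype(int), int(S_sel)))
    lor = _log2_odds(a, S_m - a, S_sel - a, S - S_m - S_sel + a)
    untestable = S_m == 0
    p = np.where(untestable, np.nan, p)
    lor = np.where(untestable, np.nan, lor)
    return _frame(regs, (sites > 0).sum(axis=0), n_tsel, lor, lor, p)


def test_woverlap(sets: GeneSetPair, tc: TargetCollection) -> pd.DataFrame:
    """Site-level ORA correcting for 3'UTR length.

    Longer UTRs harbour more sites by chance; under the null a site lands on
    the selected set with probability pi = (UTR length in selected) / (UTR
    length in universe).  p = upper tail of Binomial(S_m, pi) at a; the
    statistic is log2(observed / expected) = log2(a / (S_m * pi)).
    With equal lengths pi = n/N and the test reduces to an uncorrected
    site-proportion test.
    """
    tc_r, feats, regs, sites, _, sel = _set_inputs(sets, tc)
    L = tc_r.utr_lengths(feats).to_numpy(dtype=float)
    pi = L[sel].sum() / L.sum()
    S_m = sites.sum(axis=0)
    a = sites[sel].sum(axis=0)
    n_tsel = ((sites > 0) & sel[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = _clip_p(stats.binom.sf(a - 1, S_m.astype(int), pi))
        enr = np.where(a > 0, np.log2(a / (S_m * pi)), -np.inf)
    untestable = S_m == 0
    p = np.where(untestable, np.nan, p)
    enr = np.where(untestable, np.nan, enr)
    return _frame(regs, (sites > 0).sum(axis=0), n_tsel, enr, enr, p)


# ---------------------------------------------------------------------------
# continuous (signal-based) tests
# ---------------------------------------------------------------------------


def _signal_inputs(signal: pd.Series, tc: TargetCollection):
    if signal.index.duplicated().any():
        raise DEAError("signal has duplicated feature ids")
    universe = signal.index
    feats, regs, sites, scores = tc.matrices(universe)
    s = signal.reindex(feats).to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise DEAError("signal contains non-finite values")
    return tc, feats, regs, sites, scores, s


def _n_sig_targets(sites, s):
    return ((sites > 0) & (s < _SIG_SIGNAL)[:, None]).sum(axis=0)


def test_rank(signal: pd.Series, tc: TargetCollection, method: str = "ks") -> pd.DataFrame:
    """Two-sample rank test of target vs non-target signal values.

    ``method="ks"``: two-sided Kolmogorov-Smirnov; the statistic is D signed
    by the median difference (negative = targets shifted down).
    ``method="mw"``: two-sided Mann-Whitney / Wilcoxon; the statistic is the
    rank-biserial correlation.  Exact small-sample p-values where SciPy's
    exact distributions apply, asymptotic otherwise.
    """
    if method not in ("ks", "mw"):
        raise ValueError("method must be 'ks' or 'mw'")
    _, feats, regs, sites, _, s = _signal_inputs(signal, tc)
    n_sel = _n_sig_targets(sites, s)
    stat = np.full(len(regs), np.nan)
    pval = np.full(len(regs), np.nan)
    for j in range(len(regs)):
        mask = sites[:, j] > 0
        x, y = s[mask], s[~mask]
        if len(x) < 2 or len(y) < 2:
            continue
        if method == "ks":
            res = stats.ks_2samp(x, y)
            sign = np.sign(np.median(x) - np.median(y))
            stat[j] = res.statistic * (sign if sign != 0 else 1.0)
            pval[j] = res.pvalue
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat[j] = 2.0 * res.statistic / (len(x) * len(y)) - 1.0
            pval[j] = res.pvalue
    pval = np.where(np.isnan(pval), np.nan, _clip_p(pval))
    return _frame(regs, (sites > 0).sum(axis=0), n_sel, stat, np.nan, pval)


def _ols_stats(X: np.ndarray, s: np.ndarray):
    """Per-column simple OLS of s on x (with intercept), vectorised.

    Returns slope, t, two-sided p, residual variance, df and the squared
    slope-SE factor Sxx for each column; columns with zero variance yield
    NaN throughout.
    """
    n = len(s)
    d = n - 2
    xbar = X.mean(axis=0)
    sbar = s.mean()
    Sxx = ((X - xbar) ** 2).sum(axis=0)
    Sxy = (X * (s - sbar)[:, None]).sum(axis=0) - 0.0  # sum x*(s - sbar) == Sxy
    Syy = ((s - sbar) ** 2).sum()
    ok = Sxx > 0
    slope = np.full(X.shape[1], np.nan)
    s2 = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope[ok] = Sxy[ok] / Sxx[ok]
        sse = np.maximum(Syy - slope[ok] * Sxy[ok], 0.0)
        s2[ok] = sse / d
        se = np.sqrt(s2 * np.where(ok, 1.0 / np.where(ok, Sxx, 1.0), np.nan))
        t = slope / se
    p = np.where(np.isnan(t), np.nan, _clip_p(2.0 * stats.t.sf(np.abs(t), d)))
    return slope, t, p, s2, d, Sxx


def test_linreg(signal: pd.Series, tc: TargetCollection, predictor: str = "sites") -> pd.DataFrame:
    """Per-regulator linear regression of the signal on the predictor.

    The regression runs over ALL universe features, with non-targets at
    predictor value 0 — that contrast is what makes the slope well-posed.
    ``predictor="sites"`` uses binding-site counts (an active regulator gives
    a negative slope); ``predictor="score"`` uses the repression scores as-is
    (negative for targets, so an active regulator gives a positive slope).
    The statistic is the slope t; p is two-sided from t(n-2).
    """
    if predictor not in ("sites", "score"):
        raise ValueError("predictor must be 'sites' or 'score'")
    _, feats, regs, sites, scores, s = _signal_inputs(signal, tc)
    if len(feats) < 3:
        raise DEAError("need at least 3 universe features for regression")
    X = sites if predictor == "sites" else scores
    _, t, p, _, _, _ = _ols_stats(X, s)
    return _frame(regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), t, np.nan, p)


def _trigamma_inverse(y: float, tol: float = 1e-8, maxit: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(maxit):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_inv_chisq_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to observed
    residual variances with d residual df, on the log scale (digamma /
    trigamma matching).  Returns (inf, mean(s2)) when the observed spread is
    no larger than sampling noise alone."""
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, d / 2.0)
    if not np.isfinite(evar) or evar <= 0:
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def test_ebayes(
    signal: pd.Series, tc: TargetCollection, moderate: bool = True, _min_regulators: int = 10
) -> pd.DataFrame:
    """Score regression with empirical-Bayes moderated t-statistics.

    Runs the per-regulator score regression of :func:`test_linreg`, then
    shrinks each residual variance toward a prior fitted across regulators:
    with prior df d0 and scale s0^2, the posterior variance is
    (d0*s0^2 + d*s2_m) / (d0 + d) and the moderated t has d0 + d df.
    Moderation stabilises regulators with few/weak targets.  With fewer than
    10 testable regulators (or ``moderate=False``, or fitted d0 = 0) the
    result equals the unmoderated regression.
    """
    _, feats, regs, sites, scores, s = _signal_inputs(signal, tc)
    if len(feats) < 3:
        raise DEAError("need at least 3 universe features for regression")
    slope, t, p, s2, d, Sxx = _ols_stats(scores, s)
    ok = ~np.isnan(slope)
    if not moderate or ok.sum() < _min_regulators:
        if moderate and ok.sum() < _min_regulators:
            log.warning(
                "only %d testable regulators; falling back to unmoderated regression", ok.sum()
            )
        res = _frame(regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), t, np.nan, p)
        res.attrs["prior_df"] = 0.0
        return res
    d0, s02 = _fit_inv_chisq_prior(s2[ok], d)
    if d0 == 0:
        post = s2
        df_mod = float(d)
    elif np.isinf(d0):
        post = np.full_like(s2, s02)
        df_mod = np.inf
    else:
        post = (d0 * s02 + d * s2) / (d0 + d)
        df_mod = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(post / Sxx)
        t_mod = slope / se
    if np.isinf(df_mod):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_mod)
    p_mod = np.where(np.isnan(t_mod), np.nan, _clip_p(p_mod))
    res = _frame(regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), t_mod, np.nan, p_mod)
    res.attrs["prior_df"] = d0
    res.attrs["prior_scale"] = s02
    res.attrs["moderated_df"] = df_mod
    return res


def _joint_ols(X: np.ndarray, y: np.ndarray):
    """OLS of y on X plus intercept; returns (coef, t, p) for the X columns."""
    n, k = X.shape
    D = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = n - (k + 1)
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = _clip_p(2.0 * stats.t.sf(np.abs(t), df))
    return beta[1:], t[1:], p[1:]


def test_lmadd(
    signal: pd.Series, tc: TargetCollection, cfg: TestConfig | None = None
) -> pd.DataFrame:
    """Consecutive additive score regression: disentangles correlated
    regulators by requiring each additional one to carry a significant
    effect conditional on the stronger ones.

    Procedure: (1) rank regulators by their moderated-t (ebayes) p-value;
    (2) walk that order, fitting the joint OLS of the signal on the score
    columns of the already-accepted set plus the candidate, accepting the
    candidate when its coefficient is repression-consistent (positive on
    score) with p < ``alpha_add``, up to ``max_terms`` terms; (3) accepted
    regulators report their coefficient p from the final joint model
    (selected = True), the rest report the conditional p observed when they
    were tested.  Candidates whose addition makes the design ill-conditioned
    are skipped with p = 1 (no separable additional effect).
    """
    cfg = cfg or TestConfig()
    eb = test_ebayes(signal, tc)
    _, feats, regs, sites, scores, s = _signal_inputs(signal, tc)
    order = eb["pvalue"].to_numpy()
    testable = np.where(~np.isnan(order))[0]
    cand = testable[np.argsort(order[testable], kind="stable")]
    pval = np.full(len(regs), np.nan)
    tstat = np.full(len(regs), np.nan)
    selected = np.zeros(len(regs), dtype=bool)
    chosen: list[int] = []
    for j in cand:
        cols = scores[:, chosen + [j]]
        if len(chosen) >= cfg.max_terms:
            # model is full: report the conditional p anyway, never accept
            pass
        if np.linalg.cond(np.column_stack([np.ones(len(s)), cols])) > 1e8:
            log.info("lmadd: skipping %s (collinear with accepted set)", regs[j])
            pval[j] = 1.0
            continue
        _, t, p = _joint_ols(cols, s)
        pval[j], tstat[j] = p[-1], t[-1]
        if len(chosen) < cfg.max_terms and p[-1] < cfg.alpha_add and t[-1] > 0:
            chosen.append(j)
            selected[j] = True
    if chosen:
        _, t_fin, p_fin = _joint_ols(scores[:, chosen], s)
        for i, j in enumerate(chosen):
            pval[j], tstat[j] = p_fin[i], t_fin[i]
    res = _frame(
        regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), tstat, np.nan, pval, selected
    )
    res.attrs["selected_order"] = [regs[j] for j in chosen]
    return res


def test_areamir(signal: pd.Series, tc: TargetCollection) -> pd.DataFrame:
    """Score-weighted analytic rank enrichment (aREA-style z-statistic).

    Signal values are rank-transformed to normal quantiles
    q_i = ndtri(rank_i / (n+1)) (most downregulated -> most negative q,
    average ranks on ties); each regulator weights its targets by repression
    magnitude w = max(0, -score) and scores

        z = sum(w * (q - mean q)) / sd_perm,
        sd_perm^2 = sum((w - mean w)^2) * sum((q - mean q)^2) / (n - 1),

    the exact mean and variance of the weighted sum under random permutation
    of the signal, so z is unit-variance under the null even with heavily
    tied signals (BH-adjusted FDRs tie in plateaus) and sparse weights.  For
    a single weighted feature z reduces to its quantile q_i up to the
    finite-population factor.  Negative z means the targets sit low in the
    ranking (regulator active in a gain-of-function design); p is two-sided
    normal.
    """
    _, feats, regs, sites, scores, s = _signal_inputs(signal, tc)
    n = len(feats)
    if n < 10:
        raise DEAError("need at least 10 universe features for rank enrichment")
    q = ndtri(stats.rankdata(s) / (n + 1.0))
    qc = q - q.mean()
    W = np.maximum(0.0, -scores)
    sq = (qc**2).sum() / (n - 1)
    denom = np.sqrt(((W - W.mean(axis=0)) ** 2).sum(axis=0) * sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W.T @ qc) / denom
    z = np.where(denom > 0, z, np.nan)
    p = np.where(np.isnan(z), np.nan, _clip_p(2.0 * stats.norm.sf(np.abs(z))))
    return _frame(regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), z, np.nan, p)


def test_regmir(
    signal: pd.Series, tc: TargetCollection, cfg: TestConfig | None = None
) -> pd.DataFrame:
    """Regularised regression to select regulators, followed by OLS testing.

    The feature × regulator matrix of repression magnitudes (max(0, -score),
    columns standardised so the penalty is scale-free) enters a lasso with
    k-fold cross-validation; the penalty is chosen by the 1-SE rule (largest
    penalty whose CV error is within one standard error of the minimum).
    The surviving support is re-fit by joint OLS: selected regulators carry
    their OLS coefficient p, the rest p = 1.
    """
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import KFold

    cfg = cfg or TestConfig()
    _, feats, regs, sites, scores, s = _signal_inputs(signal, tc)
    W = np.maximum(0.0, -scores)
    sd = W.std(axis=0)
    ok = sd > 0
    X = np.zeros_like(W)
    X[:, ok] = (W[:, ok] - W[:, ok].mean(axis=0)) / sd[ok]
    pval = np.full(len(regs), np.nan)
    tstat = np.full(len(regs), np.nan)
    selected = np.zeros(len(regs), dtype=bool)
    pval[ok] = 1.0
    support: np.ndarray = np.array([], dtype=int)
    if ok.any() and np.ptp(s) > 0:
        cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        lcv = LassoCV(cv=cv, alphas=60, max_iter=5000).fit(X[:, ok], s)
        mse = lcv.mse_path_.mean(axis=1)
        i_min = int(np.argmin(mse))
        alpha = lcv.alphas_[i_min]
        if cfg.lambda_rule == "1se":
            se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
            within = np.where(mse <= mse[i_min] + se[i_min])[0]
            alpha = lcv.alphas_[within].max()  # alphas_ descending: max = sparsest
        coef = Lasso(alpha=alpha, max_iter=5000).fit(X[:, ok], s).coef_
        if not np.any(coef != 0) and cfg.lambda_rule == "1se":
            coef = Lasso(alpha=lcv.alphas_[i_min], max_iter=5000).fit(X[:, ok], s).coef_
        support = np.where(ok)[0][coef != 0]
    if support.size:
        _, t, p = _joint_ols(X[:, support], s)
        pval[support] = p
        tstat[support] = t
        selected[support] = True
    else:
        log.warning("regmir: empty lasso support; reporting p = 1 for all regulators")
    return _frame(
        regs, (sites > 0).sum(axis=0), _n_sig_targets(sites, s), tstat, np.nan, pval, selected
    )


def _gsea_es_from_positions(pos: np.ndarray, w_abs: np.ndarray, N: int) -> np.ndarray:
    """Enrichment scores for row-wise target positions on a ranked list.

    ``pos``: (B, K) 0-based positions (each row sorted ascending) of the
    target features in the descending-signal ranking; ``w_abs``: |signal| at
    every rank.  Weight exponent 1; zero total weight in a set falls back to
    uniform hit increments.  The running sum's extrema occur at hit
    positions (maxima) or just before them / at the end (minima), so only
    target positions are visited.
    """
    B, K = pos.shape
    w = w_abs[pos]
    NR = w.sum(axis=1, keepdims=True)
    zero = NR[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        NR = w.sum(axis=1, keepdims=True)
    H = np.cumsum(w, axis=1) / NR
    j = np.arange(1, K + 1)
    miss = 1.0 / (N - K)
    after = H - (pos + 1 - j) * miss
    pre = np.concatenate([np.zeros((B, 1)), H[:, :-1]], axis=1) - (pos - j + 1) * miss
    pos_max = after.max(axis=1)
    neg_min = np.minimum(pre.min(axis=1), 0.0)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def test_gsea(
    signal: pd.Series,
    tc: TargetCollection,
    cfg: TestConfig | None = None,
    min_size: int = 5,
    max_frac: float = 0.5,
) -> pd.DataFrame:
    """Classic weighted running-sum gene-set enrichment of each target set.

    Features are ranked by descending signal; the running sum gains
    |s|/sum(|s| in set) at targets and loses 1/(N-K) elsewhere; the ES is
    the maximum deviation from zero (in [-1, 1]; negative = targets near the
    bottom, i.e. downregulated).  p-values come from seeded gene-label
    permutations with the (b+1)/(nperm+1) estimator, two-sided on |ES|, so
    p > 0 always.  Target sets outside [min_size, max_frac * N] are reported
    untestable.
    """
    cfg = cfg or TestConfig()
    _, feats, regs, sites, _, s = _signal_inputs(signal, tc)
    N = len(feats)
    order = np.argsort(-s, kind="stable")
    w_abs = np.abs(s)[order]
    rank_of = np.empty(N, dtype=int)
    rank_of[order] = np.arange(N)
    rng = np.random.default_rng(cfg.seed)
    es = np.full(len(regs), np.nan)
    pval = np.full(len(regs), np.nan)
    K_all = (sites > 0).sum(axis=0)
    for jreg in range(len(regs)):
        K = int(K_all[jreg])
        if K < min_size or K > max_frac * N:
            if K > 0:
                log.info("gsea: %s untestable (set size %d outside bounds)", regs[jreg], K)
            continue
        pos = np.sort(rank_of[sites[:, jreg] > 0])[None, :]
        es_obs = _gsea_es_from_positions(pos, w_abs, N)[0]
        perm = np.sort(
            rng.permuted(np.tile(np.arange(N), (cfg.nperm, 1)), axis=1)[:, :K], axis=1
        )
        es_perm = _gsea_es_from_positions(perm, w_abs, N)
        b = int((np.abs(es_perm) >= abs(es_obs)).sum())
        es[jreg] = es_obs
        pval[jreg] = (b + 1.0) / (cfg.nperm + 1.0)
    return _frame(regs, K_all, _n_sig_targets(sites, s), es, np.nan, pval)


# ---------------------------------------------------------------------------
# multiple testing and dispatch
# ---------------------------------------------------------------------------


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-NA entries; NA preserved."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


_DISPATCH = {
    "overlap": ("binary", lambda sets, tc, sig, cfg: test_overlap(sets, tc)),
    "siteoverlap": ("binary", lambda sets, tc, sig, cfg: test_siteoverlap(sets, tc)),
    "woverlap": ("binary", lambda sets, tc, sig, cfg: test_woverlap(sets, tc)),
    "ks": ("continuous", lambda sets, tc, sig, cfg: test_rank(sig, tc, "ks")),
    "mw": ("continuous", lambda sets, tc, sig, cfg: test_rank(sig, tc, "mw")),
    "modsites": ("continuous", lambda sets, tc, sig, cfg: test_linreg(sig, tc, "sites")),
    "modscore": ("continuous", lambda sets, tc, sig, cfg: test_linreg(sig, tc, "score")),
    "ebayes": ("continuous", lambda sets, tc, sig, cfg: test_ebayes(sig, tc)),
    "lmadd": ("continuous", lambda sets, tc, sig, cfg: test_lmadd(sig, tc, cfg)),
    "areamir": ("continuous", lambda sets, tc, sig, cfg: test_areamir(sig, tc)),
    "regmir": ("continuous", lambda sets, tc, sig, cfg: test_regmir(sig, tc, cfg)),
    "gsea": ("continuous", lambda sets, tc, sig, cfg: test_gsea(sig, tc, cfg)),
}


def run_enrichment(
    data: pd.DataFrame | GeneSetPair,
    tc: TargetCollection,
    test: str,
    cfg: TestConfig | None = None,
) -> pd.DataFrame:
    """Single entry point: dispatch a named test, BH-correct and sort.

    ``data`` is either a normalised DEA frame or a :class:`GeneSetPair`.
    Binary tests fed a DEA derive the default selected set (FDR < 0.05,
    downregulated) with a logged notice; continuous tests require a DEA — a
    bare gene set carries no signal to regress on.  The rank tests (ks, mw)
    are fed the raw logFC vector, which is tie-free, rather than the default
    FDR-derived signal whose BH plateaus would make KS conservative; the
    other continuous tests use the default signal.
    """
    if test not in _DISPATCH:
        raise ValueError(f"unknown test '{test}'; choose from {', '.join(ALL_TESTS)}")
    cfg = cfg or TestConfig()
    kind, fn = _DISPATCH[test]
    sets, sig = None, None
    if isinstance(data, GeneSetPair):
        if kind == "continuous":
            raise DEAError(
                f"test '{test}' needs a continuous signal; a gene set alone cannot provide one"
            )
        sets = data
    else:
        dea = validate_dea(data)
        if kind == "binary":
            log.info("binary test '%s' on a DEA input: deriving default selected set", test)
            sets = derive_sets(
                dea, alpha=cfg.sel_alpha, direction=cfg.sel_direction, use=cfg.sel_use
            )
        elif test in ("ks", "mw"):
            sig = pd.Series(
                dea["logFC"].to_numpy(), index=pd.Index(dea["feature"], name="feature")
            )
        else:
            sig = compute_signal(dea)
    res = fn(sets, tc, sig, cfg)
    if not isinstance(data, GeneSetPair) and test in ("ks", "mw"):
        # n_selected_targets is defined on the default signal (FDR < 0.05
        # and downregulated), not on the logFC vector the rank test used
        sig0 = compute_signal(dea)
        down = set(sig0.index[sig0.to_numpy() < _SIG_SIGNAL])
        rec = tc.records[tc.records["feature"].isin(set(dea["feature"]))]
        counts = rec[rec["feature"].isin(down)].groupby("regulator").size()
        res["n_selected_targets"] = (
            res["regulator"].map(counts).fillna(0.0).astype(float)
        )
    res["fdr"] = adjust_bh(res["pvalue"].to_numpy())
    res = res.sort_values(
        by=["pvalue", "enrichment", "regulator"],
        key=lambda c: -c.abs() if c.name == "enrichment" else c,
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    res.attrs["test"] = test
    return res


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table as CSV with the stable column order, NA as 'NA'."""
    results[RESULT_COLUMNS].to_csv(path, index=False, na_rep="NA")
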