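"""Group-level inference for decoding analyses.

Implements the full statistical menu used downstream of the decoder: pointwise
t-tests against chance with Bonferroni correction, nonparametric cluster-based
permutation t-tests on 1D time courses and 2D time-by-time grids, Spearman
correlations, default-prior (JZS) Bayes factors, TOST equivalence tests, Welch
t-tests, logistic regression of tinnitus status on the prediction score with a
hearing covariate, and the trial-subsampling Bayes-factor curve.

The cluster test follows the nonparametric maxsum convention: pointwise t maps
are thresholded at a parametric t quantile (``cluster_alpha``), contiguous
supra-threshold points (time-adjacency in 1D, 4-neighborhood in 2D) form
clusters scored by their summed t, and the null distribution is the maximum
cluster score over random relabelings, with the (b+1)/(m+1) p estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage
from scipy import stats as sps

TAILS = ("two_sided", "one_sided_pos", "one_sided_neg")


# ---------------------------------------------------------------------------
# pointwise tests


def pointwise_vs_chance(acc: np.ndarray, chance: float = 0.25, alpha: float = 0.05) -> dict:
    """One-sample t-test per time point against chance, Bonferroni over points.

    ``acc`` is subjects x time points.  Points with zero variance yield an
    undefined t and are reported non-significant with a warning.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise ValueError("need a subjects x timepoints array with >= 2 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_1samp(acc, popmean=chance, axis=0)
    bad = ~np.isfinite(t)
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} time point(s) have zero variance; treated as non-significant"
        )
        p = np.where(bad, 1.0, p)
        t = np.where(bad, 0.0, t)
    n_tests = acc.shape[1]
    return {
        "t": t,
        "p": p,
        "significant": p < alpha / n_tests,
        "alpha_corrected": alpha / n_tests,
        "n_tests": n_tests,
    }


# ---------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class Cluster:
    indices: np.ndarray           # flat indices into the raveled grid
    t_sum: float
    p_perm: float


@dataclass
class ClusterTestResult:
    clusters: list
    t_obs: np.ndarray
    threshold: float
    n_permutations: int
    cluster_alpha: float
    tail: str
    grid_shape: tuple

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_perm <= alpha]

    def mask(self, alpha: float = 0.05) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool).ravel()
        for c in self.significant(alpha):
            m[c.indices] = True
        return m.reshape(self.grid_shape)


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _t_indep(data: np.ndarray, na: int) -> np.ndarray:
    """Pooled-variance two-sample t: first na rows vs the rest."""
    a, b = data[:na], data[na:]
    nb = b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1.0 / na + 1.0 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def _find_clusters(tmap: np.ndarray, threshold: float, tail: str):
    """Maximal contiguous supra-threshold clusters and their summed t."""
    if tmap.ndim == 1:
        structure = np.ones(3, dtype=bool)
    elif tmap.ndim == 2:
        structure = ndimage.generate_binary_structure(2, 1)  # 4-neighborhood
    else:
        raise ValueError("only 1D and 2D grids are supported")
    out = []
    signs = {"two_sided": (1, -1), "one_sided_pos": (1,), "one_sided_neg": (-1,)}[tail]
    for sign in signs:
        above = sign * tmap > threshold
        labels, n = ndimage.label(above, structure=structure)
        for lab in range(1, n + 1):
            idx = np.flatnonzero(labels.ravel() == lab)
            out.append((idx, float(tmap.ravel()[idx].sum())))
    return out


def _max_cluster_stat(tmap, threshold, tail) -> float:
    sums = [s for _, s in _find_clusters(tmap, threshold, tail)]
    if not sums:
        return 0.0
    if tail == "two_sided":
        return max(abs(s) for s in sums)
    if tail == "one_sided_pos":
        return max(sums)
    return -min(sums)  # magnitude of the most negative cluster


def cluster_perm_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray | None = None,
    tail: str = "two_sided",
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed=None,
) -> ClusterTestResult:
    """Cluster-based permutation t-test on a 1D or 2D grid.

    Two-sample mode (``scores_b`` given) permutes group labels of an
    independent-samples pooled-variance t; one-sample mode (``scores_b=None``)
    tests the per-subject maps against zero with sign-flip permutations.
    ``tail`` controls both the cluster-forming threshold and which clusters are
    scored; p-values use the (b+1)/(m+1) estimator against the permutation
    distribution of the maximum cluster score.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    a = np.asarray(scores_a, dtype=float)
    grid_shape = a.shape[1:]
    a2 = a.reshape(a.shape[0], -1)
    rng = np.random.default_rng(seed)

    if scores_b is not None:
        b = np.asarray(scores_b, dtype=float)
        if b.shape[1:] != grid_shape:
            raise ValueError("the two groups must share one grid")
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need >= 2 subjects per group")
        na = a.shape[0]
        data = np.concatenate([a2, b.reshape(b.shape[0], -1)], axis=0)
        n_total = data.shape[0]
        n_distinct = math.comb(n_total, na)
        if n_distinct < n_perm:
            raise ValueError(
                f"only {n_distinct} distinct relabelings exist; "
                f"reduce n_perm or add subjects"
            )
        df = n_total - 2
        t_obs = _t_indep(data, na)

        def perm_stat():
            order = rng.permutation(n_total)
            return _t_indep(data[order], na)

    else:
        if a.shape[0] < 2:
            raise ValueError("need >= 2 subjects")
        n = a.shape[0]
        if 2**min(n, 62) < n_perm:
            raise ValueError(
                f"only {2**n} distinct sign flips exist; reduce n_perm or add subjects"
            )
        df = n - 1
        t_obs = _t_one_sample(a2)

        def perm_stat():
            signs = rng.choice([-1.0, 1.0], size=(a2.shape[0], 1))
            return _t_one_sample(a2 * signs)

    if tail == "two_sided":
        threshold = sps.t.ppf(1.0 - cluster_alpha / 2.0, df)
    else:
        threshold = sps.t.ppf(1.0 - cluster_alpha, df)

    t_grid = t_obs.reshape(grid_shape)
    observed = _find_clusters(t_grid, threshold, tail)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        null_max[i] = _max_cluster_stat(perm_stat().reshape(grid_shape), threshold, tail)

    clusters = []
    for idx, s in observed:
        stat = abs(s) if tail == "two_sided" else (s if tail == "one_sided_pos" else -s)
        p = (1.0 + np.sum(null_max >= stat)) / (n_perm + 1.0)
        clusters.append(Cluster(indices=idx, t_sum=s, p_perm=float(p)))
    clusters.sort(key=lambda c: c.p_perm)
    return ClusterTestResult(
        clusters=clusters,
        t_obs=t_grid,
        threshold=float(threshold),
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        tail=tail,
        grid_shape=grid_shape,
    )


# ---------------------------------------------------------------------------
# correlations and t-tests


def spearman(x, y) -> dict:
    """Spearman rank correlation with tie-corrected ranks and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho is undefined")
        return {"rho": float("nan"), "p": float("nan"), "n": len(x), "valid": False}
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(x), "valid": True}


def welch_t(a, b) -> dict:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups: Welch t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def tost_equivalence(a, b, bounds: float, standardized: bool = True, alpha: float = 0.05) -> dict:
    """Two one-sided Welch tests against symmetric bounds ±delta.

    ``bounds`` is delta > 0, in pooled-sd units when ``standardized`` (default)
    or raw units otherwise.  Equivalence is claimed iff both one-sided p-values
    are below ``alpha``.
    """
    if bounds <= 0:
        raise ValueError("equivalence bounds must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if standardized:
        sd_pool = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        delta = bounds * sd_pool
    else:
        delta = bounds
    se = math.sqrt(va / na + vb / nb)
    if se == 0:
        raise ValueError("zero variance: TOST undefined")
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    diff = a.mean() - b.mean()
    t_lower = (diff + delta) / se     # H0: diff <= -delta, H1: diff > -delta
    t_upper = (diff - delta) / se     # H0: diff >= +delta, H1: diff < +delta
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    return {
        "equivalent": p_lower < alpha and p_upper < alpha,
        "p_lower": p_lower,
        "p_upper": p_upper,
        "t_lower": float(t_lower),
        "t_upper": float(t_upper),
        "df": float(df),
        "delta_raw": float(delta),
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# JZS Bayes factors


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior_scale: float
    test: str                     # "two_sample" | "one_sample"
    t: float
    df: float
    n_eff: float

    def __post_init__(self) -> None:
        if self.bf10 <= 0:
            raise ValueError("bf10 must be positive")

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _jzs_bf_from_t(t: float, n_eff: float, df: float, prior_scale: float) -> float:
    """JZS Bayes factor by quadrature over the g-prior mixture.

    The effect-size prior is Cauchy(0, r), represented as a normal scale
    mixture with g ~ InverseGamma(1/2, r^2/2); the marginal likelihood under
    the alternative integrates the scaled t likelihood over g.
    """
    r2 = prior_scale**2

    def integrand(g):
        return (
            (1.0 + n_eff * g) ** -0.5
            * (1.0 + t * t / ((1.0 + n_eff * g) * df)) ** (-(df + 1.0) / 2.0)
            * prior_scale
            / math.sqrt(2.0 * math.pi)
            * g**-1.5
            * math.exp(-r2 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * max(num, 1e-300):
        raise RuntimeError(
            f"JZS integration failed: integral={num}, abserr={err}, t={t}, df={df}"
        )
    den = (1.0 + t * t / df) ** (-(df + 1.0) / 2.0)
    return num / den


def jzs_bf_two_sample(a, b, prior_scale: float = math.sqrt(2) / 2.0) -> BayesFactorResult:
    """Default-prior Bayes factor for a two-sample t-test (H1 vs point null)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    n_eff = na * nb / (na + nb)
    df = na + nb - 2
    bf = _jzs_bf_from_t(float(res.statistic), n_eff, df, prior_scale)
    return BayesFactorResult(
        bf10=bf, prior_scale=prior_scale, test="two_sample",
        t=float(res.statistic), df=float(df), n_eff=float(n_eff),
    )


def jzs_bf_one_sample(x, mu: float = 0.0, prior_scale: float = math.sqrt(2) / 2.0) -> BayesFactorResult:
    """Default-prior Bayes factor for a one-sample t-test against ``mu``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 observations")
    res = sps.ttest_1samp(x, popmean=mu)
    bf = _jzs_bf_from_t(float(res.statistic), float(n), float(n - 1), prior_scale)
    return BayesFactorResult(
        bf10=bf, prior_scale=prior_scale, test="one_sample",
        t=float(res.statistic), df=float(n - 1), n_eff=float(n),
    )


# ---------------------------------------------------------------------------
# logistic model of tinnitus status


@dataclass
class LogisticModelResult:
    coefficients: dict            # name -> {"coef", "se", "p"}
    odds_ratio_per_sd: float
    score_sd: float
    reversed_model: dict          # linear model score ~ group
    separation: bool = False


def logistic_tinnitus_model(
    prediction_score: np.ndarray,
    group: np.ndarray,
    pta: np.ndarray | None = None,
) -> LogisticModelResult:
    """Logistic regression of tinnitus status on the prediction score.

    ``group`` holds "tinnitus"/"control" labels (or 0/1 with 1 = tinnitus);
    ``pta`` optionally adds the mean hearing threshold as a covariate (standard
    PTA-4 or the extended variant — the caller chooses which values to pass).
    Also fits the reversed linear model (score on group).  Perfect separation
    is detected and reported explicitly rather than silently diverging.
    """
    import statsmodels.api as sm

    score = np.asarray(prediction_score, dtype=float)
    g = np.asarray(group)
    y = (g == "tinnitus").astype(float) if g.dtype.kind in "UOS" else g.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    cols = {"prediction_score": score}
    if pta is not None:
        cols["pta"] = np.asarray(pta, dtype=float)
    X = sm.add_constant(np.column_stack(list(cols.values())))
    names = ["const"] + list(cols)

    separation = False
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError(f"perfect separation detected: {exc}") from exc
    if np.any(~np.isfinite(fit.bse)) or np.any(fit.bse > 1e6):
        separation = True

    coefficients = {
        name: {"coef": float(fit.params[i]), "se": float(fit.bse[i]), "p": float(fit.pvalues[i])}
        for i, name in enumerate(names)
    }
    sd = float(score.std(ddof=1))
    odds_ratio = float(np.exp(coefficients["prediction_score"]["coef"] * sd))

    rev = sm.OLS(score, sm.add_constant(y)).fit()
    reversed_model = {
        "coef": float(rev.params[1]),
        "se": float(rev.bse[1]),
        "p": float(rev.pvalues[1]),
    }
    return LogisticModelResult(
        coefficients=coefficients,
        odds_ratio_per_sd=odds_ratio,
        score_sd=sd,
        reversed_model=reversed_model,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# trial-subsampling Bayes-factor curve


def subsample_bf_curve(
    cohort,
    trial_counts=(200, 750, 1500, 3600),
    seed=None,
    decoder_cfg=None,
    windows=None,
    test_condition: str = "ordered",
    prior_scale: float = math.sqrt(2) / 2.0,
    at_test_time_s: float | None = -0.38,
) -> dict:
    """Group-difference Bayes factor as a function of the number of trials.

    For each requested per-condition trial count, trials are redrawn balanced
    across carrier frequencies (count/K per tone) in both the training (random)
    and testing conditions of every subject, the decoding + prediction-score
    pipeline is rerun, and a two-sample JZS Bayes factor compares the subjects'
    scores between groups.  The per-subject score is the windowed time course
    read out at ``at_test_time_s`` (default −380 ms, the peak-difference time
    point) or, with ``at_test_time_s=None``, the mean over the testing window.
    Counts exceeding availability are skipped with a warning.  A count equal to
    the full trial number reproduces the non-subsampled analysis.
    """
    from .decoding import DecoderConfig, cross_decode, cv_decode_random
    from .scores import WindowSpec, diff_score, window_score

    windows = windows or WindowSpec()
    decoder_cfg = decoder_cfg or DecoderConfig(train_window_s=windows.train_window_s)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = {}
    for count, count_ss in zip(trial_counts, ss.spawn(len(trial_counts))):
        rng = np.random.default_rng(count_ss)
        scores = {"tinnitus": [], "control": []}
        skip = False
        for spec, epochs in cohort:
            sub = {}
            for cond in (decoder_cfg.train_condition, test_condition):
                ep = epochs.sound_trials(cond)
                if count > ep.n_trials:
                    skip = True
                    break
                classes = np.unique(ep.labels)
                per_class = count // len(classes)
                idx = []
                for tone in classes:
                    # balanced across carrier frequencies; a class whose pool
                    # falls short of the per-class target contributes all of it
                    pool = np.flatnonzero(ep.labels == tone)
                    take = (
                        pool
                        if len(pool) <= per_class
                        else rng.choice(pool, size=per_class, replace=False)
                    )
                    idx.append(take)
                sub[cond] = ep.select(np.sort(np.concatenate(idx)))
            if skip:
                break
            _, tg_random, _ = cv_decode_random(sub[decoder_cfg.train_condition], decoder_cfg)
            tg_test = cross_decode(
                sub[decoder_cfg.train_condition], sub[test_condition], decoder_cfg
            )
            sc = diff_score(tg_test, tg_random)
            ws = window_score(sc, windows, at_test_time_s=at_test_time_s)
            scores[spec.group].append(
                ws["window_mean"] if at_test_time_s is None else ws["at_time_value"]
            )
        if skip:
            warnings.warn(f"trial count {count} exceeds availability; skipped")
            continue
        bf = jzs_bf_two_sample(scores["tinnitus"], scores["control"], prior_scale)
        out[int(count)] = bf.bf10
    return out
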