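"""Mutation-rate estimation, between-line variability and spatial clustering.

The per-site per-generation mutation rate is μ = Nμ / (Nc × Nlines × t),
with Nμ the mutation count, Nc the callable genome length (bp), Nlines the
number of MA lines and t the generations elapsed. Between-line variation
is characterized by maximum-likelihood distribution fits (AIC-ranked),
an overdispersion ratio against the Poisson expectation with a
parametric-bootstrap KS test, and a neutral Poisson accumulation
simulation. Spatial clustering is tested through inter-mutation distances
(IMD) and windowed mutation counts against equal-count uniform placements
on callable sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallableMask
from .types import Mutation


@dataclass(frozen=True)
class RateEstimate:
    n_mu: float
    n_c: float
    n_lines: float
    t: float
    mu: float
    stratum: str = "genome"

    def scaled(self, factor: float = 1e10) -> float:
        """Rate expressed in units of 1/factor (e.g. 1e-10 per site per gen)."""
        return self.mu * factor


def mutation_rate(n_mu: float, n_c: float, n_lines: float, t: float,
                  stratum: str = "genome") -> RateEstimate:
    """μ = Nμ / (Nc × Nlines × t); exact quotient.

    Stratified estimates (per line, contig, feature or variant class)
    adjust numerator and denominator accordingly — e.g. per-line-per-
    generation rates use ``n_c=1, n_lines=number of lines``.
    """
    if n_c <= 0 or n_lines <= 0 or t <= 0:
        raise ValueError("Nc, Nlines and t must be positive")
    if n_mu < 0:
        raise ValueError("Nmu must be >= 0")
    return RateEstimate(n_mu, n_c, n_lines, t,
                        mu=n_mu / (n_c * n_lines * t), stratum=stratum)


def generations_from_colonies(n0: float, nt: float) -> float:
    """Generations across one growth assay: t = (log Nt − log N0) / log 2."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("colony counts must be positive")
    return math.log2(nt / n0)


def line_generations(meta: list, default: float | None = None) -> pd.Series:
    """Total generations per line, summing per-transfer assays.

    Lines without assays receive the mean of measured lines (or ``default``).
    """
    measured = {}
    missing = []
    for lm in meta:
        if lm.assays:
            measured[lm.line_id] = sum(generations_from_colonies(a, b)
                                       for a, b in lm.assays)
        else:
            missing.append(lm.line_id)
    fallback = default if default is not None else (
        float(np.mean(list(measured.values()))) if measured else np.nan)
    out = dict(measured)
    out.update({line: fallback for line in missing})
    return pd.Series(out)


# ---------------------------------------------------------------------------
# distribution fitting

@dataclass
class DistributionFit:
    name: str
    params: dict
    loglik: float
    aic: float
    ks_d: float
    ks_p: float
    ok: bool = True
    message: str = ""


def _ll_poisson(x, lam):
    if lam <= 0:
        return -np.inf
    return float(np.sum(stats.poisson.logpmf(np.round(x).astype(int), lam)))


def fit_count_distributions(values) -> list[DistributionFit]:
    """Fit normal, lognormal, gamma, Poisson and exponential distributions.

    Maximum-likelihood fits ranked by AIC (lowest first); a KS statistic
    against each fitted distribution is reported alongside. The AIC
    comparison mixes discrete and continuous families applied to the same
    numeric vector — a documented caveat of the procedure this mirrors.
    Degenerate input (all values equal) fails the scale-parameter families.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    fits: list[DistributionFit] = []
    integral = np.allclose(x, np.round(x)) and (x >= 0).all()
    degenerate = np.ptp(x) == 0

    def _add(name, params, loglik, k, dist):
        if not np.isfinite(loglik):
            fits.append(DistributionFit(name, params, -np.inf, np.inf,
                                        np.nan, np.nan, ok=False,
                                        message="non-finite likelihood"))
            return
        d, p = stats.kstest(x, dist.cdf)
        fits.append(DistributionFit(name, params, loglik,
                                    2 * k - 2 * loglik, float(d), float(p)))

    # normal
    mu, sd = x.mean(), x.std(ddof=0)
    if sd > 0:
        _add("normal", {"mean": mu, "sd": sd},
             float(np.sum(stats.norm.logpdf(x, mu, sd))), 2,
             stats.norm(mu, sd))
    else:
        fits.append(DistributionFit("normal", {}, -np.inf, np.inf, np.nan,
                                    np.nan, ok=False, message="degenerate"))
    # lognormal / gamma / exponential need positive values
    if (x > 0).all() and not degenerate:
        lx = np.log(x)
        ml, sl = lx.mean(), lx.std(ddof=0)
        _add("lognormal", {"meanlog": ml, "sdlog": sl},
             float(np.sum(stats.lognorm.logpdf(x, sl, scale=np.exp(ml)))), 2,
             stats.lognorm(sl, scale=np.exp(ml)))
        try:
            a, _, scale = stats.gamma.fit(x, floc=0)
            _add("gamma", {"shape": a, "scale": scale},
                 float(np.sum(stats.gamma.logpdf(x, a, scale=scale))), 2,
                 stats.gamma(a, scale=scale))
        except Exception as exc:  # pragma: no cover - scipy fit failure
            fits.append(DistributionFit("gamma", {}, -np.inf, np.inf, np.nan,
                                        np.nan, ok=False, message=str(exc)))
        lam_e = 1 / x.mean()
        _add("exponential", {"rate": lam_e},
             float(np.sum(stats.expon.logpdf(x, scale=1 / lam_e))), 1,
             stats.expon(scale=1 / lam_e))
    else:
        for name in ("lognormal", "gamma", "exponential"):
            fits.append(DistributionFit(name, {}, -np.inf, np.inf, np.nan,
                                        np.nan, ok=False,
                                        message="requires positive, "
                                                "non-degenerate values"))
    # Poisson (discrete; meaningful for count-valued input)
    lam = x.mean()
    if integral and lam > 0:
        ll = _ll_poisson(x, lam)
        d, p = stats.kstest(x, stats.poisson(lam).cdf)
        fits.append(DistributionFit("poisson", {"lam": lam}, ll, 2 - 2 * ll,
                                    float(d), float(p)))
    else:
        fits.append(DistributionFit("poisson", {}, -np.inf, np.inf, np.nan,
                                    np.nan, ok=False,
                                    message="non-integral or zero-mean input"))
    fits.sort(key=lambda f: f.aic)
    return fits


# ---------------------------------------------------------------------------
# overdispersion

@dataclass
class OverdispersionResult:
    lam: float            # mean count per line
    variance: float       # between-line sample variance
    ratio: float          # variance / mean
    ks_d: float
    ks_p: float           # parametric-bootstrap p-value
    n_lines: int
    excluded: list = field(default_factory=list)


def overdispersion_test(per_line_counts, exclusions: list | None = None,
                        n_boot: int = 2000, seed: int = 0
                        ) -> OverdispersionResult:
    """Between-line variance against the Poisson expectation.

    λ is the mean count per line (equal generations across lines are
    assumed), σ² the sample variance; the ratio σ²/λ is ~1 under Poisson.
    The KS statistic against Poisson(λ) gets a discreteness-safe p-value
    by parametric bootstrap: counts are re-drawn from Poisson(λ̂) with λ
    re-estimated per replicate.
    """
    counts = pd.Series(per_line_counts, dtype=float)
    excluded = list(exclusions or [])
    counts = counts.drop(index=excluded, errors="ignore")
    if len(counts) < 2:
        raise ValueError("need at least 2 lines after exclusions")
    x = counts.to_numpy()
    lam = float(x.mean())
    var = float(x.var(ddof=1))
    ratio = var / lam if lam > 0 else 0.0
    if lam > 0:
        d_obs = float(stats.kstest(x, stats.poisson(lam).cdf).statistic)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_boot):
            sim = rng.poisson(lam, size=len(x))
            lam_b = sim.mean()
            d_b = stats.kstest(sim, stats.poisson(max(lam_b, 1e-12)).cdf
                               ).statistic
            if d_b >= d_obs:
                exceed += 1
        p = (exceed + 1) / (n_boot + 1)
    else:
        d_obs, p = 0.0, 1.0
    return OverdispersionResult(lam=lam, variance=var, ratio=ratio,
                                ks_d=d_obs, ks_p=p, n_lines=len(x),
                                excluded=excluded)


@dataclass
class PoissonSimResult:
    median_variance: float
    ci_low: float     # 2.5 percentile of per-replicate variances
    ci_high: float    # 97.5 percentile
    lam: float
    variances: np.ndarray


def simulate_poisson_ma(mu: float, n_c: float, n_lines: int, t: float,
                        reps: int = 1000, seed: int = 0) -> PoissonSimResult:
    """Neutral accumulation null: per-line counts ~ Poisson(μ·Nc·t).

    Each replicate draws ``n_lines`` independent counts and records their
    sample variance; the summary is the median and central 95% interval
    over replicates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mu < 0 or n_c <= 0 or n_lines < 2 or t <= 0:
        raise ValueError("invalid simulation parameters")
    lam = mu * n_c * t
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(reps, n_lines))
    variances = counts.var(axis=1, ddof=1)
    lo, med, hi = np.percentile(variances, [2.5, 50, 97.5])
    return PoissonSimResult(median_variance=float(med), ci_low=float(lo),
                            ci_high=float(hi), lam=float(lam),
                            variances=variances)


# ---------------------------------------------------------------------------
# spatial clustering

def _ks_d(sample: np.ndarray, pooled_sorted: np.ndarray) -> float:
    """Two-sample KS statistic of ``sample`` against a large pooled sample."""
    s = np.sort(sample)
    n = len(s)
    cdf1 = np.arange(1, n + 1) / n
    cdf2 = np.searchsorted(pooled_sorted, s, side="right") / len(pooled_sorted)
    d_plus = np.max(np.abs(cdf1 - cdf2))
    cdf2_lo = np.searchsorted(pooled_sorted, s, side="left") / len(pooled_sorted)
    d_minus = np.max(np.abs(cdf2_lo - np.arange(0, n) / n))
    return float(max(d_plus, d_minus))


@dataclass
class ImdResult:
    observed: np.ndarray        # pooled within-contig IMDs (bp)
    ks_d: float
    ks_p: float                 # Monte-Carlo p-value
    n_null_iters: int
    short_range: pd.DataFrame   # <10 bp excess breakdown
    null_mean_short: float


def _imds(positions_by_contig: dict[str, np.ndarray]) -> np.ndarray:
    out = []
    for pos in positions_by_contig.values():
        if len(pos) >= 2:
            out.append(np.diff(np.sort(pos)))
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


def _sample_no_replace(rng, pool: np.ndarray, k: int) -> np.ndarray:
    """Uniform sample without replacement, O(k) for k << |pool|."""
    if k >= len(pool):
        return pool.copy()
    uniq = np.unique(rng.integers(0, len(pool), size=k))
    while len(uniq) < k:
        extra = rng.integers(0, len(pool), size=k - len(uniq))
        uniq = np.unique(np.concatenate([uniq, extra]))
    return pool[uniq]


def _null_positions(rng, callable_pos: dict[str, np.ndarray],
                    counts: dict[str, int]) -> dict[str, np.ndarray]:
    return {c: _sample_no_replace(rng, callable_pos[c], n)
            for c, n in counts.items() if n > 0 and len(callable_pos[c]) >= n}


def imd_test(mutations: list[Mutation], mask: CallableMask,
             iters: int = 1000, seed: int = 0,
             genome=None, short_range_bp: int = 10) -> ImdResult:
    """Inter-mutation distance clustering test.

    Observed IMDs are distances between successive SNMs on the same
    contig, pooled across lines, compared with IMDs of equal per-contig
    counts placed uniformly on callable sites. The KS statistic against
    the pooled null sample receives a Monte-Carlo p-value: the same
    statistic is computed for every null replicate and the observed value
    is ranked among them. A short-range (<``short_range_bp``) excess table
    reports adjacent-site pairs and, when the genome is supplied, the
    reference dinucleotide at adjacent pairs.
    """
    snms = [m for m in mutations if m.kind == "SNM"]
    by_contig = {}
    for m in snms:
        by_contig.setdefault(m.contig, []).append(m.pos)
    by_contig = {c: np.array(v) for c, v in by_contig.items()}
    observed = _imds(by_contig)
    if len(observed) == 0:
        return ImdResult(observed, np.nan, np.nan, 0,
                         pd.DataFrame(), np.nan)
    counts = {c: len(v) for c, v in by_contig.items()}
    callable_pos = {c: mask.positions(c) for c in counts}
    rng = np.random.default_rng(seed)
    null_samples = [_imds(_null_positions(rng, callable_pos, counts))
                    for _ in range(iters)]
    pooled = np.sort(np.concatenate(null_samples))
    d_obs = _ks_d(observed, pooled)
    d_null = np.array([_ks_d(s, pooled) for s in null_samples])
    p = (1 + int((d_null >= d_obs).sum())) / (iters + 1)
    # short-range excess
    obs_short = int((observed < short_range_bp).sum())
    null_short = float(np.mean([(s < short_range_bp).sum()
                                for s in null_samples]))
    adjacent = int((observed == 1).sum())
    rows = [{"metric": f"imd_lt_{short_range_bp}", "observed": obs_short,
             "null_mean": null_short},
            {"metric": "adjacent_pairs", "observed": adjacent,
             "null_mean": float(np.mean([(s == 1).sum()
                                         for s in null_samples]))}]
    if genome is not None and adjacent:
        dinucs: dict[str, int] = {}
        for c, pos in by_contig.items():
            sp = np.sort(pos)
            seq = genome.sequence(c)
            for a, b in zip(sp[:-1], sp[1:]):
                if b - a == 1:
                    d = seq[a:b + 1]
                    dinucs[d] = dinucs.get(d, 0) + 1
        for d, n in sorted(dinucs.items()):
            rows.append({"metric": f"adjacent_dinuc_{d}", "observed": n,
                         "null_mean": np.nan})
    return ImdResult(observed=observed, ks_d=d_obs, ks_p=p,
                     n_null_iters=iters,
                     short_range=pd.DataFrame(rows),
                     null_mean_short=null_short)


@dataclass
class WindowClusteringResult:
    per_size: pd.DataFrame   # window size, KS D, Monte-Carlo p


def window_clustering(mutations: list[Mutation], mask: CallableMask,
                      sizes=(1_000, 10_000, 100_000, 500_000),
                      iters: int = 1000, seed: int = 0
                      ) -> WindowClusteringResult:
    """Windowed mutation-count clustering test.

    Counts SNMs in non-overlapping windows tiled over each contig and
    compares the count distribution with equal-count uniform placements on
    callable sites, per window size, using the same Monte-Carlo KS scheme
    as :func:`imd_test`. Windows with no callable sites are dropped.
    """
    snms = [m for m in mutations if m.kind == "SNM"]
    if not snms:
        raise ValueError("no SNMs supplied")
    by_contig: dict[str, list[int]] = {}
    for m in snms:
        by_contig.setdefault(m.contig, []).append(m.pos)
    positions = {c: np.array(v) for c, v in by_contig.items()}
    counts = {c: len(v) for c, v in positions.items()}
    callable_pos = {c: mask.positions(c) for c in counts}
    contig_len = {c: (int(callable_pos[c].max()) + 1
                      if len(callable_pos[c]) else 0) for c in counts}
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        edges = {c: np.arange(0, contig_len[c] + size, size) for c in counts}
        has_callable = {
            c: np.histogram(callable_pos[c], bins=edges[c])[0] > 0
            for c in counts}

        def window_counts(pos_by_contig):
            out = []
            for c, pos in pos_by_contig.items():
                h = np.histogram(pos, bins=edges[c])[0]
                out.append(h[has_callable[c]])
            return np.concatenate(out) if out else np.array([])

        obs = window_counts(positions)
        null_samples = [window_counts(_null_positions(rng, callable_pos,
                                                      counts))
                        for _ in range(iters)]
        pooled = np.sort(np.concatenate(null_samples))
        d_obs = _ks_d(obs, pooled)
        d_null = np.array([_ks_d(s, pooled) for s in null_samples])
        p = (1 + int((d_null >= d_obs).sum())) / (iters + 1)
        rows.append({"window_size": int(size), "ks_d": d_obs, "p": p,
                     "n_windows": len(obs)})
    return WindowClusteringResult(per_size=pd.DataFrame(rows))


def compare_rate_distributions(counts_a, counts_b) -> tuple[float, float]:
    """Two-sample KS comparison of per-line rate (or count) distributions."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)
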