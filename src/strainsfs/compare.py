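"""Likelihood-ratio tests for equality of gamma DFEs between datasets,
with Bonferroni-corrected chi-square critical values, plus the
genus-contrast rank-sum / label-permutation analysis."""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2, gamma as gamma_dist, rankdata

from .demography import FitResult
from .dfe import (DFEFitResult, SpectraCache, _dfe_weights, fit_dfe,
                  poisson_loglik, THETA_RATIO_DEFAULT)
from .sfs import FoldedSFS

__all__ = [
    "LRTResult",
    "SpeciesData",
    "bonferroni_critical",
    "lrt_dfe_pair",
    "genus_contrast",
    "GenusContrastResult",
]


def bonferroni_critical(df: int = 2, alpha: float = 0.05, m: int = 1) -> float:
    """Upper-tail chi-square quantile at probability alpha / m.

    For df = 2 this equals -2 * ln(alpha / m).
    """
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(chi2.isf(alpha / m, df))


@dataclass
class SpeciesData:
    """One dataset entering a DFE comparison."""

    sfs: FoldedSFS                  # nonsynonymous folded SFS
    demog: FitResult                # fitted on the matching synonymous SFS
    n_anc: float                    # ancestral size (maps s to gamma)
    theta_ns: float | None = None   # default: ratio * fitted theta_s
    label: str = ""

    def __post_init__(self):
        if self.theta_ns is None:
            theta_s = self.demog.model.theta_s
            if theta_s is None:
                raise ValueError("demography carries no theta_s")
            self.theta_ns = THETA_RATIO_DEFAULT * theta_s


@dataclass
class LRTResult:
    ll_full: float
    ll_constrained: float
    stat: float
    df: int
    alpha: float
    m: int
    critical: float
    significant: bool
    scale: str
    full_params: dict = field(default_factory=dict)
    constrained_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def _pair_ll(params, scale, caches, counts_list, thetas, n_ancs):
    """Summed Poisson LL of both datasets under shared DFE parameters.

    params = (log alpha, log mean) where the mean is E[s] for
    scale = "s" and E[2 N_anc s] for scale = "two_Nanc_s".
    """
    params = np.clip(params, -60.0, 60.0)
    alpha = np.exp(params[0])
    mean = np.exp(params[1])
    ll = 0.0
    for cache, counts, theta, n_anc in zip(caches, counts_list, thetas, n_ancs):
        if scale == "s":
            scale_gamma = (mean / alpha) * 2.0 * n_anc
        else:
            scale_gamma = mean / alpha
        weights, low_mass = _dfe_weights(cache, alpha, scale_gamma)
        spec = theta * cache.mixture_sfs(weights, low_mass)
        ll += poisson_loglik(counts, spec)
    return ll


def lrt_dfe_pair(dataA: SpeciesData, dataB: SpeciesData, scale: str = "s",
                 m: int = 1, alpha: float = 0.05,
                 grid_shape: int = 40, grid_mean: int = 40,
                 n_starts: int = 25, seed: int | None = None,
                 fitA: DFEFitResult | None = None,
                 fitB: DFEFitResult | None = None,
                 cacheA: SpectraCache | None = None,
                 cacheB: SpectraCache | None = None) -> LRTResult:
    """Test equality of gamma DFEs between two datasets.

    The full model fits each dataset's (shape, scale) independently; the
    constrained model shares (shape, E[s]) for ``scale='s'`` or
    (shape, E[2 N_anc s]) for ``scale='two_Nanc_s'``, optimized on a
    log-spaced grid followed by local refinement.  Each dataset's
    expected spectrum is always computed under its own demography and
    theta_ns.
    """
    if scale not in ("s", "two_Nanc_s"):
        raise ValueError("scale must be 's' or 'two_Nanc_s'")
    if cacheA is None:
        cacheA = SpectraCache(dataA.demog.model, dataA.sfs.n)
    if cacheB is None:
        cacheB = SpectraCache(dataB.demog.model, dataB.sfs.n)
    if fitA is None:
        fitA = fit_dfe(dataA.sfs, dataA.demog, "gamma", n_anc=dataA.n_anc,
                       n_starts=n_starts, seed=seed, cache=cacheA)
    if fitB is None:
        fitB = fit_dfe(dataB.sfs, dataB.demog, "gamma", n_anc=dataB.n_anc,
                       n_starts=n_starts,
                       seed=None if seed is None else seed + 1, cache=cacheB)
    ll_full = fitA.loglik + fitB.loglik

    caches = (cacheA, cacheB)
    counts_list = (np.asarray(dataA.sfs.counts, float),
                   np.asarray(dataB.sfs.counts, float))
    thetas = (dataA.theta_ns, dataB.theta_ns)
    n_ancs = (dataA.n_anc, dataB.n_anc)

    if scale == "s":
        mean_lo, mean_hi = 1e-8, 1.0
    else:
        mean_lo, mean_hi = 1e-4, 2.0 * GAMMA_MEAN_HI

    alphas = np.log(np.logspace(-2, 1, grid_shape))
    means = np.log(np.logspace(np.log10(mean_lo), np.log10(mean_hi), grid_mean))
    best_val, best_xy = -np.inf, None
    for la in alphas:
        for lm in means:
            val = _pair_ll((la, lm), scale, caches, counts_list, thetas, n_ancs)
            if val > best_val:
                best_val, best_xy = val, (la, lm)

    # Local refinement from the best grid node and from the full-model
    # midpoint (guards the nesting inequality).
    seeds = [np.array(best_xy)]
    mid_alpha = np.sqrt(fitA.dfe.shape * fitB.dfe.shape)
    if scale == "s":
        mid_mean = np.sqrt(fitA.dfe.mean_s * fitB.dfe.mean_s)
    else:
        mid_mean = np.sqrt(fitA.dfe.mean_s * 2 * dataA.n_anc
                           * fitB.dfe.mean_s * 2 * dataB.n_anc)
    seeds.append(np.log([mid_alpha, mid_mean]))
    ll_constrained = best_val
    best_params = best_xy
    for x0 in seeds:
        res = minimize(lambda p: -_pair_ll(p, scale, caches, counts_list,
                                           thetas, n_ancs),
                       x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 1500})
        if np.isfinite(res.fun) and -res.fun > ll_constrained:
            ll_constrained = -res.fun
            best_params = tuple(res.x)

    if ll_constrained > ll_full + 1e-3:
        raise RuntimeError(
            "constrained LL exceeds full LL "
            f"({ll_constrained:.6f} > {ll_full:.6f}): full-model optimizer "
            "failed to find its optimum (models are nested)"
        )
    stat = 2.0 * (ll_full - ll_constrained)
    if stat < 0:
        stat = 0.0
    critical = bonferroni_critical(df=2, alpha=alpha, m=m)
    return LRTResult(
        ll_full=float(ll_full), ll_constrained=float(ll_constrained),
        stat=float(stat), df=2, alpha=alpha, m=m, critical=critical,
        significant=bool(stat > critical), scale=scale,
        full_params={
            "A": {"shape": fitA.dfe.shape, "E_s": fitA.dfe.mean_s},
            "B": {"shape": fitB.dfe.shape, "E_s": fitB.dfe.mean_s},
        },
        constrained_params={
            "shape": float(np.exp(best_params[0])),
            "mean": float(np.exp(best_params[1])),
        },
    )


GAMMA_MEAN_HI = 2000.0


@dataclass
class GenusContrastResult:
    statistic: float
    p_value: float
    permutation_p: float
    n_between: int
    n_within: int
    n_perm: int


def _ranksum_z(between: np.ndarray, within: np.ndarray) -> float:
    """Normal-approximation two-sample rank-sum z statistic (no ties cor.)."""
    x = np.concatenate([between, within])
    ranks = rankdata(x)
    n1, n2 = between.size, within.size
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (w - mu) / sigma


def genus_contrast(pair_stats: dict, genus_labels: dict, n_perm: int = 10_000,
                   seed: int | None = None) -> GenusContrastResult:
    """Compare between- vs within-genus pairwise statistics.

    pair_stats: {(speciesA, speciesB): value}; genus_labels maps species
    to genus.  The observed p-value is a two-sided Wilcoxon rank-sum
    test.  The permutation control reassigns genus labels to *species*
    (holding genus sizes fixed) and recomputes the rank-sum statistic to
    form a null for the observed statistic.
    """
    species = sorted(genus_labels)
    genera = [genus_labels[s] for s in species]
    if len(set(genera)) < 2:
        raise ValueError("need at least two genera")
    pairs = list(pair_stats)
    values = np.array([pair_stats[p] for p in pairs], dtype=float)

    def split(labels: dict) -> tuple[np.ndarray, np.ndarray]:
        between = labels_arr = np.array(
            [labels[a] != labels[b] for a, b in pairs])
        return values[labels_arr], values[~labels_arr]

    between, within = split(genus_labels)
    if within.size == 0:
        raise ValueError("no within-genus pairs under the observed labels")
    from scipy.stats import ranksums
    obs = ranksums(between, within)
    z_obs = _ranksum_z(between, within)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(genera)
        labels = dict(zip(species, perm))
        b, w = split(labels)
        if w.size == 0 or b.size == 0:
            z = 0.0
        else:
            z = _ranksum_z(b, w)
        if abs(z) >= abs(z_obs) - 1e-12:
            hits += 1
    perm_p = (hits + 1) / (n_perm + 1)
    return GenusContrastResult(
        statistic=float(obs.statistic), p_value=float(obs.pvalue),
        permutation_p=float(perm_p), n_between=int(between.size),
        n_within=int(within.size), n_perm=n_perm,
    )


def all_pairs(labels: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(labels), 2))
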