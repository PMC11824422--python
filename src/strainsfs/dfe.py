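"""Distributions of fitness effects fit to nonsynonymous folded SFSs.

The DFE of new deleterious mutations is a gamma distribution over |s|
(optionally mixed with a neutral point mass p_neu).  Expected spectra
under a DFE are mixtures of selected spectra over a log-spaced grid of
population-scaled coefficients gamma = 2 * N_anc * s; the fit maximizes
a Poisson composite likelihood with theta_ns fixed at
theta_ratio * theta_s from the conditioning demographic fit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from . import engine
from .demography import MU_DEFAULT, DemographicModel, FitResult, ancestral_size
from .sfs import FoldedSFS

__all__ = [
    "DFEModel",
    "DFEFitResult",
    "SpectraCache",
    "THETA_RATIO_DEFAULT",
    "expected_selected_sfs",
    "expected_sfs_under_dfe",
    "poisson_loglik",
    "fit_dfe",
    "dfe_bin_masses",
    "S_BIN_EDGES",
]

THETA_RATIO_DEFAULT = 2.31       # theta_ns / theta_s
GAMMA_GRID_MIN = 1e-4            # smallest modeled |gamma|
GAMMA_GRID_MAX = 2000.0          # larger |gamma| -> effectively lethal
GAMMA_GRID_SIZE = 120

# |s| bin edges for the four-way summary:
# neutral-ish, moderately, highly deleterious, lethal
S_BIN_EDGES = (1e-6, 1e-2, 0.5)


@dataclass
class DFEModel:
    """Gamma or neutral+gamma DFE over |s| (deleterious only).

    gamma = 2 * N_anc * s uses ``n_anc_ref`` as the reference size.
    """

    family: str                  # "gamma" | "neu_gamma"
    shape: float                 # alpha > 0
    scale: float                 # beta > 0, on the |s| axis
    p_neu: float = 0.0
    n_anc_ref: float | None = None

    def __post_init__(self):
        if self.family not in ("gamma", "neu_gamma"):
            raise ValueError("family must be 'gamma' or 'neu_gamma'")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")
        if not 0.0 <= self.p_neu <= 1.0:
            raise ValueError("p_neu must be in [0, 1]")
        if self.family == "gamma" and self.p_neu != 0.0:
            raise ValueError("gamma family has p_neu = 0")

    @property
    def mean_s(self) -> float:
        """E[s] of the gamma component."""
        return self.shape * self.scale

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["E_s"] = self.mean_s
        return d


@dataclass
class DFEFitResult:
    dfe: DFEModel
    loglik: float
    k: int
    aic: float
    theta_ns: float
    n_starts: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["dfe"]["E_s"] = self.dfe.mean_s
        d["bin_masses"] = list(dfe_bin_masses(self.dfe))
        return json.dumps(d, indent=2, default=float)


def gamma_grid(size: int = GAMMA_GRID_SIZE, lo: float = GAMMA_GRID_MIN,
               hi: float = GAMMA_GRID_MAX) -> np.ndarray:
    """Log-spaced magnitudes |gamma| used for the mixture quadrature."""
    return np.logspace(np.log10(lo), np.log10(hi), size)


def expected_selected_sfs(model: DemographicModel, gamma: float, n: int,
                          pts=None) -> np.ndarray:
    """Expected folded SFS per unit theta under genic selection.

    ``gamma`` must be <= 0 (neutral or deleterious).
    """
    if gamma > 0:
        raise ValueError("only deleterious/neutral gamma (<= 0) supported")
    return engine.expected_folded_sfs(model.epochs, model.change_times,
                                      gamma, n, pts=pts)


class SpectraCache:
    """Folded spectra per unit theta at fixed gamma nodes for one demography.

    The DFE likelihood re-weights these cached spectra, so a fit costs
    one engine sweep regardless of how many (alpha, beta) values are
    evaluated.
    """

    def __init__(self, model: DemographicModel, n: int,
                 gammas: np.ndarray | None = None, pts=None):
        self.model = model
        self.n = n
        self.gammas = gamma_grid() if gammas is None else np.asarray(gammas)
        if np.any(self.gammas <= 0):
            raise ValueError("gamma grid holds magnitudes |gamma| > 0")
        self.neutral = expected_selected_sfs(model, 0.0, n, pts=pts)
        self.matrix = np.stack([
            expected_selected_sfs(model, -g, n, pts=pts) for g in self.gammas
        ])
        logg = np.log(self.gammas)
        half = 0.5 * (logg[1] - logg[0])
        self.edges = np.exp(np.concatenate(
            ([logg[0] - half], 0.5 * (logg[1:] + logg[:-1]), [logg[-1] + half])
        ))

    def mixture_sfs(self, weights: np.ndarray, w_neutral: float) -> np.ndarray:
        """Spectrum per unit theta for node weights plus a neutral lump."""
        return w_neutral * self.neutral + weights @ self.matrix


def _dfe_weights(cache: SpectraCache, shape: float, scale_gamma: float
                 ) -> tuple[np.ndarray, float]:
    """Mass per gamma node for a gamma DFE with scale on the |gamma| axis.

    Mass below the lowest bin edge is effectively neutral; mass above
    the highest edge contributes no polymorphism (lethal-equivalent).
    """
    cdf = gamma_dist.cdf(cache.edges, a=shape, scale=scale_gamma)
    weights = np.diff(cdf)
    return weights, float(cdf[0])


def expected_sfs_under_dfe(model: DemographicModel, dfe: DFEModel,
                           theta_ns: float, n: int,
                           cache: SpectraCache | None = None,
                           pts=None) -> np.ndarray:
    """Expected absolute folded nonsynonymous SFS under a DFE."""
    if theta_ns <= 0:
        raise ValueError("theta_ns must be positive")
    if dfe.n_anc_ref is None or dfe.n_anc_ref <= 0:
        raise ValueError("DFEModel.n_anc_ref required to map s to gamma")
    if cache is None:
        cache = SpectraCache(model, n, pts=pts)
    scale_gamma = dfe.scale * 2.0 * dfe.n_anc_ref
    weights, low_mass = _dfe_weights(cache, dfe.shape, scale_gamma)
    gamma_part = 1.0 - dfe.p_neu
    spectrum = cache.mixture_sfs(gamma_part * weights,
                                 dfe.p_neu + gamma_part * low_mass)
    return theta_ns * spectrum


def poisson_loglik(observed, expected) -> float:
    """Poisson composite log-likelihood of an SFS.

    sum_i [ x_i ln(e_i) - lnGamma(x_i + 1) - e_i ]; fractional observed
    counts are handled by the log-gamma generalized factorial.  Bins
    with expected = 0 but observed > 0 yield -inf.
    """
    x = observed.counts if isinstance(observed, FoldedSFS) else observed
    x = np.asarray(x, dtype=float)
    e = np.asarray(expected, dtype=float)
    if x.shape != e.shape:
        raise ValueError("observed and expected spectra differ in length")
    if np.any((e <= 0) & (x > 0)):
        return -np.inf
    pos = e > 0
    ll = float(np.sum(x[pos] * np.log(e[pos]) - gammaln(x[pos] + 1) - e[pos]))
    ll -= float(np.sum(e[~pos]))  # zero, but keeps shape explicit
    return ll


_ALPHA_START = (1e-2, 10.0)
_MEAN_S_START = (1e-8, 0.5)


def _neg_ll_dfe(params, family, cache, counts, theta_ns, n_anc):
    params = np.clip(params, -60.0, 60.0)   # keep exp() finite
    if family == "neu_gamma":
        la, lm, z = params
        p_neu = 1.0 / (1.0 + np.exp(-z))
    else:
        la, lm = params
        p_neu = 0.0
    alpha = np.exp(la)
    mean_s = np.exp(lm)
    scale_gamma = (mean_s / alpha) * 2.0 * n_anc
    weights, low_mass = _dfe_weights(cache, alpha, scale_gamma)
    gp = 1.0 - p_neu
    spec = theta_ns * cache.mixture_sfs(gp * weights, p_neu + gp * low_mass)
    ll = poisson_loglik(counts, spec)
    return 1e10 if not np.isfinite(ll) else -ll


def fit_dfe(nonsyn_sfs: FoldedSFS, demog: FitResult, family: str = "gamma",
            theta_ratio: float = THETA_RATIO_DEFAULT,
            n_anc: float | None = None, L_syn: float | None = None,
            mu: float = MU_DEFAULT, n_starts: int = 25,
            seed: int | None = None, cache: SpectraCache | None = None,
            pts=None) -> DFEFitResult:
    """Fit a gamma or neu+gamma DFE conditional on a fitted demography.

    theta_ns is fixed at ``theta_ratio`` times the fitted theta_s.  The
    reference size for gamma = 2 N_anc s comes from ``n_anc`` directly
    or from (theta_s, mu, L_syn).
    """
    if family not in ("gamma", "neu_gamma"):
        raise ValueError("family must be 'gamma' or 'neu_gamma'")
    theta_s = demog.model.theta_s
    if theta_s is None or theta_s <= 0:
        raise ValueError("conditioning demography must carry a fitted theta_s")
    if n_anc is None:
        n_anc = ancestral_size(theta_s, mu=mu, L_syn=L_syn)
    theta_ns = theta_ratio * theta_s
    if cache is None:
        cache = SpectraCache(demog.model, nonsyn_sfs.n, pts=pts)
    counts = np.asarray(nonsyn_sfs.counts, dtype=float)

    rng = np.random.default_rng(seed)
    ndim = 3 if family == "neu_gamma" else 2
    best = None
    failures = []
    for start_i in range(max(n_starts, 1)):
        x0 = [rng.uniform(np.log(_ALPHA_START[0]), np.log(_ALPHA_START[1])),
              rng.uniform(np.log(_MEAN_S_START[0]), np.log(_MEAN_S_START[1]))]
        if ndim == 3:
            x0.append(rng.uniform(-3.0, 3.0))
        try:
            res = minimize(_neg_ll_dfe, np.array(x0),
                           args=(family, cache, counts, theta_ns, n_anc),
                           method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8,
                                    "maxiter": 1500})
        except Exception as exc:  # pragma: no cover
            failures.append(f"start {start_i}: {exc}")
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            failures.append(f"start {start_i}: no finite likelihood")
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("all DFE optimization starts failed: "
                           + "; ".join(failures))

    if family == "neu_gamma":
        la, lm, z = best.x
        p_neu = float(1.0 / (1.0 + np.exp(-z)))
        k = 3
    else:
        (la, lm), p_neu, k = best.x, 0.0, 2
    alpha = float(np.exp(la))
    mean_s = float(np.exp(lm))
    dfe = DFEModel(family=family, shape=alpha, scale=mean_s / alpha,
                   p_neu=p_neu, n_anc_ref=float(n_anc))
    ll = -float(best.fun)
    return DFEFitResult(dfe=dfe, loglik=ll, k=k, aic=2.0 * k - 2.0 * ll,
                        theta_ns=float(theta_ns), n_starts=n_starts)


def dfe_bin_masses(dfe: DFEModel, edges=S_BIN_EDGES) -> np.ndarray:
    """Masses over |s| bins [0,1e-6), [1e-6,1e-2), [1e-2,0.5), [0.5,inf).

    The neutral point mass lands in the first bin.
    """
    cdf = gamma_dist.cdf(np.asarray(edges), a=dfe.shape, scale=dfe.scale)
    gp = 1.0 - dfe.p_neu
    masses = np.empty(len(edges) + 1)
    masses[0] = dfe.p_neu + gp * cdf[0]
    masses[1:-1] = gp * np.diff(cdf)
    masses[-1] = gp * (1.0 - cdf[-1])
    return masses
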