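"""Piecewise-constant demographic models fit to folded synonymous SFSs.

Models are one-, two-, or three-epoch histories.  theta is profiled out
analytically (multinomial likelihood), so the free parameter counts are
0, 2 and 4 respectively.  Model choice is by AIC; confidence intervals
use the 3-log-likelihood-unit rule (df = 2, asymptotic 95%).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from . import engine
from .sfs import FoldedSFS

__all__ = [
    "DemographicModel",
    "FitResult",
    "expected_neutral_sfs",
    "multinomial_loglik",
    "fit_demography",
    "select_model",
    "confidence_region",
    "likelihood_surface",
    "ancestral_size",
    "tau_to_years",
    "MU_DEFAULT",
    "TAU_MAX",
]

MU_DEFAULT = 4.08e-10       # mutations per site per generation
TAU_MAX = 0.15              # most-recent change at most 0.15 * 2 N_anc ago
NU_BOUNDS = (1e-3, 1e4)
TAU_BOUNDS = (1e-4, TAU_MAX)

_FAMILY_K = {"one": 0, "two": 2, "three": 4}


@dataclass
class DemographicModel:
    """Relative-size history plus (optionally) a fitted theta_s.

    epochs: ordered relative sizes, oldest first; epochs[0] == 1.
    change_times: times before present in units of 2 N_anc generations,
        one per size change, strictly decreasing (oldest first).
    """

    epochs: list[float] = field(default_factory=lambda: [1.0])
    change_times: list[float] = field(default_factory=list)
    theta_s: float | None = None
    n: int | None = None

    def __post_init__(self):
        if len(self.change_times) != len(self.epochs) - 1:
            raise ValueError("one change time required per size change")
        if any(e <= 0 for e in self.epochs):
            raise ValueError("relative sizes must be positive")
        if any(t <= 0 for t in self.change_times):
            raise ValueError("change times must be positive")
        ts = list(self.change_times)
        if any(b >= a for a, b in zip(ts, ts[1:])):
            raise ValueError("change times must decrease toward the present")

    @property
    def family(self) -> str:
        return {1: "one", 2: "two", 3: "three"}[len(self.epochs)]

    @property
    def nu(self) -> float:
        """Current size relative to ancestral."""
        return self.epochs[-1]

    def n_anc(self, mu: float = MU_DEFAULT, L_syn: float | None = None) -> float:
        if self.theta_s is None:
            raise ValueError("theta_s has not been fitted")
        return ancestral_size(self.theta_s, mu=mu, L_syn=L_syn)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(**d)


@dataclass
class FitResult:
    model: DemographicModel
    loglik: float
    k: int
    aic: float
    ci: dict | None = None
    n_starts: int = 0
    bounds_hit: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=float)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        d["model"] = DemographicModel.from_dict(d["model"])
        return cls(**d)


def expected_neutral_sfs(model: DemographicModel, n: int, pts=None) -> np.ndarray:
    """Expected folded neutral SFS per unit theta (bins 1..n//2)."""
    return engine.expected_folded_sfs(model.epochs, model.change_times,
                                      0.0, n, pts=pts)


def multinomial_loglik(observed: np.ndarray, model_sfs: np.ndarray) -> float:
    """Multinomial log-likelihood with theta profiled out.

    Fractional observed counts are supported through log-gamma
    generalized factorials.  Invariant to scaling of ``model_sfs``.
    """
    x = np.asarray(observed, dtype=float)
    e = np.asarray(model_sfs, dtype=float)
    if x.shape != e.shape:
        raise ValueError("observed and model spectra differ in length")
    tot = e.sum()
    if tot <= 0 or np.any(e < 0):
        return -np.inf
    p = e / tot
    mask = x > 0
    if np.any(p[mask] <= 0):
        return -np.inf
    ll = float(np.sum(x[mask] * np.log(p[mask])))
    ll += float(gammaln(x.sum() + 1) - np.sum(gammaln(x + 1)))
    return ll


def _pack(family: str, params: np.ndarray) -> tuple[list[float], list[float]]:
    """Map optimizer parameters (log scale) to (epochs, change_times)."""
    if family == "two":
        nu, tau = np.exp(params)
        return [1.0, nu], [tau]
    if family == "three":
        nu1, nu2, tau_recent, gap = np.exp(params)
        return [1.0, nu1, nu2], [tau_recent + gap, tau_recent]
    raise ValueError(family)


def _neg_ll(params, family, counts, n, pts):
    epochs, times = _pack(family, params)
    if times[0] > TAU_MAX + 1e-12 or not (NU_BOUNDS[0] <= min(epochs)):
        return 1e10
    try:
        model_sfs = engine.expected_folded_sfs(epochs, times, 0.0, n, pts=pts)
    except engine.EngineError:
        return 1e10
    ll = multinomial_loglik(counts, model_sfs)
    return 1e10 if not np.isfinite(ll) else -ll


def fit_demography(sfs: FoldedSFS, family: str, n_starts: int = 25,
                   seed: int | None = None, pts=None,
                   starts=None) -> FitResult:
    """Fit a demographic family to a folded synonymous SFS.

    Multi-start local search over log-parameters with log-uniform starts,
    nu in [1e-3, 1e4] and tau in [1e-4, 0.15].  theta_s is profiled as
    the ratio of observed to model totals at the optimum.  ``starts``
    optionally replaces the random starts with explicit parameter
    tuples in natural space ((nu, tau) or (nu1, nu2, tau_old, tau_recent)).
    """
    if family not in _FAMILY_K:
        raise ValueError(f"unknown family {family!r}")
    counts = np.asarray(sfs.counts, dtype=float)
    n = sfs.n
    k = _FAMILY_K[family]
    informative = int(np.sum(counts > 0))
    if family != "one" and informative < k + 2:
        raise ValueError(
            f"{family}-epoch fit needs >= {k + 2} informative bins, "
            f"have {informative}"
        )
    if pts is None:
        pts = engine.default_pts(n)

    if family == "one":
        model_sfs = engine.expected_folded_sfs([1.0], [], 0.0, n, pts=pts)
        ll = multinomial_loglik(counts, model_sfs)
        model = DemographicModel([1.0], [], theta_s=counts.sum() / model_sfs.sum(),
                                 n=n)
        return FitResult(model=model, loglik=ll, k=0, aic=-2.0 * ll, n_starts=0)

    rng = np.random.default_rng(seed)
    best = None
    failures = []
    if starts is not None:
        x0_list = []
        for st in starts:
            st = np.asarray(st, dtype=float)
            if family == "three":
                # (nu1, nu2, tau_old, tau_recent) -> internal packing
                st = np.array([st[0], st[1], st[3], st[2] - st[3]])
            x0_list.append(np.log(st))
    else:
        x0_list = None
    n_attempts = len(x0_list) if x0_list is not None else max(n_starts, 1)
    for start_i in range(n_attempts):
        if x0_list is not None:
            x0 = x0_list[start_i]
        elif family == "two":
            x0 = np.array([
                rng.uniform(np.log(NU_BOUNDS[0]), np.log(NU_BOUNDS[1])),
                rng.uniform(np.log(TAU_BOUNDS[0]), np.log(TAU_BOUNDS[1])),
            ])
        else:
            tau_r = rng.uniform(np.log(TAU_BOUNDS[0]), np.log(TAU_MAX / 2))
            x0 = np.array([
                rng.uniform(np.log(NU_BOUNDS[0]), np.log(NU_BOUNDS[1])),
                rng.uniform(np.log(NU_BOUNDS[0]), np.log(NU_BOUNDS[1])),
                tau_r,
                rng.uniform(np.log(TAU_BOUNDS[0]), np.log(TAU_MAX / 2)),
            ])
        try:
            res = minimize(_neg_ll, x0, args=(family, counts, n, pts),
                           method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-7,
                                    "maxiter": 1000})
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {start_i}: {exc}")
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            failures.append(f"start {start_i}: no finite likelihood")
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError(
            "all optimization starts failed: " + "; ".join(failures)
        )

    epochs, times = _pack(family, best.x)
    model_sfs = engine.expected_folded_sfs(epochs, times, 0.0, n, pts=pts)
    theta = counts.sum() / model_sfs.sum()
    model = DemographicModel(list(epochs), list(times), theta_s=float(theta), n=n)
    ll = multinomial_loglik(counts, model_sfs)

    bounds_hit = []
    for nu in epochs[1:]:
        if nu <= NU_BOUNDS[0] * 1.01 or nu >= NU_BOUNDS[1] * 0.99:
            bounds_hit.append(f"nu={nu:.4g}")
    if times[0] >= TAU_MAX * 0.999:
        bounds_hit.append(f"tau={times[0]:.4g}")
    return FitResult(model=model, loglik=float(ll), k=k, aic=2.0 * k - 2.0 * ll,
                     n_starts=n_starts, bounds_hit=bounds_hit)


def select_model(fits: list[FitResult]) -> FitResult:
    """Minimum-AIC fit; AIC ties (< 1e-6) go to the fewest parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to select between")
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic - 1e-6 or (abs(f.aic - best.aic) < 1e-6
                                       and f.k < best.k):
            best = f
    return best


def likelihood_surface(sfs: FoldedSFS, nu_grid, tau_grid, pts=None,
                       spectra=None) -> np.ndarray:
    """Two-epoch multinomial log-likelihood over a (nu, tau) grid.

    ``spectra`` may carry precomputed model spectra of shape
    (len(nu_grid), len(tau_grid), n//2) to amortize engine calls across
    many observed spectra.
    """
    counts = np.asarray(sfs.counts, dtype=float)
    if spectra is None:
        spectra = surface_spectra(nu_grid, tau_grid, sfs.n, pts=pts)
    ll = np.empty(spectra.shape[:2])
    for i in range(spectra.shape[0]):
        for j in range(spectra.shape[1]):
            ll[i, j] = multinomial_loglik(counts, spectra[i, j])
    return ll


def surface_spectra(nu_grid, tau_grid, n: int, pts=None) -> np.ndarray:
    """Model spectra per unit theta on a (nu, tau) grid."""
    out = np.empty((len(nu_grid), len(tau_grid), n // 2))
    for i, nu in enumerate(nu_grid):
        for j, tau in enumerate(tau_grid):
            out[i, j] = engine.expected_folded_sfs([1.0, nu], [tau], 0.0, n,
                                                   pts=pts)
    return out


def confidence_region(surface: np.ndarray, axes: list[np.ndarray],
                      drop: float = 3.0, ll_max: float | None = None) -> dict:
    """Per-parameter intervals from {LL >= LL_max - drop}.

    ``ll_max`` may be supplied when the MLE log-likelihood is known more
    precisely than the grid maximum.  Returns
    {"param_i": {"lo", "hi", "lo_unbounded", "hi_unbounded"}} where
    unbounded flags mark the region touching the grid edge.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != len(axes):
        raise ValueError("surface dimensionality must match axes")
    if not np.any(np.isfinite(surface)):
        raise ValueError("surface contains no finite likelihoods")
    if ll_max is None:
        ll_max = np.nanmax(surface)
    else:
        ll_max = max(float(ll_max), float(np.nanmax(surface)))
    inside = surface >= ll_max - drop
    if not inside.any():
        # refined ll_max more than `drop` above every grid node: fall
        # back to the grid argmax as a degenerate region
        inside = surface >= np.nanmax(surface)
    out = {}
    for d, axis in enumerate(axes):
        axis = np.asarray(axis, dtype=float)
        hit = inside.any(axis=tuple(i for i in range(surface.ndim) if i != d))
        idx = np.nonzero(hit)[0]
        out[f"param_{d}"] = {
            "lo": float(axis[idx[0]]),
            "hi": float(axis[idx[-1]]),
            "lo_unbounded": bool(idx[0] == 0),
            "hi_unbounded": bool(idx[-1] == axis.size - 1),
        }
    return out


def ancestral_size(theta_s: float, mu: float = MU_DEFAULT,
                   L_syn: float | None = None) -> float:
    """N_anc = theta_s / (4 mu L_syn)."""
    if L_syn is None:
        raise ValueError("L_syn is required")
    if theta_s <= 0 or mu <= 0 or L_syn <= 0:
        raise ValueError("theta_s, mu and L_syn must all be positive")
    return theta_s / (4.0 * mu * L_syn)


def tau_to_years(tau: float, n_anc: float,
                 generations_per_day: float = 1.0) -> float:
    """years = tau * 2 N_anc * 365 / generations_per_day."""
    if tau < 0 or n_anc <= 0 or generations_per_day <= 0:
        raise ValueError("inputs must be positive (tau may be zero)")
    return tau * 2.0 * n_anc * 365.0 / generations_per_day


def aic(k: int, loglik: float) -> float:
    return 2.0 * k - 2.0 * loglik


def _self_test():  # pragma: no cover - convenience
    m = DemographicModel([1.0, 0.5], [0.05])
    s = expected_neutral_sfs(m, 14)
    assert math.isfinite(s.sum())
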