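"""Synthetic data generation with known ground truth, plus independent
brute-force oracles (forward Wright-Fisher simulation, stationary PRF
quadrature, coalescent branch lengths) used to validate the diffusion
engine and the inference code.

Every generator is a pure function of (parameters, seed).  Random
streams are derived from a single master seed through named substreams,
so adding a new generator never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import gammaln

from . import engine
from .demography import DemographicModel
from .dfe import DFEModel, SpectraCache, expected_sfs_under_dfe
from .sfs import FoldedSFS

__all__ = [
    "SimScenario",
    "OracleSFS",
    "substream",
    "simulate_sfs_counts",
    "simulate_host_pileup",
    "forward_wf_sfs",
    "prf_quadrature_sfs",
    "coalescent_sfs",
    "simulate_bm_traits",
    "random_coalescent_tree",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream keyed by a name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SimScenario:
    """Ground-truth parameters for a synthetic species dataset."""

    n_hosts: int
    n_haplotypes_target: int
    genome_length: int
    frac_synonymous: float
    demography: DemographicModel
    dfe: DFEModel | None
    theta_s: float
    theta_ratio: float = 2.31
    depth_mean: float = 50.0
    depth_sd: float = 0.3          # sd of log-depth (log-normal depth model)
    strain_major_fraction: float = 1.0
    seed: int = 0
    species: str = "synthetic_species"

    def __post_init__(self):
        if self.theta_s <= 0:
            raise ValueError("theta_s must be positive")
        if not 0.5 < self.strain_major_fraction <= 1.0:
            raise ValueError("strain_major_fraction must be in (0.5, 1]")
        if not 0.0 < self.frac_synonymous < 1.0:
            raise ValueError("frac_synonymous must be in (0, 1)")
        if self.n_hosts < 2 or self.n_haplotypes_target < 2:
            raise ValueError("need at least two hosts / haplotypes")

    @property
    def theta_ns(self) -> float:
        return self.theta_ratio * self.theta_s


@dataclass
class OracleSFS:
    """Folded expected SFS from an independent oracle, per unit theta."""

    expectation: np.ndarray
    mc_stderr: np.ndarray
    method: str

    def __post_init__(self):
        self.expectation = np.asarray(self.expectation, dtype=float)
        self.mc_stderr = np.asarray(self.mc_stderr, dtype=float)
        if np.any(self.expectation < 0):
            raise ValueError("expectations must be non-negative")
        if self.expectation.shape != self.mc_stderr.shape:
            raise ValueError("expectation and stderr shapes differ")


# ---------------------------------------------------------------------------
# SFS count generator (PRF independence: bins are independent Poissons)

def simulate_sfs_counts(scenario: SimScenario, mut_class: str) -> FoldedSFS:
    """Poisson SFS draw with mean = model-expected folded spectrum.

    Synonymous spectra are neutral under the scenario's demography;
    nonsynonymous spectra additionally require the scenario's DFE.
    """
    n = scenario.n_haplotypes_target
    model = scenario.demography
    if mut_class == "synonymous":
        mean = scenario.theta_s * engine.expected_folded_sfs(
            model.epochs, model.change_times, 0.0, n)
        L = scenario.genome_length * scenario.frac_synonymous
    elif mut_class == "nonsynonymous":
        if scenario.dfe is None:
            raise ValueError(
                "nonsynonymous spectra require a DFE in the scenario")
        mean = expected_sfs_under_dfe(model, scenario.dfe, scenario.theta_ns, n)
        L = scenario.genome_length * (1.0 - scenario.frac_synonymous)
    else:
        raise ValueError("mut_class must be 'synonymous' or 'nonsynonymous'")
    rng = substream(scenario.seed, f"sfs_counts:{mut_class}")
    counts = rng.poisson(mean).astype(float)
    return FoldedSFS(n=n, counts=counts, L=float(L), mut_class=mut_class,
                     species=scenario.species)


# ---------------------------------------------------------------------------
# Host pileups (input to quasi-phasing)

def simulate_host_pileup(scenario: SimScenario) -> tuple[pd.DataFrame, dict]:
    """Per-host, per-site call table with a two-strain mixture per host.

    Each host carries a dominant strain (frequency strain_major_fraction)
    and a secondary strain drawn from the across-host population.
    Emitted major-allele frequencies are binomial reads of the mixture.
    Returns (calls table, truth) where truth holds the ground-truth
    dominant haplotypes and polymorphic-site annotations.
    """
    if scenario.depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    n_hosts = scenario.n_hosts
    L = scenario.genome_length
    rng_site = substream(scenario.seed, "pileup:sites")

    degeneracy = np.where(rng_site.random(L) < scenario.frac_synonymous,
                          "4D", "1D")
    gene_ids = np.array([f"gene_{p // 300:04d}" for p in range(L)])

    # Across-host polymorphism: minor-host-count k drawn per bin from the
    # neutral expectation at the host sample size (DFE omitted for 1D
    # sites when the scenario carries none).
    model = scenario.demography
    exp_syn = scenario.theta_s * engine.expected_folded_sfs(
        model.epochs, model.change_times, 0.0, n_hosts)
    if scenario.dfe is not None:
        exp_ns = expected_sfs_under_dfe(model, scenario.dfe,
                                        scenario.theta_ns, n_hosts)
    else:
        exp_ns = scenario.theta_ns * engine.expected_folded_sfs(
            model.epochs, model.change_times, 0.0, n_hosts)

    dominant = np.zeros((n_hosts, L), dtype=np.int8)
    poly_sites = []
    rng_poly = substream(scenario.seed, "pileup:polymorphism")
    for cls, exp in (("4D", exp_syn), ("1D", exp_ns)):
        cls_sites = np.nonzero(degeneracy == cls)[0]
        counts = rng_poly.poisson(exp)
        avail = rng_poly.permutation(cls_sites)
        cursor = 0
        for k, nk in enumerate(counts, start=1):
            for _ in range(int(nk)):
                if cursor >= avail.size:
                    break
                site = avail[cursor]
                cursor += 1
                carriers = rng_poly.choice(n_hosts, size=k, replace=False)
                dominant[carriers, site] = 1
                poly_sites.append((int(site), cls, k))

    # Secondary strain: each host pairs its dominant strain with the
    # dominant strain of a uniformly drawn other host.
    rng_mix = substream(scenario.seed, "pileup:mixture")
    partner = rng_mix.integers(0, n_hosts, size=n_hosts)
    same = partner == np.arange(n_hosts)
    partner[same] = (partner[same] + 1) % n_hosts
    secondary = dominant[partner]

    f = scenario.strain_major_fraction
    q = f * dominant + (1.0 - f) * secondary      # freq of allele "1"

    rng_depth = substream(scenario.seed, "pileup:depth")
    rng_reads = substream(scenario.seed, "pileup:reads")
    if scenario.depth_sd > 0:
        log_mean = np.log(scenario.depth_mean) - 0.5 * scenario.depth_sd ** 2
        depth = np.floor(rng_depth.lognormal(
            log_mean, scenario.depth_sd, size=(n_hosts, L))).astype(int)
        depth = np.maximum(depth, 0)
    else:
        depth = np.full((n_hosts, L), int(round(scenario.depth_mean)))
    reads1 = rng_reads.binomial(depth, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.where(depth > 0, reads1 / np.maximum(depth, 1), 0.5)
    major_allele = (freq1 >= 0.5).astype(np.int8)
    major_freq = np.where(major_allele == 1, freq1, 1.0 - freq1)

    hosts = [f"host_{h:03d}" for h in range(n_hosts)]
    calls = pd.DataFrame({
        "species": scenario.species,
        "host": np.repeat(hosts, L),
        "contig": "contig_1",
        "pos0": np.tile(np.arange(L), n_hosts),
        "gene_id": np.tile(gene_ids, n_hosts),
        "degeneracy": np.tile(degeneracy, n_hosts),
        "major_freq": major_freq.ravel(),
        "depth": depth.ravel(),
        # Allele identity of the within-host major allele.  Not part of
        # the minimal schema, but without it cross-host minor-allele
        # counts cannot be reconstructed from the table alone.
        "major_allele": major_allele.ravel(),
    })
    truth = {
        "polymorphic_sites": pd.DataFrame(
            poly_sites, columns=["pos0", "degeneracy", "minor_host_count"]),
        "dominant": pd.DataFrame(dominant, index=hosts),
        "observed_major": pd.DataFrame(major_allele, index=hosts),
        "hosts": hosts,
    }
    return calls, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher oracle

def forward_wf_sfs(N: int, gamma: float, n: int, reps: int = 20_000,
                   seed: int | None = None, epochs=(1.0,), change_times=(),
                   mut_rate: float = 5.0, burnin_factor: float = 8.0
                   ) -> OracleSFS:
    """Folded expected SFS per unit theta from haploid WF simulation.

    N haploid individuals with relative fitnesses 1 and 1 + s where
    s = gamma / N (gamma = 2 * N_anc * s with N_anc = N / 2).  Mutations
    enter as Poisson(mut_rate * nu_current) new alleles per generation,
    each at frequency 1 / N_current; the population-wide influx
    mut_rate = N * mu gives theta = 2 * N * mu = 2 * mut_rate.  ``reps``
    sets the number of mutation events during measurement (equilibrium)
    or the number of replicate non-equilibrium trajectories (with
    change_times).

    Returns the per-bin mean and a batch-means Monte Carlo stderr.
    """
    if N > 2000:
        raise ValueError("N > 2000 exceeds the intended desk scale")
    if reps < 1:
        raise ValueError("reps must be positive")
    rng = np.random.default_rng(seed)
    s = gamma / N
    u0 = mut_rate
    theta_sim = 2.0 * u0
    half = n // 2

    freqs = np.empty(0, dtype=float)

    def step(freqs, N_cur, u_cur):
        if freqs.size:
            p_sel = freqs * (1.0 + s) / (1.0 + freqs * s)
            cnt = rng.binomial(N_cur, p_sel)
            cnt = cnt[(cnt > 0) & (cnt < N_cur)]
            freqs = cnt / N_cur
        k = rng.poisson(u_cur)
        if k:
            freqs = np.concatenate([freqs, np.full(k, 1.0 / N_cur)])
        return freqs

    def sample_sfs(freqs, N_cur):
        out = np.zeros(half)
        if freqs.size:
            cnt = np.rint(freqs * N_cur).astype(int)
            m = rng.hypergeometric(cnt, N_cur - cnt, n)
            m = np.minimum(m, n - m)
            m = m[m > 0]
            if m.size:
                out += np.bincount(m, minlength=half + 1)[1:half + 1]
        return out

    burn = int(burnin_factor * N)
    for _ in range(burn):
        freqs = step(freqs, N, u0)

    change_times = tuple(change_times)
    if not change_times:
        # Equilibrium: long run, sampling every few generations.
        gap = max(1, N // 20)
        T = max(int(np.ceil(reps / u0)), 20 * N)
        n_batches = 10
        batch_len = T // n_batches
        batch_sums = np.zeros((n_batches, half))
        batch_cnt = np.zeros(n_batches)
        for t in range(n_batches * batch_len):
            freqs = step(freqs, N, u0)
            if t % gap == 0:
                b = t // batch_len
                batch_sums[b] += sample_sfs(freqs, N)
                batch_cnt[b] += 1
        batch_means = batch_sums / batch_cnt[:, None]
        mean = batch_means.mean(axis=0)
        se = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
        return OracleSFS(mean / theta_sim, se / theta_sim, "forward_wf")

    # Non-equilibrium: replicate the post-change phase from snapshots of
    # the continuing equilibrium run.
    durations = [
        t - (change_times[k + 1] if k + 1 < len(change_times) else 0.0)
        for k, t in enumerate(change_times)
    ]
    n_snap = int(reps)
    gap_snap = max(1, N // 2)
    acc = np.zeros((n_snap, half))
    for r in range(n_snap):
        for _ in range(gap_snap):
            freqs = step(freqs, N, u0)
        fr = freqs.copy()
        for nu, dur in zip(epochs[1:], durations):
            N_cur = max(2, int(round(nu * N)))
            u_cur = u0 * nu
            cnt = rng.binomial(N_cur, fr)          # resample at new size
            cnt = cnt[(cnt > 0) & (cnt < N_cur)]
            fr = cnt / N_cur
            for _ in range(int(round(dur * N))):
                fr = step(fr, N_cur, u_cur)
        acc[r] = sample_sfs(fr, max(2, int(round(epochs[-1] * N))))
    n_batches = 10
    bm = acc[: (n_snap // n_batches) * n_batches].reshape(
        n_batches, -1, half).mean(axis=1)
    mean = acc.mean(axis=0)
    se_batch = bm.std(axis=0, ddof=1) / np.sqrt(n_batches)
    # Per-snapshot SE is a stabler floor for rare bins (snapshots are
    # nearly independent for short-sojourn variants); take the max.
    se_snap = acc.std(axis=0, ddof=1) / np.sqrt(n_snap)
    se = np.maximum(se_batch, se_snap)
    return OracleSFS(mean / theta_sim, se / theta_sim, "forward_wf")


# ---------------------------------------------------------------------------
# Stationary PRF quadrature oracle

def prf_density(x: float, gamma: float) -> float:
    """Stationary allele-frequency density per unit theta.

    Neutral limit 1/x; for gamma != 0,
    (1 - exp(-2 gamma (1 - x))) / ((1 - exp(-2 gamma)) x (1 - x)).
    """
    if gamma == 0.0:
        return 1.0 / x
    num = -np.expm1(-2.0 * gamma * (1.0 - x))
    den = -np.expm1(-2.0 * gamma) * x * (1.0 - x)
    return num / den


def prf_quadrature_sfs(gamma: float, n: int) -> OracleSFS:
    """Folded equilibrium SFS per unit theta by numerical quadrature."""
    unfolded = np.empty(n - 1)
    for i in range(1, n):
        lb = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)

        def integrand(x, i=i, lb=lb):
            return prf_density(x, gamma) * np.exp(
                lb + i * np.log(x) + (n - i) * np.log1p(-x))

        val, _ = quad(integrand, 0.0, 1.0, limit=400)
        unfolded[i - 1] = val
    folded = engine.fold(unfolded)
    return OracleSFS(folded, np.zeros_like(folded), "prf_quadrature")


# ---------------------------------------------------------------------------
# Coalescent oracle (neutral, piecewise-constant demography)

def coalescent_sfs(epochs, change_times, n: int, reps: int = 100_000,
                   seed: int = 1) -> OracleSFS:
    """Neutral folded SFS per unit theta from msprime branch lengths.

    Uses time units of 2 * N_anc generations (population_size = nu,
    ploidy = 1), under which the expected branch AFS equals twice the
    per-unit-theta SFS.
    """
    import msprime

    demog = msprime.Demography()
    demog.add_population(initial_size=epochs[-1])
    sizes = list(epochs)
    for t, size in zip(sorted(change_times), sizes[-2::-1]):
        demog.add_population_parameters_change(time=t, initial_size=size)
    half = n // 2
    acc = np.zeros(half)
    acc2 = np.zeros(half)
    cnt = 0
    for ts in msprime.sim_ancestry(samples=n, ploidy=1, demography=demog,
                                   num_replicates=reps, random_seed=seed):
        afs = ts.allele_frequency_spectrum(mode="branch", polarised=False,
                                           span_normalise=False)
        v = afs[1:half + 1] / 2.0
        acc += v
        acc2 += v * v
        cnt += 1
    mean = acc / cnt
    se = np.sqrt(np.maximum(acc2 / cnt - mean ** 2, 0.0) / cnt)
    return OracleSFS(mean, se, "coalescent")


# ---------------------------------------------------------------------------
# Brownian-motion traits on a tree (Pagel-lambda validation input)

def simulate_bm_traits(tree, lambda_true: float, sigma2: float,
                       seed: int | None = None) -> pd.Series:
    """Multivariate-normal traits with lambda-scaled phylogenetic covariance.

    ``tree`` is a newick string or dendropy Tree with branch lengths.
    Off-diagonal covariances are scaled by ``lambda_true``.
    """
    from .phylo import phylo_covariance, _as_tree

    t = _as_tree(tree)
    labels, C = phylo_covariance(t)
    if len(labels) < 4:
        raise ValueError("need at least four tips")
    off = C - np.diag(np.diag(C))
    if lambda_true > 0 and np.max(np.abs(off)) == 0:
        raise ValueError("star tree: lambda transform has no effect")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    V = sigma2 * (lambda_true * off + np.diag(np.diag(C)))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(V + 1e-12 * np.eye(V.shape[0]))
    vals = chol @ rng.standard_normal(V.shape[0])
    return pd.Series(vals, index=labels)


def random_coalescent_tree(n_tips: int, seed: int = 0) -> str:
    """Random binary tree (newick) with exponential coalescence times."""
    rng = np.random.default_rng(seed)
    nodes = [f"t{i}" for i in range(n_tips)]
    heights = [0.0] * n_tips
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        bi = t - heights[i]
        bj = t - heights[j]
        merged = f"({nodes[i]}:{bi:.8f},{nodes[j]}:{bj:.8f})"
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        heights = [h for idx, h in enumerate(heights) if idx not in (i, j)]
        nodes.append(merged)
        heights.append(t)
    return nodes[0] + ";"
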