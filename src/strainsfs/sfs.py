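"""Folded site-frequency spectra: construction from quasi-phased
haplotypes and hypergeometric projection to a fixed sample size."""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = ["FoldedSFS", "build_folded_sfs", "project_sfs", "site_minor_counts"]

_CLASSES = ("synonymous", "nonsynonymous")
DEGENERACY_TO_CLASS = {"4D": "synonymous", "1D": "nonsynonymous"}


@dataclass
class FoldedSFS:
    """Minor-allele-frequency spectrum.

    counts[i-1] holds the (possibly fractional) number of sites with
    minor-allele count i, for i = 1..n//2.  L is the number of monitored
    sites including monomorphic ones.
    """

    n: int
    counts: np.ndarray
    L: float
    mut_class: str
    species: str = ""
    gene_class: str = "core"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.counts.shape != (self.n // 2,):
            raise ValueError(
                f"counts must have length n//2 = {self.n // 2}, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mut_class not in _CLASSES:
            raise ValueError(f"mut_class must be one of {_CLASSES}")
        if self.L < self.counts.sum() - 1e-9:
            raise ValueError("L must be at least the number of variable sites")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_tsv(self, path=None) -> str | None:
        buf = io.StringIO()
        buf.write(f"# n={self.n}\n# L={float(self.L)!r}\n"
                  f"# class={self.mut_class}\n")
        buf.write(f"# species={self.species}\n# gene_class={self.gene_class}\n")
        buf.write("bin\tcount\n")
        for i, c in enumerate(self.counts, start=1):
            buf.write(f"{i}\t{float(c)!r}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, source) -> "FoldedSFS":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        meta = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif not line.startswith("bin"):
                b, c = line.split("\t")
                rows.append((int(b), float(c)))
        rows.sort()
        counts = np.array([c for _, c in rows])
        return cls(n=int(meta["n"]), counts=counts, L=float(meta["L"]),
                   mut_class=meta["class"], species=meta.get("species", ""),
                   gene_class=meta.get("gene_class", "core"))


def site_minor_counts(haplotypes: list, mut_class: str) -> pd.DataFrame:
    """Per-site (minor count m, called haplotypes c) from QP haplotypes.

    ``haplotypes`` is a list of QPHaplotype-like objects exposing
    ``calls``: a mapping site-key -> allele (None for missing) and
    ``degeneracy``: mapping site-key -> "1D"/"4D" (may live on the first
    haplotype only; all haplotypes of a species share annotations).

    Sites with more than two observed alleles are dropped with a warning.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    want = {v: k for k, v in DEGENERACY_TO_CLASS.items()}[mut_class]
    degeneracy = {}
    for h in haplotypes:
        degeneracy.update(getattr(h, "degeneracy", {}))
    sites = sorted(k for k, d in degeneracy.items() if d == want)
    records = []
    n_dropped = 0
    for s in sites:
        alleles = [h.calls.get(s) for h in haplotypes]
        called = [a for a in alleles if a is not None]
        c = len(called)
        if c == 0:
            continue
        uniq = set(called)
        if len(uniq) > 2:
            n_dropped += 1
            continue
        if len(uniq) == 1:
            m = 0
        else:
            a0 = next(iter(uniq))
            k0 = sum(1 for a in called if a == a0)
            m = min(k0, c - k0)
        records.append((s, m, c))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} site(s) with >2 alleles "
            "(biallelic assumption)", stacklevel=2)
    return pd.DataFrame(records, columns=["site", "m", "c"])


def build_folded_sfs(haplotypes: list, mut_class: str,
                     species: str = "", gene_class: str = "core"
                     ) -> tuple[pd.DataFrame, FoldedSFS]:
    """Raw folded SFS over all haplotypes plus the per-site table.

    The raw spectrum bins sites by their minor-allele count m; sites
    called in fewer haplotypes than the full panel keep their observed
    m.  Monomorphic sites contribute to L only.
    """
    table = site_minor_counts(haplotypes, mut_class)
    n = len(haplotypes)
    counts = np.zeros(n // 2)
    L = 0
    for _, row in table.iterrows():
        L += 1
        m = int(row["m"])
        if 1 <= m <= n // 2:
            counts[m - 1] += 1
    sfs = FoldedSFS(n=n, counts=counts, L=float(L), mut_class=mut_class,
                    species=species, gene_class=gene_class)
    return table, sfs


def project_sfs(table: pd.DataFrame, n_target: int = 14,
                mut_class: str = "synonymous", species: str = "",
                gene_class: str = "core") -> FoldedSFS:
    """Project per-site (m, c) counts down to ``n_target`` haplotypes.

    Sites called in fewer than n_target haplotypes are omitted entirely
    (from both the spectrum and L).  Each retained site distributes the
    hypergeometric probability of drawing j minor alleles out of
    n_target across folded bins min(j, n_target - j); the monomorphic
    mass (j = 0 or j = n_target) is discarded from the spectrum.
    Fractional bin counts are retained.
    """
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if np.any(table["m"] > table["c"]):
        raise ValueError("minor count m exceeds called haplotypes c")
    keep = table[table["c"] >= n_target]
    half = n_target // 2
    counts = np.zeros(half)
    L = 0.0
    j = np.arange(0, n_target + 1)
    jf = np.minimum(j, n_target - j)
    for m, c, nrep in keep.groupby(["m", "c"]).size().reset_index(
            name="nsites").itertuples(index=False):
        L += nrep
        if m == 0:
            continue
        pmf = hypergeom.pmf(j, c, m, n_target)
        for jj, mass in zip(jf, pmf):
            if jj >= 1:
                counts[jj - 1] += nrep * mass
    return FoldedSFS(n=n_target, counts=counts, L=L, mut_class=mut_class,
                     species=species, gene_class=gene_class)
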