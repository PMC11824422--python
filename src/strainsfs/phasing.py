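"""Quasi-phasing of per-host call tables and sample/site/gene filters.

A quasi-phased haplotype records, for every monitored site in one host,
the genotype of the host's dominant lineage: the major allele where its
within-host frequency is at least 0.8 and read depth at least 20, and
an explicit missing state otherwise (the 0.5-0.8 frequency band is
treated as unphaseable).

Coordinates are 0-based half-open throughout; mask intervals use union
semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QPHaplotype",
    "GeneClassTable",
    "MaskTrack",
    "MAJOR_FREQ_MIN",
    "MIN_SITE_DEPTH",
    "CLONAL_DIVERGENCE_THRESHOLD",
    "call_quasi_phased",
    "filter_genes",
    "exclude_clonal",
    "apply_masks",
    "mean_depth_filter",
    "read_host_site_calls",
    "write_qp_haplotypes",
]

MAJOR_FREQ_MIN = 0.8            # call major allele iff freq >= 0.8
MIN_SITE_DEPTH = 20             # reads
MIN_SAMPLE_MEAN_DEPTH = 20.0    # per-(host, species) mean depth
CLONAL_DIVERGENCE_THRESHOLD = 2e-4   # per bp
SWEEP_FLANK = 1000              # bp masked on each side of a sweep
RECOMB_WINDOW = 1000            # bp tiling of the recombination track

CALL_COLUMNS = ["species", "host", "contig", "pos0", "gene_id",
                "degeneracy", "major_freq", "depth"]
MISSING = "."


@dataclass
class QPHaplotype:
    """Dominant-lineage genotype for one (species, host)."""

    host: str
    calls: dict = field(default_factory=dict)       # (contig,pos0) -> allele|None
    degeneracy: dict = field(default_factory=dict)  # (contig,pos0) -> "1D"/"4D"

    def n_called(self) -> int:
        return sum(1 for v in self.calls.values() if v is not None)


@dataclass
class GeneClassTable:
    """gene_id -> prevalence and core/accessory/excluded class."""

    table: pd.DataFrame     # columns: gene_id, prevalence, gene_class

    def genes(self, gene_class: str) -> list[str]:
        t = self.table
        return sorted(t.loc[t["gene_class"] == gene_class, "gene_id"])


@dataclass
class MaskTrack:
    """Half-open masked intervals (union semantics)."""

    intervals: list = field(default_factory=list)   # (contig, start0, end0, kind)

    def __post_init__(self):
        for contig, start, end, kind in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {contig}:{start}-{end}")

    def covers(self, contig: str, pos0: int) -> bool:
        return any(c == contig and s <= pos0 < e
                   for c, s, e, _ in self.intervals)

    def mask_array(self, contig: str, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=bool)
        for c, s, e, _ in self.intervals:
            if c == contig:
                out[max(0, s):min(length, e)] = True
        return out


def call_quasi_phased(calls: pd.DataFrame,
                      min_depth_site: int = MIN_SITE_DEPTH) -> QPHaplotype:
    """Quasi-phase one (species, host) call table.

    A site is called as the host's major allele iff major_freq >= 0.8
    and depth >= min_depth_site; otherwise it is explicitly missing.
    """
    if len(calls) == 0:
        return QPHaplotype(host="", calls={}, degeneracy={})
    hosts = calls["host"].unique()
    species = calls["species"].unique()
    if len(hosts) != 1 or len(species) != 1:
        raise ValueError("call_quasi_phased expects a single (species, host)")
    if (calls["major_freq"] < 0.5 - 1e-9).any() or \
            (calls["major_freq"] > 1.0 + 1e-9).any():
        raise ValueError("major_freq must lie in [0.5, 1]")
    callable_ = (calls["major_freq"] >= MAJOR_FREQ_MIN) & \
                (calls["depth"] >= min_depth_site)
    allele_col = "major_allele" if "major_allele" in calls.columns else None
    haplo = QPHaplotype(host=str(hosts[0]))
    for row, ok in zip(calls.itertuples(index=False), callable_):
        key = (row.contig, int(row.pos0))
        haplo.degeneracy[key] = row.degeneracy
        if ok:
            haplo.calls[key] = (getattr(row, "major_allele")
                                if allele_col else "major")
        else:
            haplo.calls[key] = None
    return haplo


def filter_genes(copy_numbers: pd.DataFrame) -> GeneClassTable:
    """Classify genes as core/accessory/excluded from a host x gene
    copy-number matrix.

    A gene with copy number > 3.0 in any host is excluded outright.
    Presence in a host requires 0.3 <= CN <= 3.0; prevalence is the
    fraction of hosts where the gene is present.  core: >= 0.95;
    accessory: 0.30-0.70; everything else excluded.
    """
    if copy_numbers.size == 0:
        raise ValueError("empty copy-number matrix")
    if (copy_numbers.values < 0).any():
        raise ValueError("copy numbers must be non-negative")
    rows = []
    for gene in copy_numbers.columns:
        cn = copy_numbers[gene].to_numpy(dtype=float)
        if np.any(cn > 3.0):
            rows.append((gene, np.nan, "excluded"))
            continue
        present = (cn >= 0.3) & (cn <= 3.0)
        prev = present.mean()
        if prev >= 0.95:
            cls = "core"
        elif 0.30 <= prev <= 0.70:
            cls = "accessory"
        else:
            cls = "excluded"
        rows.append((gene, prev, cls))
    table = pd.DataFrame(rows, columns=["gene_id", "prevalence", "gene_class"])
    counts = table["gene_class"].value_counts().to_dict()
    logger.info("gene filter: %s", counts)
    return GeneClassTable(table)


def exclude_clonal(divergences: pd.DataFrame,
                   threshold: float = CLONAL_DIVERGENCE_THRESHOLD,
                   call_counts: dict | None = None) -> set:
    """Retain one representative per cluster of near-clonal hosts.

    Hosts with pairwise divergence below ``threshold`` form edges of a
    graph; within each connected component the host with the highest
    site-call count is kept (ties broken by lexicographic host id).
    """
    hosts = list(divergences.index)
    if list(divergences.columns) != hosts:
        raise ValueError("divergence matrix must be square with matching labels")
    D = divergences.to_numpy(dtype=float)
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("divergence matrix must be symmetric")
    call_counts = call_counts or {}
    parent = {h: h for h in hosts}

    def find(h):
        while parent[h] != h:
            parent[h] = parent[parent[h]]
            h = parent[h]
        return h

    for i, a in enumerate(hosts):
        for j in range(i + 1, len(hosts)):
            if D[i, j] < threshold:
                parent[find(hosts[j])] = find(a)
    components = {}
    for h in hosts:
        components.setdefault(find(h), []).append(h)
    retained = set()
    for members in components.values():
        members.sort(key=lambda h: (-call_counts.get(h, 0), h))
        retained.add(members[0])
    logger.info("clonal exclusion: retained %d of %d hosts",
                len(retained), len(hosts))
    return retained


def apply_masks(haplotypes: list[QPHaplotype], recomb_rates: pd.DataFrame,
                sweeps: MaskTrack) -> tuple[list[QPHaplotype], MaskTrack]:
    """Remove sites in low-recombination windows or near sweeps.

    recomb_rates: columns (contig, window_start0, rate) on non-overlapping
    1,000-bp tiles; windows with rate strictly below the median (over
    windows with defined rates) are masked.  Sweep intervals are expanded
    by 1,000 bp on each side (clipped at zero).  Idempotent.
    """
    intervals = []
    rates = recomb_rates.dropna(subset=["rate"])
    if len(rates):
        median = float(np.median(rates["rate"]))
        low = rates[rates["rate"] < median]
        for row in low.itertuples(index=False):
            s = int(row.window_start0)
            intervals.append((row.contig, s, s + RECOMB_WINDOW,
                              "low_recombination"))
    for contig, s, e, _kind in sweeps.intervals:
        intervals.append((contig, max(0, s - SWEEP_FLANK), e + SWEEP_FLANK,
                          "sweep"))
    track = MaskTrack(intervals)

    masked = []
    n_removed = 0
    for h in haplotypes:
        calls, degen = {}, {}
        for key, allele in h.calls.items():
            if track.covers(*key):
                n_removed += 1
                continue
            calls[key] = allele
            degen[key] = h.degeneracy.get(key)
        masked.append(QPHaplotype(host=h.host, calls=calls, degeneracy=degen))
    logger.info("masking: removed %d site calls across %d haplotypes",
                n_removed, len(haplotypes))
    return masked, track


def mean_depth_filter(calls: pd.DataFrame,
                      min_mean_depth: float = MIN_SAMPLE_MEAN_DEPTH) -> set:
    """Hosts passing the per-(host, species) mean-depth filter."""
    means = calls.groupby("host")["depth"].mean()
    return set(means[means >= min_mean_depth].index)


def read_host_site_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table missing columns {missing}")
    return df


def write_qp_haplotypes(haplotypes: list[QPHaplotype], path) -> None:
    """TSV with one row per (host, site); missing state written as '.'"""
    rows = []
    for h in haplotypes:
        for (contig, pos0), allele in sorted(h.calls.items()):
            rows.append((h.host, contig, pos0,
                         h.degeneracy.get((contig, pos0), ""),
                         MISSING if allele is None else allele))
    pd.DataFrame(rows, columns=["host", "contig", "pos0", "degeneracy",
                                "allele"]).to_csv(path, sep="\t", index=False)


def read_qp_haplotypes(path) -> list[QPHaplotype]:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str})
    out = []
    for host, grp in df.groupby("host"):
        h = QPHaplotype(host=str(host))
        for row in grp.itertuples(index=False):
            key = (row.contig, int(row.pos0))
            h.degeneracy[key] = row.degeneracy
            h.calls[key] = None if row.allele == MISSING else row.allele
        out.append(h)
    return out
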