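"""Quasi-phasing rules and sample/site/gene filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from strainsfs.phasing import (MaskTrack, apply_masks, call_quasi_phased,
                               exclude_clonal, filter_genes,
                               mean_depth_filter, read_qp_haplotypes,
                               write_qp_haplotypes, QPHaplotype)


def _calls(rows):
    df = pd.DataFrame(rows, columns=["pos0", "major_freq", "depth"])
    df["species"] = "sp"
    df["host"] = "h1"
    df["contig"] = "c1"
    df["gene_id"] = "g1"
    df["degeneracy"] = "4D"
    return df


class TestCallQuasiPhased:
    def test_clear_call(self):
        h = call_quasi_phased(_calls([(0, 0.85, 25)]))
        assert h.calls[("c1", 0)] is not None

    def test_boundary_inclusive_at_080(self):
        h = call_quasi_phased(_calls([(0, 0.80, 25), (1, 0.799, 25)]))
        assert h.calls[("c1", 0)] is not None
        assert h.calls[("c1", 1)] is None

    def test_depth_below_20_missing(self):
        h = call_quasi_phased(_calls([(0, 0.95, 19)]))
        assert h.calls[("c1", 0)] is None

    def test_empty_input(self):
        h = call_quasi_phased(_calls([]))
        assert h.calls == {}

    def test_multiple_hosts_rejected(self):
        df = _calls([(0, 0.9, 30)])
        df2 = df.copy()
        df2["host"] = "h2"
        with pytest.raises(ValueError):
            call_quasi_phased(pd.concat([df, df2]))

    def test_truth_recovery_on_clean_synthetic(self, scenario_factory):
        # No strain mixture, deep coverage: every called site must equal
        # the ground-truth dominant haplotype.
        from strainsfs.synthetic import simulate_host_pileup
        sc = scenario_factory(strain_major_fraction=1.0, depth_mean=100.0,
                              genome_length=2000, theta_s=40.0, seed=5)
        calls, truth = simulate_host_pileup(sc)
        dominant = truth["dominant"]
        n_called = n_correct = 0
        for host, grp in calls.groupby("host"):
            h = call_quasi_phased(grp)
            for (contig, pos), allele in h.calls.items():
                if allele is None:
                    continue
                n_called += 1
                n_correct += int(allele == dominant.loc[host, pos])
        assert n_called > 0
        assert n_correct == n_called


class TestFilterGenes:
    def _matrix(self, prevalence, n_hosts=100):
        cn = np.zeros((n_hosts, 1))
        cn[: int(round(prevalence * n_hosts)), 0] = 1.0
        return pd.DataFrame(cn, columns=["g"])

    def test_core_at_96(self):
        t = filter_genes(self._matrix(0.96)).table
        assert t.iloc[0]["gene_class"] == "core"

    def test_accessory_at_50_excluded_at_80(self):
        assert filter_genes(self._matrix(0.50)).table.iloc[0][
            "gene_class"] == "accessory"
        assert filter_genes(self._matrix(0.80)).table.iloc[0][
            "gene_class"] == "excluded"

    def test_boundaries(self):
        assert filter_genes(self._matrix(0.95)).table.iloc[0][
            "gene_class"] == "core"
        assert filter_genes(self._matrix(0.30)).table.iloc[0][
            "gene_class"] == "accessory"
        assert filter_genes(self._matrix(0.70)).table.iloc[0][
            "gene_class"] == "accessory"

    def test_high_copy_number_excludes_gene_entirely(self):
        cn = pd.DataFrame({"g": [1.0] * 99 + [3.5]})
        t = filter_genes(cn).table
        assert t.iloc[0]["gene_class"] == "excluded"

    def test_out_of_range_copy_number_not_present(self):
        cn = pd.DataFrame({"g": [0.2] * 60 + [1.0] * 40})
        t = filter_genes(cn).table
        assert t.iloc[0]["prevalence"] == pytest.approx(0.40)
        assert t.iloc[0]["gene_class"] == "accessory"

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame())


class TestExcludeClonal:
    def _dm(self, hosts, close_pairs):
        d = pd.DataFrame(1e-3, index=hosts, columns=hosts)
        for a, b, v in close_pairs:
            d.loc[a, b] = d.loc[b, a] = v
        np.fill_diagonal(d.values, 0.0)
        return d

    def test_no_close_pairs_keeps_all(self):
        d = self._dm(["a", "b", "c"], [])
        assert exclude_clonal(d) == {"a", "b", "c"}

    def test_close_pair_keeps_one(self):
        d = self._dm(["a", "b", "c"], [("a", "b", 1e-4)])
        kept = exclude_clonal(d)
        assert len(kept & {"a", "b"}) == 1
        assert "c" in kept

    def test_triangle_keeps_one_brute_force(self):
        d = self._dm(["a", "b", "c"],
                     [("a", "b", 1e-4), ("b", "c", 1e-4), ("a", "c", 1e-4)])
        kept = exclude_clonal(d)
        assert len(kept) == 1
        # brute force: every maximal independent set of the clique has size 1
        edges = {("a", "b"), ("b", "c"), ("a", "c")}
        best = max(
            (s for s in itertools.chain.from_iterable(
                itertools.combinations("abc", r) for r in range(1, 4))
             if not any((x, y) in edges or (y, x) in edges
                        for x, y in itertools.combinations(s, 2))),
            key=len)
        assert len(kept) == len(best)

    def test_representative_prefers_call_counts_then_lexicographic(self):
        d = self._dm(["a", "b"], [("a", "b", 1e-4)])
        assert exclude_clonal(d, call_counts={"a": 5, "b": 9}) == {"b"}
        assert exclude_clonal(d) == {"a"}

    def test_retained_set_is_independent(self):
        rng = np.random.default_rng(3)
        hosts = [f"h{i}" for i in range(12)]
        d = pd.DataFrame(rng.uniform(0, 4e-4, (12, 12)), index=hosts,
                         columns=hosts)
        d = (d + d.T) / 2
        np.fill_diagonal(d.values, 0.0)
        kept = exclude_clonal(d)
        for a, b in itertools.combinations(sorted(kept), 2):
            assert d.loc[a, b] >= 2e-4


def _hap_with_sites(positions, contig="c1"):
    h = QPHaplotype(host="h1")
    for p in positions:
        h.calls[(contig, p)] = "A"
        h.degeneracy[(contig, p)] = "4D"
    return h


class TestApplyMasks:
    def test_sweep_flanking_kilobase(self):
        h = _hap_with_sites([3999, 4000, 5500, 6999, 7000])
        rates = pd.DataFrame(columns=["contig", "window_start0", "rate"])
        sweeps = MaskTrack([("c1", 5000, 6000, "sweep")])
        masked, track = apply_masks([h], rates, sweeps)
        kept = set(p for (_, p) in masked[0].calls)
        assert kept == {3999, 7000}

    def test_median_rule_is_strict_less_than(self):
        h = _hap_with_sites([500, 1500, 2500, 3500, 4500])
        rates = pd.DataFrame({
            "contig": ["c1"] * 5,
            "window_start0": [0, 1000, 2000, 3000, 4000],
            "rate": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        masked, _ = apply_masks([h], rates, MaskTrack([]))
        kept = set(p for (_, p) in masked[0].calls)
        assert kept == {2500, 3500, 4500}   # median 3; windows 1,2 masked

    def test_uniform_rates_and_no_sweeps_mask_nothing(self):
        h = _hap_with_sites([100, 1100, 2100])
        rates = pd.DataFrame({
            "contig": ["c1"] * 3,
            "window_start0": [0, 1000, 2000],
            "rate": [2.0, 2.0, 2.0],
        })
        masked, track = apply_masks([h], rates, MaskTrack([]))
        assert len(masked[0].calls) == 3
        assert track.intervals == []

    def test_idempotent(self):
        h = _hap_with_sites([500, 1500, 2500, 5500])
        rates = pd.DataFrame({
            "contig": ["c1"] * 3,
            "window_start0": [0, 1000, 2000],
            "rate": [1.0, 5.0, 9.0],
        })
        sweeps = MaskTrack([("c1", 5000, 6000, "sweep")])
        once, _ = apply_masks([h], rates, sweeps)
        twice, _ = apply_masks(once, rates, sweeps)
        assert once[0].calls == twice[0].calls

    def test_sweep_clipped_at_contig_start(self):
        sweeps = MaskTrack([("c1", 300, 600, "sweep")])
        h = _hap_with_sites([0, 100])
        rates = pd.DataFrame(columns=["contig", "window_start0", "rate"])
        masked, track = apply_masks([h], rates, sweeps)
        assert masked[0].calls == {}
        assert track.intervals[0][1] == 0


class TestMiscFilters:
    def test_mean_depth_filter(self):
        df = pd.DataFrame({
            "host": ["a"] * 3 + ["b"] * 3,
            "depth": [25, 25, 25, 10, 15, 20],
        })
        assert mean_depth_filter(df) == {"a"}

    def test_qp_haplotype_tsv_roundtrip(self, tmp_path):
        h = QPHaplotype(host="h1",
                        calls={("c1", 0): "A", ("c1", 5): None},
                        degeneracy={("c1", 0): "4D", ("c1", 5): "1D"})
        path = tmp_path / "qp.tsv"
        write_qp_haplotypes([h], path)
        back = read_qp_haplotypes(path)
        assert back[0].calls == h.calls
        assert back[0].degeneracy == h.degeneracy

    def test_mask_track_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            MaskTrack([("c1", 5, 5, "sweep")])
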