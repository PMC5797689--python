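"""Mapping, annotation attribution, clusters, enrichment, recombination."""

import random

import numpy as np
import pandas as pd
import pytest

from hasrna.core import CountMatrix
from hasrna.genomic import (
    AnnotationSet,
    MappingTable,
    attribute_annotation,
    build_clusters,
    cluster_association,
    correlate_with_recombination,
    exact_map,
    family_enrichment,
    gene_proximity_enrichment,
    nucleotide_composition,
    recombination_rate,
    reverse_complement,
    size_class_enrichment,
    spatial_enrichment,
    windowed_counts,
)
from hasrna.normalize import rpmqn
from hasrna.simulate import simulate_design, simulate_genome, simulate_srna_counts


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestExactMap:
    def test_unique_substring_found_once(self):
        rng = random.Random(0)
        genome = {"chr1": _random_seq(rng, 5000)}
        query = genome["chr1"][100:121]
        table = exact_map({"q": query}, genome)
        assert table.entries["q"] == [("chr1", 100, 121, "+")]

    def test_absent_srna_unmapped(self):
        table = exact_map({"q": "A" * 21}, {"chr1": "C" * 1000})
        assert "q" not in table.entries

    def test_minus_strand_hit(self):
        rng = random.Random(1)
        genome = {"chr1": _random_seq(rng, 2000)}
        query = reverse_complement(genome["chr1"][500:522])
        table = exact_map({"q": query}, genome)
        assert ("chr1", 500, 522, "-") in table.entries["q"]

    def test_matches_naive_scan_oracle(self):
        rng = random.Random(2)
        genome = {"chr1": _random_seq(rng, 20_000), "chr2": _random_seq(rng, 8_000)}
        queries = {}
        for i in range(20):
            queries[f"q{i}"] = _random_seq(rng, 21)
        for i in range(10):  # guaranteed hits, some on minus strand
            chrom = "chr1" if i % 2 else "chr2"
            start = rng.randrange(len(genome[chrom]) - 21)
            sub = genome[chrom][start : start + 21]
            queries[f"p{i}"] = sub if i % 3 else reverse_complement(sub)

        def oracle():
            hits = {}
            for qid, q in queries.items():
                found = []
                rc = reverse_complement(q)
                for chrom, seq in genome.items():
                    for pos in range(len(seq) - len(q) + 1):
                        window = seq[pos : pos + len(q)]
                        if window == q:
                            found.append((chrom, pos, pos + len(q), "+"))
                        if window == rc and rc != q:
                            found.append((chrom, pos, pos + len(q), "-"))
                if found:
                    hits[qid] = sorted(found)
            return hits

        table = exact_map(queries, genome)
        assert {k: sorted(v) for k, v in table.entries.items()} == oracle()


class TestAttributeAnnotation:
    def _ann(self):
        genes = pd.DataFrame(
            [("chr1", 1000, 2000, "+", "g1")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )
        repeats = pd.DataFrame(
            [("chr1", 5000, 5500, "-", "LTR_Gypsy", "r1")],
            columns=["chrom", "start", "end", "strand", "family", "repeat_id"],
        )
        return AnnotationSet(genes=genes, repeats=repeats)

    def test_single_categories(self):
        mapping = MappingTable(
            {
                "in_gene": [("chr1", 1100, 1121, "+")],
                "in_repeat": [("chr1", 5100, 5121, "+")],
                "nowhere": [("chr1", 9000, 9021, "+")],
            }
        )
        labels = attribute_annotation(mapping, self._ann())
        assert labels["in_gene"] == frozenset({"gene"})
        assert labels["in_repeat"] == frozenset({"repeat"})
        assert labels["nowhere"] == frozenset({"intergenic"})

    def test_conjunction_for_multi_position_srna(self):
        mapping = MappingTable(
            {"multi": [("chr1", 1100, 1121, "+"), ("chr1", 9000, 9021, "+")]}
        )
        labels = attribute_annotation(mapping, self._ann())
        assert labels["multi"] == frozenset({"gene", "intergenic"})

    def test_unmapped_absent_and_unknown_chrom_rejected(self):
        labels = attribute_annotation(MappingTable({}), self._ann())
        assert labels == {}
        mapping = MappingTable({"x": [("chrZ", 0, 21, "+")]})
        with pytest.raises(ValueError, match="chrZ"):
            attribute_annotation(mapping, self._ann(), chrom_names=["chr1"])


class TestBuildClusters:
    def _expr(self, ids, value=8.0):
        return pd.DataFrame(value, index=pd.Index(ids), columns=["L1", "L2"])

    def test_gap_rule(self):
        mapping = MappingTable(
            {
                "a": [("chr1", 100, 121, "+")],
                "b": [("chr1", 250, 271, "+")],  # gap 129 -> merge
                "c": [("chr1", 500, 521, "+")],  # gap 229 -> separate
            }
        )
        clusters = build_clusters(mapping, self._expr(["a", "b", "c"]), min_members=1)
        spans = sorted((c.start, c.end) for c in clusters)
        assert spans == [(100, 271), (500, 521)]

    def test_min_members_filter(self):
        mapping = MappingTable(
            {f"s{i}": [("chr1", 100 + 10 * i, 121 + 10 * i, "+")] for i in range(3)}
        )
        assert build_clusters(mapping, self._expr([f"s{i}" for i in range(3)])) == []

    def test_repeat_normalized_expression(self):
        # one member with 4 genomic positions and 8 rpmqn contributes 2 per position
        positions = [("chr1", 100 + 30 * k, 121 + 30 * k, "+") for k in range(4)]
        mapping = MappingTable(
            {"multi": positions}
            | {f"s{i}": [("chr1", 130 + 10 * i, 151 + 10 * i, "+")] for i in range(4)}
        )
        ids = ["multi"] + [f"s{i}" for i in range(4)]
        clusters = build_clusters(mapping, self._expr(ids, 8.0), min_members=5)
        assert len(clusters) == 1
        # 4 positions x (8/4) from "multi" + 4 singles x 8
        assert clusters[0].expression["L1"] == pytest.approx(4 * 2 + 4 * 8)

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            ids = [f"s{i}" for i in range(n)]
            entries = {}
            for i, srna in enumerate(ids):
                k = int(rng.integers(1, 3))
                entries[srna] = [
                    (
                        f"chr{int(rng.integers(1, 3))}",
                        int(start := rng.integers(0, 20_000)),
                        int(start) + 21,
                        "+",
                    )
                    for _ in range(k)
                ]
            mapping = MappingTable(entries)
            expr = self._expr(ids, 1.0)
            got = sorted(
                (c.chrom, c.start, c.end, tuple(sorted(c.members)))
                for c in build_clusters(mapping, expr, gap=200, min_members=5)
            )
            assert got == _brute_force_clusters(entries, gap=200, min_members=5)


def _brute_force_clusters(entries, gap, min_members):
    """Graph-based single linkage: positions connected iff gap <= threshold."""
    import networkx as nx

    positions = [
        (chrom, start, end, srna)
        for srna, plist in entries.items()
        for chrom, start, end, _ in plist
    ]
    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            ci, si, ei, _ = positions[i]
            cj, sj, ej, _ = positions[j]
            if ci == cj and max(si, sj) - min(ei, ej) <= gap:
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = tuple(sorted({positions[i][3] for i in comp}))
        if len(members) < min_members:
            continue
        chrom = positions[next(iter(comp))][0]
        start = min(positions[i][1] for i in comp)
        end = max(positions[i][2] for i in comp)
        out.append((chrom, start, end, members))
    return sorted(out)


class TestClusterAssociation:
    def test_empty(self, tiny_design):
        table = cluster_association([], tiny_design)
        assert table.empty

    def test_planted_cluster_recovered(self):
        design = simulate_design(7, 14, seed=2)
        matrix, truth = simulate_srna_counts(
            design, n_srnas=600, n_planted_pos=0, n_planted_neg=40, seed=9
        )
        m = rpmqn(matrix)
        neg_ids = [p.srna_id for p in truth.planted]
        # co-locate planted sRNAs in 200-bp loci of 8; background far away
        entries = {}
        for k, srna in enumerate(neg_ids):
            locus, slot = divmod(k, 8)
            entries[srna] = [("chr1", 100_000 * (locus + 1) + 25 * slot,
                              100_000 * (locus + 1) + 25 * slot + 22, "+")]
        clusters = build_clusters(MappingTable(entries), m)
        assert len(clusters) == 5
        table = cluster_association(clusters, design)
        called_neg = table[table["direction"] == "negative"]
        assert len(called_neg) == 5


class TestWindowedCounts:
    def test_position_lands_in_window(self):
        mapping = MappingTable({"s": [("chr1", 1_500_000, 1_500_021, "+")]})
        wc = windowed_counts(mapping, ["s"], {"chr1": 3_000_000}, 1_000_000)
        assert wc.loc[(wc.start == 1_000_000), "count"].iloc[0] == 1
        assert wc["count"].sum() == 1

    def test_conservation_and_empty_subset(self):
        rng = np.random.default_rng(0)
        entries = {
            f"s{i}": [
                ("chr1", int(p), int(p) + 21, "+")
                for p in rng.integers(0, 2_000_000 - 21, rng.integers(1, 4))
            ]
            for i in range(30)
        }
        mapping = MappingTable(entries)
        wc = windowed_counts(mapping, entries.keys(), {"chr1": 2_000_000}, 100_000)
        assert wc["count"].sum() == sum(len(v) for v in entries.values())
        empty = windowed_counts(mapping, [], {"chr1": 2_000_000}, 100_000)
        assert (empty["count"] == 0).all()


class TestSpatialEnrichment:
    def test_subset_equal_universe_factor_one_nothing_flagged(self):
        rng = np.random.default_rng(3)
        entries = {
            f"s{i}": [("chr1", int(p), int(p) + 21, "+")]
            for i, p in enumerate(rng.integers(0, 5_000_000, 100))
        }
        mapping = MappingTable(entries)
        ids = list(entries)
        res = spatial_enrichment(ids, ids, mapping, {"chr1": 5_000_000}, runs=50, seed=0)
        occupied = res[res.observed > 0]
        np.testing.assert_allclose(occupied["factor"], 1.0)
        assert not res["flagged"].any()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()

    def test_empty_windows_never_flagged(self):
        mapping = MappingTable({"s": [("chr1", 10, 31, "+")]})
        res = spatial_enrichment(["s"], ["s"], mapping, {"chr1": 3_000_000},
                                 runs=20, seed=0)
        assert not res.loc[res.observed == 0, "flagged"].any()


class TestSizeClassEnrichment:
    def test_pure_24nt_subset(self):
        lengths = {}
        ids = []
        for i in range(60):
            L = 24 if i < 30 else 22
            ids.append(f"s{i}")
            lengths[f"s{i}"] = L
        subset = [f"s{i}" for i in range(30)]  # all the 24-nt ones
        res = size_class_enrichment(subset, ids, lengths=lengths, runs=400, seed=1)
        by = {r.unit: r for r in res}
        assert by["24"].factor > 1 and by["24"].p_enriched < 0.05
        assert by["22"].observed == 0 and by["22"].factor == 0.0
        assert by["22"].p_depleted < 0.05

    def test_random_subset_is_calibrated(self):
        rng = np.random.default_rng(5)
        lengths = {f"s{i}": int(rng.choice([21, 22, 24])) for i in range(200)}
        ids = list(lengths)
        hits = 0
        for seed in range(5):
            subset = list(np.random.default_rng(seed).choice(ids, 40, replace=False))
            res = size_class_enrichment(subset, ids, lengths=lengths, runs=400,
                                        seed=seed)
            if any(min(r.p_enriched, r.p_depleted) < 0.05 for r in res):
                hits += 1
        assert hits <= 2


class TestFamilyEnrichment:
    def test_planted_family_bias_detected(self):
        rng = np.random.default_rng(2)
        lengths = {f"s{i}": int(rng.choice([22, 24])) for i in range(300)}
        ids = list(lengths)
        families = {
            s: {"LTR_Gypsy"} if i < 150 else {"DNA_hAT"}
            for i, s in enumerate(ids)
        }
        subset = ids[:60]  # all Gypsy
        res = family_enrichment(subset, ids, families, lengths=lengths, runs=400,
                                seed=3)
        by = {r.unit: r for r in res}
        assert by["LTR_Gypsy"].factor > 1 and by["LTR_Gypsy"].p_enriched < 0.05
        assert by["DNA_hAT"].p_depleted < 0.05

    def test_single_family_universe_factor_one(self):
        lengths = {f"s{i}": 22 for i in range(40)}
        ids = list(lengths)
        families = {s: {"LTR_Copia"} for s in ids}
        res = family_enrichment(ids[:10], ids, families, lengths=lengths, runs=50,
                                seed=0)
        assert res[0].factor == pytest.approx(1.0)

    def test_length_matched_draws(self):
        from hasrna.genomic import _length_matched_draw

        rng = np.random.default_rng(0)
        lengths = np.array([22] * 10 + [24] * 10)
        by_length = {22: np.arange(10), 24: np.arange(10, 20)}
        hist = {22: 3, 24: 5}
        for _ in range(20):
            draw = _length_matched_draw(rng, lengths, hist, by_length)
            drawn = lengths[draw]
            assert (drawn == 22).sum() == 3 and (drawn == 24).sum() == 5
            assert len(set(draw)) == len(draw)  # without replacement

    def test_subset_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            family_enrichment(["x"], ["a", "b"], {"a": {"X"}, "b": {"X"}},
                              lengths={"a": 22, "b": 24, "x": 22}, runs=10, seed=0)


class TestGeneProximity:
    def _de_genes(self):
        return pd.DataFrame(
            [("chr1", 50_000, 55_000, "+", "g1")],
            columns=["chrom", "start", "end", "strand", "gene_id"],
        )

    def test_subset_equal_universe_factor_one(self):
        rng = np.random.default_rng(4)
        entries = {
            f"s{i}": [("chr1", int(p), int(p) + 22, "+")]
            for i, p in enumerate(rng.integers(0, 200_000, 80))
        }
        mapping = MappingTable(entries)
        ids = list(entries)
        lengths = {s: 22 for s in ids}
        res, n_genes, _ = gene_proximity_enrichment(
            ids, ids, mapping, self._de_genes(), lengths=lengths, runs=50, seed=0
        )
        assert res.factor == pytest.approx(1.0)

    def test_planted_adjacency_enriched(self):
        rng = np.random.default_rng(5)
        near = {
            f"n{i}": [("chr1", int(p), int(p) + 22, "+")]
            for i, p in enumerate(rng.integers(49_500, 55_500, 40))
        }
        far = {
            f"f{i}": [("chr1", int(p), int(p) + 22, "+")]
            for i, p in enumerate(rng.integers(500_000, 900_000, 160))
        }
        mapping = MappingTable(near | far)
        ids = list(near) + list(far)
        lengths = {s: 22 for s in ids}
        res, n_genes, strands = gene_proximity_enrichment(
            list(near), ids, mapping, self._de_genes(), lengths=lengths,
            runs=400, seed=1,
        )
        assert res.factor > 1 and res.p_enriched < 0.05
        assert n_genes == 1
        assert strands["positions"].sum() == res.observed

    def test_flank_boundary_closed(self):
        mapping = MappingTable({"edge": [("chr1", 49_000, 49_022, "+")]})
        res, n_genes, _ = gene_proximity_enrichment(
            ["edge"], ["edge"], mapping, self._de_genes(),
            lengths={"edge": 22}, flank=1000, runs=10, seed=0,
        )
        assert res.observed == 1  # position starting exactly at start - 1 kbp


class TestRecombination:
    def test_linear_map_constant_rate(self):
        gmap = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "bp": [0, 2_000_000], "cM": [0.0, 4.0]}
        )
        rates = recombination_rate(gmap, {"chr1": 2_000_000}, window=1_000_000)
        np.testing.assert_allclose(rates["cm_per_mb"], [2.0, 2.0])

    def test_flat_segment_zero(self):
        gmap = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "bp": [0, 1_000_000, 2_000_000],
                "cM": [0.0, 0.0, 3.0],
            }
        )
        rates = recombination_rate(gmap, {"chr1": 2_000_000}, window=1_000_000)
        np.testing.assert_allclose(rates["cm_per_mb"], [0.0, 3.0])

    def test_matches_difference_oracle_on_random_map(self):
        rng = np.random.default_rng(6)
        bp = np.sort(rng.choice(np.arange(0, 5_000_001, 1000), 30, replace=False))
        bp[0], bp[-1] = 0, 5_000_000
        cm = np.cumsum(rng.random(30))
        gmap = pd.DataFrame({"chrom": "chr1", "bp": bp, "cM": cm})
        window = 500_000
        rates = recombination_rate(gmap, {"chr1": 5_000_000}, window=window)
        for r in rates.itertuples():
            c0 = np.interp(r.start, bp, cm)
            c1 = np.interp(r.end, bp, cm)
            assert r.cm_per_mb == pytest.approx((c1 - c0) / (window / 1e6))

    def test_non_monotone_rejected(self):
        gmap = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "bp": [0, 1000, 2000], "cM": [0.0, 2.0, 1.0]}
        )
        with pytest.raises(ValueError):
            recombination_rate(gmap, {"chr1": 10_000_000})

    def test_correlation_extremes(self):
        win = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 1_000_000, 2_000_000],
                "end": [1_000_000, 2_000_000, 3_000_000],
                "count": [1.0, 2.0, 3.0],
            }
        )
        rates = win.rename(columns={"count": "cm_per_mb"})
        up = correlate_with_recombination(win, rates)
        assert up.loc[up.chrom == "genome", "r"].iloc[0] == pytest.approx(1.0)
        rates_down = rates.copy()
        rates_down["cm_per_mb"] = [3.0, 2.0, 1.0]
        down = correlate_with_recombination(win, rates_down)
        assert down.loc[down.chrom == "genome", "r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        win = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 1_000_000],
                "end": [1_000_000, 2_000_000],
                "count": [1.0, 1.0],
            }
        )
        rates = win.rename(columns={"count": "cm_per_mb"}).assign(
            cm_per_mb=[1.0, 2.0]
        )
        with pytest.raises(ValueError):
            correlate_with_recombination(win, rates)


class TestNucleotideComposition:
    def test_uniform_start_base(self):
        freqs = nucleotide_composition(["AGC", "ATT", "ACG"], length=3)
        assert freqs.loc["A", 1] == 1.0

    def test_columns_sum_to_one_and_sampling(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 22)) for _ in range(800)]
        freqs = nucleotide_composition(seqs, length=22)
        np.testing.assert_allclose(freqs.sum(axis=0), 1.0)
        # ~binomial(800, .25) sampling error: 5 sigma ~ 0.077
        assert ((freqs - 0.25).abs() < 0.08).all().all()

    def test_errors(self):
        with pytest.raises(ValueError):
            nucleotide_composition([], 22)
        with pytest.raises(ValueError):
            nucleotide_composition(["ACG", "ACGT"], 3)
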