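import numpy as np
import pandas as pd
import pytest

from snpsat.errors import InputError, UndefinedMetricError
from snpsat.io_formats import DepthTable, FeatureRecord
from snpsat.strain_profiles import (
    aggregate_snps_by_taxon,
    allele_frequency_spectrum,
    annotate_snp_context,
    cds_proportions,
    chi_square_nonsyn_syn,
    compute_dnds,
    relative_abundance,
    round_half_up,
    shared_snp_partition,
    snp_enriched_genes,
    strain_metrics,
)

from tests.conftest import make_record


class TestRelativeAbundance:
    def test_single_strain(self):
        (a,) = relative_abundance({"s": 10}, {"s": 1000})
        assert a.abundance == 1.0

    def test_symmetry_and_arithmetic(self):
        res = relative_abundance({"a": 100, "b": 200}, {"a": 1000, "b": 1000})
        assert [r.abundance for r in res] == pytest.approx([1 / 3, 2 / 3])
        eq = relative_abundance({"a": 5, "b": 10}, {"a": 500, "b": 1000})
        assert [r.abundance for r in eq] == pytest.approx([0.5, 0.5])

    def test_sums_to_one_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = {f"s{i}": int(rng.integers(1, 1000)) for i in range(20)}
        lengths = {s: int(rng.integers(1000, 9999)) for s in counts}
        res = relative_abundance(counts, lengths)
        assert sum(r.abundance for r in res) == pytest.approx(1.0, abs=1e-9)
        scaled = relative_abundance({s: 7 * n for s, n in counts.items()}, lengths)
        for a, b in zip(res, scaled):
            assert a.abundance == pytest.approx(b.abundance, abs=1e-12)

    def test_errors(self):
        with pytest.raises(UndefinedMetricError):
            relative_abundance({"a": 0}, {"a": 100})
        with pytest.raises(InputError):
            relative_abundance({"a": 1}, {"a": 0})


class TestStrainMetrics:
    def _table(self, depths):
        return DepthTable(
            "s",
            pd.DataFrame(
                {"chrom": "s", "pos": range(1, len(depths) + 1), "depth": depths}
            ),
        )

    def test_uniform_full_coverage(self):
        m = strain_metrics(self._table([5] * 100), 100, [])
        assert m.genome_depth == 5.0
        assert m.coverage == 1.0

    def test_half_covered(self):
        m = strain_metrics(self._table([10] * 50), 100, [])
        assert m.genome_depth == 5.0
        assert m.coverage == 0.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        depths = rng.integers(0, 40, 500)
        snps = [make_record(pos=i, chrom="s") for i in range(1, 21)]
        m = strain_metrics(self._table(depths), 1000, snps)
        assert m.genome_depth == pytest.approx(depths.sum() / 1000)
        assert m.coverage == pytest.approx((depths >= 1).sum() / 1000)
        assert m.snp_density == pytest.approx(20 / (depths >= 1).sum())


class TestAnnotate:
    def test_containment_inclusive(self):
        feats = [FeatureRecord("c", 50, 150, "+", "CDS", "kinase")]
        snps = [make_record(pos=p, chrom="c") for p in (49, 50, 100, 150, 151)]
        ann = annotate_snp_context(snps, feats)
        assert [r.in_cds for r in ann] == [False, True, True, True, False]
        assert ann[1].gene_product == "kinase"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        feats = []
        for _ in range(20):
            start = int(rng.integers(1, 9000))
            feats.append(
                FeatureRecord("c", start, start + int(rng.integers(0, 500)), "+", "CDS")
            )
        snps = [make_record(pos=int(p), chrom="c") for p in rng.integers(1, 10000, 500)]
        ann = annotate_snp_context(snps, feats)
        for rec in ann:
            expected = any(f.start <= rec.pos <= f.end for f in feats)
            assert rec.in_cds == expected
        p_cds, p_non = cds_proportions(ann)
        assert p_cds + p_non == pytest.approx(1.0)

    def test_unknown_contig_warns_but_disjoint_errors(self, caplog):
        feats = [FeatureRecord("c1", 1, 100, "+", "CDS")]
        mixed = [make_record(chrom="c1", pos=5), make_record(chrom="cX", pos=5)]
        ann = annotate_snp_context(mixed, feats)
        assert [r.in_cds for r in ann] == [True, False]
        with pytest.raises(InputError):
            annotate_snp_context([make_record(chrom="cX", pos=5)], feats)


class TestDnds:
    def test_zero_nonsyn(self):
        assert compute_dnds(counts=(0, 10)).ratio == 0.0

    def test_zero_syn_undefined(self):
        assert compute_dnds(counts=(5, 0)).ratio is None

    def test_scale_invariance(self):
        r1 = compute_dnds(counts=(15.73, 76.06)).ratio
        r2 = compute_dnds(counts=(1573, 7606)).ratio
        assert r1 == pytest.approx(r2)

    def test_from_labelled_records(self):
        labels = (
            ["missense_variant"] * 3
            + ["stop_gained"]
            + ["synonymous_variant"] * 8
            + ["start_retained_variant"] * 2
            + ["intergenic_region"] * 5
        )
        snps = [make_record(pos=i + 1, effect=e) for i, e in enumerate(labels)]
        res = compute_dnds(snps)
        assert (res.n_nonsyn, res.n_syn, res.n_other) == (4, 10, 5)
        assert res.ratio == pytest.approx(0.4)

    def test_space_separated_labels_accepted(self):
        snps = [
            make_record(pos=1, effect="missense variant"),
            make_record(pos=2, effect="synonymous variant"),
        ]
        assert compute_dnds(snps).ratio == 1.0


class TestSharedPartition:
    def test_enumeration_example(self):
        part = shared_snp_partition({"1": {"a", "b"}, "2": {"b", "c"}, "3": {"b"}})
        assert part.subsets[frozenset({"1"})] == {"a"}
        assert part.subsets[frozenset({"2"})] == {"c"}
        assert part.subsets[frozenset({"1", "2", "3"})] == {"b"}
        assert part.union_size() == 3

    def test_identical_sets(self):
        part = shared_snp_partition({"1": {"x", "y"}, "2": {"x", "y"}})
        assert part.subsets == {frozenset({"1", "2"}): {"x", "y"}}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        universe = list(range(200))
        sets = {
            f"s{i}": {k for k in universe if rng.random() < 0.4} for i in range(4)
        }
        part = shared_snp_partition(sets)
        # brute force: check each key lands in exactly its membership subset
        union = set().union(*sets.values())
        assert part.union_size() == len(union)
        for key in union:
            members = frozenset(s for s in sets if key in sets[s])
            assert key in part.subsets[members]
        # subsets are disjoint
        seen = set()
        for keys in part.subsets.values():
            assert not (keys & seen)
            seen |= keys

    def test_per_subset_dnds(self):
        effects = {"a": "missense_variant", "b": "synonymous_variant", "c": "synonymous_variant"}
        part = shared_snp_partition(
            {"1": {"a", "b"}, "2": {"b", "c"}}, effects=effects
        )
        both = part.dnds[frozenset({"1", "2"})]
        assert (both.n_nonsyn, both.n_syn) == (0, 1)

    def test_requires_two_samples(self):
        with pytest.raises(InputError):
            shared_snp_partition({"1": {"a"}})


class TestChiSquare:
    def test_identical_proportions_zero(self):
        stat, df, p = chi_square_nonsyn_syn({"a": (10, 40), "b": (20, 80)})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed(self):
        obs = np.array([[10, 30], [40, 30]], dtype=float)  # 2x2: rows nonsyn/syn
        col = obs.sum(axis=0)
        row = obs.sum(axis=1)
        expected = np.outer(row, col) / obs.sum()
        stat_hand = float(((obs - expected) ** 2 / expected).sum())
        stat, df, p = chi_square_nonsyn_syn({"a": (10, 40), "b": (30, 30)})
        assert stat == pytest.approx(stat_hand)
        assert df == 1

    def test_single_category_rejected(self):
        with pytest.raises(InputError):
            chi_square_nonsyn_syn({"a": (10, 40)})


class TestTaxonAggregation:
    def _tax(self, strain, phylum, species=None):
        return {
            "phylum": phylum,
            "class": "c",
            "order": "o",
            "family": "f",
            "genus": "g",
            "species": species or strain,
            "strain": strain,
        }

    def test_single_strain_all_levels_one(self):
        df = aggregate_snps_by_taxon({"s1": 42}, {"s1": self._tax("s1", "Firmicutes")})
        assert (df["proportion"] == 1.0).all()

    def test_two_phyla_60_40(self):
        df = aggregate_snps_by_taxon(
            {"s1": 60, "s2": 40},
            {"s1": self._tax("s1", "Firmicutes"), "s2": self._tax("s2", "Bacteroidetes")},
        )
        phy = df[df["level"] == "phylum"].set_index("taxon")["proportion"]
        assert phy["Firmicutes"] == pytest.approx(0.6)
        assert phy["Bacteroidetes"] == pytest.approx(0.4)

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(4)
        phyla = ["Firmicutes", "Bacteroidetes", "Proteobacteria"]
        counts = {f"s{i}": int(rng.integers(0, 100)) for i in range(12)}
        tax = {s: self._tax(s, phyla[i % 3]) for i, s in enumerate(counts)}
        df = aggregate_snps_by_taxon(counts, tax)
        total = sum(counts.values())
        for ph in phyla:
            strains = [s for s in counts if tax[s]["phylum"] == ph]
            expected_snps = sum(counts[s] for s in strains)
            row = df[(df["level"] == "phylum") & (df["taxon"] == ph)].iloc[0]
            assert row["snps"] == expected_snps
            assert row["proportion"] == pytest.approx(expected_snps / total)
            assert row["mean_snps_per_genome"] == pytest.approx(
                expected_snps / len(strains)
            )
        # proportions sum to 1 per level
        for lv, grp in df.groupby("level"):
            assert grp["proportion"].sum() == pytest.approx(1.0)

    def test_missing_lineage_excluded(self):
        df = aggregate_snps_by_taxon(
            {"s1": 10, "s2": 5}, {"s1": self._tax("s1", "F"), "s2": {"phylum": "F"}}
        )
        assert set(df[df["level"] == "strain"]["taxon"]) == {"s1"}


class TestAlleleFrequencySpectrum:
    def test_freq_one_in_last_bin(self):
        snps = [make_record(pos=i + 1, var_freq=1.0, alt_reads=30) for i in range(7)]
        counts, edges = allele_frequency_spectrum(snps, n_bins=10)
        assert counts[-1] == 7 and counts[:-1].sum() == 0

    def test_uniform_grid_near_uniform(self):
        snps = [
            make_record(pos=i + 1, var_freq=(i + 0.5) / 50, alt_reads=None, total_depth=None)
            for i in range(50)
        ]
        counts, _ = allele_frequency_spectrum(snps, n_bins=50)
        assert (counts == 1).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        freqs = rng.uniform(0, 1, 300)
        snps = [
            make_record(pos=i + 1, var_freq=float(f), alt_reads=None, total_depth=None)
            for i, f in enumerate(freqs)
        ]
        counts, edges = allele_frequency_spectrum(snps, n_bins=20)
        assert counts.sum() == 300
        brute = np.zeros(20, dtype=int)
        for f in freqs:
            b = min(int(f * 20), 19)
            brute[b] += 1
        assert (counts == brute).all()

    def test_missing_freq_rejected(self):
        with pytest.raises(InputError):
            allele_frequency_spectrum(
                [make_record(var_freq=None, alt_reads=None, total_depth=None)]
            )


def test_round_half_up():
    assert round_half_up(0.205, 2) == 0.21
    assert round_half_up(0.2049, 2) == 0.20


def test_snp_enriched_genes_ranking():
    feats = [
        FeatureRecord("c", 1, 100, "+", "CDS", "dense gene"),
        FeatureRecord("c", 201, 1200, "+", "CDS", "sparse gene"),
    ]
    snps = [make_record(pos=p, chrom="c") for p in (10, 20, 30, 300, 400)]
    ann = annotate_snp_context(snps, feats)
    df = snp_enriched_genes(ann, feats)
    assert df.iloc[0]["product"] == "dense gene"
    assert df.iloc[0]["snps"] == 3
    assert df.iloc[0]["snps_per_kb"] == pytest.approx(30.0)
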