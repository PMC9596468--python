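"""Species merging, per-gene filters, concatenation and rate binning."""

import numpy as np
import pytest

from orodiversify.dataset_builder import (
    FilterThresholds,
    OrthogroupSet,
    bin_by_rate,
    concatenate,
    count_ambiguous,
    count_missing,
    filter_orthogroups,
    gene_rates,
    merge_to_species,
    taxon_coverage,
)
from orodiversify.io_model import Alignment
from orodiversify.synthetic_data import GeneFixtureSpec, make_orthogroup_fixtures


def _ogs(**genes):
    return OrthogroupSet({k: Alignment(list(v), dict(v)) for k, v in genes.items()})


class TestMergeToSpecies:
    SMAP = {"s1": "sp", "s2": "sp", "lone": "solo"}

    def test_missing_vs_base(self):
        ogs = _ogs(g1={"s1": "ANA", "s2": "AAA"})
        merged = merge_to_species(ogs, self.SMAP)
        assert merged.genes["g1"].sequences["sp"] == "AAA"

    def test_conflict_becomes_iupac(self):
        ogs = _ogs(g1={"s1": "ACA", "s2": "AGA"})
        merged = merge_to_species(ogs, self.SMAP)
        assert merged.genes["g1"].sequences["sp"] == "ASA"  # C|G -> S

    def test_single_sample_passthrough(self):
        ogs = _ogs(g1={"lone": "ACGT"})
        merged = merge_to_species(ogs, self.SMAP)
        assert merged.genes["g1"].sequences["solo"] == "ACGT"

    def test_unmapped_sample_errors(self):
        ogs = _ogs(g1={"mystery": "ACGT"})
        with pytest.raises(KeyError, match="mystery"):
            merge_to_species(ogs, self.SMAP)

    def test_all_missing_gene_dropped(self):
        ogs = _ogs(g1={"s1": "NN--", "s2": "NNNN"})
        merged = merge_to_species(ogs, self.SMAP)
        assert "g1" not in merged.genes


class TestMetrics:
    def test_one_ambiguous_cell(self):
        aln = Alignment(["a", "b"], {"a": "ACGTACGTAR", "b": "ACGTACGTAC"})
        assert count_ambiguous(aln) == pytest.approx(1 / 20)

    def test_all_gap_row_missing(self):
        aln = Alignment(["a", "b"], {"a": "----------", "b": "ACGTACGTAC"})
        assert count_missing(aln) == pytest.approx(0.5)

    def test_coverage_boundary(self):
        taxa = [f"t{i}" for i in range(20)]
        aln = Alignment(taxa[:19], {t: "ACGT" for t in taxa[:19]})
        assert taxon_coverage(aln, taxa) == pytest.approx(0.95)

    def test_all_missing_taxon_not_covered(self):
        aln = Alignment(["a", "b"], {"a": "NN--", "b": "ACGT"})
        assert taxon_coverage(aln, ["a", "b"]) == pytest.approx(0.5)


class TestFilter:
    def _gene_with_missing(self, frac, cells=100):
        n_miss = round(frac * cells)
        seq = "N" * n_miss + "A" * (cells - n_miss)
        return Alignment(["t0"], {"t0": seq})

    def test_strict_missing_boundary(self):
        thr = FilterThresholds(max_missing_fraction=0.60, min_taxon_fraction=0.0)
        ogs = OrthogroupSet(
            {"under": self._gene_with_missing(0.59),
             "at": self._gene_with_missing(0.60)}
        )
        kept, report = filter_orthogroups(ogs, thr)
        assert "under" in kept.genes            # 0.59 < 0.60 retained
        assert "at" not in kept.genes           # 0.60 is not < 0.60
        assert report.loc["at", "fail_reason"] == "missing"

    def test_inclusive_coverage_boundary(self):
        taxa = [f"t{i}" for i in range(20)]
        ogs = OrthogroupSet({"g": Alignment(taxa[:19], {t: "ACGT" for t in taxa[:19]})})
        thr = FilterThresholds(min_taxon_fraction=0.95)
        kept, _ = filter_orthogroups(ogs, thr, full_taxa=taxa)
        assert "g" in kept.genes                # 0.95 >= 0.95 retained

    def test_matches_construction_record(self):
        taxa = [f"t{i}" for i in range(20)]
        specs = [GeneFixtureSpec(missing=m, ambiguous=a, n_absent_taxa=k)
                 for m in (0.0, 0.3, 0.65)
                 for a in (0.0, 0.002)
                 for k in (0, 2)]
        ogs, record = make_orthogroup_fixtures(specs, taxa, length=200, seed=3)
        thr = FilterThresholds.individual_level()
        kept, report = filter_orthogroups(ogs, thr, full_taxa=taxa)
        for gid, row in record.iterrows():
            expected = (
                row["ambiguous"] < thr.max_ambiguous_fraction
                and row["missing"] < thr.max_missing_fraction
                and row["coverage"] >= thr.min_taxon_fraction
            )
            assert report.loc[gid, "passed"] == expected
            assert (gid in kept.genes) == expected

    def test_relaxing_thresholds_is_monotone(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        specs = [
            GeneFixtureSpec(
                missing=float(rng.uniform(0, 0.8)),
                ambiguous=float(rng.uniform(0, 0.01)),
                n_absent_taxa=int(rng.integers(0, 3)),
            )
            for _ in range(30)
        ]
        ogs, _ = make_orthogroup_fixtures(specs, taxa, length=100, seed=9)
        tight = FilterThresholds(0.001, 0.4, 1.0)
        loose = FilterThresholds(0.01, 0.7, 0.7)
        kept_tight, _ = filter_orthogroups(ogs, tight, full_taxa=taxa)
        kept_loose, _ = filter_orthogroups(ogs, loose, full_taxa=taxa)
        assert set(kept_tight.genes) <= set(kept_loose.genes)


class TestConcatenate:
    def test_partitions_and_padding(self):
        ogs = _ogs(
            b={"x": "ACGTACGTA", "y": "ACGTACGTA"},         # length 9
            a={"x": "ACGTACGTACGT"},                        # length 12, y absent
        )
        sm = concatenate(ogs)
        assert sm.alignment.length == 21
        assert sm.partitions == {"a": (0, 12), "b": (12, 21)}  # lexicographic
        assert sm.alignment.sequences["y"][:12] == "N" * 12

    def test_completeness_identity(self):
        ogs = _ogs(
            a={"x": "ACGT", "y": "AC-T"},
            b={"x": "ACGTAN", "y": "ACGTAC"},
        )
        sm = concatenate(ogs)
        total = sm.alignment.ntaxa * sm.alignment.length
        missing = sum(
            s.count("-") + s.count("N") for s in sm.alignment.sequences.values()
        )
        assert sm.completeness == pytest.approx(1 - missing / total)

    def test_full_matrix_completeness_one(self):
        sm = concatenate(_ogs(a={"x": "ACGT", "y": "ACGT"}))
        assert sm.completeness == pytest.approx(1.0)

    def test_gene_order_independence(self):
        genes = {"g3": {"x": "AAAA"}, "g1": {"x": "CCCC", "y": "GGGG"},
                 "g2": {"y": "TTTT"}}
        sm1 = concatenate(_ogs(**genes))
        shuffled = dict(reversed(list(genes.items())))
        sm2 = concatenate(_ogs(**shuffled))
        assert sm1.alignment == sm2.alignment and sm1.partitions == sm2.partitions

    def test_zero_genes_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            concatenate(OrthogroupSet({}))


class TestRates:
    def test_identical_sequences_rate_zero(self):
        rates = gene_rates(_ogs(g={"x": "ACGT", "y": "ACGT"}))
        assert rates["g"] == 0.0

    def test_ranking_matches_brute_force_recount(self, rng):
        # brute force: per pair, count mismatches over A/C/G/T-only sites
        genes = {}
        for g in range(8):
            L = 60
            seqs = {}
            for t in ("x", "y", "z"):
                seqs[t] = "".join(rng.choice(list("ACGTN"), size=L,
                                             p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            genes[f"g{g}"] = seqs
        ogs = _ogs(**genes)
        rates = gene_rates(ogs)

        def brute(gid):
            aln = ogs.genes[gid]
            vals = []
            for i, a in enumerate(aln.taxa):
                for b in aln.taxa[i + 1:]:
                    num = den = 0
                    for ca, cb in zip(aln.sequences[a], aln.sequences[b]):
                        if ca in "ACGT" and cb in "ACGT":
                            den += 1
                            num += ca != cb
                    if den:
                        vals.append(num / den)
            return float(np.mean(vals))

        brute_rates = {g: brute(g) for g in genes}
        order = sorted(rates, key=lambda g: (rates[g], g))
        brute_order = sorted(brute_rates, key=lambda g: (brute_rates[g], g))
        assert order == brute_order
        for g in genes:
            assert rates[g] == pytest.approx(brute_rates[g], abs=1e-12)

    def test_balanced_bins(self):
        rates = {f"g{i}": i / 10 for i in range(10)}
        bins = bin_by_rate(rates, n_bins=3)
        sizes = [list(bins.values()).count(b) for b in range(3)]
        assert sorted(sizes, reverse=True) == [4, 3, 3]
        # contiguity: bin index non-decreasing with rate
        ordered = [bins[g] for g in sorted(rates, key=rates.get)]
        assert ordered == sorted(ordered)

    def test_undefined_rate_goes_to_median_bin(self):
        rates = {f"g{i}": i / 10 for i in range(6)}
        rates["lonely"] = None
        with pytest.warns(UserWarning, match="median"):
            bins = bin_by_rate(rates, n_bins=3)
        assert bins["lonely"] == 1

    def test_fewer_genes_than_bins_lowers_count(self):
        with pytest.warns(UserWarning, match="lowering"):
            bins = bin_by_rate({"a": 0.1, "b": 0.2}, n_bins=200)
        assert set(bins.values()) == {0, 1}
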