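"""Synthetic-data generator: determinism, composition and round-trips."""

import numpy as np
import pytest

from emmir import genome_map, preprocess, simulate
from emmir.discovery import evaluate_hairpin, fold_hairpin
from emmir.seqtools import revcomp


class TestGenerateGenome:
    def test_fixed_seed_is_deterministic(self):
        a = simulate.generate_genome(10_000, gc=0.5, seed=1)
        b = simulate.generate_genome(10_000, gc=0.5, seed=1)
        assert a == b
        assert a != simulate.generate_genome(10_000, gc=0.5, seed=2)

    def test_zero_gc_contains_no_strong_bases(self):
        g = simulate.generate_genome(10_000, gc=0.0, seed=1)
        assert set(g) <= {"A", "T"}

    def test_gc_within_three_standard_errors(self):
        n, gc = 100_000, 0.45
        g = simulate.generate_genome(n, gc=gc, seed=7)
        se = np.sqrt(gc * (1 - gc) / n)
        observed = (g.count("G") + g.count("C")) / n
        assert abs(observed - gc) <= 3 * se

    def test_rejects_non_positive_or_tiny_length(self):
        with pytest.raises(ValueError):
            simulate.generate_genome(0)
        with pytest.raises(ValueError):
            simulate.generate_genome(999)


class TestPlantHairpins:
    def test_truth_set_reproducible_and_disjoint(self):
        g = simulate.generate_genome(30_000, seed=3)
        g1, t1 = simulate.plant_hairpins(g, 10, seed=4)
        g2, t2 = simulate.plant_hairpins(g, 10, seed=4)
        assert g1 == g2
        assert [m.mature_seq for m in t1.mirnas] == [m.mature_seq for m in t2.mirnas]
        intervals = sorted(m.precursor_interval[1:3] for m in t1.mirnas)
        assert all(b[0] >= a[1] for a, b in zip(intervals, intervals[1:]))

    def test_mature_lies_on_planted_precursor(self, planted):
        genome, truth = planted
        for m in truth.mirnas:
            _, s, e, strand = m.precursor_interval
            prec = genome[s:e] if strand == "+" else revcomp(genome[s:e])
            assert m.mature_seq in prec
            assert m.star_seq == revcomp(m.mature_seq)

    def test_capacity_error_on_tiny_genome(self):
        with pytest.raises(ValueError, match="cannot hold"):
            simulate.plant_hairpins("A" * 500, 1)

    def test_all_planted_precursors_pass_hairpin_criteria(self):
        g = simulate.generate_genome(40_000, seed=5)
        g, truth = simulate.plant_hairpins(
            g, 20, stem_len=(18, 25), loop_len=(4, 15), seed=6
        )
        for m in truth.mirnas:
            _, s, e, strand = m.precursor_interval
            prec = g[s:e] if strand == "+" else revcomp(g[s:e])
            structure = fold_hairpin(prec)
            start = prec.find(m.mature_seq)
            ev = evaluate_hairpin((start, start + len(m.mature_seq)), structure)
            assert ev.passed, ev.reasons


class TestSimulateCounts:
    def test_null_design_balances_conditions(self):
        truth = simulate.make_count_truth(50, seed=1)
        design = simulate.SimDesign(
            library_depth=200_000, nb_dispersion=0.0, contaminant_fraction=0.0, seed=2
        )
        counts = simulate.simulate_counts(truth, design)
        salt = counts[["S1", "S2"]].to_numpy().mean()
        ctrl = counts[["Ck1", "Ck2"]].to_numpy().mean()
        assert abs(salt / ctrl - 1.0) < 0.02

    def test_fold_change_recovered_within_20_percent(self):
        # many miRNAs so the single induced one barely shifts library totals
        truth = simulate.make_count_truth(500, seed=3, fold=8.0, n_affected=1)
        design = simulate.SimDesign(
            library_depth=500_000, nb_dispersion=0.0, contaminant_fraction=0.0, seed=4
        )
        counts = simulate.simulate_counts(truth, design)
        row = counts.loc["mir-1"]
        ratio = row[["S1", "S2"]].mean() / row[["Ck1", "Ck2"]].mean()
        assert 0.8 * 8 <= ratio <= 1.2 * 8

    def test_single_abundant_mirna_takes_all_counts(self):
        truth = simulate.make_count_truth(5, seed=5)
        truth.base_abundance = {k: (1.0 if k == "mir-3" else 0.0) for k in truth.base_abundance}
        counts = simulate.simulate_counts(
            truth, simulate.SimDesign(library_depth=1000, contaminant_fraction=0.0, seed=6)
        )
        assert counts.drop(index="mir-3").to_numpy().sum() == 0
        assert counts.loc["mir-3"].sum() > 0

    def test_rejects_non_positive_fold_change(self):
        truth = simulate.make_count_truth(3, seed=7)
        truth.fold_changes["mir-1"] = 0.0
        with pytest.raises(ValueError, match="fold"):
            simulate.simulate_counts(truth, simulate.SimDesign(seed=8))


class TestSynthesizeReads:
    def _clean_design(self, **kw):
        base = dict(
            library_depth=5_000, nb_dispersion=0.0, contaminant_fraction=0.0,
            adapter3="", seed=9,
        )
        base.update(kw)
        return simulate.SimDesign(**base)

    def test_contaminant_free_roundtrip_recovers_counts(self, planted):
        _, truth = planted
        design = self._clean_design()
        counts = simulate.simulate_counts(truth, design)
        reads = simulate.synthesize_reads(counts, truth, design)
        tags, _ = preprocess.collapse_and_filter(reads)
        mature = {m.mature_seq: m.id for m in truth.mirnas}
        recovered = {
            mature[t.sequence]: {lib: t.counts.get(lib, 0) for lib in counts.columns}
            for t in tags if t.sequence in mature
        }
        for mid in counts.index:
            for lib in counts.columns:
                assert recovered.get(mid, {}).get(lib, 0) == counts.at[mid, lib]

    def test_adapter_trimming_restores_read_lengths(self, planted):
        _, truth = planted
        design = self._clean_design(adapter3="TGGAATTCTCGGGTGCCAAGG")
        counts = simulate.simulate_counts(truth, design)
        reads = simulate.synthesize_reads(counts, truth, design)
        matures = {m.mature_seq for m in truth.mirnas}
        for lib_reads in reads.values():
            for read in lib_reads[:200]:
                assert preprocess.trim_adapter(read, design.adapter3) in matures

    def test_contaminant_fraction_is_removed_by_annotation(self, planted, ncrna_refs):
        _, truth = planted
        design = self._clean_design(contaminant_fraction=0.10, library_depth=20_000)
        counts = simulate.simulate_counts(truth, design)
        reads = simulate.synthesize_reads(counts, truth, design, ncrna_refs)
        tags, _ = preprocess.collapse_and_filter(reads)
        classes = genome_map.annotate_ncrna(tags, ncrna_refs)
        total = sum(t.total_count for t in tags)
        removed = sum(t.total_count for t in tags if t.tag_id in classes)
        assert abs(removed / total - 0.10) < 0.01

    def test_fastq_output_byte_identical_across_runs(self, planted, ncrna_refs, tmp_path):
        _, truth = planted
        design = self._clean_design(contaminant_fraction=0.2, adapter3="TGGAATTC")
        counts = simulate.simulate_counts(truth, design)
        for sub in ("a", "b"):
            simulate.synthesize_reads(counts, truth, design, ncrna_refs, out_dir=tmp_path / sub)
        for lib in counts.columns:
            a = (tmp_path / "a" / f"{lib}.fastq").read_bytes()
            b = (tmp_path / "b" / f"{lib}.fastq").read_bytes()
            assert a == b

    def test_empty_truth_rejected(self):
        import pandas as pd

        empty = simulate.TruthSet("g", [], {}, {})
        with pytest.raises(ValueError, match="empty truth"):
            simulate.synthesize_reads(pd.DataFrame(), empty, self._clean_design())
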