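"""The synthetic-data generators: determinism, invariants, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from epimark.exceptions import ValidationError
from epimark.io_model import (
    read_gene_annotation, read_gwas_summary, read_intervals,
    read_methylation_counts, write_bed,
)
from epimark.synthetic import (
    SimulationSpec, coplant_fraction, generate_chain_file,
    generate_expression_matrix, generate_genome_annotation,
    generate_gwas_summary, generate_methylation_data, generate_peak_samples,
    planted_signal_factor, write_cpg_table, write_gene_table, write_gwas_table,
)


class TestGenomeAnnotation:
    def test_deterministic_under_seed(self, tiny_spec):
        a = generate_genome_annotation(tiny_spec)
        b = generate_genome_annotation(tiny_spec)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_zero_genes_gives_empty_table(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, n_genes=0,
                                   n_specific_per_tissue=0)
        assert len(generate_genome_annotation(spec)) == 0

    def test_infeasible_packing_is_error(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, chrom_len=50_000)
        with pytest.raises(ValidationError, match="pack"):
            generate_genome_annotation(spec)

    def test_genes_nonoverlapping_with_bounded_lengths(self, tiny_genes):
        df = tiny_genes.df
        lengths = df["end"] - df["start"]
        assert lengths.between(1000, 5000).all()
        for _, grp in df.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()


class TestPeakSamples:
    def test_sample_grid_and_disjoint_planting(self, tiny_spec, tiny_peaks):
        samples, truth = tiny_peaks
        assert len(samples) == tiny_spec.n_tissues * tiny_spec.samples_per_tissue
        planted_sets = [set(v) for v in truth.specific_features.values()]
        for i in range(len(planted_sets)):
            for j in range(i + 1, len(planted_sets)):
                assert not planted_sets[i] & planted_sets[j]

    def test_planted_signal_factor_matches_lognormal_moments(self):
        spec = SimulationSpec(seed=1, noise_sd=0.5)
        cv = np.sqrt(np.exp(0.25) - 1)
        assert planted_signal_factor(spec) == pytest.approx(1 + 3 * cv)

    def test_planted_samples_carry_elevated_signal(self, tiny_spec, tiny_peaks):
        samples, truth = tiny_peaks
        tis = tiny_spec.tissue_names[0]
        planted = set(truth.specific_features[tis])
        in_sig, out_sig = [], []
        for ps in samples:
            for iv in ps.intervals:
                gid = iv.name.split("_")[0]
                if gid in planted:
                    (in_sig if ps.tissue == tis else out_sig).append(iv.signal)
        assert np.mean(in_sig) > 2 * np.mean(out_sig)

    def test_null_spec_plants_nothing(self, tiny_spec, tiny_genes):
        spec = dataclasses.replace(tiny_spec, n_specific_per_tissue=0)
        _, truth = generate_peak_samples(spec, tiny_genes)
        assert all(len(v) == 0 for v in truth.specific_features.values())


class TestExpressionCoplanting:
    def test_infeasible_rho_is_error(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, rho_modality=0.99)
        with pytest.raises(ValidationError, match="not achievable"):
            coplant_fraction(spec)

    def test_fraction_increases_with_target_rho(self, tiny_spec):
        fs = [
            coplant_fraction(dataclasses.replace(tiny_spec, rho_modality=r))
            for r in (0.0, 0.2, 0.4)
        ]
        assert fs[0] < fs[1] < fs[2]

    def test_expression_planting_size_preserved(self, tiny_spec, tiny_genes,
                                                tiny_peaks):
        _, truth = tiny_peaks
        generate_expression_matrix(tiny_spec, tiny_genes, truth)
        for tis, genes in truth.expression_specific.items():
            assert len(genes) == tiny_spec.n_specific_per_tissue

    def test_deterministic_under_seed(self, tiny_spec, tiny_genes, tiny_peaks):
        _, truth = tiny_peaks
        E1 = generate_expression_matrix(tiny_spec, tiny_genes, truth)
        E2 = generate_expression_matrix(tiny_spec, tiny_genes, truth)
        assert np.array_equal(E1.values, E2.values)


class TestMethylation:
    def test_levels_bounded_and_planted_hypomethylated(self, tiny_spec,
                                                       tiny_genes, tiny_peaks):
        from epimark.signal_aggregation import promoter_windows
        from epimark.specificity import build_methylation_matrix

        _, truth = tiny_peaks
        tables = generate_methylation_data(tiny_spec, tiny_genes, truth)
        assert len(tables) == tiny_spec.n_tissues * tiny_spec.meth_samples_per_tissue
        windows = promoter_windows(tiny_genes, 1000, 500, tiny_spec.chrom_lens)
        M = build_methylation_matrix(tables, windows)
        finite = M.values[np.isfinite(M.values)]
        assert finite.min() >= 0 and finite.max() <= 1
        tis = tiny_spec.tissue_names[0]
        planted = truth.specific_features[tis]
        own = [i for i, t in enumerate(M.tissue_labels) if t == tis]
        other = [i for i, t in enumerate(M.tissue_labels) if t != tis]
        rows = [M.feature_ids.index(g) for g in planted]
        assert np.nanmean(M.values[np.ix_(rows, own)]) < 0.35
        assert np.nanmean(M.values[np.ix_(rows, other)]) > 0.65

    def test_inverted_specificity_ranks_planted_genes_top(self, tiny_spec,
                                                          tiny_genes, tiny_peaks):
        from epimark.signal_aggregation import promoter_windows
        from epimark.specificity import (
            build_methylation_matrix, methylation_specificity,
        )

        _, truth = tiny_peaks
        tables = generate_methylation_data(tiny_spec, tiny_genes, truth)
        windows = promoter_windows(tiny_genes, 1000, 500, tiny_spec.chrom_lens)
        R = methylation_specificity(build_methylation_matrix(tables, windows))
        tis = tiny_spec.tissue_names[0]
        planted = [g for g in truth.specific_features[tis] if g in R.t.index]
        top = R.t[tis].nlargest(len(planted)).index
        assert len(set(planted) & set(top)) / len(planted) >= 0.9


class TestGwas:
    def test_planted_region_without_marker_is_error(self, tiny_spec):
        from epimark.io_model import GenomicInterval

        with pytest.raises(ValidationError, match="no marker"):
            generate_gwas_summary(
                tiny_spec, {"tr": [GenomicInterval("chr1", 10, 12)]}
            )

    def test_planted_markers_mean_shifted(self, tiny_spec):
        from epimark.io_model import GenomicInterval
        from epimark.enrichment import build_marker_set

        region = [GenomicInterval("chr1", 100_000, 200_000)]
        tabs = generate_gwas_summary(tiny_spec, {"tr": region})
        g = tabs["tr"]
        mset = build_marker_set(g, region)
        inside = g.stats[mset.indices]
        outside = np.delete(g.stats, mset.indices)
        assert inside.mean() > outside.mean() + 1.0

    def test_marker_grid_shared_across_traits(self, tiny_spec):
        from epimark.io_model import GenomicInterval

        tabs = generate_gwas_summary(
            tiny_spec,
            {"a": [GenomicInterval("chr1", 100_000, 200_000)],
             "b": [GenomicInterval("chr2", 100_000, 200_000)]},
        )
        assert tabs["a"].df["marker_id"].tolist() == tabs["b"].df["marker_id"].tolist()


class TestRoundTrips:
    """Emitted files survive the io_model readers unchanged."""

    def test_peaks_round_trip(self, tmp_path, tiny_peaks):
        samples, _ = tiny_peaks
        ps = samples[0]
        path = tmp_path / "s.narrowPeak"
        write_bed(ps, path, dialect="narrowPeak")
        back = read_intervals(path, dialect="narrowPeak")
        assert [(iv.chrom, iv.start, iv.end) for iv in back.intervals] == [
            (iv.chrom, iv.start, iv.end) for iv in ps.intervals
        ]
        assert np.allclose(
            [iv.signal for iv in back.intervals],
            [iv.signal for iv in ps.intervals],
            rtol=1e-5,
        )

    def test_gene_table_round_trip(self, tmp_path, tiny_genes):
        path = tmp_path / "genes.tsv"
        write_gene_table(tiny_genes, path)
        back = read_gene_annotation(path, format="tsv")
        pd.testing.assert_frame_equal(back.df, tiny_genes.df)

    def test_gwas_round_trip(self, tmp_path, tiny_spec):
        from epimark.io_model import GenomicInterval

        tabs = generate_gwas_summary(
            tiny_spec, {"tr": [GenomicInterval("chr1", 100_000, 200_000)]}
        )
        path = tmp_path / "g.tsv"
        write_gwas_table(tabs["tr"], path)
        back = read_gwas_summary(path, tiny_spec.chrom_names)
        assert back.df["marker_id"].tolist() == tabs["tr"].df["marker_id"].tolist()
        assert np.allclose(back.stats, tabs["tr"].stats, rtol=1e-9)

    def test_cpg_round_trip(self, tmp_path, tiny_spec, tiny_genes, tiny_peaks):
        _, truth = tiny_peaks
        spec = dataclasses.replace(tiny_spec, n_genes=200)
        tables = generate_methylation_data(spec, tiny_genes, truth)
        path = tmp_path / "cpg.tsv"
        write_cpg_table(tables[0], path)
        back = read_methylation_counts(path)
        assert len(back) == len(tables[0])


def test_chain_generation_extremes(tmp_path, tiny_spec, tiny_peaks):
    from epimark.liftover import parse_chain, transfer_efficiency, transfer_peaks

    samples, _ = tiny_peaks
    full = dataclasses.replace(tiny_spec, chain_coverage=1.0)
    p1 = tmp_path / "full.chain"
    generate_chain_file(full, p1)
    _, results = transfer_peaks(samples[0], parse_chain(p1), 0.5)
    assert transfer_efficiency(results) == 1.0

    none = dataclasses.replace(tiny_spec, chain_coverage=0.0)
    p0 = tmp_path / "none.chain"
    truth = generate_chain_file(none, p0)
    assert parse_chain(p0).blocks == {}
    assert [c for c, s, e in truth.chain_unmappable] == tiny_spec.chrom_names
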