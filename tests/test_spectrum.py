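"""K-mer counting and spectrum-model tests: oracle equivalence, conservation,
peak fitting, genome-size arithmetic, decomposition and copy-number views."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

import axokit as ak
from axokit._encode import canonical_str, revcomp


def brute_force_histogram(reads: list[str], k: int) -> dict[int, int]:
    """Independent dictionary-of-strings counter."""
    per_kmer: Counter = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            km = read[i : i + k]
            if set(km) <= set("ACGT"):
                per_kmer[canonical_str(km)] += 1
    return dict(Counter(per_kmer.values()))


class TestCountKmers:
    def test_single_kmer(self):
        assert ak.count_kmers(["ACGTA"], k=5).counts == {1: 1}

    def test_reverse_complements_collapse(self):
        assert ak.count_kmers(["ACGTA", "TACGT"], k=5).counts == {2: 1}

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ak.count_kmers(["ACGTACGT"], k=4)

    def test_empty_input_gives_empty_histogram(self):
        hist = ak.count_kmers([], k=5)
        assert hist.counts == {} and hist.total_mass() == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(41)
        bases = np.array(list("ACGT"))
        reads = ["".join(bases[rng.integers(0, 4, size=100)]) for _ in range(2000)]
        hist = ak.count_kmers(reads, k=21)
        assert hist.counts == brute_force_histogram(reads, 21)

    def test_ambiguous_bases_skipped_with_conservation(self):
        reads = ["ACGTNACGTACGT", "ACGTACGTACGTA"]
        hist = ak.count_kmers(reads, k=5)
        expected = brute_force_histogram(reads, 5)
        assert hist.counts == expected
        assert hist.total_mass() == sum(m * c for m, c in expected.items())

    def test_mass_conservation_on_simulated_reads(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        assert hist.total_mass() == reads.n_reads * (reads.read_length - 21 + 1)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(43)
        bases = np.array(list("ACGT"))
        reads = ["".join(bases[rng.integers(0, 4, size=60)]) for _ in range(300)]
        fwd = ak.count_kmers(reads, k=17)
        rev = ak.count_kmers([revcomp(r) for r in reads], k=17)
        assert fwd.counts == rev.counts

    def test_fastq_and_fasta_paths(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("@r1\nACGTA\n+\nIIIII\n@r2\nTACGT\n+\nIIIII\n")
        fa = tmp_path / "r.fasta"
        fa.write_text(">r1\nACGTA\n>r2\nTACGT\n")
        assert ak.count_kmers(str(fq), k=5).counts == {2: 1}
        assert ak.count_kmers(str(fa), k=5).counts == {2: 1}

    def test_histogram_roundtrip(self, tmp_path):
        hist = ak.SpectrumHistogram(k=21, counts={1: 10, 5: 3, 9: 7}, read_length=100)
        path = tmp_path / "h.tsv"
        hist.write(path)
        back = ak.SpectrumHistogram.read(path, k=21, read_length=100)
        assert back.counts == hist.counts


class TestErrorCutoff:
    def test_hand_readable_valley(self):
        hist = ak.SpectrumHistogram(k=21, counts={1: 1000, 2: 100, 3: 10, 4: 50, 5: 200})
        assert ak.find_error_cutoff(hist) == 3

    def test_no_valley_raises(self):
        hist = ak.SpectrumHistogram(k=21, counts={1: 5, 2: 100, 3: 1000, 4: 2000})
        with pytest.raises(ValueError, match="separation|valley"):
            ak.find_error_cutoff(hist)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            ak.find_error_cutoff(ak.SpectrumHistogram(k=21, counts={1: 5, 2: 1}))

    def test_separates_truth_erroneous_kmers(self):
        """On a 1 Mb simulation at 15x / 1% error the cutoff should put
        >= 95% of k-mers absent from the true genome below it."""
        from axokit._encode import canonical_kmers

        g = ak.build_genome(ak.GenomeSpec(1_000_000, seed=51))
        reads = ak.simulate_reads(
            g, ak.ReadSimSpec(coverage=15, read_length=100, error_rate=0.01, seed=52)
        )
        kmers, mult = ak.spectrum.kmer_counts(reads, 21)
        truth = np.unique(
            np.concatenate([canonical_kmers(h, 21) for h in g.hap_codes])
        )
        erroneous = ~np.isin(kmers, truth)
        hist = ak.count_kmers(reads, k=21)
        cutoff = ak.find_error_cutoff(hist)
        below = (mult[erroneous] <= cutoff).mean()
        assert below >= 0.95


class TestPeakFit:
    def test_symmetric_triangle_closed_form(self):
        counts = {m: (m - 9 if m <= 15 else 21 - m) for m in range(10, 21)}
        fit = ak.fit_single_copy_peak(ak.SpectrumHistogram(k=21, counts=counts), 9)
        assert fit.mode == 15
        assert fit.mean == pytest.approx(15.0)
        # discrete symmetric triangle over [10, 20]: var = 35/6
        assert fit.sigma == pytest.approx(np.sqrt(35 / 6))

    def test_modal_tie_gives_half_integer_mean(self):
        counts = {11: 50, 12: 80, 13: 100, 14: 100, 15: 80, 16: 50}
        fit = ak.fit_single_copy_peak(ak.SpectrumHistogram(k=21, counts=counts), 5)
        assert fit.mode == 13  # ties break toward the lower multiplicity
        assert fit.mean == pytest.approx(13.5)

    def test_mean_stays_within_one_of_mode(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        m_err = ak.find_error_cutoff(hist)
        fit = ak.fit_single_copy_peak(hist, m_err)
        assert abs(fit.mean - fit.mode) <= 1.0

    def test_flat_histogram_raises(self):
        hist = ak.SpectrumHistogram(k=21, counts={5: 7, 6: 7, 7: 7})
        with pytest.raises(ValueError, match="flat"):
            ak.fit_single_copy_peak(hist, 4)

    def test_recovers_kmer_coverage_on_error_free_simulation(self):
        g = ak.build_genome(ak.GenomeSpec(500_000, seed=53))
        reads = ak.simulate_reads(g, ak.ReadSimSpec(coverage=20, read_length=100, seed=54))
        hist = ak.count_kmers(reads, k=21)
        fit = ak.fit_single_copy_peak(hist, 0)
        expected = 20 * (100 - 21 + 1) / 100
        assert fit.mean == pytest.approx(expected, rel=0.05)


class TestCoverageConversion:
    def test_study_scale_values(self):
        assert ak.kmer_to_base_coverage(13.50, 100, 31) == pytest.approx(19.29, abs=0.005)
        assert ak.kmer_to_base_coverage(16.0, 100, 21) == pytest.approx(20.0)

    def test_k_equal_one_is_identity(self):
        assert ak.kmer_to_base_coverage(7.3, 100, 1) == pytest.approx(7.3)

    def test_read_length_not_above_k_rejected(self):
        with pytest.raises(ValueError):
            ak.kmer_to_base_coverage(10.0, 21, 21)

    @given(
        c=st.floats(0.1, 1e4),
        L=st.integers(32, 300),
        k=st.integers(1, 31),
    )
    def test_round_trip_exact(self, c, L, k):
        back = ak.base_to_kmer_coverage(ak.kmer_to_base_coverage(c, L, k), L, k)
        assert back == pytest.approx(c, rel=1e-12)


class TestGenomeSize:
    def test_single_bin(self):
        hist = ak.SpectrumHistogram(k=21, counts={10: 100})
        assert ak.estimate_genome_size(hist, 10.0, 0) == pytest.approx(100.0)

    def test_linearity(self):
        h1 = ak.SpectrumHistogram(k=21, counts={3: 5, 10: 100, 40: 7})
        h2 = ak.SpectrumHistogram(k=21, counts={m: 2 * c for m, c in h1.counts.items()})
        g1 = ak.estimate_genome_size(h1, 9.7, 1)
        assert ak.estimate_genome_size(h2, 9.7, 1) == pytest.approx(2 * g1)

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            ak.estimate_genome_size(ak.SpectrumHistogram(k=21, counts={5: 5}), 0.0, 1)


class TestSingleCopyFraction:
    def test_all_mass_inside_window(self):
        hist = ak.SpectrumHistogram(k=21, counts={9: 50, 10: 100, 11: 50})
        assert ak.single_copy_mass_fraction(hist, (5.0, 20.0), 0) == pytest.approx(1.0)

    def test_empty_window_raises(self):
        hist = ak.SpectrumHistogram(k=21, counts={9: 5})
        with pytest.raises(ValueError):
            ak.single_copy_mass_fraction(hist, (10.0, 5.0), 0)

    def test_distinct_variant_differs_from_mass(self):
        hist = ak.SpectrumHistogram(k=21, counts={10: 100, 100: 100})
        mass = ak.single_copy_mass_fraction(hist, (5, 20), 0)
        distinct = ak.single_copy_mass_fraction(hist, (5, 20), 0, distinct=True)
        assert mass == pytest.approx(1000 / 11000)
        assert distinct == pytest.approx(0.5)


class TestDecomposition:
    def test_components_resum_exactly(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        d = ak.decompose_spectrum(hist, model)
        np.testing.assert_array_equal(
            d.error + d.allelic_1n + d.diploid_2n + d.repeat + d.residual, d.observed
        )

    def test_homozygous_genome_has_negligible_1n_mass(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        d = ak.decompose_spectrum(hist, model)
        mult = d.multiplicity
        n1_mass = float((d.allelic_1n * mult).sum())
        genomic = hist.genomic_mass(model.error_cutoff)
        assert n1_mass / genomic < 0.02

    def test_heterozygous_1n_centre_near_half_coverage(self):
        g = ak.build_genome(ak.GenomeSpec(300_000, heterozygosity=0.01, seed=61))
        reads = ak.simulate_reads(
            g, ak.ReadSimSpec(coverage=25, read_length=100, error_rate=0.002, seed=62)
        )
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        d = ak.decompose_spectrum(hist, model)
        assert d.center_1n is not None
        assert d.center_1n == pytest.approx(model.mean_kmer_coverage / 2, rel=0.15)


class TestCopyNumberSpectrum:
    def test_fractions_sum_to_one(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        cns = ak.copy_number_spectrum(hist, model)
        assert cns.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_multiplicity_equal_to_coverage_maps_to_cn_one(self):
        hist = ak.SpectrumHistogram(k=21, counts={2: 10, 3: 4, 10: 100, 20: 5})
        model = ak.CoverageModel(
            k=21, read_length=100, error_cutoff=1, mode=10, mean_kmer_coverage=10.0,
            sigma=3.0, base_coverage=12.5, genome_size=1000.0,
            single_copy_window=(2.0, 19.0), single_copy_fraction=0.9, single_copy_bp=900.0,
        )
        cns = ak.copy_number_spectrum(hist, model)
        assert 1.0 in cns.copy_number.tolist()

    def test_family_mass_concentrates_near_true_copy_number(self, repeat_genome):
        reads = ak.simulate_reads(
            repeat_genome,
            ak.ReadSimSpec(coverage=20, read_length=100, error_rate=0.002, seed=63),
        )
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        cns = ak.copy_number_spectrum(hist, model)
        truth_frac = repeat_genome.class_fractions()["fam50"]
        assert cns.mass_in(40, 60) >= 0.6 * truth_frac

    def test_invalid_chromosome_count_rejected(self, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        with pytest.raises(ValueError):
            ak.copy_number_spectrum(hist, model, chromosomes=0)


class TestModelRoundTrip:
    def test_json_round_trip(self, tmp_path, homozygous_readset):
        _, reads = homozygous_readset
        hist = ak.count_kmers(reads, k=21)
        model = ak.fit_coverage_model(hist, read_length=100)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ak.CoverageModel.from_json(path)
        assert back == model
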