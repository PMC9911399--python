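"""Ground-truth landscapes, equilibrium partitioning and read simulation."""

import math

import numpy as np
import pandas as pd
import pytest

import hitseq as hq
from hitseq.sequences import all_kmers
from hitseq.simulate import (
    DEFAULT_CONCS,
    ConstructLayout,
    LandscapeParams,
    free_fraction,
    simulate_equilibrium,
)


class TestLandscape:
    def test_covers_all_unique_7mers(self, landscape):
        assert len(landscape.variants) == 4**7 == 16384
        assert len(np.unique(landscape.variants)) == 16384
        assert (landscape.kd > 0).all()

    def test_cognate_motif_variants_get_cognate_mode(self, landscape):
        has_motif = np.char.find(landscape.variants.astype("U"), "GCAUG") >= 0
        assert has_motif.sum() == 48
        assert (landscape.mode_label[has_motif] == "cognate-mode").all()
        assert (landscape.mode_label[~has_motif] == "non-cognate-mode").all()

    def test_deterministic_given_seed(self):
        a = hq.make_landscape(seed=5)
        b = hq.make_landscape(seed=5)
        assert np.array_equal(a.kd, b.kd)

    def test_zero_spread_collapses_each_mode(self):
        params = LandscapeParams(cognate_log_kd_sd=0.0, background_log_kd_sd=0.0)
        lsc = hq.make_landscape(params, seed=0)
        cognate = lsc.mode_label == "cognate-mode"
        assert np.allclose(lsc.kd[cognate], lsc.kd[cognate][0])
        assert np.allclose(lsc.kd[~cognate], lsc.kd[~cognate][0])

    def test_invalid_motif_symbol_is_named(self):
        with pytest.raises(ValueError, match="X"):
            LandscapeParams(cognate_motifs=("GCXUG",))

    def test_additive_landscape_log_kd_differences_are_additive(self, rng):
        # oracle: recompute ln(kd) differences by direct per-position summation
        coefs = pd.DataFrame(rng.normal(0, 0.4, (7, 4)), columns=list("ACGU"))
        lsc = hq.make_additive_landscape(coefs, baseline="UGCAUGU")
        kd = lsc.kd_series
        pick = rng.choice(lsc.variants, size=20, replace=False)
        for a, b in zip(pick[:10], pick[10:]):
            expected = sum(
                coefs.loc[i, a[i]] - coefs.loc[i, b[i]] for i in range(7)
            )
            assert math.isclose(
                math.log(kd[a]) - math.log(kd[b]), expected, abs_tol=1e-9
            )

    def test_tsv_round_trip(self, landscape, tmp_path):
        path = tmp_path / "landscape.tsv"
        landscape.to_tsv(path)
        back = hq.AffinityLandscape.from_tsv(path)
        assert np.array_equal(back.variants, landscape.variants)
        assert np.allclose(back.kd, landscape.kd)


class TestEquilibrium:
    def test_no_protein_leaves_pool_unchanged(self, landscape):
        cfg = hq.SimulationConfig(depth=10)
        comp = simulate_equilibrium(landscape, cfg)
        s0 = cfg.total_rna / 16384
        assert np.allclose(comp[cfg.labels[0]], s0)

    def test_free_fraction_at_reported_concentrations(self):
        # kd 1.6 nM vs the top protein concentration 19,740 nM
        assert free_fraction(1.6, 19740.0) == pytest.approx(1.6 / 19741.6, rel=1e-12)

    def test_pairwise_ratio_matches_competitive_binding_form(self, rng):
        # algebraic oracle: S1/S2 = (S1,0/S2,0)(1+E/K2)/(1+E/K1)
        k1, k2 = 3.0, 30.0
        for e in [1.0, 50.0, 19740.0]:
            lhs = free_fraction(k1, e) / free_fraction(k2, e)
            rhs = (1 + e / k2) / (1 + e / k1)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_free_fraction_strictly_decreases_with_concentration(self, landscape):
        cfg = hq.SimulationConfig()
        comp = simulate_equilibrium(landscape, cfg).to_numpy()
        assert (np.diff(comp, axis=1) < 0).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            free_fraction(1.0, -5.0)
        with pytest.raises(ValueError):
            hq.SimulationConfig(protein_concs=(0.0, -1.0))


class TestSimulationConfig:
    def test_control_must_come_first(self):
        with pytest.raises(ValueError):
            hq.SimulationConfig(protein_concs=(1.0, 2.0))

    def test_concentrations_must_ascend(self):
        with pytest.raises(ValueError):
            hq.SimulationConfig(protein_concs=(0.0, 10.0, 5.0))

    def test_default_series_tops_out_at_reported_maximum(self):
        assert DEFAULT_CONCS[0] == 0.0
        assert DEFAULT_CONCS[-1] == pytest.approx(19740.0)
        assert len(DEFAULT_CONCS) == 8

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            hq.SimulationConfig(error_rate=1.0)


class TestReadSampling:
    @pytest.fixture()
    def comp(self, landscape):
        cfg = hq.SimulationConfig(depth=5000, seed=11)
        return simulate_equilibrium(landscape, cfg)

    def test_same_seed_gives_identical_reads(self, comp):
        cfg = hq.SimulationConfig(depth=5000, seed=11, error_rate=0.01)
        a = hq.sample_reads(comp, ConstructLayout(), cfg)
        b = hq.sample_reads(comp, ConstructLayout(), cfg)
        assert np.array_equal(a.seqs, b.seqs)
        assert np.array_equal(a.lib, b.lib)

    def test_read_counts_conserve_depth_times_duplication(self, comp):
        cfg = hq.SimulationConfig(depth=5000, seed=2, pcr_duplication=3.0)
        reads = hq.sample_reads(comp, ConstructLayout(), cfg)
        n_libs = len(cfg.protein_concs)
        # geometric duplication, mean 3: total within 5 sd of expectation
        expected = n_libs * 5000 * 3.0
        sd = math.sqrt(n_libs * 5000 * (3.0**2 - 3.0))
        assert abs(len(reads) - expected) < 5 * sd
        assert reads.source_counts.sum().sum() == n_libs * 5000

    def test_noise_free_reads_parse_back_to_sampled_counts(self, comp, landscape):
        cfg = hq.SimulationConfig(depth=5000, seed=4, error_rate=0.0)
        reads = hq.sample_reads(comp, ConstructLayout(), cfg)
        libs = cfg.libraries()
        table = hq.count_reads(reads, dict(zip(libs["index"], libs["label"])))
        assert table.stats["accepted"] == len(reads)
        pd.testing.assert_frame_equal(
            table.counts, reads.source_counts, check_dtype=False
        )

    def test_reads_are_valid_dna_of_layout_length(self, comp):
        cfg = hq.SimulationConfig(depth=200, seed=4)
        reads = hq.sample_reads(comp, ConstructLayout(), cfg)
        seqs = reads.sequences()
        assert all(len(s) == 50 for s in seqs)
        assert all(set(s) <= set("ACGT") for s in seqs)

    def test_zero_depth_warns_and_returns_empty(self, comp):
        cfg = hq.SimulationConfig(depth=0)
        with pytest.warns(UserWarning, match="depth"):
            reads = hq.sample_reads(comp, ConstructLayout(), cfg)
        assert len(reads) == 0


class TestFastq:
    def _tiny_readset(self, landscape, depth=3):
        cfg = hq.SimulationConfig(depth=depth, protein_concs=(0.0, 10.0), seed=0)
        comp = simulate_equilibrium(landscape, cfg)
        return hq.sample_reads(comp, ConstructLayout(), cfg)

    def test_three_reads_make_twelve_lines(self, landscape, tmp_path):
        reads = self._tiny_readset(landscape)
        path = tmp_path / "r.fastq"
        hq.write_fastq(reads, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * len(reads)

    def test_empty_set_writes_empty_file(self, landscape, tmp_path):
        cfg = hq.SimulationConfig(depth=0, protein_concs=(0.0, 10.0))
        comp = simulate_equilibrium(landscape, cfg)
        with pytest.warns(UserWarning):
            reads = hq.sample_reads(comp, ConstructLayout(), cfg)
        path = tmp_path / "empty.fastq"
        hq.write_fastq(reads, path)
        assert path.read_text() == ""

    def test_round_trip_preserves_sequences(self, landscape, tmp_path):
        from Bio import SeqIO

        reads = self._tiny_readset(landscape, depth=25)
        path = tmp_path / "rt.fastq"
        hq.write_fastq(reads, path)
        back = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
        assert back == reads.sequences()
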