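"""Read parsing, demultiplexing, UMI collapse and count normalisation."""

import numpy as np
import pandas as pd
import pytest

import hitseq as hq
from hitseq.reads import (
    ParsedRead,
    Rejection,
    count_reads,
    dedup_and_count,
    demultiplex,
    normalize_counts,
    parse_construct,
)
from hitseq.simulate import INDEX_SEQUENCES, ConstructLayout

LAYOUT = ConstructLayout()


def make_read(umi="AA", index="ATC", kmer="GCATGTT", constant=None, tail=True):
    constant = constant or LAYOUT.constant5
    read = umi + index + constant + kmer
    if tail:
        read += LAYOUT.constant3[: LAYOUT.read_len - len(read)]
    return read


class TestParseConstruct:
    def test_exact_read_parses_with_zero_mismatches(self):
        pr = parse_construct(make_read())
        assert isinstance(pr, ParsedRead)
        assert (pr.umi, pr.index, pr.kmer) == ("AA", "ATC", "GCAUGUU")
        assert pr.constant_mismatches == 0

    def test_single_constant_substitution_accepted(self):
        mutated = "T" + LAYOUT.constant5[1:]
        pr = parse_construct(make_read(constant=mutated))
        assert isinstance(pr, ParsedRead)
        assert pr.constant_mismatches == 1

    def test_two_constant_substitutions_rejected(self, rng):
        # brute-force Hamming oracle on random double mutants
        for _ in range(20):
            pos = rng.choice(24, size=2, replace=False)
            const = list(LAYOUT.constant5)
            for p in pos:
                const[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[const[p]]
            const = "".join(const)
            hamming = sum(a != b for a, b in zip(const, LAYOUT.constant5))
            result = parse_construct(make_read(constant=const))
            assert hamming == 2
            assert isinstance(result, Rejection)
            assert result.reason == "constant_mismatch"

    def test_short_read_rejected_with_reason(self):
        result = parse_construct("ACGT")
        assert isinstance(result, Rejection)
        assert result.reason == "too_short"

    def test_ambiguous_base_in_kmer_rejected(self):
        result = parse_construct(make_read(kmer="GCANGTT"))
        assert isinstance(result, Rejection)


class TestDemultiplex:
    @pytest.fixture()
    def index_table(self):
        return {idx: f"lib{i + 1}" for i, idx in enumerate(INDEX_SEQUENCES)}

    def test_known_index_routes_to_its_library(self, index_table):
        pr = parse_construct(make_read(index="ATC"))
        groups = demultiplex([pr], index_table)
        assert groups["lib1"] == [pr]

    def test_unknown_index_goes_to_unassigned(self, index_table):
        pr = parse_construct(make_read(index="AAA"))
        groups = demultiplex([pr], index_table)
        assert groups["unassigned"] == [pr]

    def test_partition_conserves_reads(self, index_table, rng):
        reads = [
            parse_construct(
                make_read(index=str(rng.choice(list(INDEX_SEQUENCES) + ["AAA"])))
            )
            for _ in range(200)
        ]
        groups = demultiplex(reads, index_table)
        assert sum(len(g) for g in groups.values()) == 200

    def test_duplicate_index_keys_rejected(self):
        with pytest.raises(ValueError, match="unique|duplicate"):
            demultiplex([], {"ATC": "lib1", "GAT": "lib1"})


class TestDedupAndCount:
    def _groups(self, parsed):
        return {"lib1": parsed}

    def test_pure_pcr_duplicates_collapse_to_one(self):
        reads = [parse_construct(make_read(umi="AA"))] * 5
        table = dedup_and_count(self._groups(reads))
        assert table.umi_counts.loc["GCAUGUU", "lib1"] == 1
        assert table.counts.loc["GCAUGUU", "lib1"] == 5

    def test_distinct_umis_count_separately(self):
        reads = [parse_construct(make_read(umi=u)) for u in ("AA", "AC", "GT")]
        table = dedup_and_count(self._groups(reads))
        assert table.umi_counts.loc["GCAUGUU", "lib1"] == 3

    def test_umi_ceiling_is_sixteen(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), 2)) for _ in range(100)]
        reads = [parse_construct(make_read(umi=u)) for u in umis]
        with pytest.warns(UserWarning, match="UMI"):
            table = dedup_and_count(self._groups(reads))
        observed = table.umi_counts.loc["GCAUGUU", "lib1"]
        assert observed == len(set(umis)) <= 16

    def test_counting_is_order_independent(self, rng):
        kmers = ["GCATGTT", "AAAAAAA", "CGTACGT"]
        reads = [
            parse_construct(make_read(umi="AC", kmer=str(k)))
            for k in rng.choice(kmers, 50)
        ]
        t1 = dedup_and_count(self._groups(list(reads)))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        t2 = dedup_and_count(self._groups(shuffled))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(t1.umi_counts, t2.umi_counts)


class TestVectorisedCounting:
    def test_matches_scalar_pipeline(self, landscape):
        cfg = hq.SimulationConfig(
            depth=300, protein_concs=(0.0, 100.0), error_rate=0.02, seed=9
        )
        comp = hq.simulate_equilibrium(landscape, cfg)
        reads = hq.sample_reads(comp, LAYOUT, cfg)
        libs = cfg.libraries()
        index_table = dict(zip(libs["index"], libs["label"]))

        fast = count_reads(reads, index_table)
        parsed, n_rejected = [], 0
        for seq in reads.sequences():
            out = parse_construct(seq)
            if isinstance(out, ParsedRead):
                parsed.append(out)
            else:
                n_rejected += 1
        groups = demultiplex(parsed, index_table)
        slow = dedup_and_count(groups)
        pd.testing.assert_frame_equal(fast.counts, slow.counts)
        pd.testing.assert_frame_equal(fast.umi_counts, slow.umi_counts)
        assert fast.stats["too_short"] + fast.stats["constant_mismatch"] + \
            fast.stats["invalid_base"] == n_rejected

    def test_read_accounting_balances(self, small_run):
        counts, _ = small_run
        s = counts.stats
        assert (
            s["accepted"] + s["too_short"] + s["constant_mismatch"]
            + s["invalid_base"] + s["unassigned"]
        ) == s["total"]

    def test_count_table_is_dense_and_nonnegative(self, small_run):
        counts, _ = small_run
        assert counts.counts.shape[0] == 16384
        assert (counts.counts.to_numpy() >= 0).all()
        assert counts.control_label in counts.counts.columns

    def test_fastq_source_equals_readset_source(self, landscape, tmp_path):
        cfg = hq.SimulationConfig(
            depth=200, protein_concs=(0.0, 50.0), error_rate=0.01, seed=3
        )
        comp = hq.simulate_equilibrium(landscape, cfg)
        reads = hq.sample_reads(comp, LAYOUT, cfg)
        path = tmp_path / "reads.fastq"
        hq.write_fastq(reads, path)
        libs = cfg.libraries()
        index_table = dict(zip(libs["index"], libs["label"]))
        from_mem = count_reads(reads, index_table)
        from_file = count_reads(str(path), index_table)
        pd.testing.assert_frame_equal(from_mem.counts, from_file.counts)


class TestNormalization:
    def _table(self, data, control="lib1"):
        counts = pd.DataFrame(data)
        counts.index = [f"kmer{i}" for i in range(len(counts))]
        return hq.CountTable(
            counts=counts, umi_counts=counts.copy(), control_label=control
        )

    def test_control_against_itself_is_unity(self):
        table = self._table({"lib1": [10, 20, 30]})
        norm = normalize_counts(table)
        assert np.allclose(norm["lib1"], 1.0)

    def test_bound_variant_depletes_below_one(self):
        table = self._table({"lib1": [100, 100], "lib2": [10, 190]})
        norm = normalize_counts(table)
        assert norm.loc["kmer0", "lib2"] < 1.0
        assert norm.loc["kmer1", "lib2"] > 1.0

    def test_absent_variant_normalises_to_one_with_pseudocount(self):
        # equal totals, variant missing everywhere -> pseudocount/pseudocount
        table = self._table({"lib1": [0, 50, 50], "lib2": [0, 50, 50]})
        norm = normalize_counts(table)
        assert norm.loc["kmer0", "lib2"] == pytest.approx(1.0)

    def test_pseudocount_must_be_positive(self, small_run):
        counts, _ = small_run
        with pytest.raises(ValueError):
            normalize_counts(counts, pseudocount=0.0)
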