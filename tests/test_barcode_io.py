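"""Extraction, threshold filtering and matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

import clonetrace as ct
from clonetrace.barcode_io import MalformedFastqError

from conftest import fifty_triple_fixture

F5, F3 = "CTGACTCGAG", "AGCTGTCGAC"


def _fastq(records):
    return "".join(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n" for name, seq in records)


class TestExtract:
    def test_length_filter_boundary(self, tmp_path):
        """A 36 bp insert is excluded; a 37 bp insert survives."""
        recs = [
            ("r0:CELL1:UMI1", F5 + "A" * 36 + F3),
            ("r1:CELL1:UMI2", F5 + "A" * 37 + F3),
        ]
        p = tmp_path / "r.fastq"
        p.write_text(_fastq(recs))
        triples, report = ct.extract_barcodes(p, F5, F3, min_len=37)
        assert report.n_short_insert == 1
        assert len(triples) == 1
        assert triples.iloc[0]["lineage_bc"] == "A" * 37

    def test_identical_observations_aggregate(self, tmp_path):
        recs = [("r0:C:U", F5 + "G" * 40 + F3), ("r1:C:U", F5 + "G" * 40 + F3)]
        p = tmp_path / "r.fastq"
        p.write_text(_fastq(recs))
        triples, _ = ct.extract_barcodes(p, F5, F3)
        assert len(triples) == 1
        assert triples.iloc[0]["reads"] == 2

    def test_missing_flank_counted_not_fatal(self, tmp_path):
        recs = [("r0:C:U", "T" * 60), ("r1:C:U", F5 + "G" * 40 + F3)]
        p = tmp_path / "r.fastq"
        p.write_text(_fastq(recs))
        triples, report = ct.extract_barcodes(p, F5, F3)
        assert report.n_missing_flank == 1
        assert len(triples) == 1

    def test_whitelist_excludes_unknown_cells(self, tmp_path):
        recs = [("r0:GOOD:U", F5 + "G" * 40 + F3), ("r1:BAD:U", F5 + "G" * 40 + F3)]
        p = tmp_path / "r.fastq"
        p.write_text(_fastq(recs))
        triples, report = ct.extract_barcodes(p, F5, F3, whitelist={"GOOD"})
        assert report.n_not_whitelisted == 1
        assert set(triples["cell_bc"]) == {"GOOD"}

    def test_malformed_record_reports_index(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r0:C:U\nACGT\n+\nIIII\n@broken\nACGT\n")
        with pytest.raises(MalformedFastqError, match="index 1"):
            ct.extract_barcodes(p, F5, F3)

    def test_empty_flank_rejected(self):
        with pytest.raises(ValueError):
            ct.extract_barcodes([], "", F3)

    def test_simulator_fastq_round_trip(self, small_sim, tmp_path):
        """Extraction from the simulator's FASTQ reproduces its triples."""
        fq = tmp_path / "reads.fastq.gz"
        ct.write_fastq(small_sim, fq)
        whitelist = set(small_sim.annotations["cell_id"])
        triples, report = ct.extract_barcodes(fq, F5, F3, whitelist=whitelist)
        assert report.n_missing_flank == 0
        assert_frame_equal(triples, small_sim.triples)

    def test_order_independent(self, small_sim):
        """Shuffled observation order yields identical aggregated triples."""
        base = small_sim.triples.head(200)
        obs = [
            (k, f"r{k}:{t.cell_bc}:{t.umi}", F5 + t.lineage_bc + F3)
            for k, t in enumerate(base.itertuples(index=False))
            for _ in range(int(t.reads))
        ]
        a, _ = ct.extract_barcodes(iter(obs), F5, F3)
        rng = np.random.default_rng(0)
        shuffled = [obs[i] for i in rng.permutation(len(obs))]
        b, _ = ct.extract_barcodes(iter(shuffled), F5, F3)
        assert_frame_equal(a, b)


class TestFilterTriples:
    def test_fifty_triple_fixture_exact(self):
        triples, expected = fifty_triple_fixture()
        assert len(triples) == 50
        pairs, report = ct.filter_triples(triples)
        assert_frame_equal(pairs, expected)
        assert report.n_triples_in == 50

    def test_umi_rule_binds_regardless_of_depth(self):
        rows = [("C1", f"u{k}", "B2", 1000) for k in range(5)]
        triples = pd.DataFrame(rows, columns=["cell_bc", "umi", "lineage_bc", "reads"])
        pairs, _ = ct.filter_triples(triples)
        assert len(pairs) == 0

    def test_strict_read_boundary(self):
        rows = [("C", f"u{k}", "B", 9) for k in range(10)]
        triples = pd.DataFrame(rows, columns=["cell_bc", "umi", "lineage_bc", "reads"])
        pairs, _ = ct.filter_triples(triples)
        assert len(pairs) == 0

    def test_empty_input_not_an_error(self):
        empty = pd.DataFrame(columns=["cell_bc", "umi", "lineage_bc", "reads"])
        pairs, report = ct.filter_triples(empty)
        assert len(pairs) == 0
        assert report.n_triples_in == 0

    def test_unaggregated_input_rejected(self):
        dup = pd.DataFrame(
            [("C", "u", "B", 5), ("C", "u", "B", 7)],
            columns=["cell_bc", "umi", "lineage_bc", "reads"],
        )
        with pytest.raises(ValueError, match="aggregate"):
            ct.filter_triples(dup)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 3),  # cell
                st.integers(0, 5),  # umi
                st.integers(0, 3),  # barcode
                st.integers(1, 30),  # reads
            ),
            min_size=0,
            max_size=60,
        ),
        bump_reads=st.integers(0, 5),
        bump_umis=st.integers(0, 3),
    )
    def test_filter_monotone_in_thresholds(self, data, bump_reads, bump_umis):
        """Raising min_reads or min_umis never increases surviving pairs."""
        df = pd.DataFrame(
            [(f"c{c}", f"u{u}", f"b{b}", r) for c, u, b, r in data],
            columns=["cell_bc", "umi", "lineage_bc", "reads"],
        ).drop_duplicates(["cell_bc", "umi", "lineage_bc"])
        loose, _ = ct.filter_triples(df, min_reads=5, min_umis=2)
        tight, _ = ct.filter_triples(df, min_reads=5 + bump_reads, min_umis=2 + bump_umis)
        loose_keys = set(map(tuple, loose[["cell_bc", "lineage_bc"]].to_numpy()))
        tight_keys = set(map(tuple, tight[["cell_bc", "lineage_bc"]].to_numpy()))
        assert tight_keys <= loose_keys


class TestMatrix:
    def test_small_matrix_counts(self):
        pairs = pd.DataFrame(
            [("c1", "b1"), ("c1", "b2"), ("c2", "b2")],
            columns=["cell_bc", "lineage_bc"],
        )
        m = ct.build_matrix(pairs)
        assert m.shape == (2, 2)
        assert m.matrix.nnz == 3
        assert list(m.cell_ids) == ["c1", "c2"]

    def test_empty_pairs(self):
        m = ct.build_matrix(pd.DataFrame(columns=["cell_bc", "lineage_bc"]))
        assert m.shape == (0, 0)

    def test_duplicate_pairs_rejected(self):
        pairs = pd.DataFrame([("c", "b"), ("c", "b")], columns=["cell_bc", "lineage_bc"])
        with pytest.raises(ValueError, match="duplicate"):
            ct.build_matrix(pairs)

    def test_whitelist_drop_report(self):
        pairs = pd.DataFrame([("c1", "b1")], columns=["cell_bc", "lineage_bc"])
        m = ct.build_matrix(pairs, whitelist=["c1", "c2", "c3"])
        assert m.n_dropped_cells == 2

    def test_noise_free_matrix_equals_truth_incidence(self):
        """With full recovery and permissive thresholds the matrix is exactly
        the truth clone-barcode incidence."""
        from clonetrace.distributions import DistSpec

        cfg = ct.SimulationConfig(
            n_progenitors_per_subtype={"RGC_1": 15, "RGC_2": 15},
            barcode_recovery_rate=1.0,
            umi_per_pair_dist=DistSpec("fixed", {"value": 8}),
            reads_per_triple_dist=DistSpec("fixed", {"value": 20}),
            n_genes=20,
            n_marker_genes_per_type=4,
            seed=3,
        )
        sim = ct.simulate_experiment(cfg)
        pairs, _ = ct.filter_triples(sim.triples)
        m = ct.build_matrix(pairs)
        truth = sim.truth.cells.merge(sim.truth.clones, on="clone_id")
        assert set(m.cell_ids) == set(truth["cell_id"])
        lookup = truth.set_index("cell_id")["barcodes"]
        for i, cell in enumerate(m.cell_ids):
            assert m.barcode_set(i) == frozenset(lookup[cell].split(";"))

    def test_round_trip_long_csv_and_mtx(self, tmp_path):
        pairs = pd.DataFrame(
            [("c1", "b1"), ("c1", "b2"), ("c2", "b2"), ("c3", "b3")],
            columns=["cell_bc", "lineage_bc"],
        )
        m = ct.build_matrix(pairs)
        m.to_long_csv(tmp_path / "long.csv")
        m2 = ct.CellBarcodeMatrix.from_long_csv(tmp_path / "long.csv")
        assert m.equals(m2)
        m.to_mtx(tmp_path / "mat")
        m3 = ct.CellBarcodeMatrix.from_mtx(tmp_path / "mat")
        assert m.equals(m3)

    def test_triple_tsv_round_trip(self, tmp_path, small_sim):
        p = tmp_path / "t.tsv"
        ct.write_triples(small_sim.triples, p)
        back = ct.read_triples(p)
        assert_frame_equal(back, small_sim.triples)
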