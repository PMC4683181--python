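"""Synthetic-data generator: planted structure, determinism, round-trips."""

import numpy as np
import pytest

from polyxnet import (
    PlantedDomainSpec,
    PlantedRepeatSpec,
    SyntheticConfig,
    build_polyx_groups,
    find_homopolymer_runs,
    generate_domain_annotations,
    generate_interactome,
    generate_proteome,
    read_domain_annotations,
    read_fasta,
    read_interactions,
    simulate_dataset,
)
from polyxnet.overlap import overlap_summary
from polyxnet.repeats import RepeatOccurrence
from polyxnet.simulate import write_edge_list, write_fasta

SMALL = SyntheticConfig(
    n_proteins=100,
    length_mean=150.0,
    length_min=60,
    length_max=400,
    repeats=(PlantedRepeatSpec("Q", fraction=0.10, mean_extra=2.0),),
    n_decoy_domains=5,
)


class TestGenerateProteome:
    def test_planted_group_recovered_exactly(self):
        records, truth = generate_proteome(SMALL, seed=3)
        assert len(records) == 100
        assert len(truth.groups["Q"]) == 10
        groups = build_polyx_groups(records, 4)
        assert groups["Q"].members == set(truth.groups["Q"])
        # suppression: no accidental group of any other residue
        for res, grp in groups.items():
            if res != "Q":
                assert grp.size == 0

    def test_planted_coordinates_are_maximal_runs(self):
        records, truth = generate_proteome(SMALL, seed=5)
        seqs = {r.id: r.sequence for r in records}
        for pid, runs in truth.repeats.items():
            found = find_homopolymer_runs(seqs[pid], 4)
            for run in runs:
                assert run in found

    def test_zero_fraction_plants_nothing(self):
        cfg = SyntheticConfig(
            n_proteins=40, length_mean=120.0, length_min=60, length_max=300,
            repeats=(PlantedRepeatSpec("Q", fraction=0.0),),
        )
        records, truth = generate_proteome(cfg, seed=1)
        assert truth.groups["Q"] == []
        groups = build_polyx_groups(records, 4)
        assert all(g.size == 0 for g in groups.values())

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        r1, _ = generate_proteome(SMALL, seed=9)
        r2, _ = generate_proteome(SMALL, seed=9)
        f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(r1, f1)
        write_fasta(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_suppression_off_recomputes_truth_by_scanning(self):
        cfg = SyntheticConfig(
            n_proteins=60, length_mean=300.0, length_min=100, length_max=800,
            repeats=(PlantedRepeatSpec("Q", fraction=0.1),),
            suppress_accidental=False,
        )
        records, truth = generate_proteome(cfg, seed=2)
        groups = build_polyx_groups(records, 4)
        for res, members in truth.groups.items():
            assert groups[res].members == set(members)

    def test_infeasible_run_length_rejected(self):
        cfg = SyntheticConfig(
            n_proteins=5, length_min=10,
            repeats=(PlantedRepeatSpec("Q", fraction=1.0, min_len=50),),
        )
        with pytest.raises(ValueError):
            generate_proteome(cfg, seed=0)


class TestGenerateInteractome:
    IDS = [f"P{i:03d}" for i in range(300)]

    def test_within_count_near_expectation(self):
        group = frozenset(self.IDS[:50])
        inter, n_within, _ = generate_interactome({"Q": group}, 0.2, 0.01, self.IDS, seed=4)
        mean = 0.2 * 50 * 49 / 2  # 245
        sd = np.sqrt(mean * 0.8)
        assert abs(n_within - mean) < 4 * sd
        # realized counts consistent with the emitted edges
        within_edges = [e for e in inter.edges if e[0] in group and e[1] in group]
        assert len(within_edges) == n_within

    def test_depleted_fixture_allowed(self):
        group = frozenset(self.IDS[:50])
        _, n_within, n_between = generate_interactome({"Q": group}, 0.004, 0.05, self.IDS, seed=1)
        assert n_within < n_between

    def test_determinism(self):
        g = {"Q": frozenset(self.IDS[:30])}
        i1, *_ = generate_interactome(g, 0.1, 0.02, self.IDS, seed=11)
        i2, *_ = generate_interactome(g, 0.1, 0.02, self.IDS, seed=11)
        assert i1.edges == i2.edges

    def test_tiny_universe_rejected(self):
        with pytest.raises(ValueError):
            generate_interactome({}, 0.5, 0.5, ["only"], seed=0)


class TestGenerateDomainAnnotations:
    def _dataset(self, w, seed=0):
        spec = PlantedDomainSpec("DOM", "Q", q_in=0.8, q_out=0.02, overlap_rate=w)
        records, truth = generate_proteome(SMALL, seed=seed)
        annotations, dom_truth = generate_domain_annotations(
            records, truth.groups, truth.repeats, [spec], n_decoys=3, seed=seed
        )
        repeats = [
            RepeatOccurrence(pid, res, s, e)
            for pid, occs in truth.repeats.items()
            for res, s, e in occs
        ]
        return annotations, dom_truth, repeats

    @pytest.mark.parametrize("w,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_extreme_overlap_rates(self, w, expected):
        annotations, _, repeats = self._dataset(w)
        s = overlap_summary("Q", "DOM", repeats, annotations, min_overlap=4)
        assert s.n_total > 0
        assert s.fraction == pytest.approx(expected)

    def test_realized_overlap_recorded(self):
        _, dom_truth, _ = self._dataset(1.0)
        assert dom_truth.realized_overlap["DOM"] == 1.0
        assert dom_truth.enriched_domains["DOM"] == "Q"


class TestSimulateDatasetRoundTrip:
    def test_files_round_trip_through_readers(self, tmp_path, caplog):
        cfg = SyntheticConfig(
            n_proteins=80, length_mean=150.0, length_min=60, length_max=400,
            repeats=(PlantedRepeatSpec("Q", fraction=0.15),),
            p_in=0.2, p_out=0.05, n_decoy_domains=4,
        )
        import logging

        with caplog.at_level(logging.WARNING):
            records, inter, annotations, truth = simulate_dataset(
                cfg, seed=6, outdir=tmp_path
            )
            for name in ("proteome.fasta", "interactome.tsv", "domains.tsv", "truth.json"):
                assert (tmp_path / name).exists()
            rt_records = read_fasta(tmp_path / "proteome.fasta")
            rt_inter = read_interactions(tmp_path / "interactome.tsv")
            rt_anns = read_domain_annotations(tmp_path / "domains.tsv")
        assert caplog.records == []  # zero reader warnings
        assert [(r.id, r.sequence) for r in rt_records] == [
            (r.id, r.sequence) for r in records
        ]
        assert rt_inter.edges == inter.edges
        assert set(rt_anns) == set(annotations)
        # ground truth re-derivable from the files alone
        groups = build_polyx_groups(rt_records, 4)
        assert groups["Q"].members == set(truth.groups["Q"])
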