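import numpy as np
import pytest

import circanril as ca
from circanril.gene_model import GenomicInterval
from circanril.repeat_analysis import (
    RepeatAnalysisError,
    RepeatElement,
    junction_for_intron_pair,
)

from conftest import make_model


def rmsk_line(chrom, start, end, name, rclass, rfam, strand="+"):
    return "\t".join(
        ["585", "1000", "10", "5", "2", chrom, str(start), str(end), "-100",
         strand, name, rclass, rfam, "1", "300", "0", "1"]
    )


class TestReadRepeats:
    def test_class_filter_keeps_only_alu_entries(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(
            "\n".join(
                [
                    rmsk_line("chrT", 100, 400, "AluSx", "SINE", "Alu"),
                    rmsk_line("chrT", 500, 800, "AluY", "SINE", "Alu"),
                    rmsk_line("chrT", 900, 1200, "AluJb", "SINE", "Alu", "-"),
                    rmsk_line("chrT", 1300, 1900, "L1MA4", "LINE", "L1"),
                ]
            )
            + "\n"
        )
        reps = ca.read_repeats(path, class_filter="Alu")
        assert [r.name for r in reps] == ["AluSx", "AluY", "AluJb"]
        assert reps[2].strand == "-"
        assert ca.read_repeats(path) and len(ca.read_repeats(path)) == 4

    def test_region_restriction(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(rmsk_line("chrT", 100, 400, "AluSx", "SINE", "Alu") + "\n")
        inside = GenomicInterval("chrT", 0, 500)
        outside = GenomicInterval("chrT", 5000, 6000)
        assert len(ca.read_repeats(path, region=inside)) == 1
        assert ca.read_repeats(path, region=outside) == []

    def test_bed6_layout(self, tmp_path):
        path = tmp_path / "reps.bed"
        path.write_text("chrT\t100\t400\tAluSx\t0\t-\n")
        (rep,) = ca.read_repeats(path)
        assert (rep.interval.start, rep.interval.end, rep.strand) == (100, 400, "-")

    def test_unknown_layout_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrT\t100\n")
        with pytest.raises(RepeatAnalysisError, match=":1:"):
            ca.read_repeats(path)

    def test_write_read_round_trip(self, tmp_path):
        reps = [
            RepeatElement("AluSx", GenomicInterval("chrT", 10, 310), "SINE", "Alu"),
            RepeatElement("AluY", GenomicInterval("chrT", 400, 700, "-"), "SINE", "Alu"),
        ]
        path = tmp_path / "out.tsv"
        ca.write_repeats(reps, path)
        assert ca.read_repeats(path) == reps


class TestAssignment:
    def test_full_containment_assigns_to_intron(self, toy_model):
        rep = RepeatElement("AluSx", GenomicInterval("chrT", 210, 260), "SINE", "Alu")
        asg = ca.assign_repeats_to_features([rep], toy_model)
        assert asg.intron_counts == {1: 1, 2: 0}
        assert asg.unassigned == []

    def test_boundary_straddler_reported_separately(self, toy_model):
        rep = RepeatElement("AluSx", GenomicInterval("chrT", 180, 240), "SINE", "Alu")
        asg = ca.assign_repeats_to_features([rep], toy_model)
        assert sum(asg.intron_counts.values()) == 0
        assert asg.unassigned == [rep]
        # at a lower overlap requirement it goes to the majority feature
        asg = ca.assign_repeats_to_features([rep], toy_model, min_overlap_frac=0.5)
        assert asg.intron_counts[1] == 1

    def test_exonic_repeat_assigned_to_exon(self, toy_model):
        rep = RepeatElement("AluSx", GenomicInterval("chrT", 110, 150), "SINE", "Alu")
        asg = ca.assign_repeats_to_features([rep], toy_model)
        assert asg.exon_counts["1"] == 1

    def test_planted_repeats_recovered_per_intron(self):
        cfg = ca.SimulationConfig(seed=2, background_repeats={3: 2, 9: 1})
        locus = ca.simulate_locus(cfg)
        asg = ca.assign_repeats_to_features(locus.repeats, locus.model)
        expected = {}
        for rec in locus.truth["repeats"]:
            expected[rec["intron"]] = expected.get(rec["intron"], 0) + 1
        assert {i: n for i, n in asg.intron_counts.items() if n} == expected


class TestInvertedPairs:
    def test_planted_pair_recovered_with_full_score(self):
        locus = ca.simulate_locus(ca.SimulationConfig(seed=4))
        asg = ca.assign_repeats_to_features(locus.repeats, locus.model)
        (pair,) = ca.find_inverted_pairs(asg.by_intron, locus.genome)
        assert (pair.intron_i, pair.intron_j) == (1, 6)
        assert pair.score == 2.0 * 300

    def test_repeats_in_a_single_intron_yield_no_pairs(self):
        locus = ca.simulate_locus(ca.SimulationConfig(seed=4))
        asg = ca.assign_repeats_to_features(locus.repeats, locus.model)
        only_one = {1: asg.by_intron[1]}
        assert ca.find_inverted_pairs(only_one, locus.genome) == []

    def test_detection_invariant_under_locus_strand_flip(self):
        locus = ca.simulate_locus(ca.SimulationConfig(seed=8))
        asg = ca.assign_repeats_to_features(locus.repeats, locus.model)
        pairs = ca.find_inverted_pairs(asg.by_intron, locus.genome)

        chrom, seq = next(iter(locus.genome.items()))
        flipped = {chrom: ca.reverse_complement(seq)}
        L = len(seq)
        by_intron_flipped = {
            i: [
                RepeatElement(
                    r.name,
                    GenomicInterval(chrom, L - r.interval.end, L - r.interval.start),
                    r.repeat_class,
                    r.family,
                )
                for r in reps
            ]
            for i, reps in asg.by_intron.items()
        }
        pairs_flipped = ca.find_inverted_pairs(by_intron_flipped, flipped)
        assert {(p.intron_i, p.intron_j, p.score) for p in pairs} == {
            (p.intron_i, p.intron_j, p.score) for p in pairs_flipped
        }

    def test_short_genome_sequence_is_an_error(self):
        rep = RepeatElement("AluSx", GenomicInterval("chrT", 0, 300), "SINE", "Alu")
        with pytest.raises(RepeatAnalysisError, match="shorter"):
            ca.find_inverted_pairs({1: [rep], 2: [rep]}, {"chrT": "ACGT"})


class TestJunctionPrediction:
    @pytest.mark.parametrize(
        "intron_pair,junction",
        [((1, 14), ("14", "2")), ((6, 7), ("7", "7")), ((5, 7), ("7", "6")),
         ((1, 6), ("6", "2"))],
    )
    def test_intron_pair_to_junction(self, intron_pair, junction):
        assert junction_for_intron_pair(*intron_pair) == junction

    def test_predictions_group_supporting_pairs(self):
        locus = ca.simulate_locus(
            ca.SimulationConfig(seed=9, inverted_pairs=((1, 6, 0.0), (1, 6, 0.0)))
        )
        asg = ca.assign_repeats_to_features(locus.repeats, locus.model)
        pairs = ca.find_inverted_pairs(asg.by_intron, locus.genome)
        preds = ca.predict_junctions(pairs, locus.model)
        by_junction = {p.junction: len(p.supporting_pairs) for p in preds}
        assert by_junction[("6", "2")] >= 2

    def test_predicted_circles_are_contiguous_runs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            i = int(rng.integers(1, 17))
            j = int(rng.integers(i + 1, 19))
            donor, acceptor = junction_for_intron_pair(i, j)
            assert int(acceptor) <= int(donor)
            assert list(range(int(acceptor), int(donor) + 1)) == list(
                range(i + 1, j + 1)
            )

    def test_classification_is_an_exact_partition(self):
        observed = {("6", "2"), ("10", "4"), ("14", "5")}
        predicted = [("6", "2"), ("7", "6")]
        explained, unexplained = ca.classify_observed_junctions(observed, predicted)
        assert explained == {("6", "2")}
        assert explained | unexplained == observed
        assert not explained & unexplained

    def test_empty_prediction_leaves_all_unexplained(self):
        observed = {("6", "2")}
        explained, unexplained = ca.classify_observed_junctions(observed, [])
        assert explained == set() and unexplained == observed


class TestCorrelation:
    def test_counts_proportional_to_length_give_perfect_rank_correlation(self):
        lengths = [100, 500, 1000, 4000, 9000]
        counts = [1, 5, 10, 40, 90]
        res = ca.correlate_repeat_count_with_length(lengths, counts)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_poisson_counts_with_rate_proportional_to_length(self):
        rng = np.random.default_rng(42)
        lengths = rng.lognormal(np.log(2000), 1.0, size=50)
        counts = rng.poisson(lengths / 500.0)
        res = ca.correlate_repeat_count_with_length(lengths, counts)
        assert res["spearman_rho"] > 0
        assert res["spearman_p"] < 0.05

    def test_permuted_counts_decorrelate_on_average(self):
        rng = np.random.default_rng(0)
        lengths = rng.lognormal(np.log(2000), 1.0, size=30)
        counts = rng.poisson(lengths / 500.0).astype(float)
        rhos = []
        for _ in range(100):
            perm = rng.permutation(counts)
            if np.ptp(perm) == 0:
                continue
            rhos.append(
                ca.correlate_repeat_count_with_length(lengths, perm)["spearman_rho"]
            )
        assert abs(np.mean(rhos)) < 0.1

    def test_constant_input_is_an_error(self):
        with pytest.raises(RepeatAnalysisError, match="constant"):
            ca.correlate_repeat_count_with_length([1, 2, 3], [5, 5, 5])
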