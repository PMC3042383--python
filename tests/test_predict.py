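"""Prediction ingestion, the codon log-odds baseline, and mock predictors."""

import numpy as np
import pytest

from fragbench import (
    AnnotatedGenome,
    GenomeSimConfig,
    TrainingError,
    baseline_orf_predictor,
    generate_genome,
    mock_predictor,
    oracle_predictor,
    parse_predictions,
    train_codon_model,
    write_predictions,
)
from fragbench.codons import CODONS, STOP_CODONS, codon_indices
from fragbench.predict import GenePrediction, Interval, PredictionSet, score_sequence
from tests.conftest import make_balanced_truth


class TestParsePredictions:
    def _example(self):
        return PredictionSet(
            predictor_name="p",
            predictions={
                "r1": GenePrediction(
                    read_id="r1",
                    intervals=(
                        Interval(0, 100, "+", 1.25),
                        Interval(40, 70, "-", 0.5),
                    ),
                ),
                "r2": GenePrediction(read_id="r2", intervals=(Interval(9, 30, "+", None),)),
            },
        )

    @pytest.mark.parametrize("fmt", ["tsv", "gff3"])
    def test_round_trip(self, tmp_path, fmt):
        pset = self._example()
        path = tmp_path / f"p.{fmt}"
        write_predictions(pset, path, fmt)
        back = parse_predictions(path, fmt, predictor_name="p")
        assert set(back.predictions) == set(pset.predictions)
        for rid in pset.predictions:
            assert set(back.predictions[rid].intervals) == set(
                pset.predictions[rid].intervals
            )

    def test_one_based_conversion_and_absence_convention(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("read_id\tstart\tend\tstrand\tscore\nr1\t1\t100\t+\t.\n")
        pset = parse_predictions(path, "tsv")
        assert pset.predictions["r1"].intervals[0] == Interval(0, 100, "+", None)
        assert pset.is_coding("r1") and not pset.is_coding("unlisted_read")


class TestSelectedInterval:
    def test_truth_overlap_wins(self):
        pred = GenePrediction(
            "r",
            intervals=(Interval(0, 50, score=9.0), Interval(150, 290, score=0.1)),
        )
        assert pred.selected_interval((140, 300)) == Interval(150, 290, score=0.1)

    def test_score_then_length_then_leftmost(self):
        ivs = (Interval(50, 60, score=1.0), Interval(0, 20, score=1.0), Interval(30, 50, score=1.0))
        pred = GenePrediction("r", intervals=ivs)
        assert pred.selected_interval() == Interval(0, 20, score=1.0)  # longest, leftmost


class TestCodonModel:
    def test_hand_tallied_toy_genome(self):
        """Table matches a brute-force codon count on a hand-built genome."""
        gene1 = "ATG" + "AAA" * 600 + "TAA"
        gene2 = "ATG" + "CCC" * 600 + "TGA"
        seq = "T" * 100 + gene1 + "T" * 100 + gene2 + "T" * 100
        genome = AnnotatedGenome(
            id="toy",
            sequence=seq,
            genes=((100, 100 + len(gene1), "+"), (200 + len(gene1), 200 + len(gene1) + len(gene2), "+")),
        )
        pc = 1.0
        model = train_codon_model([genome], pseudocount=pc)
        counts = np.zeros(64)
        for gs, ge, _ in genome.genes:
            for i in codon_indices(seq[gs:ge]):
                counts[i] += 1
        base = np.zeros(4)
        for i, b in enumerate("ACGT"):
            base[i] = seq.count(b)
        base /= base.sum()
        bg = np.array(
            [base["ACGT".index(c[0])] * base["ACGT".index(c[1])] * base["ACGT".index(c[2])] for c in CODONS]
        )
        total = counts.sum()
        expected = np.log2(
            ((counts + pc) / (total + 64 * pc)) / ((bg * total + pc) / (total + 64 * pc))
        )
        assert np.allclose(model.scores, expected)
        assert np.isfinite(model.scores).all()  # pseudocount covers unseen codons

    def test_zero_bias_scores_shrink_to_zero(self):
        """Genes drawn from the background codon table give near-zero log-odds."""
        config = GenomeSimConfig(
            n_genomes=1,
            genome_length=150_000,
            gene_length=(900.0, 360, 2400),
            intergenic_length=(150.0, 60, 600),
            gc=0.5,
            codon_bias_strength=0.0,
            seed=2,
        )
        genome = generate_genome(config)
        model = train_codon_model([genome])
        # structurally special codons carry known non-zero log-odds even at
        # zero bias: stops (absent from gene bodies), ATG (every gene start),
        # and the six codons that absorb the redistributed stop mass
        special = set(STOP_CODONS) | {"ATG", "AAT", "ATA", "AGT", "GAT", "GTA"}
        plain = [i for i, c in enumerate(CODONS) if c not in special]
        assert np.abs(model.scores[plain]).mean() < 0.1

    def test_insufficient_training_data_rejected(self):
        genome = AnnotatedGenome(id="t", sequence="T" * 1000, genes=())
        with pytest.raises(TrainingError):
            train_codon_model([genome])

    def test_score_sequence_equals_table_lookup(self, genomes):
        model = train_codon_model(genomes)
        seq = genomes[0].sequence[:300]
        idx = codon_indices(seq)
        assert score_sequence(model, seq) == pytest.approx(model.scores[idx].mean())


class TestBaselinePredictor:
    def test_all_stop_read_is_noncoding(self, genomes):
        import dataclasses

        model = train_codon_model(genomes, min_orf_len=30, score_threshold=10.0)
        frag = dataclasses.replace(
            make_balanced_truth(2, read_length=60)[0], sequence="TAA" * 20
        )
        pset = baseline_orf_predictor([frag], model)
        assert not pset.is_coding(frag.read_id)

    def test_high_bias_type_b_sensitivity(self, genomes):
        """Self-consistency: biased genes at 700 bp are nearly always detected."""
        from fragbench import sample_fragments

        frags = sample_fragments(genomes, 700, "B", 200, seed=3, allow_replacement=True)
        model = train_codon_model(genomes)
        pset = baseline_orf_predictor(frags, model)
        sens = np.mean([pset.is_coding(f.read_id) for f in frags])
        assert sens > 0.9

    def test_threshold_monotonicity(self, genomes, bench):
        frags = bench.stratum(read_length=300)
        coding_sets = []
        for thr in (1.0, 0.3, 0.0, -0.5):
            model = train_codon_model(genomes, score_threshold=thr)
            pset = baseline_orf_predictor(frags, model)
            coding_sets.append({rid for rid, p in pset.predictions.items() if p.is_coding})
        for tighter, looser in zip(coding_sets, coding_sets[1:]):
            assert tighter <= looser

    def test_separates_genes_from_intergenic_windows(self, genomes):
        """Codon log-odds gives AUC > 0.9 on 500 bp gene vs intergenic windows."""
        from sklearn.metrics import roc_auc_score

        model = train_codon_model(genomes)
        scores, labels = [], []
        for g in genomes:
            mask = g.coding_mask()
            for gs, ge, _ in g.genes:
                if ge - gs >= 500:
                    scores.append(score_sequence(model, g.sequence[gs : gs + 500]))
                    labels.append(1)
            runs_start = 0
            for gs, ge, _ in g.genes:
                if gs - runs_start >= 500:
                    scores.append(score_sequence(model, g.sequence[runs_start : runs_start + 500]))
                    labels.append(0)
                runs_start = ge
        assert len(set(labels)) == 2
        assert roc_auc_score(labels, scores) > 0.9


class TestMockPredictor:
    def test_oracle_reproduces_truth(self, bench):
        pset = oracle_predictor(bench)
        for frag in bench.fragments:
            pred = pset.get(frag.read_id)
            if frag.truth_interval is None:
                assert not pred.is_coding
            else:
                iv = pred.intervals[0]
                assert (iv.start, iv.end) == frag.truth_interval

    def test_nominal_sensitivity_within_binomial_error(self):
        frags = make_balanced_truth(20_000)
        pset = mock_predictor(frags, sens=0.8, spec=0.9, seed=17)
        coding = [f for f in frags if f.truth_interval is not None]
        noncoding = [f for f in frags if f.truth_interval is None]
        sens_hat = np.mean([pset.is_coding(f.read_id) for f in coding])
        spec_hat = np.mean([not pset.is_coding(f.read_id) for f in noncoding])
        n = len(coding)
        assert abs(sens_hat - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / n)
        assert abs(spec_hat - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)

    def test_independent_seeds_give_independent_errors(self):
        """Phi coefficient of two mocks' per-read errors is ~0 on 10,000 reads."""
        frags = make_balanced_truth(10_000)
        a = mock_predictor(frags, 0.8, 0.8, seed=101)
        b = mock_predictor(frags, 0.8, 0.8, seed=202)
        err_a = np.array(
            [a.is_coding(f.read_id) != (f.truth_interval is not None) for f in frags]
        )
        err_b = np.array(
            [b.is_coding(f.read_id) != (f.truth_interval is not None) for f in frags]
        )
        phi = np.corrcoef(err_a, err_b)[0, 1]
        assert abs(phi) < 0.05

    def test_determinism(self, bench):
        a = mock_predictor(bench, 0.7, 0.7, 3.0, seed=9)
        b = mock_predictor(bench, 0.7, 0.7, 3.0, seed=9)
        assert a.predictions.keys() == b.predictions.keys()
        for rid in a.predictions:
            assert a.predictions[rid].intervals == b.predictions[rid].intervals

    def test_noise_stays_inside_read(self, bench):
        pset = mock_predictor(bench, 1.0, 1.0, coord_noise_sd=50.0, seed=21)
        by_id = bench.by_id()
        for rid, pred in pset.predictions.items():
            iv = pred.intervals[0]
            assert 0 <= iv.start < iv.end <= by_id[rid].read_length
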