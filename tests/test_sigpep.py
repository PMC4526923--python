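import numpy as np
import pytest

from sspfam.config import SigpepConfig
from sspfam.seqio import ProteinRecord
from sspfam.sigpep import (
    PredictionSource,
    import_signal_predictions,
    merge_predictions,
    predict_signal,
    predict_signal_all,
)
from sspfam.synthetic import SyntheticSpec, generate_dataset

# n-region MKT (+1 net charge), 8xL h-region, ASA cleavage box, polar mature
DESIGNED_PASS = ProteinRecord("pass", "MKT" + "L" * 8 + "ASA" + "Q" * 60)


class TestHeuristic:
    def test_designed_signal_passes_all_three_rules(self):
        pred = predict_signal(DESIGNED_PASS)
        assert pred.has_signal
        assert pred.cleavage_pos == 14  # the ...ASA box: -3 and -1 are A
        assert 0 < pred.score <= 1

    def test_acidic_sequence_has_no_hydrophobic_core(self):
        pred = predict_signal(ProteinRecord("neg", "E" * 80))
        assert not pred.has_signal
        assert pred.score == 0.0
        assert pred.cleavage_pos == 0

    def test_too_short_record_is_negative_not_error(self):
        pred = predict_signal(ProteinRecord("tiny", "MKTLLLLL"))
        assert not pred.has_signal

    def test_deterministic(self):
        a = predict_signal(DESIGNED_PASS)
        b = predict_signal(DESIGNED_PASS)
        assert a == b

    def test_negative_charge_before_h_region_blocks(self):
        # acidic n-region violates the net-charge rule for the only h-region
        rec = ProteinRecord("acidic", "MDE" + "L" * 8 + "ASA" + "Q" * 60)
        assert not predict_signal(rec).has_signal

    @pytest.mark.parametrize("n_extra", [1, 2, 4, 6])
    def test_extra_leucines_in_h_region_keep_signal(self, n_extra):
        base = predict_signal(DESIGNED_PASS)
        assert base.has_signal
        rec = ProteinRecord(
            "ext", "MKT" + "L" * (8 + n_extra) + "ASA" + "Q" * 60
        )
        assert predict_signal(rec).has_signal

    def test_generator_signals_detected(self):
        spec = SyntheticSpec(seed=11, n_families=0, members_per_family=0,
                             n_decoys=1000)
        records = generate_dataset(spec).records
        frac = np.mean([predict_signal(r).has_signal for r in records])
        assert frac >= 0.95

    def test_sensitivity_and_specificity_on_synthetic_benchmark(self):
        pos = generate_dataset(
            SyntheticSpec(seed=21, n_families=0, members_per_family=0,
                          n_decoys=400)
        ).records
        neg = generate_dataset(
            SyntheticSpec(seed=22, n_families=0, members_per_family=0,
                          n_decoys=400, include_signal=False)
        ).records
        sens = np.mean([predict_signal(r).has_signal for r in pos])
        spec = 1.0 - np.mean([predict_signal(r).has_signal for r in neg])
        assert sens >= 0.95
        assert spec >= 0.90


class TestExternalPredictions:
    def test_parse_rows(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("a\tY\t22\t0.91\nb\tN\t0\t0.03\nc\tY\t18\t0.77\n")
        preds = import_signal_predictions(p)
        assert len(preds) == 3
        assert preds["a"].has_signal and preds["a"].cleavage_pos == 22
        assert preds["a"].score == pytest.approx(0.91)
        assert preds["a"].source is PredictionSource.EXTERNAL
        assert not preds["b"].has_signal

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("a\tY\t22\t0.91\nb\tMAYBE\t0\t0.1\n")
        with pytest.raises(ValueError, match=":2"):
            import_signal_predictions(p)

    def test_external_overrides_heuristic(self):
        heur = predict_signal_all([DESIGNED_PASS])
        ext = {
            "pass": heur["pass"].__class__(
                protein_id="pass", has_signal=False, cleavage_pos=0,
                score=0.02, source=PredictionSource.EXTERNAL,
            )
        }
        merged = merge_predictions(heur, ext)
        assert not merged["pass"].has_signal
        assert merged["pass"].source is PredictionSource.EXTERNAL

    def test_unknown_ids_kept(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("zzz\tY\t20\t0.5\n")
        merged = merge_predictions(predict_signal_all([DESIGNED_PASS]),
                                   import_signal_predictions(p))
        assert "zzz" in merged and "pass" in merged


def test_invariant_cleavage_window():
    cfg = SigpepConfig()
    pred = predict_signal(DESIGNED_PASS, cfg)
    assert cfg.cleavage_min <= pred.cleavage_pos <= cfg.cleavage_max
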