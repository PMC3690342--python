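import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from locrec.consistency import classify_all, consistency_summary
from locrec.dualloc import pairwise_matrix
from locrec.errors import ConfigError
from locrec.evidence import build_claims
from locrec.reconcile import reconcile_all, reconciliation_table
from locrec.simulate import (
    SynthConfig,
    evaluate_recovery,
    expected_confirmed_fraction,
    generate,
)
from locrec.vocab import COMPARTMENTS


def enumerated_match_probability(e_fp: float, e_ms: float) -> float:
    """Independent oracle: exhaustive enumeration over the 11x11 grid of
    (FP report, MS report) outcomes for a single-target protein."""
    t = COMPARTMENTS[0]

    def report_dist(e):
        d = {c: e / 10.0 for c in COMPARTMENTS if c != t}
        d[t] = 1.0 - e
        return d

    fp_d, ms_d = report_dist(e_fp), report_dist(e_ms)
    assert math.isclose(sum(fp_d.values()), 1.0)
    return sum(fp_d[c] * ms_d[c] for c in COMPARTMENTS)


class TestClosedForm:
    @pytest.mark.parametrize(
        ("e_fp", "e_ms", "expected"),
        [(0.0, 0.0, 1.0), (1.0, 1.0, 0.1), (0.2, 0.1, 0.722)],
    )
    def test_reference_values(self, e_fp, e_ms, expected):
        assert expected_confirmed_fraction(e_fp, e_ms) == pytest.approx(
            expected
        )

    @given(
        e_fp=st.floats(0, 1, allow_nan=False),
        e_ms=st.floats(0, 1, allow_nan=False),
    )
    def test_agrees_with_exhaustive_enumeration(self, e_fp, e_ms):
        assert expected_confirmed_fraction(e_fp, e_ms) == pytest.approx(
            enumerated_match_probability(e_fp, e_ms)
        )

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            expected_confirmed_fraction(1.2, 0.0)


class TestDeterminism:
    def test_same_seed_reproduces_corpus_exactly(self):
        cfg = SynthConfig(n_proteins=80, seed=7)
        r1, t1 = generate(cfg)
        r2, t2 = generate(cfg)
        assert r1 == r2 and t1 == t2

    def test_different_seeds_differ(self):
        cfg = SynthConfig(n_proteins=80, seed=7)
        r1, _ = generate(cfg)
        r2, _ = generate(replace(cfg, seed=8))
        assert r1 != r2


class TestZeroNoise:
    CFG = SynthConfig(
        n_proteins=250, dual_fraction=0.0, fp_pubs_per_protein=2,
        ms_coverage=1.0, e_fp=0.0, e_ms=0.0, seed=11,
    )

    def test_everything_confirmed_nothing_contradicted(self):
        records, _ = generate(self.CFG)
        cs = build_claims(records)
        table = reconciliation_table(
            reconcile_all(cs.restrict("FP"), cs.restrict("MS"))
        )
        total = table.loc["total"]
        assert total["n_confirmed"] == total["n_fp"] == self.CFG.n_proteins
        assert total["n_contradicted"] == 0 and total["n_unvalidated"] == 0
        assert total["pct_agree"] == 100

    def test_internal_consistency_is_perfect(self):
        records, _ = generate(self.CFG)
        fp = build_claims(records).restrict("FP")
        s = consistency_summary(classify_all(fp))
        assert s.n_multi == self.CFG.n_proteins
        assert s.n_disagree == 0 and s.pct_agree == 100

    def test_no_spurious_dual_localizations(self):
        records, _ = generate(self.CFG)
        mat = pairwise_matrix(build_claims(records).restrict("FP"))
        off = mat.values - np.diag(np.diag(mat.values))
        assert (off == 0).all()

    def test_dual_claims_recover_true_dual_proteins_exactly(self):
        cfg = replace(self.CFG, dual_fraction=0.3, seed=13)
        records, truth = generate(cfg)
        report = evaluate_recovery(records, truth, cfg)
        assert (report["n_dual_claims_observed"]
                == report["n_true_dual_proteins"] > 0)
        assert report["n_consistency_disagree"] == 0
        assert report["confirmed_fraction_observed"] == 1.0


class TestNoisyRecovery:
    NOISY = SynthConfig(
        n_proteins=2000, dual_fraction=0.0, fp_pubs_per_protein=1,
        ms_coverage=1.0, e_fp=0.2, e_ms=0.1, seed=42,
    )

    def test_confirmed_fraction_matches_closed_form_within_3se(self):
        records, truth = generate(self.NOISY)
        report = evaluate_recovery(records, truth, self.NOISY)
        p = report["confirmed_fraction_expected"]
        se = math.sqrt(p * (1 - p) / report["n_validated_claims"])
        assert report["confirmed_fraction_abs_error"] <= 3 * se

    def test_mean_over_20_seeds_matches_closed_form(self):
        cfg = replace(self.NOISY, n_proteins=500)
        errors = []
        n_total = 0
        for seed in range(20):
            records, truth = generate(replace(cfg, seed=seed))
            report = evaluate_recovery(records, truth, cfg)
            errors.append(report["confirmed_fraction_observed"]
                          - report["confirmed_fraction_expected"])
            n_total += report["n_validated_claims"]
        p = expected_confirmed_fraction(cfg.e_fp, cfg.e_ms)
        se_mean = math.sqrt(p * (1 - p) / n_total)
        assert abs(np.mean(errors)) <= 3 * se_mean

    def test_estimator_error_shrinks_with_corpus_size(self):
        def mean_abs_error(n):
            errs = []
            for seed in range(8):
                cfg = replace(self.NOISY, n_proteins=n, seed=100 + seed)
                records, truth = generate(cfg)
                report = evaluate_recovery(records, truth, cfg)
                errs.append(report["confirmed_fraction_abs_error"])
            return np.mean(errs)

        assert mean_abs_error(2000) < mean_abs_error(200)

    def test_fp_error_rate_recoverable_from_truth_match_rate(self):
        records, truth = generate(self.NOISY)
        report = evaluate_recovery(records, truth, self.NOISY)
        n_fp_records = sum(1 for r in records if r.method == "FP")
        se = math.sqrt(self.NOISY.e_fp * (1 - self.NOISY.e_fp) / n_fp_records)
        assert abs(report["e_fp_estimate"] - self.NOISY.e_fp) <= 3 * se


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigError, match="e_fp"):
            SynthConfig(e_fp=1.5).validate()
        with pytest.raises(ConfigError, match="n_proteins"):
            SynthConfig(n_proteins=0).validate()
        with pytest.raises(ConfigError, match="compartment_weights"):
            SynthConfig(compartment_weights=(1.0, 2.0)).validate()
        with pytest.raises(ConfigError, match="nonnegative"):
            SynthConfig(
                compartment_weights=(-1.0,) + (1.0,) * 10
            ).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SynthConfig(n_proteins=40, e_fp=0.05, seed=3).validate()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SynthConfig.from_yaml(path) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_proteins: 10\nnoise: 0.1\n")
        with pytest.raises(ConfigError, match="noise"):
            SynthConfig.from_yaml(path)
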