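import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from karyoexpr import (ChromosomeDosageModel, CountMatrix, GeneAnnotation, KaryotypeSpec,
                       SimulationConfig, ValidationError, benjamini_hochberg, build_gene_model,
                       dosage_test, line_relative_expression, relative_chromosome_expression,
                       simulate_counts, simulate_scenario)

EXPECTED_GAINS = [("ESC1", "19"), ("ESC1", "20"), ("ESC2", "20")]


def _cm(array, samples, genes=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    return CountMatrix(pd.DataFrame(array, index=pd.Index(genes, name="gene_id"),
                                    columns=samples))


# ---------------------------------------------------------------------------
# relative chromosome expression


def test_fractions_from_two_chromosomes():
    cm = _cm([[30], [70]], samples=["s_r1"])
    ann = GeneAnnotation(pd.Series({"g0": "1", "g1": "2"}))
    frac = relative_chromosome_expression(cm, ann)
    assert frac.loc["s_r1", "1"] == pytest.approx(0.3)
    assert frac.loc["s_r1", "2"] == pytest.approx(0.7)


def test_fractions_sum_to_one_per_sample(study_cohort):
    counts, annotation, _, _ = study_cohort
    frac = relative_chromosome_expression(counts, annotation)
    assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-9)


def test_zero_assigned_reads_is_error():
    cm = _cm([[0], [5]], samples=["s_r1"])
    ann = GeneAnnotation(pd.Series({"g0": "1"}))
    with pytest.raises(ValidationError, match="zero assigned reads"):
        relative_chromosome_expression(cm, ann)


def test_unassigned_genes_excluded_from_fractions():
    cm = _cm([[30], [70], [900]], samples=["s_r1"])
    ann = GeneAnnotation(pd.Series({"g0": "1", "g1": "2"}))  # g2 unplaced
    frac = relative_chromosome_expression(cm, ann)
    assert frac.loc["s_r1", "1"] == pytest.approx(0.3)


def test_trisomy_ratio_matches_closed_form():
    """Observed ratio tracks lambda / (1 + (lambda-1) f) for a planted trisomy."""
    cfg = SimulationConfig(n_genes={"1": 300, "2": 100, "3": 300}, library_size=2e6,
                           dispersion=0.0, depth_sigma=0.0, line_effect_sigma=0.0, seed=2)
    models = build_gene_model(cfg)
    karyos = [KaryotypeSpec("TRI", "male", copy_number={"2": 3})] + [
        KaryotypeSpec(f"EU{i}", "male") for i in range(3)
    ]
    counts, _ = simulate_counts(models, karyos, cfg)
    from karyoexpr.io import GeneAnnotation as GA

    ann = GA(pd.Series({m.gene_id: m.chromosome for m in models}))
    lf = line_relative_expression(counts, ann)
    f = sum(m.per_copy_mean for m in models if m.chromosome == "2") / sum(
        m.per_copy_mean for m in models
    )
    predicted = 1.5 / (1 + 0.5 * f)
    observed = lf.loc["TRI", "2"] / lf.loc[[f"EU{i}" for i in range(3)], "2"].mean()
    assert observed == pytest.approx(predicted, rel=0.01)


def test_ratio_invariant_to_global_depth_differences(study_cohort):
    counts, annotation, _, _ = study_cohort
    scaled = counts.counts.copy()
    for s in counts.samples_of("ESC1"):
        scaled[s] = scaled[s] * 3
    lf0 = line_relative_expression(counts, annotation)
    lf1 = line_relative_expression(CountMatrix(scaled, counts.sample_meta), annotation)
    pd.testing.assert_frame_equal(lf0, lf1, rtol=1e-12)


# ---------------------------------------------------------------------------
# paired dosage test


def test_self_comparison_gives_null_result():
    cm = _cm([[10, 10], [20, 20], [30, 30]], samples=["A_r1", "B_r1"])
    ann = GeneAnnotation(pd.Series({"g0": "1", "g1": "1", "g2": "1"}))
    t, p = dosage_test(cm, ann, "A", ["B"], "1")
    assert (t, p) == (0.0, 1.0)


def test_paired_t_matches_textbook_oracle():
    """Five genes, one replicate per line, against the hand formula."""
    cand = [120, 260, 330, 90, 500]
    ref = [100, 210, 340, 60, 420]
    other = [1000, 800]  # second chromosome filling the library
    cm = _cm(
        [[c, r] for c, r in zip(cand, ref)] + [[v, v] for v in other],
        samples=["A_r1", "B_r1"],
    )
    ann = GeneAnnotation(pd.Series({f"g{i}": "1" for i in range(5)} | {"g5": "2", "g6": "2"}))
    # oracle: plain-python rpm -> log2 -> paired t
    totals = [sum(c for c, _ in cm.counts.itertuples(index=False, name=None)),
              sum(r for _, r in cm.counts.itertuples(index=False, name=None))]
    diffs = []
    for c, r in zip(cand, ref):
        lc = math.log2(c * 1e6 / totals[0] + 1)
        lr = math.log2(r * 1e6 / totals[1] + 1)
        diffs.append(lc - lr)
    mean_d = sum(diffs) / 5
    sd_d = math.sqrt(sum((d - mean_d) ** 2 for d in diffs) / 4)
    t_expected = mean_d / (sd_d / math.sqrt(5))
    p_expected = 2 * sps.t.sf(abs(t_expected), df=4)
    t, p = dosage_test(cm, ann, "A", ["B"], "1")
    assert t == pytest.approx(t_expected, rel=1e-9)
    assert p == pytest.approx(p_expected, rel=1e-9)


def test_too_few_usable_genes_is_error():
    cm = _cm([[5, 5], [0, 0], [0, 0], [100, 100]], samples=["A_r1", "B_r1"])
    ann = GeneAnnotation(pd.Series({"g0": "1", "g1": "1", "g2": "1", "g3": "2"}))
    with pytest.raises(ValidationError, match="paired test undefined"):
        dosage_test(cm, ann, "A", ["B"], "1")


def test_trisomy_power_on_150_gene_chromosome():
    """A planted 1.5x trisomy yields p < 1e-6 in >=95% of 100 seeded runs."""
    hits = 0
    for seed in range(100):
        counts, ann, _, _ = simulate_scenario("single_trisomy", seed=seed)
        refs = [ln for ln in counts.lines if ln != "ESC2"]
        _, p = dosage_test(counts, ann, "ESC2", refs, "20")
        hits += p < 1e-6
    assert hits >= 95


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_hand_worked_step_up():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_tied_values_unchanged():
    assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
    assert np.allclose(benjamini_hochberg([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        benjamini_hochberg([0.5, 1.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_dominates_raw_p_and_preserves_order(ps):
    adj = benjamini_hochberg(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# trisomy calling


def test_table_scenario_recovers_exactly_planted_gains(es_cohort):
    counts, annotation, _, _ = es_cohort
    results = ChromosomeDosageModel(counts, annotation).fit()
    assert sorted(results.gain_calls) == sorted(EXPECTED_GAINS)
    assert results.lines_with_gains == ["ESC1", "ESC2"]


def test_call_requires_both_ratio_and_significance(es_cohort):
    counts, annotation, _, _ = es_cohort
    # absurdly strict FDR: large ratios alone must not produce gains
    strict = ChromosomeDosageModel(counts, annotation).fit(fdr_threshold=1e-300)
    assert strict.gain_calls == []


def test_infinite_ratio_threshold_calls_nothing(es_cohort):
    counts, annotation, _, _ = es_cohort
    results = ChromosomeDosageModel(counts, annotation).fit(ratio_threshold=math.inf)
    assert results.gain_calls == []


def test_loss_calls_off_by_default_and_symmetric(es_cohort):
    counts, annotation, _, _ = es_cohort
    default = ChromosomeDosageModel(counts, annotation).fit()
    assert "loss" not in set(default.frame["call"])
    with_losses = ChromosomeDosageModel(counts, annotation).fit(call_losses=True)
    assert set(with_losses.frame["call"]) <= {"normal", "gain", "loss"}


def test_sex_chromosomes_excluded_from_calling_by_default(es_cohort):
    counts, annotation, _, _ = es_cohort
    results = ChromosomeDosageModel(counts, annotation).fit()
    assert not set(results.frame["chromosome"]) & {"X", "Y"}
    with_x = ChromosomeDosageModel(counts, annotation, include_x=True).fit()
    assert "X" in set(with_x.frame["chromosome"])


def test_adjusted_p_never_below_raw(es_cohort):
    counts, annotation, _, _ = es_cohort
    frame = ChromosomeDosageModel(counts, annotation).fit().frame
    assert (frame["p_adj"] >= frame["p"] - 1e-15).all()
    assert (frame["ratio"] > 0).all()


def test_summary_mentions_calls(es_cohort):
    counts, annotation, _, _ = es_cohort
    text = ChromosomeDosageModel(counts, annotation).fit().summary()
    assert "ESC1:chr19" in text and "ESC2:chr20" in text
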