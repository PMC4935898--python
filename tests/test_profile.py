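import numpy as np
import pandas as pd
import pytest

from karyoexpr import (CountMatrix, KaryotypeSpec, SimulationConfig, ValidationError,
                       build_gene_model, simulate_counts, simulate_scenario)
from karyoexpr.profile import (correlation_clustering, differential_expression,
                               log_normalized, marker_panel, pca_profile,
                               replicates_merge_first)


def _nm(array, samples):
    return pd.DataFrame(np.asarray(array, dtype=float),
                        columns=samples,
                        index=[f"g{i}" for i in range(len(array))])


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_samples_sit_at_origin():
    coords, explained = pca_profile(_nm([[3, 3], [7, 7], [1, 1]], ["a", "b"]))
    assert np.allclose(coords.to_numpy(), 0.0)
    assert np.allclose(explained, 0.0)


def test_pca_constant_matrix_is_error():
    with pytest.raises(ValidationError, match="constant"):
        pca_profile(_nm([[5, 5], [5, 5]], ["a", "b"]))


def test_pca_fraction_spectrum_properties(study_cohort):
    counts, _, _, _ = study_cohort
    _, explained = pca_profile(log_normalized(counts))
    assert np.all(np.diff(explained) <= 1e-12)
    assert np.all((explained > 0) & (explained <= 1))
    assert explained.sum() <= 1 + 1e-9


def test_pca_matches_eigendecomposition_oracle():
    values = _nm(
        [[2, 4, 6, 9], [1, 1, 3, 3], [0, 2, 1, 5], [7, 3, 2, 1], [2, 8, 6, 4]],
        ["s1", "s2", "s3", "s4"],
    )
    coords, explained = pca_profile(values)
    centered = values.T - values.T.mean(axis=0)
    cov = centered.T @ centered  # scatter matrix; shared scaling cancels in fractions
    eigvals = np.sort(np.linalg.eigvalsh(cov.to_numpy()))[::-1]
    expected = eigvals[: len(explained)] / eigvals.sum()
    assert np.allclose(explained, expected[: len(explained)], atol=1e-9)
    # coordinates reproduce pairwise distances of the centered data
    from scipy.spatial.distance import pdist

    assert np.allclose(pdist(coords.to_numpy()), pdist(centered.to_numpy()), atol=1e-8)


def test_pca_top_variance_gene_filter():
    counts, _, _, _ = simulate_scenario("all_disomic", seed=1)
    coords, _ = pca_profile(log_normalized(counts), n_top_variance_genes=50)
    assert coords.shape[0] == len(counts.samples)


def test_pca_separates_fibroblast_from_es(study_cohort):
    counts, _, _, _ = study_cohort
    coords, explained = pca_profile(log_normalized(counts))
    fib = coords.loc[[s for s in coords.index if s.startswith("FIB")], "PC1"]
    es = coords.loc[[s for s in coords.index if not s.startswith("FIB")], "PC1"]
    gap = min(abs(f - e) for f in fib for e in es)
    spread = es.max() - es.min()
    assert gap > spread  # outgroup clearly separated along PC1
    assert explained[0] > 0.5


# ---------------------------------------------------------------------------
# correlation clustering


def test_duplicated_sample_has_unit_correlation_and_zero_merge():
    values = _nm([[1, 1, 5], [4, 4, 2], [9, 9, 3], [2, 2, 8]], ["a1", "a2", "b"])
    corr, linkage = correlation_clustering(values)
    assert corr.loc["a1", "a2"] == pytest.approx(1.0)
    assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_correlation_matrix_symmetric_unit_diagonal(study_cohort):
    counts, _, _, _ = study_cohort
    corr, _ = correlation_clustering(log_normalized(counts))
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)


def test_zero_variance_sample_is_error():
    values = _nm([[1, 3], [1, 4], [1, 5]], ["flat", "b"])
    with pytest.raises(ValidationError, match="zero-variance"):
        correlation_clustering(values)


def test_replicates_cluster_by_line_in_most_runs():
    hits = 0
    runs = 30
    for seed in range(runs):
        counts, _, _, _ = simulate_scenario("study_design", seed=seed)
        _, linkage = correlation_clustering(log_normalized(counts))
        hits += replicates_merge_first(
            linkage, counts.samples, counts.sample_meta.loc[counts.samples, "line"]
        )
    assert hits >= int(0.95 * runs)


# ---------------------------------------------------------------------------
# differential expression


def _planted_de(seed, fold=4.0, n_planted=10):
    cfg = SimulationConfig(n_genes={"1": 1000}, library_size=4e6, n_replicates=3,
                           dispersion=0.001, depth_sigma=0.05, line_effect_sigma=0.0,
                           seed=seed)
    models = build_gene_model(cfg)
    planted = [m.gene_id for m in models[:n_planted]]
    ka = KaryotypeSpec("A", "male", expression_multipliers={g: fold for g in planted})
    counts, _ = simulate_counts(models, [ka, KaryotypeSpec("B", "male")], cfg)
    return counts, planted


def test_identical_groups_give_zero_candidates():
    counts, _ = _planted_de(seed=0, fold=1.0, n_planted=0)
    merged = CountMatrix(
        pd.concat([counts.counts[counts.samples_of("A")]] * 2, axis=1,
                  keys=None).set_axis([f"A_r{i}" for i in range(1, 4)]
                                      + [f"C_r{i}" for i in range(1, 4)], axis=1)
    )
    de = differential_expression(merged, merged.samples_of("A"), merged.samples_of("C"))
    assert len(de.candidates) == 0


def test_overlapping_groups_rejected(es_cohort):
    counts, _, _, _ = es_cohort
    s = counts.samples_of("ESC1") + counts.samples_of("ESC2")
    with pytest.raises(ValidationError, match="overlap"):
        differential_expression(counts, s, s[:2])


def test_planted_fold_changes_recovered_with_low_false_discovery():
    """>=7 of 10 planted 4-fold genes flagged, FP <= 5% of flagged, in >=90% of runs."""
    good = 0
    runs = 20
    for seed in range(runs):
        counts, planted = _planted_de(seed)
        de = differential_expression(counts, counts.samples_of("A"), counts.samples_of("B"))
        cands = set(de.candidates)
        tp = len(cands & set(planted))
        fp = len(cands - set(planted))
        good += tp >= 7 and fp <= 0.05 * max(len(cands), 1)
    assert good >= int(0.9 * runs)


def test_candidate_rule_is_conjunction():
    counts, _ = _planted_de(seed=1)
    de = differential_expression(counts, counts.samples_of("A"), counts.samples_of("B"))
    flagged = de.frame[de.frame["candidate"]]
    assert (flagged["log2_fold_change"].abs() >= 1.0).all()
    assert (flagged["p_adjusted"] < 0.05).all()


def test_group_swap_flips_fold_change_sign_only():
    counts, _ = _planted_de(seed=2)
    ab = differential_expression(counts, counts.samples_of("A"), counts.samples_of("B"))
    ba = differential_expression(counts, counts.samples_of("B"), counts.samples_of("A"))
    assert np.allclose(ab.frame["log2_fold_change"], -ba.frame["log2_fold_change"])
    assert (ab.frame["candidate"] == ba.frame["candidate"]).all()


# ---------------------------------------------------------------------------
# marker panels


def test_marker_reference_ratios_are_one(study_cohort):
    counts, annotation, _, _ = study_cohort
    report = marker_panel(counts, annotation.marker_panels["pluripotency"], "ES_REF")
    assert np.allclose(report.ratio["ES_REF"], 1.0)


def test_pluripotency_markers_not_detected_in_fibroblast(study_cohort):
    counts, annotation, _, _ = study_cohort
    report = marker_panel(counts, annotation.marker_panels["pluripotency"], "ES_REF")
    formatted = report.formatted()
    assert (formatted["FIB"] == "not detected").all()
    assert (report.expression[["ESC1", "ES_REF"]].to_numpy() > 0).all()


def test_two_gene_toy_panel_ratios():
    counts = CountMatrix(pd.DataFrame(
        {"A_r1": [10, 40, 50], "B_r1": [20, 20, 60]},
        index=pd.Index(["m1", "m2", "other"], name="gene_id"),
    ))
    report = marker_panel(counts, ["m1", "m2"], "A")
    sf_ratio = 1.0  # columns have equal library and symmetric composition -> sf ~ 1
    assert report.ratio.loc["m1", "B"] == pytest.approx(2.0 * sf_ratio, rel=0.2)
    assert report.ratio.loc["m2", "B"] == pytest.approx(0.5 * sf_ratio, rel=0.2)


def test_empty_marker_overlap_is_error(study_cohort):
    counts, _, _, _ = study_cohort
    with pytest.raises(ValidationError, match="no marker genes"):
        marker_panel(counts, ["NOT_A_GENE"], "ES_REF")
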