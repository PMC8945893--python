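"""Volumetry, cohort ratio statistics and the repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

import habitatmri as hm
from habitatmri.volumetrics import (
    VolumetricSummary,
    _rm_anova_f,
    cohort_ratio_stats,
    compute_volumes,
    ratio_table,
    rm_anova_bonferroni,
    significance_star,
)


def _labelmap_from_counts(counts, spacing=(1.0, 1.0, 1.0)):
    """Flat label map with the requested voxel count per habitat."""
    total = sum(counts) + 10
    side = int(np.ceil(total ** (1 / 3))) + 1
    labels = np.zeros(side**3, dtype=np.int16)
    pos = 0
    for lbl, cnt in enumerate(counts, start=1):
        labels[pos : pos + cnt] = lbl
        pos += cnt
    return hm.HabitatLabelMap(labels=labels.reshape(side, side, side), voxel_spacing=spacing)


def test_equal_volumes_symmetry():
    lm = _labelmap_from_counts([1000, 1000, 1000, 1000])  # 1 cm^3 each at 1 mm
    s = compute_volumes(lm)
    for h in hm.HABITAT_NAMES:
        assert s.ratios[f"{h}/abv"] == pytest.approx(0.25)
    assert s.ratios["edema/solid"] == pytest.approx(1.0)
    assert s.tbv_mm3 == pytest.approx(3000.0)


def test_table_one_style_volumes():
    lm = _labelmap_from_counts([23000, 31000, 8000, 39000])
    s = compute_volumes(lm)
    assert s.ratios["necrosis/abv"] == pytest.approx(0.228, abs=5e-4)
    assert s.ratios["solid/abv"] == pytest.approx(0.307, abs=5e-4)
    assert s.ratios["peritumoral_tissue/abv"] == pytest.approx(0.079, abs=5e-4)
    assert s.ratios["edema/abv"] == pytest.approx(0.386, abs=5e-4)


def test_conservation_invariants():
    lm = _labelmap_from_counts([1234, 2345, 345, 4567], spacing=(0.9, 1.1, 1.3))
    s = compute_volumes(lm)
    frac_sum = sum(s.ratios[f"{h}/abv"] for h in hm.HABITAT_NAMES)
    assert frac_sum == pytest.approx(1.0, abs=1e-9)
    assert s.habitat_volumes_mm3["edema"] == pytest.approx(s.abv_mm3 - s.tbv_mm3, abs=1e-9)
    assert s.ratios["edema/abv"] == pytest.approx(1.0 - s.tbv_mm3 / s.abv_mm3 * 1.0, abs=1e-9)


def test_generator_round_trip(phantom_cohort):
    subjects, log = phantom_cohort
    for (_, lm), slog in zip(subjects, log["subjects"]):
        s = compute_volumes(lm)
        for h in hm.HABITAT_NAMES:
            assert s.habitat_volumes_mm3[h] == pytest.approx(
                slog["habitat_volumes_mm3"][h], abs=1e-9
            )


def test_missing_habitat_rejected():
    lm = _labelmap_from_counts([100, 100, 0, 100])
    with pytest.raises(ValueError, match="peritumoral_tissue"):
        compute_volumes(lm)


def _summary(ratios):
    return VolumetricSummary(habitat_volumes_mm3={}, tbv_mm3=0, abv_mm3=0, ratios=ratios)


def test_two_point_ratio_stats():
    summaries = [_summary({"x": 0.2}), _summary({"x": 0.4})]
    rs = cohort_ratio_stats(summaries)["x"]
    assert rs.mean == pytest.approx(0.3)
    assert rs.sd == pytest.approx(np.sqrt(0.02), abs=1e-9)
    assert rs.min == 0.2 and rs.max == 0.4
    assert rs.ci95[0] < rs.mean < rs.ci95[1]


def test_identical_subjects_degenerate_ci():
    summaries = [_summary({"x": 0.5})] * 5
    rs = cohort_ratio_stats(summaries)["x"]
    assert rs.sd == 0.0
    assert rs.ci95 == (0.5, 0.5)
    with pytest.raises(ValueError):
        cohort_ratio_stats(summaries[:1])


def test_ci_coverage_simulation(rng):
    """95% t-CI covers the true mean in ~95% of replicates."""
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        x = rng.normal(0.3, 0.1, size=100)
        summaries = [_summary({"x": float(v)}) for v in x]
        rs = cohort_ratio_stats(summaries)["x"]
        hits += rs.ci95[0] <= 0.3 <= rs.ci95[1]
    assert 0.93 <= hits / n_rep <= 0.97


def test_anova_identical_conditions_f_zero():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]})
    res = rm_anova_bonferroni(table)
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0
    assert all(p == 1.0 for p in res.pairwise_corrected_p.values())


def test_anova_large_shift_significant(rng):
    a = rng.normal(0.0, 1.0, size=20)
    table = pd.DataFrame({"a": a, "b": a + 10.0 + rng.normal(0, 0.1, 20)})
    res = rm_anova_bonferroni(table)
    assert res.pairwise_corrected_p[("a", "b")] < 0.001
    assert res.stars[("a", "b")] == "†"


def test_bonferroni_monotonicity(rng):
    table = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
    res = rm_anova_bonferroni(table)
    for pair, raw in res.pairwise_raw_p.items():
        assert res.pairwise_corrected_p[pair] >= raw
        assert res.pairwise_corrected_p[pair] <= 1.0


def test_anova_f_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM

    data = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
    f, df1, df2, p = _rm_anova_f(data)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": data.ravel(),
        }
    )
    res = AnovaRM(long, "y", "subject", within=["cond"]).fit()
    assert f == pytest.approx(float(res.anova_table["F Value"].iloc[0]), rel=1e-9)
    assert p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]), rel=1e-6)
    assert (df1, df2) == (3, 33)


def test_missing_cells_rejected():
    table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
    with pytest.raises(ValueError, match="missing"):
        rm_anova_bonferroni(table)


def test_star_convention():
    assert significance_star(0.0005) == "†"
    assert significance_star(0.004) == "**"
    assert significance_star(0.005) == "**"
    assert significance_star(0.04) == "*"
    assert significance_star(0.2) == ""
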