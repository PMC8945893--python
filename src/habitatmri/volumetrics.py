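"""Habitat volumetry: TBV/ABV summaries, cohort ratio statistics and the
repeated-measures ANOVA with Bonferroni-corrected pairwise comparisons.

Definitions: TBV (tumor bulk volume) = necrosis + solid + peritumoral tissue;
ABV (abnormal bulk volume) = TBV + edema.  All volumes in mm^3.  Statistics
are computed on per-subject ratios (mean of ratios, not ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import RATIO_NAMES
from .types import HABITAT_NAMES, HabitatLabelMap


@dataclass
class VolumetricSummary:
    habitat_volumes_mm3: dict[str, float]
    tbv_mm3: float
    abv_mm3: float
    ratios: dict[str, float]


@dataclass
class RatioStats:
    ratio: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    ci95: tuple[float, float]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df: tuple[float, float]
    pairwise_raw_p: dict[tuple[str, str], float]
    pairwise_corrected_p: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str]
    n_comparisons: int = 0
    anova_star: str = ""
    details: dict = field(default_factory=dict)


def compute_volumes(labelmap: HabitatLabelMap) -> VolumetricSummary:
    """Voxel-count volumetry of one subject; requires all four habitats present."""
    voxvol = labelmap.voxel_volume_mm3
    vols = {}
    for i, hab in enumerate(HABITAT_NAMES):
        count = int(np.count_nonzero(labelmap.labels == i + 1))
        if count == 0:
            raise ValueError(f"habitat {hab!r} missing from label map")
        vols[hab] = count * voxvol
    tbv = vols["necrosis"] + vols["solid"] + vols["peritumoral_tissue"]
    abv = tbv + vols["edema"]
    ratios = {
        "necrosis/abv": vols["necrosis"] / abv,
        "solid/abv": vols["solid"] / abv,
        "peritumoral_tissue/abv": vols["peritumoral_tissue"] / abv,
        "edema/abv": vols["edema"] / abv,
        "necrosis/solid": vols["necrosis"] / vols["solid"],
        "peritumoral_tissue/solid": vols["peritumoral_tissue"] / vols["solid"],
        "edema/solid": vols["edema"] / vols["solid"],
        "necrosis/peritumoral_tissue": vols["necrosis"] / vols["peritumoral_tissue"],
        "solid/peritumoral_tissue": vols["solid"] / vols["peritumoral_tissue"],
        "edema/peritumoral_tissue": vols["edema"] / vols["peritumoral_tissue"],
        "necrosis/tbv": vols["necrosis"] / tbv,
        "solid/tbv": vols["solid"] / tbv,
        "peritumoral_tissue/tbv": vols["peritumoral_tissue"] / tbv,
        "edema/tbv": vols["edema"] / tbv,
    }
    return VolumetricSummary(habitat_volumes_mm3=vols, tbv_mm3=tbv, abv_mm3=abv, ratios=ratios)


def ratio_table(summaries: list[VolumetricSummary]) -> pd.DataFrame:
    """Per-subject ratio table (rows = subjects, columns = ratio names)."""
    return pd.DataFrame([s.ratios for s in summaries])


def cohort_ratio_stats(summaries: list[VolumetricSummary]) -> dict[str, RatioStats]:
    """Mean, sample SD, min/max and 95% t-CI of each ratio across subjects."""
    n = len(summaries)
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    table = ratio_table(summaries)
    out = {}
    for ratio in table.columns:
        x = table[ratio].to_numpy()
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        se = sd / np.sqrt(n)
        tcrit = float(stats.t.ppf(0.975, n - 1))
        out[ratio] = RatioStats(
            ratio=ratio,
            n=n,
            mean=mean,
            sd=sd,
            min=float(x.min()),
            max=float(x.max()),
            ci95=(mean - tcrit * se, mean + tcrit * se),
        )
    return out


def stats_dataframe(statsmap: dict[str, RatioStats]) -> pd.DataFrame:
    rows = []
    for rs in statsmap.values():
        rows.append(
            {
                "ratio": rs.ratio,
                "n": rs.n,
                "mean": rs.mean,
                "sd": rs.sd,
                "min": rs.min,
                "max": rs.max,
                "ci95_low": rs.ci95[0],
                "ci95_high": rs.ci95[1],
            }
        )
    return pd.DataFrame(rows).set_index("ratio")


def significance_star(p: float) -> str:
    """Convention: p < 0.001 dagger, p <= 0.005 double star, p < 0.05 star."""
    if p < 0.001:
        return "†"
    if p <= 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _rm_anova_f(data: np.ndarray) -> tuple[float, float, float, float]:
    """One-way repeated-measures ANOVA F test (subjects x conditions)."""
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0 if ms_cond == 0 else np.inf, df1, df2, 1.0 if ms_cond == 0 else 0.0
    f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def rm_anova_bonferroni(table: pd.DataFrame, family: list[str] | None = None) -> AnovaResult:
    """Repeated-measures ANOVA across ratio types with subject as the
    repeated factor, followed by Bonferroni-corrected paired t-tests.

    ``table`` has one row per subject and one column per ratio type;
    ``family`` selects the compared columns (default: all columns).
    No sphericity (Greenhouse-Geisser) correction is applied.
    """
    family = list(family) if family is not None else list(table.columns)
    if len(family) < 2:
        raise ValueError("need at least two ratio types to compare")
    sub = table[family]
    missing = sub.index[sub.isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"subjects with missing cells: {missing}")
    data = sub.to_numpy(dtype=float)
    f, df1, df2, p = _rm_anova_f(data)

    pairs = [(a, b) for i, a in enumerate(family) for b in family[i + 1 :]]
    m = len(pairs)
    raw, corrected, stars = {}, {}, {}
    for a, b in pairs:
        d = sub[a].to_numpy() - sub[b].to_numpy()
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            pr = 1.0
        else:
            pr = float(stats.ttest_rel(sub[a], sub[b]).pvalue)
        raw[(a, b)] = pr
        pc = min(1.0, pr * m)
        corrected[(a, b)] = pc
        stars[(a, b)] = significance_star(pc)
    return AnovaResult(
        f_statistic=f,
        p_value=p,
        df=(df1, df2),
        pairwise_raw_p=raw,
        pairwise_corrected_p=corrected,
        stars=stars,
        n_comparisons=m,
        anova_star=significance_star(p),
        details={"n_subjects": int(data.shape[0]), "family": family},
    )
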