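"""Left-ventricular mass, mass index and hypertrophy classification.

LV mass follows the Devereux-corrected M-mode formula

    LVM = 0.8 * {1.04 * [(LVIDD + PWTD + IVSTD)^3 - LVIDD^3]} + 0.6 g

with chamber/wall dimensions in cm, and is indexed by height squared
(g/m^2). Left-ventricular hypertrophy (LVH) is diagnosed when the LV mass
index *exceeds* a sex-specific threshold: 110 g/m^2 in women, 125 g/m^2 in
men (strict inequality — a value exactly at the threshold is not LVH).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    EchoMeasurements,
    GROUP_CASE,
    GROUP_CONTROL,
    SEX_FEMALE,
    SEX_MALE,
    SampleRecord,
)

DEVEREUX_SHRINKAGE = 0.8
MYOCARDIAL_DENSITY = 1.04  # g/cm^3
DEVEREUX_OFFSET_G = 0.6


@dataclass(frozen=True)
class LvhThresholds:
    """Sex-specific LV mass index cut-offs (g/m^2) for LVH diagnosis."""

    female_lvmi: float = 110.0
    male_lvmi: float = 125.0

    def __post_init__(self) -> None:
        if self.female_lvmi <= 0 or self.male_lvmi <= 0:
            raise ValueError("LVH thresholds must be positive")

    def for_sex(self, sex: str) -> float:
        if sex == SEX_FEMALE:
            return self.female_lvmi
        if sex == SEX_MALE:
            return self.male_lvmi
        raise ValueError(f"unknown sex label: {sex!r}")


def compute_lv_mass(
    echo: EchoMeasurements,
    *,
    offset_g: float = DEVEREUX_OFFSET_G,
    validate: bool = True,
) -> float:
    """Devereux-corrected LV mass in grams.

    With ``validate=True`` (default) all measurements must be strictly
    positive; the guard can be disabled to evaluate the bare formula on
    degenerate inputs.
    """
    if validate:
        for name in ("lvidd", "pwtd", "ivstd", "height"):
            if getattr(echo, name) <= 0:
                raise ValueError(f"non-positive echo measurement: {name}")
    septum_sum = echo.lvidd + echo.pwtd + echo.ivstd
    return (
        DEVEREUX_SHRINKAGE
        * (MYOCARDIAL_DENSITY * (septum_sum**3 - echo.lvidd**3))
        + offset_g
    )


def compute_lvmi(lv_mass: float, height: float) -> float:
    """LV mass index: mass (g) divided by height (m) squared."""
    if height <= 0:
        raise ValueError("height must be positive")
    return lv_mass / height**2


def classify_lvh(
    lvmi: float, sex: str, thresholds: LvhThresholds = LvhThresholds()
) -> bool:
    """True when the LV mass index strictly exceeds the sex-specific cut-off."""
    if lvmi < 0:
        raise ValueError("negative LVMI")
    return lvmi > thresholds.for_sex(sex)


def lvh_label(is_lvh: bool) -> str:
    return "LVH" if is_lvh else "no-LVH"


def classify_sample(
    sample: SampleRecord, thresholds: LvhThresholds = LvhThresholds()
) -> dict:
    """LV mass, LVMI and LVH status for one sample (requires echo data)."""
    if sample.echo is None:
        raise ValueError(f"sample {sample.sample_id} has no echo measurements")
    mass = compute_lv_mass(sample.echo)
    lvmi = compute_lvmi(mass, sample.echo.height)
    return {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "sex": sample.sex,
        "lv_mass_g": mass,
        "lvmi": lvmi,
        "lvh": classify_lvh(lvmi, sample.sex, thresholds),
    }


@dataclass
class CohortSummary:
    """Group sizes and per-variable case/control comparisons."""

    n_case: int
    n_control: int
    table: pd.DataFrame  # variable, case, control, statistic, p_value, significant

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


def _welch(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    # Degenerate zero-variance groups with equal means: no difference.
    if (
        np.ptp(case) == 0
        and np.ptp(control) == 0
        and case.size
        and control.size
        and case[0] == control[0]
    ):
        return 0.0, 1.0
    stat, p = stats.ttest_ind(case, control, equal_var=False)
    return float(stat), float(p)


def _sex_comparison(case: Sequence[str], control: Sequence[str]) -> tuple[float, float]:
    table = np.array(
        [
            [sum(s == SEX_MALE for s in case), sum(s == SEX_FEMALE for s in case)],
            [sum(s == SEX_MALE for s in control), sum(s == SEX_FEMALE for s in control)],
        ]
    )
    if table.sum(axis=0).min() == 0:  # a sex absent everywhere
        return 0.0, 1.0
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 5:
        odds, p = stats.fisher_exact(table)
        return float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)


def summarize_cohort(
    samples: Iterable[SampleRecord],
    thresholds: LvhThresholds = LvhThresholds(),
    alpha: float = 0.05,
) -> CohortSummary:
    """Table-style cohort description with case/control comparisons.

    Continuous variables are compared with Welch's two-sample t-test,
    sex with a chi-square test (Fisher's exact when expected counts are
    low); differences are flagged at ``alpha``. With a single group the
    table carries means only (statistics NaN).
    """
    samples = list(samples)
    case = [s for s in samples if s.group == GROUP_CASE]
    control = [s for s in samples if s.group == GROUP_CONTROL]

    def echo_var(s: SampleRecord, name: str) -> Optional[float]:
        if s.echo is None:
            return None
        if name == "lv_mass":
            return compute_lv_mass(s.echo)
        if name == "lvmi":
            return compute_lvmi(compute_lv_mass(s.echo), s.echo.height)
        return getattr(s.echo, name)

    continuous = [
        ("age", lambda s: s.age),
        ("bmi", lambda s: s.bmi),
        ("sbp", lambda s: s.sbp),
        ("dbp", lambda s: s.dbp),
        ("lv_mass", lambda s: echo_var(s, "lv_mass")),
        ("ivstd", lambda s: echo_var(s, "ivstd")),
        ("lvmi", lambda s: echo_var(s, "lvmi")),
    ]
    rows = []
    two_groups = bool(case) and bool(control)
    for name, getter in continuous:
        vc = np.array([v for s in case if (v := getter(s)) is not None], dtype=float)
        vk = np.array([v for s in control if (v := getter(s)) is not None], dtype=float)
        if vc.size + vk.size == 0:
            continue
        if two_groups and vc.size >= 2 and vk.size >= 2:
            stat, p = _welch(vc, vk)
        else:
            stat, p = np.nan, np.nan
        rows.append(
            {
                "variable": name,
                "case": float(vc.mean()) if vc.size else np.nan,
                "control": float(vk.mean()) if vk.size else np.nan,
                "statistic": stat,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    # categorical: sex (male fraction), exact/chi-square on the 2x2 table
    if two_groups:
        stat, p = _sex_comparison([s.sex for s in case], [s.sex for s in control])
    else:
        stat, p = np.nan, np.nan
    rows.append(
        {
            "variable": "sex_male_fraction",
            "case": np.mean([s.sex == SEX_MALE for s in case]) if case else np.nan,
            "control": np.mean([s.sex == SEX_MALE for s in control]) if control else np.nan,
            "statistic": stat,
            "p_value": p,
            "significant": bool(p < alpha) if np.isfinite(p) else False,
        }
    )
    # LVH prevalence by the classifier, when echo data exist
    lvh_case = [
        classify_lvh(compute_lvmi(compute_lv_mass(s.echo), s.echo.height), s.sex, thresholds)
        for s in case
        if s.echo is not None
    ]
    lvh_control = [
        classify_lvh(compute_lvmi(compute_lv_mass(s.echo), s.echo.height), s.sex, thresholds)
        for s in control
        if s.echo is not None
    ]
    if lvh_case or lvh_control:
        rows.append(
            {
                "variable": "lvh_fraction",
                "case": np.mean(lvh_case) if lvh_case else np.nan,
                "control": np.mean(lvh_control) if lvh_control else np.nan,
                "statistic": np.nan,
                "p_value": np.nan,
                "significant": False,
            }
        )
    return CohortSummary(
        n_case=len(case), n_control=len(control), table=pd.DataFrame(rows)
    )
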