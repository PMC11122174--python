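"""Cohort screening and statistics for bilateral orbital morphometry.

Implements the analysis battery of the reference workflow: the 0.2 mL
left-right asymmetry screen, Shapiro-Wilk normality, gender / side /
larger-vs-smaller comparisons (Welch's t unpaired, paired t within
subject), the volume ~ gender * depth interaction regression, squared
Pearson correlations among the three measurements, ANOVA-based intraclass
correlation coefficients, and the two derived cohort ratios (male-female
volume difference in percent, volume per surface area in mL/cm^2).

No multiple-testing correction is applied, matching the reference
analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import DegenerateInputError

__all__ = [
    "AsymmetryRule",
    "screen_asymmetry",
    "test_normality",
    "compare_groups",
    "fit_volume_model",
    "correlations",
    "icc",
    "gender_volume_difference",
    "volume_area_ratio",
    "build_stats_report",
]

log = logging.getLogger("orbitmorph.stats")

PARAMETERS = ("volume_ml", "depth_mm", "area_mm2")
GENDERS = ("male", "female")
SIDES = ("left", "right")
R2_PAIRS = {  # pair name -> (y, x) columns without side suffix
    "VxL": ("volume_ml", "depth_mm"),
    "AxL": ("area_mm2", "depth_mm"),
    "AxV": ("area_mm2", "volume_ml"),
}


@dataclass
class AsymmetryRule:
    """Bilateral exclusion rule: flag if |V_left - V_right| > threshold."""

    threshold_ml: float = 0.2

    def __post_init__(self) -> None:
        if self.threshold_ml <= 0:
            raise ValueError("threshold_ml must be positive")


def screen_asymmetry(
    table: pd.DataFrame, rule: AsymmetryRule | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a bilateral cohort into retained and excluded subjects.

    A subject is flagged when the left and right volumes differ by
    *strictly more* than the threshold (a difference of exactly the
    threshold is retained).  Both returned frames carry
    ``asymmetric_flag`` and ``exclusion_reason`` columns; together they
    hold every input row exactly once.
    """
    rule = rule or AsymmetryRule()
    for col in ("volume_ml_left", "volume_ml_right"):
        if col not in table.columns or table[col].isna().any():
            raise DegenerateInputError(f"missing side volumes in column {col}")
    out = table.copy()
    diff = (out["volume_ml_left"] - out["volume_ml_right"]).abs()
    out["asymmetric_flag"] = diff > rule.threshold_ml
    defect = out.get("defect", pd.Series("none", index=out.index)).fillna("none")
    out["exclusion_reason"] = np.where(
        ~out["asymmetric_flag"], "none", np.where(defect != "none", "defect", "asymmetry")
    )
    retained = out[~out["asymmetric_flag"]].reset_index(drop=True)
    excluded = out[out["asymmetric_flag"]].reset_index(drop=True)
    log.info(
        "asymmetry screen: %d screened, %d flagged, %d retained",
        len(out), len(excluded), len(retained),
    )
    return retained, excluded


def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no defined normality test")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _sides_of(table: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    return (
        table[f"{parameter}_left"].to_numpy(float),
        table[f"{parameter}_right"].to_numpy(float),
    )


def compare_groups(table: pd.DataFrame, parameter: str, design: str) -> dict:
    """Group comparisons for one parameter.

    ``design``:

    * ``male_vs_female`` — Welch's unpaired t per side;
    * ``left_vs_right`` — per gender, Welch's unpaired t plus the paired t
      on within-subject differences;
    * ``larger_vs_smaller`` — per gender, the per-subject larger orbit
      (max of the two sides) against the smaller one, unpaired (treating
      orbits as independent samples) and paired within subject.

    Zero-variance paired differences are surfaced as a degenerate result
    (``p`` = NaN, ``degenerate`` = True) rather than an exception.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if design == "male_vs_female":
        out = {}
        for side in SIDES:
            groups = [
                table.loc[table.gender == g, f"{parameter}_{side}"].to_numpy(float)
                for g in GENDERS
            ]
            if any(g.size == 0 for g in groups):
                raise DegenerateInputError("both genders must be present")
            t, p = sps.ttest_ind(groups[0], groups[1], equal_var=False)
            out[side] = {"p_unpaired": float(p)}
        return out
    if design not in ("left_vs_right", "larger_vs_smaller"):
        raise ValueError(f"unknown design {design!r}")
    out = {}
    for g in GENDERS:
        sub = table[table.gender == g]
        if len(sub) == 0:
            raise DegenerateInputError(f"no {g} subjects")
        a, b = _sides_of(sub, parameter)
        if design == "larger_vs_smaller":
            a, b = np.maximum(a, b), np.minimum(a, b)
        t_u, p_u = sps.ttest_ind(a, b, equal_var=False)
        d = a - b
        if np.ptp(d) == 0 and d.std() == 0:
            out[g] = {"p_unpaired": float(p_u), "p_paired": float("nan"),
                      "degenerate": True}
            continue
        t_p, p_p = sps.ttest_rel(a, b)
        out[g] = {"p_unpaired": float(p_u), "p_paired": float(p_p),
                  "degenerate": False}
    return out


def fit_volume_model(table: pd.DataFrame, side: str) -> pd.DataFrame:
    """OLS fit of volume ~ 1 + gender + depth + gender:depth for one side.

    Gender is coded male = 1, female = 0.  Returns a frame indexed by term
    (Intercept, Gender, Depth, Gender:Depth) with ``coef`` and ``p``.
    """
    if side not in SIDES:
        raise ValueError("side must be 'left' or 'right'")
    if len(table) <= 4:
        raise DegenerateInputError("interaction model needs n > 4")
    if set(table.gender.unique()) != set(GENDERS):
        raise DegenerateInputError("both genders must be present")
    df = pd.DataFrame(
        {
            "volume": table[f"volume_ml_{side}"].to_numpy(float),
            "depth": table[f"depth_mm_{side}"].to_numpy(float),
            "gender": (table.gender == "male").astype(float).to_numpy(),
        }
    )
    model = smf.ols("volume ~ 1 + gender + depth + gender:depth", data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DegenerateInputError("design matrix is rank deficient")
    fit = model.fit()
    rename = {
        "Intercept": "Intercept",
        "gender": "Gender",
        "depth": "Depth",
        "gender:depth": "Gender:Depth",
    }
    out = pd.DataFrame({"coef": fit.params, "p": fit.pvalues})
    out.index = [rename[i] for i in out.index]
    return out


def correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlations V x L, A x L, A x V per gender and side."""
    rows = []
    for pair, (ycol, xcol) in R2_PAIRS.items():
        for g in GENDERS:
            sub = table[table.gender == g]
            for side in SIDES:
                x = sub[f"{xcol}_{side}"].to_numpy(float)
                y = sub[f"{ycol}_{side}"].to_numpy(float)
                if x.size < 3:
                    raise DegenerateInputError("correlation needs n >= 3")
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    raise DegenerateInputError("zero-variance sample in correlation")
                r = np.corrcoef(x, y)[0, 1]
                rows.append(dict(pair=pair, gender=g, side=side, r2=float(r**2)))
    return pd.DataFrame(rows)


def icc(measurements, form: str = "agreement") -> float:
    """Single-measurement intraclass correlation by two-way ANOVA.

    ``measurements`` is an (n subjects x k raters/runs) matrix.  The
    default ``"agreement"`` form is the two-way random-effects,
    absolute-agreement, single-measurement ICC; ``"consistency"`` drops
    the rater variance from the denominator.  A matrix with zero
    between-subject variance has no subject discrimination; 0.0 is
    returned with a warning.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateInputError("ICC needs at least 2 subjects and 2 raters")
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        warnings.warn("zero between-subject variance: ICC undefined, returning 0.0",
                      stacklevel=2)
        return 0.0
    if form == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    return float((msr - mse) / denom)


def gender_volume_difference(table: pd.DataFrame) -> float:
    """Male-female volume difference in percent of the female mean.

    Means are computed per gender and side, then side-averaged; the female
    mean is the denominator by convention.
    """
    means = {}
    for g in GENDERS:
        sub = table[table.gender == g]
        if len(sub) == 0:
            raise DegenerateInputError(f"no {g} subjects")
        means[g] = float(
            np.mean([sub[f"volume_ml_{s}"].mean() for s in SIDES])
        )
    return 100.0 * (means["male"] - means["female"]) / means["female"]


def volume_area_ratio(table: pd.DataFrame) -> dict:
    """Mean volume (mL) over mean area (cm^2) per gender x side + average."""
    out = {}
    cells = []
    for g in GENDERS:
        sub = table[table.gender == g]
        for side in SIDES:
            a_cm2 = sub[f"area_mm2_{side}"].mean() / 100.0
            if not a_cm2 > 0:
                raise DegenerateInputError("zero mean area")
            r = float(sub[f"volume_ml_{side}"].mean() / a_cm2)
            out[f"{g}_{side}"] = r
            cells.append(r)
    out["average"] = float(np.mean(cells))
    return out


def build_stats_report(
    table: pd.DataFrame, rule: AsymmetryRule | None = None
) -> dict:
    """Screen a cohort and compute the full statistics battery.

    Returns a plain JSON-serializable dict (see
    :mod:`orbitmorph.schemas` for the validated layout).
    """
    retained, excluded = screen_asymmetry(table, rule)
    report: dict = {
        "schema_version": 1,
        "n_screened": int(len(table)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(excluded)),
    }
    normality: dict = {}
    for parameter in PARAMETERS:
        normality[parameter] = {}
        for g in GENDERS:
            normality[parameter][g] = {}
            sub = retained[retained.gender == g]
            for side in SIDES:
                w, p = test_normality(sub[f"{parameter}_{side}"])
                normality[parameter][g][side] = {"W": w, "p": p}
    report["normality"] = normality

    group_tests: dict = {}
    for parameter in PARAMETERS:
        group_tests[parameter] = {
            design: compare_groups(retained, parameter, design)
            for design in ("male_vs_female", "left_vs_right", "larger_vs_smaller")
        }
    report["group_tests"] = group_tests

    report["volume_model"] = {
        side: {
            term: {"coef": float(row.coef), "p": float(row.p)}
            for term, row in fit_volume_model(retained, side).iterrows()
        }
        for side in SIDES
    }
    corr = correlations(retained)
    report["correlations"] = {
        pair: {
            g: {
                side: float(
                    corr[(corr.pair == pair) & (corr.gender == g) & (corr.side == side)]
                    .r2.iloc[0]
                )
                for side in SIDES
            }
            for g in GENDERS
        }
        for pair in R2_PAIRS
    }
    report["gender_volume_difference_pct"] = gender_volume_difference(retained)
    report["volume_area_ratio"] = volume_area_ratio(retained)
    return report
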