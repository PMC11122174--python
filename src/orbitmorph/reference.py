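"""Reference summary statistics for an adult orbital CT cohort.

These are published per-gender, per-side summary statistics (mean, median,
SD, range) of bony-orbit depth, volume and surface area for 91 men and 83
women, measured with a deterministic automated CT segmentation tool after
excluding asymmetric orbits.  They serve two purposes here:

* they are the default sampling targets of the synthetic cohort generator
  (:mod:`orbitmorph.cohort`), and
* the derived cohort-level quantities (gender volume difference, the
  volume/area ratio, rounded depth and area summaries) are computed from
  them directly.

Units: depth mm, volume mL, area mm^2.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_summary",
    "reference_r2",
    "gender_volume_difference_pct",
    "volume_area_ratios",
    "depth_summary_mm",
    "area_summary_cm2",
]

# parameter -> gender -> side -> (mean, median, sd, min, max)
_SUMMARY = {
    "depth_mm": {
        "male": {
            "left": (39.74, 40.00, 2.91, 31.27, 46.15),
            "right": (39.83, 40.29, 3.07, 31.24, 46.53),
        },
        "female": {
            "left": (37.41, 37.33, 2.67, 29.45, 46.06),
            "right": (37.27, 37.30, 2.65, 29.26, 45.44),
        },
    },
    "volume_ml": {
        "male": {
            "left": (28.95, 29.61, 3.63, 17.37, 38.43),
            "right": (29.02, 29.40, 3.63, 17.91, 36.85),
        },
        "female": {
            "left": (25.39, 25.13, 3.14, 17.36, 35.29),
            "right": (25.48, 25.19, 3.25, 17.90, 36.78),
        },
    },
    "area_mm2": {
        "male": {
            "left": (3878.68, 3952.46, 395.61, 2697.10, 4648.56),
            "right": (3871.49, 3898.07, 382.11, 2646.76, 4793.88),
        },
        "female": {
            "left": (3492.22, 3465.58, 339.04, 2712.26, 4523.00),
            "right": (3490.72, 3494.79, 336.55, 2628.22, 4448.10),
        },
    },
}

# Squared Pearson correlations among the three measurements,
# pair -> gender -> side.  V = volume, L = depth, A = area.
_R2 = {
    "VxL": {
        "male": {"left": 0.71, "right": 0.73},
        "female": {"left": 0.58, "right": 0.51},
    },
    "AxL": {
        "male": {"left": 0.85, "right": 0.87},
        "female": {"left": 0.84, "right": 0.78},
    },
    "AxV": {
        "male": {"left": 0.96, "right": 0.95},
        "female": {"left": 0.87, "right": 0.87},
    },
}

N_SUBJECTS = {"male": 91, "female": 83}
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 38.49, 13.52, 18.0, 74.0

#: Screening cohort size and flagged counts for the asymmetry screen:
#: 186 screened, 12 flagged (4 men, 8 women), 174 retained.
N_SCREENED, N_FLAGGED = 186, 12


def reference_summary() -> pd.DataFrame:
    """Reference summaries as a tidy DataFrame.

    Columns: parameter, gender, side, mean, median, sd, min, max.
    """
    rows = []
    for parameter, by_gender in _SUMMARY.items():
        for gender, by_side in by_gender.items():
            for side, (mean, median, sd, lo, hi) in by_side.items():
                rows.append(
                    dict(parameter=parameter, gender=gender, side=side,
                         mean=mean, median=median, sd=sd, min=lo, max=hi)
                )
    return pd.DataFrame(rows)


def reference_r2() -> pd.DataFrame:
    """Reference squared correlations (pair, gender, side, r2)."""
    rows = []
    for pair, by_gender in _R2.items():
        for gender, by_side in by_gender.items():
            for side, r2 in by_side.items():
                rows.append(dict(pair=pair, gender=gender, side=side, r2=r2))
    return pd.DataFrame(rows)


def _side_mean(parameter: str, gender: str) -> float:
    d = _SUMMARY[parameter][gender]
    return (d["left"][0] + d["right"][0]) / 2.0


def gender_volume_difference_pct() -> float:
    """Male-vs-female volume difference in percent of the female mean.

    Side-averaged means; by convention the female mean is the denominator.
    """
    male = _side_mean("volume_ml", "male")
    female = _side_mean("volume_ml", "female")
    return 100.0 * (male - female) / female


def volume_area_ratios() -> dict:
    """Mean volume (mL) over mean area (cm^2) per gender and side.

    Returns the four gender x side cells plus their average under key
    ``"average"``.
    """
    out: dict = {}
    cells = []
    for gender in ("male", "female"):
        for side in ("left", "right"):
            v = _SUMMARY["volume_ml"][gender][side][0]
            a_cm2 = _SUMMARY["area_mm2"][gender][side][0] / 100.0
            r = v / a_cm2
            out[f"{gender}_{side}"] = r
            cells.append(r)
    out["average"] = sum(cells) / len(cells)
    return out


def depth_summary_mm() -> dict:
    """Side-averaged mean orbital depth per gender, exact and rounded mm."""
    out = {}
    for gender in ("male", "female"):
        m = _side_mean("depth_mm", gender)
        out[gender] = m
        out[f"{gender}_rounded"] = round(m)
    return out


def area_summary_cm2() -> dict:
    """Side-averaged mean orbital surface area per gender in cm^2."""
    out = {}
    for gender in ("male", "female"):
        m = _side_mean("area_mm2", gender) / 100.0
        out[gender] = m
        out[f"{gender}_rounded"] = round(m)
    return out
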