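"""Study-style report tables built from per-subject ROI samples.

The input is a long-format ``pandas.DataFrame`` of ROI samples, one row
per subject x tissue class, with columns::

    subject_id, age, tissue_class (lesion | contralateral_normal),
    zone (tz | pz), gleason_group, enhanced, f, d, dstar, adc

Parameter columns are in reporting units: f in percent, D / D* / ADC in
1e-3 mm^2/s.  The builders return tidy DataFrames mirroring the usual
clinical-report layouts: group medians with quartiles and Mann-Whitney p,
paired lesion-vs-normal comparisons, Spearman correlations against age,
and a per-parameter diagnostic-accuracy table (cutoff, AUC with 95% CI,
sensitivity/specificity/PPV/NPV/accuracy, age-adjusted OR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    age_adjusted_or,
    confusion_metrics,
    mann_whitney,
    paired_test,
    roc_analysis,
    spearman_vs_age,
)

PARAMS = ("f", "d", "dstar", "adc")

__all__ = [
    "PARAMS",
    "paired_comparison_table",
    "group_comparison_table",
    "age_correlation_table",
    "diagnostic_accuracy_table",
    "diagnostics_json",
]


def _fmt_summary(s: dict) -> str:
    return f"{s['median']:.2f} ({s['q1']:.2f}, {s['q3']:.2f})"


def _paired_frames(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    lesion = samples[samples.tissue_class == "lesion"].set_index("subject_id")
    normal = samples[samples.tissue_class == "contralateral_normal"].set_index(
        "subject_id"
    )
    common = lesion.index.intersection(normal.index)
    if len(common) == 0:
        raise ValueError("no matched lesion/normal pairs")
    return lesion.loc[common], normal.loc[common]


def paired_comparison_table(samples: pd.DataFrame, params=PARAMS) -> pd.DataFrame:
    """Lesion vs matched contralateral normal tissue, per parameter:
    medians with quartiles, paired-t p, Mann-Whitney p."""
    lesion, normal = _paired_frames(samples)
    rows = []
    for p in params:
        pt = paired_test(lesion[p].to_numpy(), normal[p].to_numpy())
        mw = mann_whitney(lesion[p].to_numpy(), normal[p].to_numpy())
        rows.append(
            {
                "param": p,
                "lesion": _fmt_summary(pt.summaries[0]),
                "normal": _fmt_summary(pt.summaries[1]),
                "paired_t_p": pt.p_value,
                "mann_whitney_p": mw.p_value,
                "n_pairs": len(lesion),
            }
        )
    return pd.DataFrame(rows)


def group_comparison_table(
    samples: pd.DataFrame, group_col: str, params=PARAMS
) -> pd.DataFrame:
    """Two-level subgroup comparison (e.g. Gleason group, enhancement) of
    lesion parameters; Mann-Whitney p per parameter."""
    df = samples[samples[group_col].isin(samples[group_col].unique()[:2])]
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, got {levels}")
    ga = df[df[group_col] == levels[0]]
    gb = df[df[group_col] == levels[1]]
    rows = []
    for p in params:
        mw = mann_whitney(ga[p].to_numpy(), gb[p].to_numpy())
        rows.append(
            {
                "param": p,
                str(levels[0]): _fmt_summary(mw.summaries[0]),
                str(levels[1]): _fmt_summary(mw.summaries[1]),
                "mann_whitney_p": mw.p_value,
            }
        )
    return pd.DataFrame(rows)


def age_correlation_table(
    zone_samples: pd.DataFrame, params=PARAMS, zones=("tz", "pz")
) -> pd.DataFrame:
    """Spearman correlation of each zone parameter with age over all
    subjects.  Expects one row per subject x zone with the parameter
    columns plus ``age`` and ``zone``."""
    rows = []
    for p in params:
        for z in zones:
            sub = zone_samples[zone_samples.zone == z]
            if p not in sub or sub[p].isna().all():
                continue
            sp = spearman_vs_age(sub[p].to_numpy(), sub["age"].to_numpy())
            rows.append({"param": p, "zone": z, "rho": sp.statistic, "p": sp.p_value})
    return pd.DataFrame(rows)


def diagnostic_accuracy_table(samples: pd.DataFrame, params=PARAMS) -> pd.DataFrame:
    """Per-parameter diagnostic accuracy for lesion vs contralateral normal:
    Youden cutoff, AUC (DeLong 95% CI), confusion metrics at the cutoff,
    and the age-adjusted OR of the dichotomized parameter."""
    lesion, normal = _paired_frames(samples)
    rows = []
    for p in params:
        roc = roc_analysis(lesion[p].to_numpy(), normal[p].to_numpy())
        cm = confusion_metrics(roc.table)
        pooled = pd.concat(
            [lesion[[p, "age"]].assign(y=1), normal[[p, "age"]].assign(y=0)]
        )
        if roc.orientation == "lower_is_positive":
            exposed = (pooled[p] <= roc.cutoff).astype(float)
        else:
            exposed = (pooled[p] >= roc.cutoff).astype(float)
        orr = age_adjusted_or(pooled["y"].to_numpy(), exposed.to_numpy(),
                              pooled["age"].to_numpy())
        rows.append(
            {
                "param": p,
                "cutoff": roc.cutoff,
                "orientation": roc.orientation,
                "auc": roc.auc,
                "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high,
                "sensitivity": cm["sensitivity"],
                "specificity": cm["specificity"],
                "ppv": cm["ppv"],
                "npv": cm["npv"],
                "accuracy": cm["accuracy"],
                "age_adj_or": orr.odds_ratio if orr.available else None,
                "or_ci_low": orr.ci_low if orr.available else None,
                "or_ci_high": orr.ci_high if orr.available else None,
                "or_note": "" if orr.available else orr.reason,
            }
        )
    return pd.DataFrame(rows)


def diagnostics_json(table: pd.DataFrame) -> dict:
    """Per-parameter diagnostics report dict (JSON-serializable)."""
    out = {}
    for _, r in table.iterrows():
        out[r["param"]] = {
            "cutoff": r["cutoff"],
            "auc": r["auc"],
            "ci": [r["auc_ci_low"], r["auc_ci_high"]],
            "sens": r["sensitivity"],
            "spec": r["specificity"],
            "ppv": r["ppv"],
            "npv": r["npv"],
            "accuracy": r["accuracy"],
            "or": r["age_adj_or"],
            "or_ci": [r["or_ci_low"], r["or_ci_high"]],
        }
    return out


def cohort_zone_samples(truth: pd.DataFrame, unit_scale: bool = True) -> pd.DataFrame:
    """Reshape a cohort ground-truth frame (one row per subject with
    f_tz/d_tz/... columns) to long zone samples in reporting units."""
    rows = []
    for _, r in truth.iterrows():
        for z in ("tz", "pz"):
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "age": r["age"],
                    "zone": z,
                    "f": r[f"f_{z}"] * (100.0 if unit_scale else 1.0),
                    "d": r[f"d_{z}"] * (1e3 if unit_scale else 1.0),
                    "dstar": r[f"dstar_{z}"] * (1e3 if unit_scale else 1.0),
                }
            )
    return pd.DataFrame(rows)
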