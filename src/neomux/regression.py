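"""Per-density mixed-model regression, AUC aggregation and strength tests.

Network metrics are regressed on gestational age (GA, mean-centered)
and hemisphere (within-subject factor, L=0 / R=1) with their
interaction, using a linear mixed model with a subject-level random
intercept (REML).  One model is fitted per (metric, modality, density);
densities above ``max_density`` (default 0.5) are excluded because a
near-saturated network leaves too little inter-individual variability
for the model.  p-values are BH-adjusted across densities within each
(metric, modality, term) family.  Values outside Tukey fences
(1.5 x IQR beyond the quartiles) are removed per cell before fitting.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .inference import bh_adjust
from .thresholding import DensityGrid

__all__ = [
    "iqr_filter",
    "auc_aggregate",
    "fit_density_models",
    "fit_auc_models",
    "strength_ttest",
]

TERMS = ["Intercept", "ga_c", "hemi", "ga_c:hemi"]


def iqr_filter(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier removal.

    Returns ``(kept_values, keep_mask)``; the mask is aligned to the
    input order.  Quartiles use the linear-interpolation convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR filtering")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (v >= lo) & (v <= hi)
    return v[mask], mask


def auc_aggregate(values: Sequence[float], grid: DensityGrid) -> float:
    """Trapezoidal area under a metric-versus-density profile."""
    v = np.asarray(values, dtype=float)
    d = grid.as_array()
    if len(grid) < 2:
        raise ValueError("AUC undefined on a single-point grid")
    if v.size != d.size:
        raise ValueError(f"expected {d.size} values (one per density), got {v.size}")
    if np.any(np.isnan(v)):
        raise ValueError("missing values in the density profile")
    return float(np.trapezoid(v, d))


def _prepare(profiles: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(subjects, pd.DataFrame):
        subjects = pd.DataFrame([vars(s) for s in subjects])
    data = profiles.merge(
        subjects[["subject_id", "ga_birth"]], on="subject_id", how="left"
    )
    if data["ga_birth"].isna().any():
        missing = data.loc[data["ga_birth"].isna(), "subject_id"].unique()
        raise ValueError(f"GA missing for subject(s): {', '.join(missing)}")
    data = data[data["hemisphere"].isin(["L", "R"])].copy()
    data["hemi"] = (data["hemisphere"] == "R").astype(int)
    return data


def _fit_cell(cell: pd.DataFrame) -> dict:
    """Fit value ~ ga_c * hemi with a subject random intercept on one cell."""
    cell = cell.dropna(subset=["value"]).copy()
    # outlier removal per hemisphere before fitting
    keep_parts = []
    for _, part in cell.groupby("hemi"):
        if len(part) >= 4:
            _, mask = iqr_filter(part["value"].to_numpy())
            part = part[mask]
        keep_parts.append(part)
    cell = pd.concat(keep_parts, ignore_index=True)
    cell["ga_c"] = cell["ga_birth"] - cell["ga_birth"].mean()
    out = {
        "n_observations": len(cell),
        "n_subjects": cell["subject_id"].nunique(),
        "converged": False,
    }
    for t in TERMS:
        out[t] = (np.nan, np.nan, np.nan)
    if cell["subject_id"].nunique() < 3 or len(cell) < 8:
        out["note"] = "too few observations"
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ ga_c * hemi", cell, groups=cell["subject_id"]
            )
            fit = model.fit(reml=True)
        for t in TERMS:
            out[t] = (
                float(fit.params[t]),
                float(fit.bse[t]),
                float(fit.pvalues[t]),
            )
        out["converged"] = bool(fit.converged)
    except (np.linalg.LinAlgError, ValueError) as exc:  # singular fit
        out["note"] = f"singular fit: {exc}"
    return out


def _collect(
    fits: list[tuple[str, str, object, dict]]
) -> pd.DataFrame:
    rows = []
    for metric, modality, density, res in fits:
        for t in TERMS:
            est, se, p = res[t]
            rows.append(
                {
                    "metric": metric,
                    "modality": modality,
                    "density": density,
                    "term": t,
                    "estimate": est,
                    "se": se,
                    "p_raw": p,
                    "n_observations": res["n_observations"],
                    "n_subjects": res["n_subjects"],
                    "converged": res["converged"],
                }
            )
    table = pd.DataFrame(rows)
    # BH across densities within each (metric, modality, term) family
    table["p_adjusted"] = np.nan
    for _, idx in table.groupby(["metric", "modality", "term"]).groups.items():
        sub = table.loc[idx]
        ok = sub["p_raw"].notna()
        if ok.any():
            table.loc[sub.index[ok], "p_adjusted"] = bh_adjust(
                sub.loc[ok, "p_raw"].to_numpy()
            )
    return table


def fit_density_models(
    profiles: pd.DataFrame,
    subjects,
    max_density: float = 0.5,
) -> pd.DataFrame:
    """Per-density mixed models of metric values on GA and hemisphere.

    ``profiles`` is long-format with columns subject_id, modality,
    metric, hemisphere (L/R), density, value.  Undefined (NaN) values
    are excluded listwise.  Returns one row per (metric, modality,
    density, term).
    """
    data = _prepare(profiles, subjects)
    data = data[data["density"] <= max_density + 1e-9]
    if data.empty:
        raise ValueError("no densities at or below max_density")
    fits = []
    for (metric, modality, density), cell in data.groupby(
        ["metric", "modality", "density"]
    ):
        fits.append((metric, modality, float(density), _fit_cell(cell)))
    return _collect(fits)


def fit_auc_models(
    profiles: pd.DataFrame,
    subjects,
    grid: DensityGrid,
) -> pd.DataFrame:
    """Single mixed model per (metric, modality) on AUC-aggregated scores.

    AUC is computed per subject x hemisphere over the *full* grid (all
    densities, including those excluded from per-density models).
    """
    data = _prepare(profiles, subjects)
    rows = []
    for (sid, metric, modality, hemi_lab), part in data.groupby(
        ["subject_id", "metric", "modality", "hemisphere"]
    ):
        part = part.sort_values("density")
        auc = auc_aggregate(part["value"].to_numpy(), grid)
        rows.append(
            {
                "subject_id": sid,
                "metric": metric,
                "modality": modality,
                "hemisphere": hemi_lab,
                "value": auc,
                "ga_birth": part["ga_birth"].iloc[0],
                "hemi": int(hemi_lab == "R"),
            }
        )
    auc_data = pd.DataFrame(rows)
    fits = []
    for (metric, modality), cell in auc_data.groupby(["metric", "modality"]):
        fits.append((metric, modality, "AUC", _fit_cell(cell)))
    return _collect(fits)


def strength_ttest(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-tailed p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 scores")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
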