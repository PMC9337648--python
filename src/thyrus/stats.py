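"""Observer-agreement statistics for volumetry studies.

Implements the study's evaluation battery on a long-format table of total
volumes (volunteer × observer × repeat × modality):

* intraobserver variability — per-volunteer coefficient of variation of the
  repeats, summarized mean ± SD across volunteers (percent);
* pairwise interobserver agreement — Bland–Altman mean difference with
  ±1.96·SD limits of agreement plus a paired t-test per observer pair;
* reference comparison — each observer's first scan series against the
  per-volunteer reference volume (the MRI stand-in), paired t-test;
* the training/unseen group split used to check for segmentation bias.

Sample SDs use the n−1 denominator; each test is reported at α = 0.05 with
no multiple-testing correction, matching the clinical analysis convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

__all__ = [
    "BlandAltmanResult",
    "TTestResult",
    "intraobserver_variability",
    "bland_altman",
    "paired_t_test",
    "interobserver_table",
    "reference_comparison",
    "split_groups",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < ALPHA


def intraobserver_variability(volumes_per_volunteer: dict | pd.Series
                              ) -> tuple[float, float, pd.Series]:
    """Coefficient of variation of repeated measurements, per volunteer.

    For each volunteer with repeats x₁..xₖ (k ≥ 2):
    CV% = 100 · SD(x)/mean(x) (sample SD).  Returns (mean, SD) of the CVs
    across volunteers plus the per-volunteer series.
    """
    if isinstance(volumes_per_volunteer, pd.Series):
        grouped = volumes_per_volunteer.groupby(level=0)
        items = [(k, np.asarray(g, dtype=float)) for k, g in grouped]
    else:
        items = [(k, np.asarray(v, dtype=float)) for k, v in volumes_per_volunteer.items()]
    cvs = {}
    for key, vals in items:
        if vals.size < 2:
            raise ValueError(f"volunteer {key!r} has <2 repeats")
        cvs[key] = 100.0 * vals.std(ddof=1) / vals.mean()
    series = pd.Series(cvs, name="cv_percent")
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return float(series.mean()), sd, series


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired series: differences a−b, their
    mean and sample SD, and 95% limits of agreement mean ± 1.96·SD."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be paired 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, a.size)


def paired_t_test(series_a, series_b) -> TTestResult:
    """Two-sided paired t-test of mean difference zero.

    t = mean(d)/(SD(d)/√n) with d = a−b, df = n−1.  A zero-variance
    difference yields an explicit degenerate result (p = 1 if the mean
    difference is 0, else p = 0) rather than an error.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be paired 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0.0:
        return TTestResult(
            t=np.inf if mean != 0 else 0.0, df=n - 1,
            p=0.0 if mean != 0 else 1.0, mean_diff=mean, degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), mean)


def _first_series(study: pd.DataFrame, modality: str) -> pd.DataFrame:
    req = {"volunteer", "observer", "repeat", "modality", "volume_ml"}
    missing = req - set(study.columns)
    if missing:
        raise ValueError(f"study table lacks columns: {sorted(missing)}")
    sub = study[(study["modality"] == modality) & (study["repeat"] == study["repeat"].min())]
    return sub


def interobserver_table(study: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Pairwise interobserver agreement for one modality (first scan series).

    One row per observer pair "i/j": Bland–Altman mean ± SD of the paired
    differences, limits of agreement, and the paired t-test at α = 0.05.
    """
    sub = _first_series(study, modality)
    observers = sorted(sub["observer"].unique())
    if len(observers) < 2:
        raise ValueError("need at least 2 observers")
    pivot = sub.pivot_table(index="volunteer", columns="observer", values="volume_ml")
    if pivot.isna().any().any():
        raise ValueError("missing observer measurements for some volunteers")
    rows = []
    for i in range(len(observers)):
        for j in range(i + 1, len(observers)):
            a, b = observers[i], observers[j]
            ba = bland_altman(pivot[a].values, pivot[b].values)
            tt = paired_t_test(pivot[a].values, pivot[b].values)
            rows.append(
                {
                    "pair": f"{_short(a)}/{_short(b)}",
                    "modality": modality,
                    "mean_diff_ml": ba.mean_diff,
                    "sd_diff_ml": ba.sd_diff,
                    "loa_low_ml": ba.loa_low,
                    "loa_high_ml": ba.loa_high,
                    "n": ba.pairs,
                    "t": tt.t,
                    "df": tt.df,
                    "p": tt.p,
                    "significant": tt.significant,
                }
            )
    return pd.DataFrame(rows)


def _short(name: str) -> str:
    return name[2:] if name.startswith("MD") and len(name) > 2 else name


def reference_comparison(study: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Per observer: first-series volumes vs the per-volunteer reference.

    Reports mean ± SD of the observer's volumes and a paired t-test against
    the reference (MRI stand-in) at α = 0.05.
    """
    if "reference_ml" not in study.columns:
        raise ValueError("study table lacks a reference_ml column")
    sub = _first_series(study, modality)
    rows = []
    for obs, g in sub.groupby("observer"):
        g = g.sort_values("volunteer")
        vols = g["volume_ml"].values
        ref = g["reference_ml"].values
        tt = paired_t_test(vols, ref)
        rows.append(
            {
                "observer": obs,
                "modality": modality,
                "mean_ml": float(vols.mean()),
                "sd_ml": float(vols.std(ddof=1)) if vols.size > 1 else 0.0,
                "mean_ref_ml": float(ref.mean()),
                "mean_diff_ml": tt.mean_diff,
                "n": int(vols.size),
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "significant": tt.significant,
                "degenerate": tt.degenerate,
            }
        )
    return pd.DataFrame(rows)


def split_groups(study: pd.DataFrame, training_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the study by whether the volunteer contributed training data
    (group 1 = seen during training, group 2 = unseen)."""
    ids = set(training_ids)
    known = set(study["volunteer"].unique())
    unknown = ids - known
    if unknown:
        raise ValueError(f"unknown volunteer ids: {sorted(unknown)}")
    in_g1 = study["volunteer"].isin(ids)
    return study[in_g1].copy(), study[~in_g1].copy()
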