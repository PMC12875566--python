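"""Statistical summaries of step-level MoS.

Three analyses mirror the usual reporting of trip-perturbation studies:

* per-step-label medians with interquartile range and means with
  t-based 95% confidence intervals (:func:`summarize_steps`);
* two-sided paired Wilcoxon signed-rank tests between step classes
  (:func:`paired_wilcoxon`), with an exact tie-aware null distribution
  for small samples and a normal approximation with tie correction for
  large ones;
* an exploratory OLS regression of MoS on risk-tertile indicators per
  condition x step label (:func:`condition_regression`).

Pairing unit for step comparisons: each perturbation event contributes
one pair (e.g. its pre-perturbation MoS vs its perturbed MoS), pooled
across participants; a participant-median pairing mode is available.
Zero differences are dropped (Wilcoxon's original rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StepSummary",
    "PairedTestResult",
    "summarize_steps",
    "paired_wilcoxon",
    "condition_regression",
    "build_step_pairs",
]

#: exact signed-rank enumeration is used up to this many non-zero pairs
EXACT_LIMIT = 25


@dataclass
class StepSummary:
    group: tuple
    step_label: str
    n: int
    median: float
    iqr_low: float
    iqr_high: float
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class PairedTestResult:
    label_a: str
    label_b: str
    n_pairs: int  # non-zero differences
    statistic: float  # signed-rank sum W+ (ranks of positive differences)
    p_value: float
    method: str  # exact | normal-approx


def summarize_steps(
    mos: pd.DataFrame, group_by: tuple[str, ...] = ("label",)
) -> pd.DataFrame:
    """Median/IQR and mean with t-based 95% CI per group.

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Groups with a single value get a degenerate CI
    flagged by ``ci_low == ci_high == mean``; empty groups are omitted
    with a warning.
    """

    mos = mos[mos["valid"]] if "valid" in mos.columns else mos
    rows = []
    for key, sub in mos.groupby(list(group_by), sort=False, dropna=False):
        values = sub["mos"].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            warnings.warn(f"group {key}: no valid MoS values; omitted")
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        mean = float(values.mean())
        if values.size > 1:
            sem = values.std(ddof=1) / np.sqrt(values.size)
            tcrit = stats.t.ppf(0.975, values.size - 1)
            ci_low, ci_high = mean - tcrit * sem, mean + tcrit * sem
        else:
            ci_low = ci_high = mean
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_by, key_t))
            | {
                "n": values.size,
                "median": float(med),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "mean": mean,
                "ci_low": float(ci_low),
                "ci_high": float(ci_high),
            }
        )
    return pd.DataFrame(rows)


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, float]:
    """Average ranks of |d| (zeros removed) and the W+ statistic."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    return ranks, w_plus


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, tie-aware.

    The null distribution of W+ given the (possibly tied, average)
    ranks is built by dynamic programming over doubled ranks, which are
    integers.  Two-sided p = P(|W - mu| >= |w_obs - mu|), equivalent to
    twice the smaller tail for this symmetric distribution.
    """

    r2 = np.round(ranks * 2).astype(int)  # average ranks doubled -> integers
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    p = counts[np.abs(support - mu) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def paired_wilcoxon(
    pairs: np.ndarray | list[tuple[float, float]],
    label_a: str = "a",
    label_b: str = "b",
    force_method: str | None = None,
) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test on (a, b) pairs.

    Differences ``a - b`` equal to zero are dropped.  The exact null is
    enumerated for up to 25 non-zero pairs; beyond that a normal
    approximation with tie correction is used.  ``force_method`` (for
    cross-checks) can be ``"exact"`` or ``"normal"``.
    """

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    diffs = arr[:, 0] - arr[:, 1]
    if not np.all(np.isfinite(diffs)):
        raise ValueError("pairs must be finite")
    ranks, w_plus = _signed_ranks(diffs)
    n = len(ranks)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    method = force_method or ("exact" if n <= EXACT_LIMIT else "normal")
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
        method_name = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # variance with tie correction: sum(r^2)/4 over the actual ranks
        sigma2 = float(np.sum(ranks**2)) / 4.0
        if sigma2 == 0:
            raise ValueError("zero variance in signed ranks")
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method_name = "normal-approx"
    return PairedTestResult(label_a, label_b, n, w_plus, min(1.0, p), method_name)


def build_step_pairs(
    mos: pd.DataFrame,
    label_a: str,
    label_b: str,
    unit: str = "perturbation",
) -> np.ndarray:
    """Assemble (a, b) MoS pairs for a step-class comparison.

    ``unit="perturbation"`` pairs the two labels within each
    perturbation window (participant, condition, perturbation id),
    pooled across participants; ``unit="participant"`` pairs
    per-participant medians of each label.
    """

    mos = mos[mos["valid"]] if "valid" in mos.columns else mos
    if unit == "perturbation":
        key_cols = ["participant_id", "condition", "window_id"]
        a = mos[mos["label"] == label_a].set_index(key_cols)["mos"]
        b = mos[mos["label"] == label_b].set_index(key_cols)["mos"]
        joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"])
        return joined.to_numpy()
    if unit == "participant":
        med = (
            mos[mos["label"].isin([label_a, label_b])]
            .groupby(["participant_id", "label"])["mos"]
            .median()
            .unstack("label")
            .dropna()
        )
        return med[[label_a, label_b]].to_numpy()
    raise ValueError(f"unknown pairing unit {unit!r}")


def condition_regression(
    mos: pd.DataFrame,
    profiles,
    covariate: str = "tertile",
) -> pd.DataFrame:
    """Exploratory OLS of MoS per condition x step label.

    ``covariate="tertile"`` regresses on tertile indicators with the
    low tertile as reference; ``covariate="risk_score"`` uses the
    continuous score.  Returns coefficients and standard errors; a
    rank-deficient design (a tertile absent from a cell) raises an
    error naming the missing group.
    """

    mos = mos[mos["valid"]] if "valid" in mos.columns else mos
    prof = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "tertile": [p.tertile for p in profiles],
            "risk_score": [p.risk_score for p in profiles],
        }
    )
    data = mos.merge(prof, on="participant_id", how="left")
    if data["tertile"].isna().any():
        missing = sorted(data.loc[data["tertile"].isna(), "participant_id"].unique())
        raise ValueError(f"no risk profile for participant(s) {missing}")
    rows = []
    for (condition, label), cell in data.groupby(["condition", "label"], sort=False):
        if covariate == "tertile":
            present = cell["tertile"].unique()
            if len(present) < 2:
                raise ValueError(
                    f"rank-deficient design in ({condition}, {label}): only "
                    f"tertile(s) {sorted(present)} present"
                )
            x = pd.get_dummies(
                pd.Categorical(cell["tertile"], categories=["low", "mid", "high"]),
                drop_first=True,
                dtype=float,
            )
            x = x.loc[:, x.sum() > 0]  # drop absent groups already validated >=2
            x.columns = [f"tertile_{c}" for c in x.columns]
        elif covariate == "risk_score":
            x = cell[["risk_score"]].astype(float)
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        x = sm.add_constant(x.reset_index(drop=True))
        fit = sm.OLS(cell["mos"].reset_index(drop=True), x).fit()
        for name, coef, se in zip(fit.params.index, fit.params, fit.bse):
            rows.append(
                {
                    "condition": condition,
                    "step_label": label,
                    "term": name,
                    "coef": float(coef),
                    "se": float(se),
                    "n": int(len(cell)),
                }
            )
    return pd.DataFrame(rows)
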