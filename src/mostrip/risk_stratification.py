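"""Fall-risk tertiles, binary grouping variants, and ROC/AUC discrimination.

Participants are ranked by an externally supplied fall-risk score (a
FRAT-style percentage, treated as an opaque input) and split into
tertiles.  Three binary regroupings are analysed:

* variant 1 — low tertile vs high tertile (middle excluded),
* variant 2 — low vs middle+high,
* variant 3 — low+middle vs high.

Discrimination of step-level MoS between the groups is quantified by
the area under the ROC curve, computed as the Mann–Whitney pairwise
statistic with ties counted one half, with the higher-risk group as the
positive class and MoS as the score, unflipped.  By default the ROC
observations are pooled step-level MoS values (every perturbation
repetition of a condition x step label), each labeled by its
participant's group; a participant-mean mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RiskProfile",
    "RocAnalysis",
    "assign_tertiles",
    "variant_labels",
    "roc_auc",
    "VARIANTS",
]

VARIANTS = (1, 2, 3)
TERTILE_NAMES = ("low", "mid", "high")


@dataclass(frozen=True)
class RiskProfile:
    participant_id: str
    risk_score: float
    tertile: str  # low | mid | high


@dataclass
class RocAnalysis:
    variant: int
    condition: str | None
    step_label: str | None
    auc: float
    n_pos: int
    n_neg: int
    curve: pd.DataFrame | None = None  # fpr, tpr, threshold


def assign_tertiles(scores: pd.DataFrame | dict) -> list[RiskProfile]:
    """Split participants into risk tertiles.

    Participants are ranked by score, ties broken by input order
    (stable sort), and ranks split as evenly as possible with any
    surplus going to the lower tertiles first — so 19 participants give
    sizes 7/6/6 (low/mid/high).
    """

    if isinstance(scores, dict):
        table = pd.DataFrame(
            {"participant_id": list(scores), "risk_score": list(scores.values())}
        )
    else:
        table = scores[["participant_id", "risk_score"]].copy()
    n = len(table)
    if n < 3:
        raise ValueError(f"tertile assignment needs at least 3 participants, got {n}")
    if not np.all(np.isfinite(table["risk_score"])):
        raise ValueError("risk scores must be finite")
    order = np.argsort(table["risk_score"].to_numpy(), kind="stable")
    base, surplus = divmod(n, 3)
    sizes = [base + (1 if i < surplus else 0) for i in range(3)]
    tertiles = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(TERTILE_NAMES, sizes):
        tertiles[order[start : start + size]] = name
        start += size
    return [
        RiskProfile(str(row.participant_id), float(row.risk_score), tertiles[i])
        for i, row in enumerate(table.itertuples(index=False))
    ]


def variant_labels(profiles: list[RiskProfile], variant: int) -> dict[str, str]:
    """Binary group per participant: positive / negative / excluded."""
    mapping = {
        1: {"low": "negative", "mid": "excluded", "high": "positive"},
        2: {"low": "negative", "mid": "positive", "high": "positive"},
        3: {"low": "negative", "mid": "negative", "high": "positive"},
    }
    if variant not in mapping:
        raise ValueError(f"unknown variant {variant!r}; expected 1, 2 or 3")
    return {p.participant_id: mapping[variant][p.tertile] for p in profiles}


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    variant: int | None = None,
    condition: str | None = None,
    step_label: str | None = None,
    with_curve: bool = True,
) -> RocAnalysis:
    """Mann–Whitney AUC of MoS scores for a binary grouping.

    ``labels`` is boolean (or 0/1) with True = positive (higher-risk)
    class.  The AUC equals the mean over all (positive, negative) pairs
    of 1 if the positive score is larger, 0.5 if equal, 0 otherwise;
    computed via average ranks, so it is exact with ties and invariant
    to input order.
    """

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes must be non-empty (n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = rankdata(scores, method="average")
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    curve = None
    if with_curve:
        fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
        curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocAnalysis(
        variant=variant if variant is not None else 0,
        condition=condition,
        step_label=step_label,
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
        curve=curve,
    )


def analyze_mos_table(
    mos: pd.DataFrame,
    profiles: list[RiskProfile],
    step_labels: tuple[str, ...] = ("perturbed", "recovery1", "recovery2"),
    pooling: str = "pooled",
) -> pd.DataFrame:
    """AUC per condition x step label x variant.

    ``mos`` is a tidy table with columns participant_id, condition,
    label, mos, valid.  Perturbed conditions are analysed at
    ``step_labels``; the unperturbed bout is analysed once over all its
    baseline steps.  ``pooling="pooled"`` scores every step;
    ``pooling="participant_mean"`` reduces each participant to their
    mean MoS first.
    """

    if pooling not in ("pooled", "participant_mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    mos = mos[mos["valid"]].copy()
    rows = []
    for variant in VARIANTS:
        groups = variant_labels(profiles, variant)
        mos_v = mos.assign(group=mos["participant_id"].map(groups))
        mos_v = mos_v[mos_v["group"] != "excluded"]
        for condition, sub in mos_v.groupby("condition", sort=False):
            labels_here = (
                ("baseline",) if (sub["label"] == "baseline").all() else step_labels
            )
            for lab in labels_here:
                cell = sub[sub["label"] == lab]
                if pooling == "participant_mean":
                    cell = (
                        cell.groupby(["participant_id", "group"], as_index=False)["mos"]
                        .mean()
                    )
                if cell.empty or cell["group"].nunique() < 2:
                    continue
                res = roc_auc(
                    cell["mos"].to_numpy(),
                    (cell["group"] == "positive").to_numpy(),
                    variant=variant,
                    condition=condition,
                    step_label=lab,
                    with_curve=False,
                )
                rows.append(
                    {
                        "variant": variant,
                        "condition": condition,
                        "step_label": lab,
                        "auc": res.auc,
                        "n_pos": res.n_pos,
                        "n_neg": res.n_neg,
                    }
                )
    return pd.DataFrame(rows)
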