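"""Transition and fixation-time statistics of a scanpath.

A *transition* is the move between two consecutively fixated locations,
categorised by the AOI roles at its endpoints: own-own, other-other,
intracell (own<->other within one matrix cell — comparing the two players'
payoffs for one outcome), cross (own<->other across cells), or out (either
endpoint outside every AOI).  The proportions of own, other and intracell
transitions are the regressors of the logistic baseline; fixation-time
aggregates and log response time feed the behavioural summaries and the
confidence-correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .render import OUT, AOILayout, assign_aoi
from .synth import ScanpathRecord

#: FeatureVector columns used as the logistic-baseline design matrix
BASELINE_COLUMNS = ("prop_trans_own", "prop_trans_other", "prop_trans_intracell")

FEATURE_COLUMNS = (
    "prop_trans_own",
    "prop_trans_other",
    "prop_trans_intracell",
    "prop_trans_cross",
    "prop_trans_out",
    "prop_fix_own",
    "prop_fix_other",
    "fixtime_own",
    "fixtime_other",
    "log_rt",
)


@dataclass(frozen=True)
class FeatureVector:
    prop_trans_own: float
    prop_trans_other: float
    prop_trans_intracell: float
    prop_trans_cross: float
    prop_trans_out: float
    prop_fix_own: float
    prop_fix_other: float
    fixtime_own: float  # ms
    fixtime_other: float  # ms
    log_rt: float  # ln(ms)
    has_transitions: bool = True

    def as_array(self, columns=FEATURE_COLUMNS) -> np.ndarray:
        return np.array([getattr(self, c) for c in columns], dtype=float)


def classify_transition(a: str, b: str, layout: AOILayout) -> str:
    """Category of the move from AOI ``a`` to AOI ``b`` (ids or OUT)."""
    if a == OUT or b == OUT:
        return "out"
    ra, rb = layout.by_id(a), layout.by_id(b)
    if ra.role == "own" and rb.role == "own":
        return "own"
    if ra.role == "other" and rb.role == "other":
        return "other"
    return "intracell" if ra.cell == rb.cell else "cross"


def extract_features(record: ScanpathRecord, layout: AOILayout) -> FeatureVector:
    """Per-trial feature vector from consecutive-fixation AOI assignments.

    Transitions are taken between consecutive *fixations* (not recorded
    saccade endpoints); a record with fewer than two fixations yields zero
    proportions with ``has_transitions`` cleared.
    """
    aois = [assign_aoi(f.x, f.y, layout) for f in record.fixations]
    counts = {"own": 0, "other": 0, "intracell": 0, "cross": 0, "out": 0}
    for a, b in zip(aois, aois[1:]):
        counts[classify_transition(a, b, layout)] += 1
    total = sum(counts.values())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}

    fixtime = {"own": 0.0, "other": 0.0}
    n_fix_role = {"own": 0, "other": 0}
    for f, aid in zip(record.fixations, aois):
        if aid != OUT:
            role = layout.by_id(aid).role
            fixtime[role] += f.end - f.start
            n_fix_role[role] += 1
    n_fix = len(record.fixations)

    return FeatureVector(
        prop_trans_own=props["own"],
        prop_trans_other=props["other"],
        prop_trans_intracell=props["intracell"],
        prop_trans_cross=props["cross"],
        prop_trans_out=props["out"],
        prop_fix_own=n_fix_role["own"] / n_fix if n_fix else 0.0,
        prop_fix_other=n_fix_role["other"] / n_fix if n_fix else 0.0,
        fixtime_own=fixtime["own"],
        fixtime_other=fixtime["other"],
        log_rt=math.log(record.rt) if record.rt > 0 else 0.0,
        has_transitions=total > 0,
    )


def features_frame(records: list[ScanpathRecord], layout: AOILayout) -> pd.DataFrame:
    """One row per record: identifiers, label, rt and all feature columns."""
    rows = []
    for rec in records:
        fv = extract_features(rec, layout)
        row = {
            "participant_id": rec.participant_id,
            "game_id": rec.game_id,
            "chosen": rec.chosen,
            "label": rec.label.value if rec.label is not None else None,
            "rt_ms": rec.rt,
            "has_transitions": fv.has_transitions,
        }
        row.update({c: getattr(fv, c) for c in FEATURE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_strategy(records: list[ScanpathRecord], layout: AOILayout) -> pd.DataFrame:
    """Behavioural summary grouped by strategy label.

    Returns one row per strategy with the share of trials, mean/SD response
    time, mean transition proportions and mean fixation times — the shape
    of the study's behavioural results.  Unlabelled records are ignored
    with a warning.
    """
    import warnings

    df = features_frame(records, layout)
    if df["label"].isna().any():
        warnings.warn("dropping records without a strategy label", stacklevel=2)
        df = df.dropna(subset=["label"])
    if df.empty:
        raise ValueError("no labelled records to summarise")
    out = df.groupby("label").agg(
        n=("label", "size"),
        mean_rt_ms=("rt_ms", "mean"),
        sd_rt_ms=("rt_ms", "std"),
        prop_trans_own=("prop_trans_own", "mean"),
        prop_trans_other=("prop_trans_other", "mean"),
        prop_trans_intracell=("prop_trans_intracell", "mean"),
        fixtime_own=("fixtime_own", "mean"),
        fixtime_other=("fixtime_other", "mean"),
    )
    out["share"] = out["n"] / out["n"].sum()
    return out
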