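"""Behavioral scoring for the mnemonic similarity task.

Quality control follows the standard protocol for this task: trials with
responses faster than 300 ms or slower than 3 s are dropped first;
participants are then excluded if more than 20% of their test trials have
no response, if their lure discrimination index is below 0, or if their
recognition score is below 0.5. For longitudinal tables the performance
thresholds are applied on the immediate session only.

Indices (computed over non-missing responses):

    LDI         = p("similar" | lure)  - p("similar" | foil)
    recognition = p("old" | repeat)    - p("old" | foil)
    lure FA     = p("old" | lure)      - p("old" | foil)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ValidationError, validate_trial_table


class AggregationError(ValueError):
    """Bin-level aggregation is missing required inputs."""


@dataclass
class QCThresholds:
    """Trial- and participant-level exclusion rules."""

    rt_min: float = 0.3          # s; strictly faster excluded
    rt_max: float = 3.0          # s; strictly slower excluded
    max_missing: float = 0.2     # fraction of test trials without a response
    min_ldi: float = 0.0
    min_recognition: float = 0.5
    # count trial-QC removals as misses in addition to true non-responses
    count_rt_excluded_as_missing: bool = False


def apply_qc(
    table: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply trial-level then participant-level quality control.

    Returns the retained table plus a report listing every exclusion with
    the rule that triggered it. Participant filters are evaluated on the
    post-trial-QC data; for tables with a delayed session the performance
    thresholds are checked on the immediate session only. Idempotent.
    """
    thr = thresholds or QCThresholds()
    validate_trial_table(table)
    report: list[dict] = []

    responded = table["response"].notna()
    fast = responded & (table["rt"] < thr.rt_min)
    slow = responded & (table["rt"] > thr.rt_max)
    for idx in table.index[fast | slow]:
        rule = "rt_too_fast" if fast.loc[idx] else "rt_too_slow"
        report.append({"level": "trial", "index": int(idx), "rule": rule,
                       "participant": table.loc[idx, "participant"]})
    kept = table.loc[~(fast | slow)].copy()

    excluded_participants = set()
    for pid, sub in kept[kept["phase"] == "test"].groupby("participant"):
        n_rt_removed = int(((fast | slow) & (table["participant"] == pid)
                            & (table["phase"] == "test")).sum())
        n_missing = int(sub["response"].isna().sum())
        denom = len(sub) + n_rt_removed
        if thr.count_rt_excluded_as_missing:
            n_missing += n_rt_removed
        if denom and n_missing / denom > thr.max_missing:
            excluded_participants.add(pid)
            report.append({"level": "participant", "participant": pid,
                           "rule": "missing_rate", "value": n_missing / denom})
            continue
        perf = sub[sub["session"] == "immediate"] if (sub["session"] == "delayed").any() else sub
        metrics = _indices(perf)
        if not np.isnan(metrics["ldi"]) and metrics["ldi"] < thr.min_ldi:
            excluded_participants.add(pid)
            report.append({"level": "participant", "participant": pid,
                           "rule": "min_ldi", "value": metrics["ldi"]})
        elif not np.isnan(metrics["recognition"]) and metrics["recognition"] < thr.min_recognition:
            excluded_participants.add(pid)
            report.append({"level": "participant", "participant": pid,
                           "rule": "min_recognition", "value": metrics["recognition"]})
    kept = kept.loc[~kept["participant"].isin(excluded_participants)].copy()
    return kept, report


def _p(sub: pd.DataFrame, response: str, condition: str) -> float:
    """p(response | condition) over non-missing responses; NaN if no trials."""
    rows = sub[(sub["condition"] == condition) & sub["response"].notna()]
    if len(rows) == 0:
        return float("nan")
    return float((rows["response"] == response).mean())


def _indices(sub: pd.DataFrame) -> dict[str, float]:
    p_sim_foil = _p(sub, "similar", "foil")
    p_old_foil = _p(sub, "old", "foil")
    return {
        "ldi": _p(sub, "similar", "lure") - p_sim_foil,
        "recognition": _p(sub, "old", "repeat") - p_old_foil,
        "lure_fa": _p(sub, "old", "lure") - p_old_foil,
    }


@dataclass
class BehaviorSummary:
    """Per-participant (x session) indices and diagnostics."""

    table: pd.DataFrame                       # one row per participant x session
    probabilities: pd.DataFrame               # p(response | condition) long format
    undefined: list[dict] = field(default_factory=list)


def compute_metrics(table: pd.DataFrame) -> BehaviorSummary:
    """LDI, recognition and lure false alarms per participant and session.

    Probabilities condition on a response having been made. Conditions with
    no trials yield NaN indices and are listed in ``undefined`` rather than
    silently scored 0. Per-bin LDI and lure-FA columns (``ldi_bin{b}``,
    ``lure_fa_bin{b}``) use the lure trials of each bin against the overall
    foil rates.
    """
    validate_trial_table(table)
    test = table[table["phase"] == "test"]
    if len(test) == 0:
        raise ValidationError("no test-phase rows")
    rows, probs, undefined = [], [], []
    for (pid, session), sub in test.groupby(["participant", "session"]):
        rec = {"participant": pid, "session": session}
        rec.update(_indices(sub))
        for name, value in list(rec.items())[2:]:
            if np.isnan(value):
                undefined.append({"participant": pid, "session": session, "metric": name})
        for cond in ("repeat", "lure", "foil", "first"):
            for resp in ("old", "similar", "new"):
                p = _p(sub, resp, cond)
                if not np.isnan(p):
                    probs.append({"participant": pid, "session": session,
                                  "condition": cond, "response": resp, "p": p})
        p_sim_foil = _p(sub, "similar", "foil")
        p_old_foil = _p(sub, "old", "foil")
        bins = sorted(int(b) for b in sub["lure_bin"].dropna().unique())
        for b in bins:
            lure_b = sub[(sub["condition"] == "lure") & (sub["lure_bin"] == b)]
            if lure_b["response"].notna().any():
                resp = lure_b.loc[lure_b["response"].notna(), "response"]
                rec[f"ldi_bin{b}"] = float((resp == "similar").mean()) - p_sim_foil
                rec[f"lure_fa_bin{b}"] = float((resp == "old").mean()) - p_old_foil
        rec["n_trials"] = len(sub)
        rec["n_missing"] = int(sub["response"].isna().sum())
        rec["age"] = float(sub["age"].iloc[0])
        rows.append(rec)
    return BehaviorSummary(
        table=pd.DataFrame(rows), probabilities=pd.DataFrame(probs), undefined=undefined
    )


def bin_and_aggregate(
    tables: pd.DataFrame | list[pd.DataFrame],
    lossiness: dict[str, float],
    n_bins: int = 5,
) -> pd.DataFrame:
    """Bin-level table joining behavior to per-item lossiness.

    One row per participant x session x lure bin with the bin's LDI and
    lure false-alarm rate, the mean lossiness of the lure items shown in
    that bin, and the participant's age -- the input shape for the mixed
    model and GAM. Bin labels are taken from the trial table (they come
    from an independent normative sample, not computed here).
    """
    if isinstance(tables, list):
        tables = pd.concat(tables, ignore_index=True)
    validate_trial_table(tables)
    test = tables[tables["phase"] == "test"]
    lure_items = test.loc[test["condition"] == "lure", "stimulus"].unique()
    missing = sorted(set(lure_items) - set(lossiness))
    if missing:
        raise AggregationError(f"items missing from lossiness map: {missing}")

    rows = []
    for (pid, session), sub in test.groupby(["participant", "session"]):
        p_sim_foil = _p(sub, "similar", "foil")
        p_old_foil = _p(sub, "old", "foil")
        bins = sorted(int(b) for b in sub["lure_bin"].dropna().unique())
        for b in bins:
            if b > n_bins:
                continue
            lure_b = sub[(sub["condition"] == "lure") & (sub["lure_bin"] == b)]
            resp = lure_b.loc[lure_b["response"].notna(), "response"]
            if len(resp) == 0:
                continue
            items = lure_b["stimulus"].unique()
            rows.append({
                "participant": pid,
                "session": session,
                "bin": b,
                "ldi": float((resp == "similar").mean()) - p_sim_foil,
                "lure_fa": float((resp == "old").mean()) - p_old_foil,
                "lossiness": float(np.mean([lossiness[i] for i in items])),
                "age": float(sub["age"].iloc[0]),
                "n_lure_trials": int(len(resp)),
            })
    return pd.DataFrame(rows)
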