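"""Consensus candidate selection: dock-score gate against the control
compound, rank-threshold consensus voting, and top-k selection.

Voting rule: among the candidates (control excluded), the three highest
scorers per metric receive that metric's vote weight — 1 for dock score,
SVM and MLR, 2 for the Bayesian-network prediction.  Ties spanning rank 3
are inclusive: every tied candidate receives the vote, which keeps the
outcome independent of input order.  Candidates are then ranked by vote
sum, with dock score and finally name as deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

log = logging.getLogger(__name__)

#: metric name -> vote weight awarded to its top-3
VOTE_WEIGHTS = {"dock": 1, "svm": 1, "mlr": 1, "bn": 2}


@dataclass
class CandidateRecord:
    """One screening-table row: predictions, dock score, votes."""

    name: str
    svm_pred: float
    mlr_pred: float
    bn_pred: float
    dock_score: float
    is_control: bool = False
    votes: dict[str, int] = field(default_factory=dict)

    @property
    def vote_sum(self) -> int:
        return sum(self.votes.values())

    def metric(self, key: str) -> float:
        return {"svm": self.svm_pred, "mlr": self.mlr_pred,
                "bn": self.bn_pred, "dock": self.dock_score}[key]


def read_score_table(path) -> list[CandidateRecord]:
    """CSV columns: name, svm, mlr, bn, dock, is_control (0/1)."""
    df = pd.read_csv(path)
    return [
        CandidateRecord(
            name=row["name"], svm_pred=float(row["svm"]),
            mlr_pred=float(row["mlr"]), bn_pred=float(row["bn"]),
            dock_score=float(row["dock"]),
            is_control=bool(int(row.get("is_control", 0))),
        )
        for _, row in df.iterrows()
    ]


def write_score_table(records: list[CandidateRecord], path) -> None:
    rows = []
    for r in records:
        row = {"name": r.name, "svm": r.svm_pred, "mlr": r.mlr_pred,
               "bn": r.bn_pred, "dock": r.dock_score,
               "is_control": int(r.is_control)}
        if r.votes:
            for k in VOTE_WEIGHTS:
                row[f"vote_{k}"] = r.votes.get(k, 0)
            row["vote_sum"] = r.vote_sum
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def bundled_score_table() -> list[CandidateRecord]:
    """The packaged FKBP52 screening table (ten candidates + control)."""
    with resources.as_file(
        resources.files("fkbpscreen.data").joinpath("table1_scores.csv")
    ) as p:
        return read_score_table(p)


def dock_gate(candidates: list[CandidateRecord],
              control: CandidateRecord) -> list[CandidateRecord]:
    """Keep candidates whose dock score is at least the control's
    (strictly lower scores are eliminated); order preserved."""
    kept = [c for c in candidates if c.dock_score >= control.dock_score]
    if not kept:
        log.warning("dock gate eliminated every candidate")
    return kept


def consensus_vote(candidates: list[CandidateRecord],
                   top_n: int = 3) -> list[CandidateRecord]:
    """Fill ``votes`` and thereby ``vote_sum`` on each candidate.

    Per metric the top ``top_n`` scorers (descending) get the metric's
    weight; a tie at the cut-off rank extends the award to all tied
    candidates.  With fewer than ``top_n`` candidates everyone gets every
    vote.
    """
    if any(c.is_control for c in candidates):
        raise ValueError("exclude the control before voting")
    for c in candidates:
        c.votes = {}
    if not candidates:
        return candidates
    few = len(candidates) <= top_n
    if few and len(candidates) < top_n:
        log.warning("fewer than %d candidates: all receive every vote", top_n)
    for key, weight in VOTE_WEIGHTS.items():
        values = sorted((c.metric(key) for c in candidates), reverse=True)
        threshold = values[min(top_n, len(values)) - 1]
        for c in candidates:
            c.votes[key] = weight if c.metric(key) >= threshold else 0
    return candidates


def select_candidates(candidates: list[CandidateRecord],
                      k: int = 3) -> list[CandidateRecord]:
    """Top-k by vote sum, tie-broken by dock score (descending) then
    name (ascending)."""
    if any(not c.votes for c in candidates):
        raise ValueError("votes not computed; run consensus_vote first")
    if k > len(candidates):
        log.warning("k=%d exceeds %d candidates; returning all", k,
                    len(candidates))
    ranked = sorted(candidates,
                    key=lambda c: (-c.vote_sum, -c.dock_score, c.name))
    return ranked[:k]


def run_screen(records: list[CandidateRecord], k: int = 3,
               apply_gate: bool = True,
               control_name: Optional[str] = None) -> dict:
    """End-to-end: split off the control, optionally gate, vote, select.

    Returns a dict with the voted candidate list (original order), the
    ranked selection, and the control record.
    """
    if control_name is not None:
        controls = [c for c in records if c.name == control_name]
    else:
        controls = [c for c in records if c.is_control]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control, found {len(controls)}")
    control = controls[0]
    candidates = [c for c in records if c is not control]
    if apply_gate:
        candidates = dock_gate(candidates, control)
    consensus_vote(candidates)
    return {
        "control": control,
        "candidates": candidates,
        "selected": select_candidates(candidates, k=k),
    }
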