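"""Behavioral scoring: DMS percent correct and subsequent-memory accuracy."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouplevel import RATING_ORDER

__all__ = ["SmtScore", "dms_accuracy", "smt_score", "OLD_RATINGS"]

logger = logging.getLogger(__name__)

#: Ratings counted as an "old" endorsement (low/high confidence old, plus R).
OLD_RATINGS = frozenset({"3", "4", "R"})


@dataclass
class SmtScore:
    """Subsequent-memory test score.

    ``corrected_accuracy`` is the true-positive proportion minus the
    false-positive proportion (chance level 0).
    """

    true_positive_rate: float
    false_positive_rate: float
    corrected_accuracy: float
    response_distribution: pd.DataFrame
    n_old: int
    n_lures: int


def dms_accuracy(trials: pd.DataFrame) -> dict[str, float]:
    """Percent correct on the delayed match-to-sample task.

    A trial is correct when (match and "yes") or (nonmatch and "no").
    Missing responses are excluded (and counted).

    Returns
    -------
    dict with keys ``overall``, ``match``, ``nonmatch`` (percent) and
    ``n_missing``, ``n_scored``.
    """
    resp = trials["dms_response"]
    missing = resp.isna() | ~resp.astype(str).isin(["yes", "no"])
    if missing.any():
        logger.warning("excluding %d trials with missing DMS responses", missing.sum())
    scored = trials[~missing]
    is_match = scored["condition"].astype(str) == "match"
    said_yes = scored["dms_response"].astype(str) == "yes"
    correct = np.where(is_match, said_yes, ~said_yes)

    def pct(mask):
        return float(100.0 * correct[mask].mean()) if mask.any() else float("nan")

    return {
        "overall": float(100.0 * correct.mean()) if len(scored) else float("nan"),
        "match": pct(is_match.to_numpy()),
        "nonmatch": pct(~is_match.to_numpy()),
        "n_missing": int(missing.sum()),
        "n_scored": int(len(scored)),
    }


def smt_score(
    trials: pd.DataFrame,
    lures: pd.DataFrame,
    correct_trials_only: bool = True,
) -> SmtScore:
    """Score the subsequent-memory test.

    Old items are the studied trials (restricted to correct DMS trials when
    ``correct_trials_only``); an item is endorsed old when its rating is in
    {3, 4, R}.  Corrected accuracy = TPR - FPR.
    """
    old = trials
    if correct_trials_only:
        old = trials[trials["dms_correct"].astype(bool)]
    if len(old) == 0:
        raise ValueError("no old items to score")
    if len(lures) == 0:
        raise ValueError("no lure items to score")
    old_ratings = old["smt_rating"].astype(str)
    lure_ratings = lures["smt_rating"].astype(str)
    tpr = float(old_ratings.isin(OLD_RATINGS).mean())
    fpr = float(lure_ratings.isin(OLD_RATINGS).mean())
    dist = pd.DataFrame(
        {
            "rating": list(RATING_ORDER),
            "old": [int((old_ratings == r).sum()) for r in RATING_ORDER],
            "lure": [int((lure_ratings == r).sum()) for r in RATING_ORDER],
        }
    )
    return SmtScore(
        true_positive_rate=tpr,
        false_positive_rate=fpr,
        corrected_accuracy=tpr - fpr,
        response_distribution=dist,
        n_old=int(len(old)),
        n_lures=int(len(lures)),
    )
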