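"""Decile stratification, intersection/union fusion and quantile hit rates.

Predictions and ground truth are each stratified into deciles of their
own distribution (rank 1 = largest value = strongest promoter; decile
d = ceil(10 * rank / N); ties broken by stable input order).  The
*top-m set* of a ranking is every item with decile <= m.  The *quantile
hit rate* (QHR) of a candidate set against truth is the percentage of
candidates whose true strength falls in the top m_true deciles of the
truth distribution.

Fusing two predictors means intersecting (or uniting) their top-m sets:
the intersection trades coverage for precision, which is the mechanism
that narrows an experimental validation campaign to a small
high-confidence candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["assign_deciles", "top_set", "quantile_hit_rate", "QHRReport",
           "fuse_and_report"]


def assign_deciles(values: pd.Series, n_quantiles: int = 10) -> pd.DataFrame:
    """Rank values descending and assign quantile bins 1..n_quantiles.

    Returns a frame indexed by item id with columns ``value``, ``rank``
    (1 = largest) and ``decile`` = ceil(n_quantiles * rank / N).  Equal
    values keep their input order (stable ties).
    """
    if len(values) == 0:
        raise ValueError("cannot stratify an empty vector")
    vals = np.asarray(values, dtype=np.float64)
    if np.isnan(vals).any():
        raise ValueError("NaN values cannot be ranked")
    order = np.argsort(-vals, kind="stable")
    rank = np.empty(len(vals), dtype=np.int64)
    rank[order] = np.arange(1, len(vals) + 1)
    decile = np.ceil(n_quantiles * rank / len(vals)).astype(np.int64)
    return pd.DataFrame({"value": vals, "rank": rank, "decile": decile},
                        index=values.index)


def top_set(assignment: pd.DataFrame, m: int) -> set:
    """Ids whose decile is <= m (m in 1..n_quantiles)."""
    if not 1 <= m <= 10:
        raise ValueError(f"m must be in 1..10, got {m}")
    return set(assignment.index[assignment["decile"] <= m])


def quantile_hit_rate(candidate_ids, truth_assignment: pd.DataFrame, m_true: int) -> float:
    """Percentage of candidates whose truth decile is <= m_true."""
    candidates = list(candidate_ids)
    if not candidates:
        raise ValueError("hit rate of an empty candidate set is undefined")
    deciles = truth_assignment.loc[candidates, "decile"]
    return 100.0 * float((deciles <= m_true).sum()) / len(candidates)


@dataclass
class QHRReport:
    """Hit-rate table plus the candidate-reduction accounting.

    ``rates``: long-format rows (m_pred, m_true, set, candidates, hits,
    rate_pct) for set in {model1, model2, intersection, union}; the rate
    of an empty candidate set is NaN ("undefined"), never 0.
    ``counts``: per m_pred, the pool decomposition — |S1|, |S2|, |∩|,
    |∪|, the non-intersection count, hits within the intersection broken
    out by exact truth decile, and non-hits within the intersection.
    """

    rates: pd.DataFrame
    counts: pd.DataFrame


def fuse_and_report(
    pred1: pd.Series,
    pred2: pd.Series,
    truth: pd.Series,
    m_pred_list: tuple[int, ...] = (2, 3, 4, 5),
    m_true_list: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_quantiles: int = 10,
) -> QHRReport:
    """Stratify both predictions and the truth, fuse top sets, score QHR."""
    ids = set(pred1.index)
    if ids != set(pred2.index) or ids != set(truth.index):
        raise ValueError("pred1, pred2 and truth must cover the same item ids")
    a1 = assign_deciles(pred1, n_quantiles)
    a2 = assign_deciles(pred2, n_quantiles)
    at = assign_deciles(truth, n_quantiles)

    rate_rows, count_rows = [], []
    max_true = max(m_true_list)
    for m in m_pred_list:
        s1, s2 = top_set(a1, m), top_set(a2, m)
        inter, union = s1 & s2, s1 | s2
        for label, cset in (("model1", s1), ("model2", s2),
                            ("intersection", inter), ("union", union)):
            for mt in m_true_list:
                if cset:
                    hits = int((at.loc[sorted(cset), "decile"] <= mt).sum())
                    rate = 100.0 * hits / len(cset)
                else:
                    hits, rate = 0, np.nan
                rate_rows.append({"m_pred": m, "m_true": mt, "set": label,
                                  "candidates": len(cset), "hits": hits,
                                  "rate_pct": rate})
        inter_deciles = at.loc[sorted(inter), "decile"] if inter else pd.Series(dtype=int)
        per_decile = {f"hits_d{d}": int((inter_deciles == d).sum())
                      for d in range(1, max_true + 1)}
        non_hits = int((inter_deciles > max_true).sum())
        count_rows.append({"m_pred": m, "model1": len(s1), "model2": len(s2),
                           "intersection": len(inter), "union": len(union),
                           "non_intersection": len(union) - len(inter),
                           **per_decile, "non_hits_in_intersection": non_hits})
    return QHRReport(rates=pd.DataFrame(rate_rows), counts=pd.DataFrame(count_rows))
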