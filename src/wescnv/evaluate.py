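"""Scoring detected CNVs against planted truth.

A detected non-normal segment is a true positive when it overlaps at
least 50% of a planted altered region (denominator: the truth region's
exon count) and its direction (loss vs gain) matches; it is a false
positive when it overlaps no truth region at all.  Calls whose overlap
falls strictly between 0 and 50% fit neither definition and are reported
separately as "partial".  For every true positive, the distance (in
exons) between each predicted breakpoint and the matching true
breakpoint is recorded; a breakpoint is "exact" at distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOSS_STATES = {"two_copy_deletion", "one_copy_deletion"}
GAIN_STATES = {"one_copy_duplication", "multi_copy_amplification"}
SMALL_FP_EXONS = 5


@dataclass
class Metrics:
    """Accuracy summary for one chromosome (or one batch)."""

    tp: int = 0
    fp: int = 0
    partial: int = 0
    n_truth: int = 0
    breakpoint_distances: list[int] = field(default_factory=list)
    fp_sizes: list[int] = field(default_factory=list)

    @property
    def tpr(self) -> float:
        return self.tp / self.n_truth if self.n_truth else float("nan")

    @property
    def breakpoint_exact_fraction(self) -> float:
        d = np.asarray(self.breakpoint_distances)
        return float((d == 0).mean()) if len(d) else float("nan")

    @property
    def small_fp_fraction(self) -> float:
        s = np.asarray(self.fp_sizes)
        return float((s < SMALL_FP_EXONS).mean()) if len(s) else float("nan")

    def breakpoint_distance_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.breakpoint_distances, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def calls_to_exon_table(calls) -> pd.DataFrame:
    """Project CNVCall objects onto exon-index space for scoring."""
    rows = [{
        "first_exon": c.segment.first_exon_index,
        "last_exon": c.segment.last_exon_index,
        "n_exons": c.segment.n_exons,
        "copy_number": c.copy_number,
        "state": c.state,
    } for c in calls]
    return pd.DataFrame(rows, columns=["first_exon", "last_exon", "n_exons",
                                       "copy_number", "state"])


def _direction(state: str) -> str | None:
    if state in LOSS_STATES:
        return "loss"
    if state in GAIN_STATES:
        return "gain"
    return None


_TRUTH_DIRECTION = {"one_copy": "loss", "three_copy": "gain",
                    "loss": "loss", "gain": "gain"}


def score_calls(calls: pd.DataFrame, truth: list[tuple[int, int, str]],
                reciprocal: bool = False) -> Metrics:
    """Score exon-space calls against planted truth regions.

    Parameters
    ----------
    calls : DataFrame with columns first_exon, last_exon, n_exons, state
        (inclusive exon indices); normal-state rows are ignored.
    truth : list of (first_exon, last_exon, state) inclusive tuples.
    reciprocal : require >= 50% overlap of BOTH call and truth instead of
        the truth region only.
    """
    truth_sorted = sorted(truth)
    for (a0, a1, _), (b0, b1, _) in zip(truth_sorted, truth_sorted[1:]):
        if b0 <= a1:
            raise ValueError("truth regions overlap; scoring is undefined")

    metrics = Metrics(n_truth=len(truth))
    matched: set[int] = set()
    for row in calls.itertuples(index=False):
        direction = _direction(row.state)
        if direction is None:
            continue
        c0, c1 = int(row.first_exon), int(row.last_exon)
        c_len = c1 - c0 + 1
        best_t, best_ov = None, 0
        for t_i, (t0, t1, _t_state) in enumerate(truth):
            ov = min(c1, t1) - max(c0, t0) + 1
            if ov > best_ov:
                best_t, best_ov = t_i, ov
        if best_ov <= 0:
            metrics.fp += 1
            metrics.fp_sizes.append(c_len)
            continue
        t0, t1, t_state = truth[best_t]
        t_len = t1 - t0 + 1
        ok = best_ov >= 0.5 * t_len
        if reciprocal:
            ok = ok and best_ov >= 0.5 * c_len
        if ok and direction == _TRUTH_DIRECTION[t_state] and best_t not in matched:
            metrics.tp += 1
            matched.add(best_t)
            metrics.breakpoint_distances.extend([abs(c0 - t0), abs(c1 - t1)])
        else:
            metrics.partial += 1
    return metrics


def tpr_fp_curves(metrics_by_cell: pd.DataFrame) -> pd.DataFrame:
    """Pivot a benchmark table into per-D_Norm TPR / FP curves over N.

    Returns one row per (state, D, d_norm, N) with the cell's TPR and
    FP-per-chromosome rate, sorted so each (state, D, d_norm) group is a
    curve over N; a ``monotone_in_D`` audit column flags any N/d_norm
    combination where TPR decreases as D grows.
    """
    df = metrics_by_cell.sort_values(["state", "d_norm", "D", "N"]).copy()
    flags = []
    for (_state, _dn, n), sub in df.groupby(["state", "d_norm", "N"]):
        tprs = sub.sort_values("D")["tpr"].to_numpy()
        ok = bool(np.all(np.diff(tprs) >= -0.05))  # allow sampling jitter
        flags.append(pd.Series(ok, index=sub.index))
    df["monotone_in_D"] = pd.concat(flags).sort_index() if flags else True
    cols = ["state", "D", "d_norm", "N", "tpr", "tpr_se", "fp_per_chrom",
            "breakpoint_exact_fraction", "n_chromosomes", "monotone_in_D"]
    return df[[c for c in cols if c in df.columns]]
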