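"""Five-state copy-number classification of segment means.

Segment mean log2 ratios are modeled as a mixture of five truncated
normal components, one per copy-number state (0, 1, 2, 3, 4+ copies).
In a sample where only a fraction c of cells carry the alteration
(cellularity), a CN-state mean shrinks toward 0:

    mu_s(c) = log2((c * CN_s + (1 - c) * 2) / 2),   CN_s in {0, 1, 2, 3, 4}

so at c = 1 the means are (-inf -> floored, -1, 0, log2(3/2) = 0.585, 1)
and at lower cellularity every shift is attenuated.  Component means are
FIXED at mu_s(c): that is what keeps the five states identifiable from
the handful of segments a single exome yields.  Each component is
truncated to the interval between the midpoints of adjacent state means,
so the supports partition the real line and calling reduces to a
nearest-mean rule softened by the mixture weights and the shared
component sd.  Mixture weights and the shared sd are fitted by EM; when
the cellularity is not supplied it is selected on a grid by maximum
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from wescnv.hslm import Segment
from wescnv.targets_io import STATE_LABELS, STATE_COPY_NUMBERS

logger = logging.getLogger(__name__)

COPY_NUMBERS = np.array(STATE_COPY_NUMBERS, dtype=float)
CN0_FLOOR = -5.0  # stands in for log2(0) when c = 1
DEFAULT_MIN_POSTERIOR = 0.5
CELLULARITY_GRID = np.round(np.arange(0.1, 1.0 + 1e-9, 0.05), 2)
EM_TOL = 1e-6
EM_MAX_ITER = 500
WEIGHT_FLOOR = 1e-6


def state_means(cellularity: float) -> np.ndarray:
    """Expected log2 ratios of the five states at a given cellularity.

    The CN = 0 mean at c = 1 is log2(0); it is floored at -5, far below
    any observable exome signal.
    """
    c = float(cellularity)
    if not 0 < c <= 1:
        raise ValueError(f"cellularity must be in (0, 1], got {c}")
    mixed = (c * COPY_NUMBERS + (1 - c) * 2.0) / 2.0
    with np.errstate(divide="ignore"):
        means = np.log2(mixed)
    return np.maximum(means, CN0_FLOOR)


def truncation_bounds(means: np.ndarray) -> np.ndarray:
    """Four interior cut points at midpoints between adjacent state means."""
    return (means[:-1] + means[1:]) / 2.0


@dataclass
class FastCallModel:
    """Fitted five-component truncated-normal mixture."""

    cellularity: float
    means: np.ndarray          # five state means mu_s(c), increasing
    sigma: float               # shared component sd
    weights: np.ndarray        # five mixture proportions, sum 1
    bounds: np.ndarray         # four interior cut points
    loglik: float = np.nan
    degenerate: bool = False

    def support(self, s: int) -> tuple[float, float]:
        lo = -np.inf if s == 0 else self.bounds[s - 1]
        hi = np.inf if s == 4 else self.bounds[s]
        return lo, hi

    def log_component_density(self, m: np.ndarray) -> np.ndarray:
        """(n, 5) log density of each truncated component at each mean."""
        m = np.atleast_1d(np.asarray(m, dtype=float))
        out = np.full((len(m), 5), -np.inf)
        for s in range(5):
            lo, hi = self.support(s)
            a = (lo - self.means[s]) / self.sigma
            b = (hi - self.means[s]) / self.sigma
            inside = (m >= lo) & (m <= hi)
            if inside.any():
                out[inside, s] = stats.truncnorm.logpdf(
                    m[inside], a, b, loc=self.means[s], scale=self.sigma)
        return out


def _log_mixture(model: FastCallModel, m: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    logd = model.log_component_density(m)
    logw = np.log(np.maximum(model.weights, WEIGHT_FLOOR))
    return logsumexp(logd + logw, axis=1)


def _weighted_loglik(model: FastCallModel, m: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * _log_mixture(model, m)))


def _em_fixed_c(m: np.ndarray, seg_w: np.ndarray, c: float,
                sigma_init: float) -> FastCallModel:
    """EM over mixture weights and the shared sd at a fixed cellularity.

    Because the supports partition the line, responsibilities are hard
    (each segment lies in exactly one support), so the E-step is a bin
    assignment and the M-step re-estimates proportions and, by bounded
    1-D likelihood maximization, the shared sd.  The sd update is only
    accepted when it improves the likelihood, keeping the loglik
    sequence non-decreasing.
    """
    means = state_means(c)
    bounds = truncation_bounds(means)
    sigma = max(sigma_init, 1e-3)

    assign = np.searchsorted(bounds, m)  # state index per segment
    counts = np.bincount(assign, weights=seg_w, minlength=5)
    weights = np.maximum(counts / counts.sum(), WEIGHT_FLOOR)
    weights = weights / weights.sum()

    model = FastCallModel(cellularity=c, means=means, sigma=sigma,
                          weights=weights, bounds=bounds)
    loglik = _weighted_loglik(model, m, seg_w)
    for _ in range(EM_MAX_ITER):
        # E-step: posteriors are one-hot under partitioned supports
        # M-step 1: weights from (weighted) support occupancy — already
        # fixed by the assignment, so only sigma moves across iterations.
        def neg_ll(log_sigma):
            trial = FastCallModel(cellularity=c, means=means,
                                  sigma=float(np.exp(log_sigma)),
                                  weights=weights, bounds=bounds)
            return -_weighted_loglik(trial, m, seg_w)

        res = minimize_scalar(neg_ll, bounds=(np.log(1e-4), np.log(5.0)),
                              method="bounded", options={"xatol": 1e-6})
        new_sigma = float(np.exp(res.x))
        new_model = FastCallModel(cellularity=c, means=means, sigma=new_sigma,
                                  weights=weights, bounds=bounds)
        new_loglik = _weighted_loglik(new_model, m, seg_w)
        delta = new_loglik - loglik
        if new_loglik >= loglik:
            model, loglik = new_model, new_loglik
        if abs(delta) < EM_TOL:
            break
    model.loglik = loglik
    return model


def fit_mixture(segment_means, segment_weights=None,
                fixed_c: float | None = None) -> FastCallModel:
    """Fit the five-state truncated-normal mixture to segment means.

    ``segment_weights`` (exon counts) multiply each segment's
    log-likelihood contribution, so long segments dominate the fit.  When
    ``fixed_c`` is absent the cellularity is chosen on the grid
    0.10, 0.15, ..., 1.00 by maximum likelihood.  Fewer than ~5 segments
    is allowed but the fit is then driven by the assignment rule alone.
    """
    m = np.asarray(segment_means, dtype=float)
    if m.ndim != 1 or len(m) == 0:
        raise ValueError("segment_means must be a non-empty 1-D sequence")
    seg_w = (np.ones(len(m)) if segment_weights is None
             else np.asarray(segment_weights, dtype=float))
    if (seg_w < 1).any():
        raise ValueError("segment weights (exon counts) must be >= 1")

    if np.ptp(m) == 0 and len(m) > 1:
        logger.warning("all segment means identical (%.4g): degenerate fit", m[0])

    sigma_init = max(float(np.std(m)) if len(m) > 1 else 0.1, 0.05)
    if fixed_c is not None:
        model = _em_fixed_c(m, seg_w, float(fixed_c), sigma_init)
    else:
        best = None
        for c in CELLULARITY_GRID:
            cand = _em_fixed_c(m, seg_w, float(c), sigma_init)
            if best is None or cand.loglik > best.loglik:
                best = cand
        model = best
        logger.info("selected cellularity c=%.2f (loglik %.3f)",
                    model.cellularity, model.loglik)
    model.degenerate = np.ptp(m) == 0 and len(m) > 1
    return model


@dataclass(frozen=True)
class CNVCall:
    """A segment with its called copy-number state."""

    segment: Segment
    state: str                    # one of STATE_LABELS
    copy_number: int              # 0,1,2,3,4 (4 == "4 or more")
    posteriors: np.ndarray        # five probabilities, sum 1
    uncertain: bool = False


def posterior_matrix(model: FastCallModel, m) -> np.ndarray:
    """(n, 5) posterior state probabilities for segment means ``m``."""
    m = np.atleast_1d(np.asarray(m, dtype=float))
    logd = model.log_component_density(m)
    logw = np.log(np.maximum(model.weights, WEIGHT_FLOOR))
    num = logd + logw
    from scipy.special import logsumexp

    post = np.exp(num - logsumexp(num, axis=1, keepdims=True))
    return post / post.sum(axis=1, keepdims=True)


def call_states(segments: list[Segment], model: FastCallModel,
                min_posterior: float = DEFAULT_MIN_POSTERIOR) -> list[CNVCall]:
    """Assign each segment the maximum-posterior copy-number state.

    Exact posterior ties break toward the lower copy number (conservative
    about amplification).  Calls whose winning posterior falls below
    ``min_posterior`` are kept but flagged uncertain.
    """
    if not segments:
        return []
    m = np.array([s.mean_level for s in segments])
    post = posterior_matrix(model, m)
    calls = []
    for j, seg in enumerate(segments):
        row = post[j]
        best = int(np.flatnonzero(row >= row.max() - 1e-12)[0])  # tie -> lower CN
        calls.append(CNVCall(
            segment=seg,
            state=STATE_LABELS[best],
            copy_number=STATE_COPY_NUMBERS[best],
            posteriors=row,
            uncertain=bool(row[best] < min_posterior),
        ))
    return calls


def calls_to_frame(calls: list[CNVCall], emit_all: bool = False) -> pd.DataFrame:
    """Tabulate calls; by default only non-diploid segments are emitted."""
    rows = []
    for c in calls:
        if not emit_all and c.copy_number == 2:
            continue
        rows.append({
            "chrom": c.segment.chrom,
            "start": c.segment.start_bp,
            "end": c.segment.end_bp,
            "first_exon": c.segment.first_exon_index,
            "last_exon": c.segment.last_exon_index,
            "state": c.state,
            "copy_number": c.copy_number,
            "posterior": float(c.posteriors[STATE_COPY_NUMBERS.index(c.copy_number)]),
            "mean_log2r": c.segment.mean_level,
            "n_exons": c.segment.n_exons,
            "uncertain": c.uncertain,
        })
    cols = ["chrom", "start", "end", "first_exon", "last_exon", "state",
            "copy_number", "posterior", "mean_log2r", "n_exons", "uncertain"]
    return pd.DataFrame(rows, columns=cols)
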