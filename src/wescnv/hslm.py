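"""Heterogeneous shifting level model (HSLM) segmentation.

The ordered log2-ratio sequence x_1..x_n is modeled as x_i = m_i + eps_i,
where m_i is an unobserved piecewise-constant mean level and eps_i is
Gaussian white noise with standard deviation sigma_eps.  Between
consecutive targets the mean level either stays (probability 1 - eta) or
jumps to a fresh level drawn from Normal(mu, sigma_mu^2) (probability
eta).  Exome targets are not equally spaced, so eta depends on the
genomic distance d_i between consecutive target midpoints:

    eta(d_i) = min(eta_max, eta0 ** (d_norm / d_i))

which equals eta0 at d_i = d_norm, decays to 0 for tightly packed targets
and saturates at eta_max for isolated ones.  d_norm is the resolution
knob: smaller values make jumps cheap at short range, which finds smaller
events at the price of more false breakpoints.

Inference discretizes the level space onto a finite grid (a Gaussian span
around mu blended with empirical quantiles of the data) and runs Viterbi
with the position-dependent transition matrix

    T_i(j -> k) = (1 - eta(d_i)) * 1[j == k] + eta(d_i) * p(k)

where p(k) is the Normal(mu, sigma_mu^2) prior over grid levels,
renormalized.  Because the jump term does not depend on the source level,
each Viterbi step costs O(L) rather than O(L^2).  Ties are broken toward
staying on the current level, so the fitted path never has more
breakpoints than necessary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from wescnv.normalize import Log2RatioProfile

logger = logging.getLogger(__name__)

#: baseline jump probability: at d_i = d_norm a level change is as likely
#: as not, making d_norm the distance scale at which the segmentation
#: starts treating consecutive targets as effectively independent
DEFAULT_ETA0 = 0.5
DEFAULT_D_NORM = 1e5
DEFAULT_N_LEVELS = 21
ETA_MAX = 0.999
# no real read-depth log2 ratio is quieter than this (Poisson noise at
# 10,000x coverage is already ~0.014); keeps degenerate inputs stable
SIGMA_EPS_FLOOR = 0.01

#: empirical quantiles blended into the level grid so levels exist near
#: rare extreme states (a single small CNV barely moves mu or sigma_mu)
GRID_QUANTILES = (0.001, 0.005, 0.01, 0.025, 0.05, 0.25, 0.5, 0.75,
                  0.95, 0.975, 0.99, 0.995, 0.999)


@dataclass(frozen=True)
class HSLMParams:
    """Parameters of the heterogeneous shifting level model."""

    eta0: float = DEFAULT_ETA0
    d_norm: float = DEFAULT_D_NORM
    mu: float = 0.0
    sigma_mu: float = 0.3
    sigma_eps: float = 0.2
    n_levels: int = DEFAULT_N_LEVELS
    eta_max: float = ETA_MAX

    def __post_init__(self):
        if not 0 < self.eta0 < 1:
            raise ValueError("eta0 must be in (0, 1)")
        if self.d_norm <= 0:
            raise ValueError("d_norm must be positive")
        if self.sigma_mu <= 0 or self.sigma_eps <= 0:
            raise ValueError("sigma_mu and sigma_eps must be positive")
        if not self.eta0 <= self.eta_max < 1:
            raise ValueError("need eta0 <= eta_max < 1")
        if self.n_levels < 3:
            raise ValueError("n_levels must be >= 3")


@dataclass(frozen=True)
class Segment:
    """A maximal run of targets sharing one fitted mean level."""

    chrom: str
    first_exon_index: int
    last_exon_index: int
    start_bp: int
    end_bp: int
    mean_level: float
    n_exons: int


def eta(d_i, params: HSLMParams):
    """Distance-modulated jump probability eta(d_i) = min(eta_max, eta0^(d_norm/d_i)).

    Strictly increasing in d_i below the cap; tends to 0 as d_i -> 0 and
    to eta_max as d_i -> infinity.  Accepts scalars or arrays.
    """
    d = np.asarray(d_i, dtype=float)
    if np.any(d <= 0):
        raise ValueError("inter-target distances must be positive")
    out = np.minimum(params.eta_max, params.eta0 ** (params.d_norm / d))
    return float(out) if np.isscalar(d_i) else out


def estimate_parameters(log2r, eta0: float = DEFAULT_ETA0,
                        d_norm: float = DEFAULT_D_NORM,
                        n_levels: int = DEFAULT_N_LEVELS) -> HSLMParams:
    """Moment-style parameter estimates from an observed log2-ratio sequence.

    The white-noise scale is the robust sd of first differences,
    ``MAD(diff x) / (sqrt(2) * 0.6745)`` — differencing cancels the
    piecewise-constant mean, and successive-difference noise has variance
    2 sigma_eps^2.  The global level mu is a 10%-trimmed mean, and
    sigma_mu comes from the excess of total variance over sigma_eps^2,
    floored at sigma_eps so the jump distribution never collapses.
    """
    x = np.asarray(log2r, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValueError(f"insufficient data: need >= 20 unmasked points, got {len(x)}")
    diffs = np.diff(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma_eps = max(mad / (np.sqrt(2) * 0.6745), SIGMA_EPS_FLOOR)
    mu = float(stats.trim_mean(x, 0.1))
    total_var = float(np.var(x))
    # jump levels are at least as dispersed as the noise: rare CNVs barely
    # move the total variance, and a collapsed sigma_mu would price real
    # copy-number levels out of the jump prior
    sigma_mu = max(np.sqrt(max(total_var - sigma_eps ** 2, 0.0)), sigma_eps)
    return HSLMParams(eta0=eta0, d_norm=d_norm, mu=mu,
                      sigma_mu=float(sigma_mu), sigma_eps=float(sigma_eps),
                      n_levels=n_levels)


def make_level_grid(x: np.ndarray, params: HSLMParams) -> np.ndarray:
    """Hybrid level grid: Gaussian span around mu plus data quantiles."""
    span = np.linspace(params.mu - 3 * params.sigma_mu,
                       params.mu + 3 * params.sigma_mu, params.n_levels)
    anchors = np.quantile(x, GRID_QUANTILES)
    grid = np.union1d(span, anchors)
    # collapse levels closer than a small fraction of the noise scale;
    # near-duplicate levels create spurious zero-length "jumps"
    tol = 0.05 * params.sigma_eps
    keep = [grid[0]]
    for v in grid[1:]:
        if v - keep[-1] > tol:
            keep.append(v)
    return np.asarray(keep)


def level_log_prior(levels: np.ndarray, params: HSLMParams) -> np.ndarray:
    """Log prior over grid levels: Normal(mu, sigma_mu^2) renormalized."""
    logw = stats.norm.logpdf(levels, params.mu, params.sigma_mu)
    from scipy.special import logsumexp

    return logw - logsumexp(logw)


def viterbi_path(x: np.ndarray, d: np.ndarray, params: HSLMParams,
                 levels: np.ndarray) -> np.ndarray:
    """Most probable level-index path given observations and distances.

    ``d`` holds the n-1 midpoint distances between consecutive
    observations.  Emission: Normal(level, sigma_eps^2).  Transition at
    step i: stay with 1 - eta(d_i); jump with eta(d_i) to level k with
    probability p(k) = renormalized Normal(level_k; mu, sigma_mu^2).  Ties
    between staying and jumping are resolved toward staying.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    n, L = len(x), len(levels)
    if n == 0:
        return np.empty(0, dtype=int)
    if len(d) != n - 1:
        raise ValueError("need exactly n-1 distances for n observations")
    if L == 1:
        return np.zeros(n, dtype=int)

    log_prior = level_log_prior(levels, params)
    emit = stats.norm.logpdf(x[:, None], levels[None, :], params.sigma_eps)

    score = log_prior + emit[0]
    back = np.zeros((n, L), dtype=int)
    back[0] = np.arange(L)
    prior = np.exp(log_prior)
    ks = np.arange(L)
    for i in range(1, n):
        e = eta(d[i - 1], params)
        # T(k->k) = (1-eta) + eta*p(k); T(j->k) = eta*p(k) for j != k
        # eta underflows to 0 for tightly packed targets: log -> -inf is
        # the intended "no jump" limit
        with np.errstate(divide="ignore"):
            log_diag = np.log((1 - e) + e * prior)
            log_jump = np.log(e) + log_prior
        # best off-diagonal source: global best, or runner-up when the
        # global best is k itself
        order = np.argsort(score)
        best, second = order[-1], order[-2]
        off_src = np.where(ks == best, second, best)
        off_score = np.where(ks == best, score[second], score[best])
        stay = score + log_diag
        jump = off_score + log_jump
        # ties go to "stay": fewer breakpoints
        take_stay = stay >= jump
        score = np.where(take_stay, stay, jump) + emit[i]
        back[i] = np.where(take_stay, ks, off_src)
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def transition_log_matrix(d_i: float, params: HSLMParams,
                          levels: np.ndarray) -> np.ndarray:
    """Dense log transition matrix T(j -> k) for one inter-target gap.

    Exposed for exhaustive-enumeration cross-checks; ``viterbi_path``
    uses the equivalent factored form.
    """
    e = eta(d_i, params)
    p = np.exp(level_log_prior(levels, params))
    T = e * np.tile(p, (len(levels), 1))
    np.fill_diagonal(T, T.diagonal() + (1 - e))
    return np.log(T)


def _segments_from_path(chrom: str, idx: np.ndarray, x: np.ndarray,
                        path: np.ndarray, targets) -> list[Segment]:
    segs: list[Segment] = []
    run_start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[run_start]:
            members = slice(run_start, i)
            t_first, t_last = idx[run_start], idx[i - 1]
            segs.append(Segment(
                chrom=chrom,
                first_exon_index=run_start,
                last_exon_index=i - 1,
                start_bp=int(targets.loc[t_first, "start"]),
                end_bp=int(targets.loc[t_last, "end"]),
                mean_level=float(np.mean(x[members])),
                n_exons=i - run_start,
            ))
            run_start = i
    return segs


def segment(profile: Log2RatioProfile, params: HSLMParams | None = None) -> list[Segment]:
    """Segment a log2-ratio profile chromosome by chromosome.

    Masked targets are skipped; distances span across them.  Segment mean
    levels are the empirical means of member targets (not the quantized
    grid values), so downstream calling sees unquantized evidence.
    Adjacent runs that Viterbi assigns the same grid level are one
    segment by construction.
    """
    all_segments: list[Segment] = []
    for chrom, idx, x, d in profile.chromosome_arrays():
        if len(x) == 1:
            logger.warning("%s has a single unmasked target; emitting one single-exon segment", chrom)
            all_segments.append(Segment(
                chrom=chrom, first_exon_index=0, last_exon_index=0,
                start_bp=int(profile.targets.loc[idx[0], "start"]),
                end_bp=int(profile.targets.loc[idx[0], "end"]),
                mean_level=float(x[0]), n_exons=1))
            continue
        p = params if params is not None else estimate_parameters(x)
        levels = make_level_grid(x, p)
        path = viterbi_path(x, d, p, levels)
        all_segments.extend(_segments_from_path(chrom, idx, x, path, profile.targets))
    return all_segments


def segments_to_frame(segments: list[Segment]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([{
        "chrom": s.chrom,
        "start": s.start_bp,
        "end": s.end_bp,
        "first_exon": s.first_exon_index,
        "last_exon": s.last_exon_index,
        "n_exons": s.n_exons,
        "mean_log2r": s.mean_level,
    } for s in segments])
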