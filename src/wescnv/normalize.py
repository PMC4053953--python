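"""Median normalization of read densities and the test/control log2 ratio.

Capture read depth is biased by local GC content, genomic mappability and
target size.  Each bias is removed by one pass of median normalization:
targets are binned by the covariate (1% GC bins, 0.1 mappability bins,
10 bp size bins) and each density is rescaled by

    EMRC_i_corrected = EMRC_i * m / m_X

where ``m_X`` is the median density of the bin holding target *i* and
``m`` the overall median.  After the pass every non-empty bin has median
``m``, so the per-bin mean level is equalized to one master level.

The CNV signal itself is the per-target log2(test/control) density ratio,
optionally LOWESS-corrected against overall intensity (MA-style) and
re-centered to median 0, together with the midpoint-to-midpoint distances
between consecutive targets that drive the distance-aware segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from wescnv.emrc import EMRCProfile

logger = logging.getLogger(__name__)

COVARIATES = ("gc", "mappability", "size")
_COV_COLUMN = {"gc": "gc_percent", "mappability": "mappability", "size": "size_bp"}
_BIN_WIDTH = {"gc": 1.0, "mappability": 0.1, "size": 10.0}

#: size bins above this value collapse into one open-ended bin so sparse
#: large exons do not form singleton bins
SIZE_BIN_CAP = 1000.0

DEFAULT_CONTROL_FLOOR = 0.1  # reads/bp; controls below are masked
LOWESS_FRAC = 0.3
LOWESS_IT = 3


@dataclass
class NormalizationBinTable:
    """Per-bin medians used by one median-normalization pass."""

    covariate: str
    bin_ids: np.ndarray      # sorted unique bin identifiers
    m_x: np.ndarray          # median EMRC per bin
    m: float                 # overall median EMRC

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bin_ids, "m_x": self.m_x, "m": self.m})


@dataclass
class Log2RatioProfile:
    """Ordered log2(test/control) signal ready for segmentation.

    ``log2r`` is NaN for masked targets.  ``distances`` maps each
    chromosome to the midpoint-to-midpoint gaps between consecutive
    *unmasked* targets (length ``n_unmasked - 1``).
    """

    targets: pd.DataFrame
    log2r: np.ndarray
    mask: np.ndarray
    distances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.log2r = np.asarray(self.log2r, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.targets)

    def chromosome_arrays(self):
        """Yield (chrom, index array, log2r, distances) for unmasked targets."""
        for chrom, sub in self.targets.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            keep = ~self.mask[idx]
            idx = idx[keep]
            if len(idx) == 0:
                continue
            yield str(chrom), idx, self.log2r[idx], self.distances.get(str(chrom), np.array([]))

    def to_frame(self) -> pd.DataFrame:
        df = self.targets.copy()
        df["log2r"] = self.log2r
        df["mask"] = self.mask
        return df


def _bin_index(values: np.ndarray, covariate: str) -> np.ndarray:
    """Map covariate values to integer bin identifiers."""
    width = _BIN_WIDTH[covariate]
    vals = np.asarray(values, dtype=float)
    if covariate == "size":
        vals = np.minimum(vals, SIZE_BIN_CAP)
    if covariate == "gc":
        return np.rint(vals).astype(int)  # integer percents are the bins
    return np.floor(vals / width + 1e-9).astype(int)


def compute_bin_table(profile: EMRCProfile, covariate: str) -> NormalizationBinTable:
    """Median EMRC per covariate bin, over unmasked targets."""
    col = _COV_COLUMN[covariate]
    if col not in profile.targets.columns:
        raise ValueError(f"targets lack the {col!r} column; annotate covariates first")
    keep = ~profile.mask
    bins = _bin_index(profile.targets[col].to_numpy(), covariate)
    m = float(np.median(profile.emrc[keep]))
    ids = np.unique(bins[keep])
    m_x = np.array([np.median(profile.emrc[keep & (bins == b)]) for b in ids])
    return NormalizationBinTable(covariate=covariate, bin_ids=ids, m_x=m_x, m=m)


def median_normalize(profile: EMRCProfile, covariate: str,
                     bin_table: NormalizationBinTable | None = None) -> EMRCProfile:
    """One median-normalization pass for a single covariate.

    Each density is multiplied by ``m / m_X`` of its bin.  Bins whose
    median is zero cannot be rescaled: their targets keep their values and
    are masked.  Empty bins (unseen covariate values) contribute factor 1.
    """
    if covariate not in COVARIATES:
        raise ValueError(f"covariate must be one of {COVARIATES}, got {covariate!r}")
    if bin_table is None:
        bin_table = compute_bin_table(profile, covariate)
    out = profile.copy()
    bins = _bin_index(profile.targets[_COV_COLUMN[covariate]].to_numpy(), covariate)
    factor = np.ones(len(profile))
    lookup = {b: mx for b, mx in zip(bin_table.bin_ids, bin_table.m_x)}
    zero_bins = 0
    for b in np.unique(bins):
        m_x = lookup.get(b)
        if m_x is None:
            continue  # empty in the table: no correction
        sel = bins == b
        if m_x == 0:
            out.mask[sel] = True
            zero_bins += 1
        else:
            factor[sel] = bin_table.m / m_x
    if zero_bins:
        logger.warning("%s: %d bins had zero median EMRC; their targets were masked",
                       covariate, zero_bins)
    out.emrc = profile.emrc * factor
    return out


def normalize_three_step(profile: EMRCProfile) -> EMRCProfile:
    """Sequential median normalization for GC, mappability, then size.

    One pass per covariate, in the order the biases act on capture data;
    the bin tables of each pass are logged for reproducibility.  Returns a
    profile flagged ``normalized``.
    """
    out = profile
    for covariate in COVARIATES:
        table = compute_bin_table(out, covariate)
        logger.info("normalize[%s]: %d bins, overall median %.4g",
                    covariate, len(table.bin_ids), table.m)
        out = median_normalize(out, covariate, table)
    out.normalized = True
    return out


def pool_controls(profiles: list[EMRCProfile]) -> EMRCProfile:
    """Pool control samples by summing per-target read counts.

    The pooled reference has ``rc`` equal to the element-wise sum across
    controls and a density recomputed from the summed counts; it is then
    bias-normalized like any single sample.
    """
    if not profiles:
        raise ValueError("need at least one control profile")
    ref = profiles[0].targets
    for p in profiles[1:]:
        same = (len(p.targets) == len(ref)
                and (p.targets[["chrom", "start", "end"]].to_numpy()
                     == ref[["chrom", "start", "end"]].to_numpy()).all())
        if not same:
            raise ValueError("control profiles have mismatched target sets")
    rc = np.sum([p.rc for p in profiles], axis=0)
    sizes = (ref["end"] - ref["start"]).to_numpy()
    pooled = EMRCProfile(targets=ref, rc=rc, emrc=rc / sizes,
                         sample_id="pooled_controls",
                         mask=np.any([p.mask for p in profiles], axis=0))
    return normalize_three_step(pooled)


def _midpoint_distances(targets: pd.DataFrame, keep_idx: np.ndarray) -> dict[str, np.ndarray]:
    distances: dict[str, np.ndarray] = {}
    kept = targets.loc[keep_idx]
    for chrom, sub in kept.groupby("chrom", sort=False):
        mids = sub["midpoint"].to_numpy(dtype=float)
        d = np.diff(mids)
        if (d <= 0).any():
            raise ValueError(f"non-increasing target midpoints on {chrom}")
        distances[str(chrom)] = d
    return distances


def log2_ratio(test: EMRCProfile, control: EMRCProfile, lowess: bool = True,
               control_floor: float = DEFAULT_CONTROL_FLOOR,
               lowess_frac: float = LOWESS_FRAC) -> Log2RatioProfile:
    """Build the per-target log2(test/control) profile.

    Targets whose control density falls below ``control_floor`` (reads/bp)
    are masked — a ratio against near-zero coverage is noise, not signal.
    With ``lowess=True`` the LOWESS trend of the ratio (M) against average
    log intensity A = 0.5*log2(test*control) is subtracted, removing
    intensity-dependent distortion; the unmasked ratios are then
    re-centered to median 0 so the diploid state sits at log2r = 0.
    """
    if len(test) != len(control):
        raise ValueError("test and control profiles have different target sets")
    t = np.asarray(test.emrc, dtype=float)
    c = np.asarray(control.emrc, dtype=float)
    mask = test.mask | control.mask | (c < control_floor) | (t <= 0)
    if mask.all():
        raise ValueError("control coverage insufficient: every target is masked")

    log2r = np.full(len(t), np.nan)
    ok = ~mask
    log2r[ok] = np.log2(t[ok] / c[ok])

    if lowess and ok.sum() >= 10:
        a = 0.5 * np.log2(t[ok] * c[ok])
        trend = sm_lowess(log2r[ok], a, frac=lowess_frac, it=LOWESS_IT,
                          return_sorted=False)
        log2r[ok] = log2r[ok] - trend

    log2r[ok] -= np.median(log2r[ok])

    targets = test.targets
    if "midpoint" not in targets.columns:
        targets = targets.copy()
        targets["midpoint"] = (targets["start"] + targets["end"]) // 2
    keep_idx = targets.index.to_numpy()[ok]
    distances = _midpoint_distances(targets, keep_idx)
    n_masked = int(mask.sum())
    if n_masked:
        logger.info("log2_ratio: masked %d/%d targets (control floor %.3g reads/bp)",
                    n_masked, len(t), control_floor)
    return Log2RatioProfile(targets=targets, log2r=log2r, mask=mask, distances=distances)
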