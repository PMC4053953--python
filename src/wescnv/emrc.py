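"""Exon mean read count (EMRC): aligned-read density per capture target.

For a target region *e* of size ``L_e`` bp with ``RC_e`` aligned reads,

    EMRC_e = RC_e / L_e

Read-to-target assignment counts a read for the unique target containing
its leftmost aligned base, so a read can never be counted for two abutting
exons; ``overlap_any=True`` switches to counting a read for every target it
overlaps.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)


@dataclass
class EMRCProfile:
    """Per-target read counts and densities for one sample.

    Attributes
    ----------
    targets : pandas.DataFrame
        Annotated target table (chrom, start, end, gc_percent,
        mappability, size_bp, midpoint).
    rc : numpy.ndarray
        Aligned read count per target (non-negative integers).
    emrc : numpy.ndarray
        Read density per target, reads/bp.
    sample_id : str
    normalized : bool
        True once bias correction has been applied; ``emrc`` then no
        longer equals ``rc / size_bp``.
    """

    targets: pd.DataFrame
    rc: np.ndarray
    emrc: np.ndarray
    sample_id: str = "sample"
    normalized: bool = False
    mask: np.ndarray = field(default=None)  # True = unusable target

    def __post_init__(self):
        self.rc = np.asarray(self.rc)
        self.emrc = np.asarray(self.emrc, dtype=float)
        n = len(self.targets)
        if len(self.rc) != n or len(self.emrc) != n:
            raise ValueError("rc/emrc length must match the target table")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.targets)

    def copy(self) -> "EMRCProfile":
        return replace(self, targets=self.targets, rc=self.rc.copy(),
                       emrc=self.emrc.copy(), mask=self.mask.copy())

    def to_frame(self) -> pd.DataFrame:
        df = self.targets.copy()
        df["rc"] = self.rc
        df["emrc"] = self.emrc
        df["mask"] = self.mask
        return df


def _check_chrom_names(alignment: pysam.AlignmentFile, targets: pd.DataFrame) -> None:
    bam_chroms = set(alignment.references)
    missing = sorted(set(targets["chrom"].astype(str)) - bam_chroms)
    if missing:
        raise ValueError(
            "chromosome names in the target BED absent from the alignment header: "
            + ", ".join(missing)
        )


def compute_emrc(alignments: str | os.PathLike, targets: pd.DataFrame,
                 min_mapq: int = 1, drop_duplicates: bool = True,
                 overlap_any: bool = False, sample_id: str | None = None) -> EMRCProfile:
    """Count aligned reads per target and compute EMRC = RC_e / L_e.

    Reads are filtered to primary, mapped alignments with
    ``MAPQ >= min_mapq``; duplicate-flagged reads are excluded when
    ``drop_duplicates`` is set.  By default a read is assigned to the
    (unique) target containing its leftmost aligned base; with
    ``overlap_any`` it is counted once for every target it overlaps.

    Parameters
    ----------
    alignments : path to a coordinate-sorted SAM/BAM file.
    targets : annotated or plain target table, sorted and non-overlapping.
    """
    mode = "r" if str(alignments).endswith(".sam") else "rb"
    n = len(targets)
    rc = np.zeros(n, dtype=np.int64)

    # per-chromosome sorted target arrays for O(log n) assignment
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in targets.groupby("chrom", sort=False):
        per_chrom[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                                 sub.index.to_numpy())

    total_kept = 0
    with pysam.AlignmentFile(str(alignments), mode) as af:
        _check_chrom_names(af, targets)
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.mapping_quality < min_mapq
                    or (drop_duplicates and read.is_duplicate)):
                continue
            chrom = read.reference_name
            if chrom not in per_chrom:
                continue
            starts, ends, idx = per_chrom[chrom]
            pos = read.reference_start
            if overlap_any:
                rend = read.reference_end or (pos + 1)
                lo = np.searchsorted(ends, pos, side="right")
                hi = np.searchsorted(starts, rend, side="left")
                if hi > lo:
                    rc[idx[lo:hi]] += 1
                    total_kept += 1
            else:
                j = np.searchsorted(starts, pos, side="right") - 1
                if j >= 0 and pos < ends[j]:
                    rc[idx[j]] += 1
                    total_kept += 1

    sizes = (targets["end"] - targets["start"]).to_numpy()
    emrc = rc / sizes
    logger.info("counted %d reads over %d targets (min_mapq=%d, drop_duplicates=%s)",
                total_kept, n, min_mapq, drop_duplicates)
    return EMRCProfile(targets=targets, rc=rc, emrc=emrc,
                       sample_id=sample_id or os.path.basename(str(alignments)))


def generate_alignment_fixture(targets: pd.DataFrame, per_target_depth,
                               read_len: int, seed: int,
                               out_path: str | os.PathLike) -> str:
    """Write a deterministic synthetic SAM file with reads inside each target.

    ``per_target_depth`` is either one integer (reads per target) or a
    sequence with one count per target.  Reads are placed uniformly within
    each target; a read longer than its target is clipped to the target
    size (with a warning).  Re-running with the same seed reproduces the
    file byte for byte.
    """
    rng = np.random.default_rng(seed)
    depths = np.broadcast_to(np.asarray(per_target_depth, dtype=int), (len(targets),))
    if (depths < 0).any():
        raise ValueError("per_target_depth must be >= 0")

    chrom_sizes: dict[str, int] = {}
    for row in targets.itertuples(index=False):
        chrom_sizes[row.chrom] = max(chrom_sizes.get(row.chrom, 0), int(row.end) + read_len + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_sizes.items()],
    }

    records = []  # (chrom_order, pos, name, length)
    chrom_order = {c: i for i, c in enumerate(chrom_sizes)}
    clipped = False
    for t_i, row in enumerate(targets.itertuples(index=False)):
        size = int(row.end) - int(row.start)
        rlen = read_len
        if rlen > size:
            rlen = size
            clipped = True
        for r_i in range(depths[t_i]):
            pos = int(row.start) + int(rng.integers(0, size - rlen + 1))
            records.append((chrom_order[row.chrom], pos, f"read_t{t_i}_{r_i}", rlen))
    if clipped:
        logger.warning("read_len exceeds some target sizes; reads clipped to fit")
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    out_path = str(out_path)
    with pysam.AlignmentFile(out_path, "wh", header=header) as out:
        for c_i, pos, name, rlen in records:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * rlen
            a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
            a.reference_id = c_i
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.flag = 0
            out.write(a)
    return out_path
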