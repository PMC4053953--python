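"""Reading and writing the interval formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (BED convention): ``start``
is the first base of the target and ``end`` is one past the last.  VCF
output converts to 1-based inclusive coordinates (``POS = start + 1``,
``END = end``).

Targets are held in a :class:`pandas.DataFrame` with columns
``chrom, start, end, id`` (after annotation also ``gc_percent,
mappability, size_bp, midpoint``), sorted by chromosome (order of first
appearance in the input) then start, with overlapping or abutting records
merged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ["chrom", "start", "end", "id"]
ANNOT_COLUMNS = TARGET_COLUMNS + ["gc_percent", "mappability", "size_bp", "midpoint"]

#: five-state classification labels, ordered by copy number
STATE_LABELS = ["two_copy_deletion", "one_copy_deletion", "normal",
                "one_copy_duplication", "multi_copy_amplification"]
STATE_COPY_NUMBERS = [0, 1, 2, 3, 4]


class BedParseError(ValueError):
    """Raised for a malformed BED record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class TargetRegion:
    """A capture target: 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def _merge_sorted_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting sorted intervals on one chromosome."""
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlap or abut
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def load_targets(bed_path: str | os.PathLike) -> pd.DataFrame:
    """Load capture targets from a BED file (>=3 columns).

    Records are sorted by (chromosome, start) — chromosomes keep the order
    of their first appearance — and overlapping or abutting records are
    merged.  Merged records get the id of the first contributing record
    (or ``None``).

    Raises
    ------
    BedParseError
        For a malformed line or a record with ``end <= start``, naming the
        offending 1-based line number.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    ids: list[str | None] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"expected >=3 columns, got {len(fields)}", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinate: {exc}", lineno) from None
            if end <= start:
                raise BedParseError(f"end ({end}) <= start ({start})", lineno)
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            ids.append(fields[3] if len(fields) > 3 else None)

    if not chroms:
        return pd.DataFrame(columns=TARGET_COLUMNS)

    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "id": ids})
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    df["_corder"] = df["chrom"].map(chrom_order)
    df = df.sort_values(["_corder", "start", "end"], kind="stable").drop(columns="_corder")

    merged_parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        s, e = _merge_sorted_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        # keep the id of the first record falling in each merged interval
        idx = np.searchsorted(s, sub["start"].to_numpy(), side="right") - 1
        ids_out = [None] * len(s)
        for rec_i, m_i in enumerate(idx):
            if ids_out[m_i] is None:
                ids_out[m_i] = sub["id"].iloc[rec_i]
        merged_parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "id": ids_out}))
    out = pd.concat(merged_parts, ignore_index=True)
    logger.info("loaded %d targets (%d records) from %s", len(out), len(df), bed_path)
    return out


def _read_bedgraph(path: str | os.PathLike) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chromosome (starts, ends, values) arrays."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float})
    df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy())
    return out


def _track_stats(path: str | os.PathLike, chrom: str, start: int, end: int,
                 cache: dict) -> tuple[float, int]:
    """(sum of values over covered bases, number of covered bases) for an interval.

    Accepts bigWig (via pyBigWig) or bedGraph text; bases with no track
    value are excluded from the mean.
    """
    path = str(path)
    kind = cache.get("_kind")
    if kind is None:
        if path.endswith((".bw", ".bigwig", ".bigWig")):
            import pyBigWig

            cache["_bw"] = pyBigWig.open(path)
            kind = cache["_kind"] = "bigwig"
        else:
            cache["_bg"] = _read_bedgraph(path)
            kind = cache["_kind"] = "bedgraph"
    if kind == "bigwig":
        bw = cache["_bw"]
        if chrom not in bw.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from track {path}")
        vals = np.asarray(bw.values(chrom, start, end), dtype=float)
        covered = np.isfinite(vals)
        return float(vals[covered].sum()), int(covered.sum())
    intervals = cache["_bg"]
    if chrom not in intervals:
        raise KeyError(f"chromosome {chrom!r} absent from track {path}")
    s, e, v = intervals[chrom]
    # overlap-weighted sum == exact per-base sum for step tracks
    ov = np.minimum(e, end) - np.maximum(s, start)
    keep = ov > 0
    return float((v[keep] * ov[keep]).sum()), int(ov[keep].sum())


def annotate_covariates(targets: pd.DataFrame, gc_track: str | os.PathLike,
                        map_track: str | os.PathLike) -> pd.DataFrame:
    """Attach GC percentage, mappability, size and midpoint to each target.

    ``gc_percent`` is the per-base mean of the GC track rounded to the
    nearest integer percent (the normalization bins are integer percents);
    ``mappability`` is the per-base mean uniqueness fraction.  Tracks may be
    bigWig or bedGraph; bases without a track value are excluded from the
    mean, and a target with no covered bases gets value 0 and is flagged
    in the log.  Mappability tracks expressed as 0–100 percentages are
    rescaled to [0, 1].
    """
    gc_cache: dict = {}
    map_cache: dict = {}
    gc_out = np.empty(len(targets))
    map_out = np.empty(len(targets))
    uncovered = 0
    for i, row in enumerate(targets.itertuples(index=False)):
        gsum, gn = _track_stats(gc_track, row.chrom, row.start, row.end, gc_cache)
        msum, mn = _track_stats(map_track, row.chrom, row.start, row.end, map_cache)
        gc_out[i] = gsum / gn if gn else 0.0
        map_out[i] = msum / mn if mn else 0.0
        if gn == 0 or mn == 0:
            uncovered += 1
    if uncovered:
        logger.warning("%d targets had no covered track bases; covariates set to 0", uncovered)
    if np.nanmax(map_out, initial=0.0) > 1.0:  # percentage-style uniqueness track
        map_out = map_out / 100.0
    out = targets.copy()
    out["gc_percent"] = np.clip(np.rint(gc_out), 0, 100).astype(int)
    out["mappability"] = np.clip(map_out, 0.0, 1.0)
    out["size_bp"] = (out["end"] - out["start"]).astype(int)
    out["midpoint"] = (out["start"] + out["end"]) // 2
    return out


def load_target_table(tsv_path: str | os.PathLike) -> pd.DataFrame:
    """Load a precomputed 5-column target table (chrom,start,end,gc,map).

    A convenience bypass for users without GC/mappability tracks; fills
    the same columns :func:`annotate_covariates` produces.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    if not {"chrom", "start", "end"}.issubset(df.columns):
        df = pd.read_csv(tsv_path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gc_percent", "mappability"])
    df["chrom"] = df["chrom"].astype(str)
    if "id" not in df.columns:
        df["id"] = None
    if "gc_percent" in df.columns:
        df["gc_percent"] = np.clip(np.rint(df["gc_percent"].astype(float)), 0, 100).astype(int)
    if "mappability" in df.columns:
        df["mappability"] = np.clip(df["mappability"].astype(float), 0.0, 1.0)
    df["size_bp"] = (df["end"] - df["start"]).astype(int)
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df[[c for c in ANNOT_COLUMNS if c in df.columns]]


# ---------------------------------------------------------------------------
# Call output
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["chrom", "start", "end", "state", "copy_number", "posterior",
                "mean_log2r", "n_exons"]


def write_calls(calls: pd.DataFrame, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write CNV calls as TSV, BED and VCF 4.2 (``<prefix>.{tsv,bed,vcf}``).

    ``calls`` needs columns ``chrom, start, end, state, copy_number,
    posterior, mean_log2r, n_exons`` with BED-style 0-based half-open
    coordinates.  The TSV round-trips losslessly through
    :func:`read_calls_tsv`.
    """
    out_prefix = str(out_prefix)
    paths = {ext: f"{out_prefix}.{ext}" for ext in ("tsv", "bed", "vcf")}

    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    calls[cols].to_csv(paths["tsv"], sep="\t", index=False, float_format="%.6g")

    with open(paths["bed"], "w") as bed:
        bed.write("#chrom\tstart\tend\tname\tscore\n")
        for row in calls.itertuples(index=False):
            score = int(round(1000 * float(row.posterior)))
            bed.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                      f"{row.state};CN={row.copy_number}\t{score}\n")

    with open(paths["vcf"], "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write('##ALT=<ID=DEL,Description="Deletion">\n')
        vcf.write('##ALT=<ID=DUP,Description="Duplication">\n')
        vcf.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">\n')
        vcf.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n')
        vcf.write('##INFO=<ID=LOG2R,Number=1,Type=Float,Description="Mean log2 ratio of the segment">\n')
        vcf.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Integer copy number">\n')
        vcf.write('##FORMAT=<ID=CNP,Number=1,Type=Float,Description="Posterior probability of the called state">\n')
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for row in calls.itertuples(index=False):
            cn = int(row.copy_number)
            if cn == 2:
                continue  # VCF records only non-diploid segments
            svtype = "DEL" if cn < 2 else "DUP"
            pos = int(row.start) + 1  # 1-based
            vcf.write(f"{row.chrom}\t{pos}\t.\tN\t<{svtype}>\t.\tPASS\t"
                      f"END={int(row.end)};SVTYPE={svtype};LOG2R={float(row.mean_log2r):.4f}\t"
                      f"CN:CNP\t{cn}:{float(row.posterior):.4f}\n")
    logger.info("wrote %d calls to %s.{tsv,bed,vcf}", len(calls), out_prefix)
    return paths


def read_calls_tsv(tsv_path: str | os.PathLike) -> pd.DataFrame:
    """Read back a call TSV written by :func:`write_calls`."""
    df = pd.read_csv(tsv_path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df
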