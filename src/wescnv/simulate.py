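"""Synthetic chromosomes with exome-like architecture and planted CNVs.

A synthetic chromosome is built from synthetic genes: every gene except
the g altered ones has an exon count drawn from U(5, 100); altered genes
have exactly N exons.  The total exon count is constrained to 1,000 (the
last gene is truncated to fit).  Gaps between exons of the same gene are
drawn from U(10, 10000) bp, while the gap between adjacent genes is a
fixed distance D.  Altered exons carry an expected log2 ratio of
log2(1/2) = -1 (one-copy loss) or log2(3/2) ~ 0.585 (three-copy gain);
all other exons have expectation 0.  Per-exon noise is i.i.d. Gaussian —
a pinned, documented stand-in for the empirical exome noise real
log2-ratio profiles inherit from sequencing.

This generator defines the study conditions for every benchmark in the
package; its defaults are not tuning knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wescnv.normalize import Log2RatioProfile
from wescnv.hslm import (DEFAULT_D_NORM, DEFAULT_ETA0, HSLMParams,
                         estimate_parameters, segment as hslm_segment)
from wescnv.fastcall import fit_mixture, call_states
from wescnv.evaluate import score_calls, calls_to_exon_table

logger = logging.getLogger(__name__)

TOTAL_EXONS = 1000
EXONS_PER_GENE = (5, 100)
INTRA_GENE_GAP = (10, 10000)
EXON_WIDTH = (50, 500)          # bp, only for coordinate realization
DEFAULT_NOISE_SD = 0.5
ONE_COPY_SHIFT = np.log2(1 / 2)     # -1
THREE_COPY_SHIFT = np.log2(3 / 2)   # ~0.585


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic-chromosome cell."""

    g: int = 1                      # number of altered genes
    n_exons_altered: int = 10       # N: exons per altered gene
    inter_gene_distance: float = 1e5  # D, bp
    altered_state: str = "one_copy"   # "one_copy" or "three_copy"
    noise_sd: float = DEFAULT_NOISE_SD
    deleted_sd_scale: float = 1.0   # optionally < 1: losses are less noisy
    total_exons: int = TOTAL_EXONS
    seed: int | None = None

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.g and self.n_exons_altered < 2:
            raise ValueError("altered genes need N >= 2 exons")
        if self.g * self.n_exons_altered >= self.total_exons:
            raise ValueError("g * N must be < total exon count")
        if self.altered_state not in ("one_copy", "three_copy"):
            raise ValueError("altered_state must be 'one_copy' or 'three_copy'")

    @property
    def shift(self) -> float:
        return ONE_COPY_SHIFT if self.altered_state == "one_copy" else THREE_COPY_SHIFT


@dataclass
class SyntheticChromosome:
    """A simulated log2-ratio profile plus the planted truth."""

    profile: Log2RatioProfile
    truth: list[tuple[int, int, str]]   # (first_exon, last_exon, state), inclusive
    config: SimulationConfig

    @property
    def n_exons(self) -> int:
        return len(self.profile)


def _draw_gene_sizes(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[list[int], set[int]]:
    """Gene exon counts summing exactly to total_exons, plus altered slots."""
    budget = cfg.total_exons - cfg.g * cfg.n_exons_altered
    normal_sizes: list[int] = []
    while budget > 0:
        size = int(rng.integers(EXONS_PER_GENE[0], EXONS_PER_GENE[1] + 1))
        normal_sizes.append(min(size, budget))  # last gene truncated to fit
        budget -= size

    n_genes = len(normal_sizes) + cfg.g
    if cfg.g:
        # altered slots uniform among gene positions, never adjacent
        while True:
            slots = sorted(rng.choice(n_genes, size=cfg.g, replace=False))
            if all(b - a > 1 for a, b in zip(slots, slots[1:])):
                break
        slots = set(int(s) for s in slots)
    else:
        slots = set()

    sizes: list[int] = []
    it = iter(normal_sizes)
    for slot in range(n_genes):
        sizes.append(cfg.n_exons_altered if slot in slots else next(it))
    return sizes, slots


def generate_chromosome(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SyntheticChromosome:
    """Generate one synthetic chromosome; deterministic given a seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes, altered_slots = _draw_gene_sizes(rng, config)

    starts = np.empty(config.total_exons, dtype=np.int64)
    ends = np.empty(config.total_exons, dtype=np.int64)
    altered = np.zeros(config.total_exons, dtype=bool)
    truth: list[tuple[int, int, str]] = []

    pos = 1000  # leading pad
    e = 0
    for slot, size in enumerate(sizes):
        if slot > 0:
            pos += int(config.inter_gene_distance)
        first = e
        for k in range(size):
            if k > 0:
                pos += int(rng.integers(INTRA_GENE_GAP[0], INTRA_GENE_GAP[1] + 1))
            width = int(rng.integers(EXON_WIDTH[0], EXON_WIDTH[1] + 1))
            starts[e] = pos
            ends[e] = pos + width
            pos += width
            e += 1
        if slot in altered_slots:
            altered[first:e] = True
            truth.append((first, e - 1, config.altered_state))
    assert e == config.total_exons

    sd = np.full(config.total_exons, config.noise_sd)
    if config.altered_state == "one_copy":
        sd[altered] *= config.deleted_sd_scale
    log2r = rng.normal(0.0, 1.0, config.total_exons) * sd
    log2r[altered] += config.shift

    targets = pd.DataFrame({
        "chrom": "chrS",
        "start": starts,
        "end": ends,
        "id": [f"exon_{i}" for i in range(config.total_exons)],
    })
    targets["size_bp"] = targets["end"] - targets["start"]
    targets["midpoint"] = (targets["start"] + targets["end"]) // 2
    mids = targets["midpoint"].to_numpy(dtype=float)
    profile = Log2RatioProfile(
        targets=targets, log2r=log2r,
        mask=np.zeros(config.total_exons, dtype=bool),
        distances={"chrS": np.diff(mids)},
    )
    return SyntheticChromosome(profile=profile, truth=truth, config=config)


def analyze_chromosome(chrom: SyntheticChromosome,
                       d_norm: float = DEFAULT_D_NORM, eta0: float = DEFAULT_ETA0,
                       cellularity: float = 1.0,
                       params: HSLMParams | None = None):
    """Segment + classify one synthetic chromosome; returns (calls, segments)."""
    x = chrom.profile.log2r
    if params is None:
        params = estimate_parameters(x, eta0=eta0, d_norm=d_norm)
    segs = hslm_segment(chrom.profile, params)
    model = fit_mixture([s.mean_level for s in segs],
                        [s.n_exons for s in segs], fixed_c=cellularity)
    calls = call_states(segs, model)
    return calls, segs


def run_benchmark(config_grid: list[SimulationConfig], n_chromosomes: int,
                  d_norm_values=(DEFAULT_D_NORM,), eta0: float = DEFAULT_ETA0,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate, segment and call every grid cell; tabulate accuracy.

    For each (config, d_norm) cell, ``n_chromosomes`` chromosomes are
    generated and pushed through HSLM + five-state calling; true/false
    positives use the 50%-overlap rule and breakpoint accuracy is the
    fraction of true-positive breakpoints at exon distance 0.  Binomial
    standard errors accompany each rate.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for cfg in config_grid:
        for d_norm in d_norm_values:
            # one independent, reproducible stream per grid cell
            cell_rng = np.random.default_rng(ss.spawn(1)[0])
            tp = fp = partial = n_truth = 0
            bp_exact = bp_total = 0
            for _ in range(n_chromosomes):
                chrom = generate_chromosome(cfg, cell_rng)
                calls, _segs = analyze_chromosome(chrom, d_norm=d_norm, eta0=eta0)
                metrics = score_calls(calls_to_exon_table(calls), chrom.truth)
                tp += metrics.tp
                fp += metrics.fp
                partial += metrics.partial
                n_truth += len(chrom.truth)
                bp_exact += int(np.sum(np.asarray(metrics.breakpoint_distances) == 0))
                bp_total += len(metrics.breakpoint_distances)
            tpr = tp / n_truth if n_truth else np.nan
            rows.append({
                "g": cfg.g, "N": cfg.n_exons_altered,
                "D": cfg.inter_gene_distance, "state": cfg.altered_state,
                "noise_sd": cfg.noise_sd, "d_norm": d_norm,
                "n_chromosomes": n_chromosomes,
                "tp": tp, "fp": fp, "partial": partial, "n_truth": n_truth,
                "tpr": tpr,
                "tpr_se": (np.sqrt(tpr * (1 - tpr) / n_truth) if n_truth else np.nan),
                "fp_per_chrom": fp / n_chromosomes,
                "breakpoint_exact_fraction": (bp_exact / bp_total if bp_total else np.nan),
                "n_breakpoints": bp_total,
            })
            logger.info("cell g=%d N=%d D=%.0f %s d_norm=%.0f: TPR=%.3f FP/chrom=%.3f",
                        cfg.g, cfg.n_exons_altered, cfg.inter_gene_distance,
                        cfg.altered_state, d_norm, rows[-1]["tpr"],
                        rows[-1]["fp_per_chrom"])
    return pd.DataFrame(rows)
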