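"""Fragment-recruitment filtering, coverage, and hypervariable regions.

Environmental reads recruited to the reference genome are accepted under
two alternative rules (long/strict-ends or shorter/stricter identity), with
a mate-rescue pass for rejected reads whose mate aligned well.  Accepted
alignments give a per-position fold-coverage profile; hypervariable regions
(HVRs) are maximal runs of at least ``min_len`` bp whose coverage falls
below a fraction of the genome-wide central coverage — recruitment
"deserts" interpreted as rapidly evolving loci.  Finally, the placement of
the evolved populations' mutations relative to HVRs is scored with an
upper-tail hypergeometric test.

Alignment-record dialect (TSV): read_id, start, end, aligned_len,
pct_identity, unaligned_left, unaligned_right, mate_id, mate_aligned_frac.
Coordinates are 1-based inclusive; emitted BED intervals are converted to
the BED 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import hypergeometric_enrichment

__all__ = [
    "HypervariableRegion",
    "accept_alignment",
    "accepted_mask",
    "mate_rescue",
    "recruit",
    "coverage_profile",
    "call_hypervariable",
    "hvr_mutation_overlap",
    "read_alignment_table",
    "regions_to_bed",
]

ALIGNMENT_COLUMNS = ["read_id", "start", "end", "aligned_len", "pct_identity",
                     "unaligned_left", "unaligned_right", "mate_id",
                     "mate_aligned_frac"]


@dataclass(frozen=True)
class HypervariableRegion:
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def accept_alignment(aligned_len: float, pct_identity: float,
                     unaligned_left: float, unaligned_right: float) -> bool:
    """Acceptance rules for a recruited read.

    Rule 1: aligned over more than 300 bp at 65% identity with fewer than 25
    unaligned bases on either end.  Rule 2: aligned over more than 100 bp at
    strictly more than 65% identity with fewer than 20 unaligned bases on
    either end.  (The >=65 vs >65 asymmetry is deliberate and tested.)
    """
    rule1 = (aligned_len > 300 and pct_identity >= 65
             and unaligned_left < 25 and unaligned_right < 25)
    rule2 = (aligned_len > 100 and pct_identity > 65
             and unaligned_left < 20 and unaligned_right < 20)
    return rule1 or rule2


def accepted_mask(records: pd.DataFrame) -> pd.Series:
    """Vectorized acceptance over an alignment-record table."""
    rule1 = ((records["aligned_len"] > 300) & (records["pct_identity"] >= 65)
             & (records["unaligned_left"] < 25) & (records["unaligned_right"] < 25))
    rule2 = ((records["aligned_len"] > 100) & (records["pct_identity"] > 65)
             & (records["unaligned_left"] < 20) & (records["unaligned_right"] < 20))
    return rule1 | rule2


def mate_rescue(mate_aligned_frac: float | None, mate_accepted: bool) -> bool:
    """A rejected read is recovered iff its mate is an accepted record that
    aligned over strictly more than 80% of its length."""
    if mate_aligned_frac is None or not mate_accepted:
        return False
    return mate_aligned_frac > 0.8


def recruit(records: pd.DataFrame) -> pd.DataFrame:
    """Accepted records plus mate-rescued ones; adds a ``rescued`` column."""
    ok = accepted_mask(records)
    accepted_ids = set(records.loc[ok, "read_id"])
    rescued = (
        ~ok
        & records["mate_id"].notna()
        & records["mate_id"].isin(accepted_ids)
        & (records["mate_aligned_frac"].fillna(0.0) > 0.8)
    )
    out = records.loc[ok | rescued].copy()
    out["rescued"] = rescued.loc[out.index]
    return out


def coverage_profile(records: pd.DataFrame, genome_length: int) -> np.ndarray:
    """Per-position fold-coverage: depth[p] = #records spanning position p+1."""
    depth_delta = np.zeros(genome_length + 1, dtype=np.int64)
    starts = records["start"].to_numpy(int)
    ends = records["end"].to_numpy(int)
    if len(starts) and (starts.min() < 1 or ends.max() > genome_length
                        or (ends < starts).any()):
        raise ValueError("alignment coordinates outside the genome")
    np.add.at(depth_delta, starts - 1, 1)
    np.add.at(depth_delta, ends, -1)
    return np.cumsum(depth_delta[:-1])


def call_hypervariable(depth: np.ndarray, min_len: int = 500,
                       frac: float = 0.2, center: str = "median"
                       ) -> list[HypervariableRegion]:
    """Maximal low-coverage runs of at least ``min_len`` bp.

    A position is "low" when its depth is strictly below ``frac`` times the
    central coverage; ``center`` is the genome-wide median (default) or
    mean — both occur in the source literature for this definition, so the
    choice is explicit.
    """
    depth = np.asarray(depth)
    if len(depth) == 0:
        raise ValueError("empty coverage profile")
    if not (depth > 0).any():
        raise ValueError("all-zero coverage: HVR threshold is degenerate")
    if center == "median":
        c = float(np.median(depth))
    elif center == "mean":
        c = float(np.mean(depth))
    else:
        raise ValueError(f"unknown center {center!r}")
    low = depth < frac * c
    regions: list[HypervariableRegion] = []
    # run-length scan over the low-coverage mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):   # [s, e) 0-based
        if e - s >= min_len:
            regions.append(HypervariableRegion(
                start=int(s) + 1, end=int(e),
                mean_depth=float(depth[s:e].mean())))
    return regions


def hvr_mutation_overlap(regions: list[HypervariableRegion],
                         mutation_positions, genome_length: int,
                         unit: str = "mutations"
                         ) -> tuple[float, float, float]:
    """(fraction of mutations in HVRs, HVR genome fraction, hypergeometric p).

    ``unit='mutations'`` counts every mutation record; ``unit='positions'``
    counts distinct mutated positions (the two differ when several alleles
    segregate at one site).
    """
    positions = [int(p) for p in mutation_positions]
    if unit == "positions":
        positions = sorted(set(positions))
    elif unit != "mutations":
        raise ValueError(f"unknown unit {unit!r}")
    region_bp = sum(r.length for r in regions)
    n_total = len(positions)
    n_in = sum(1 for p in positions
               if any(r.start <= p <= r.end for r in regions))
    frac_mut = n_in / n_total if n_total else 0.0
    frac_genome = region_bp / genome_length if genome_length else 0.0
    p = hypergeometric_enrichment(n_in, n_total, region_bp, genome_length)
    return frac_mut, frac_genome, p


def read_alignment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return df


def regions_to_bed(regions: list[HypervariableRegion], path,
                   chrom: str = "genome") -> None:
    """BED output: 0-based half-open, so (start-1, end) per region."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\tHVR{i}\t"
                     f"{r.mean_depth:.3f}\n")
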