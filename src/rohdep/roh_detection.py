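"""Sliding-window detection of runs of homozygosity (ROH).

The caller mirrors the PLINK ``--homozyg`` scan: windows of L consecutive
SNPs are scored homozygous when they contain at most one heterozygote (and a
configurable number of missing calls); a SNP is eligible when the proportion
of homozygous windows covering it reaches a threshold; maximal eligible runs
are split at inter-SNP gaps above 1 Mb and kept when they span >= 2 Mb,
contain >= L SNPs and average at least one SNP per 100 kb.  Segments shorter
than 8 Mb are the "ancient" class (ROH2_8), the rest "recent" (ROH8); their
genome fractions F_ROH use a fixed autosome length of 2,489,385 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

#: autosomal genome length (kb) of the cattle reference assembly
GENOME_LENGTH_KB = 2_489_385.0

ROH2_8 = "ROH2_8"
ROH8 = "ROH8"


@dataclass
class RohParams:
    window_snps: int
    max_het_per_window: int = 1
    max_missing_per_window: int = 0
    window_hit_proportion: float = 0.05
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 100.0
    min_length_kb: float = 2000.0
    min_snps: int | None = None  # defaults to window_snps
    class_boundary_kb: float = 8000.0

    def __post_init__(self):
        if self.min_snps is None:
            self.min_snps = self.window_snps
        if not (0 < self.window_hit_proportion <= 1):
            raise ValueError("window_hit_proportion must be in (0, 1]")
        for name in ("window_snps", "max_gap_kb", "min_density_kb_per_snp",
                     "min_length_kb", "min_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_window_length(alpha: float, n_snps_per_indiv: int, n_indivs: int,
                          mean_het: float) -> int:
    """Window length L = ceil( ln(alpha/(n_s*n_i)) / ln(1 - mean_het) ).

    Caps the expected number of falsely homozygous windows genome-wide at
    ``alpha`` given the mean per-SNP heterozygosity.
    """
    if not (0 < mean_het < 1):
        raise ValueError("mean_het must lie strictly between 0 and 1")
    if n_snps_per_indiv <= 0 or n_indivs <= 0:
        raise ValueError("counts must be positive")
    L = math.ceil(math.log(alpha / (n_snps_per_indiv * n_indivs))
                  / math.log(1.0 - mean_het))
    return max(1, int(L))


def params_for_genotypes(geno: GenotypeMatrix, alpha: float = 0.05,
                         **overrides) -> RohParams:
    """ROH parameters with L computed from the data's mean heterozygosity."""
    het = (geno.codes == 1).mean()
    L = compute_window_length(alpha, geno.n_snps, geno.n_samples, float(het))
    return RohParams(window_snps=L, **overrides)


def _chrom_slices(snp_map: pd.DataFrame):
    chrom = snp_map["chrom"].to_numpy()
    bounds = np.flatnonzero(np.diff(chrom) != 0) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(chrom)]])
    return [(int(chrom[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def detect_roh(geno: GenotypeMatrix, params: RohParams) -> pd.DataFrame:
    """Detect ROH segments for every animal.

    Returns a DataFrame with columns animal_id, chrom, start_bp, end_bp
    (1-based inclusive), n_snps, length_kb, length_class.  Chromosomes with
    fewer SNPs than the window length yield no segments.
    """
    L = params.window_snps
    pos_all = geno.snp_map["pos_bp"].to_numpy()
    kernel = np.ones(L)
    out = []
    slices = _chrom_slices(geno.snp_map)
    for ai, animal in enumerate(geno.samples):
        row = geno.codes[ai]
        for chrom, a, b in slices:
            n = b - a
            if n < L:
                continue
            g = row[a:b]
            pos = pos_all[a:b]
            het = (g == 1).astype(np.float64)
            mis = (g == MISSING).astype(np.float64)
            hetc = np.convolve(het, kernel, "valid")
            misc = np.convolve(mis, kernel, "valid")
            ok = ((hetc <= params.max_het_per_window + 1e-9)
                  & (misc <= params.max_missing_per_window + 1e-9))
            cok = np.concatenate([[0], np.cumsum(ok)])
            idx = np.arange(n)
            lo = np.maximum(0, idx - L + 1)
            hi = np.minimum(n - L, idx)
            n_win = hi - lo + 1
            n_ok = cok[hi + 1] - cok[lo]
            elig = n_ok / n_win >= params.window_hit_proportion - 1e-12
            out.extend(_runs_to_segments(elig, pos, animal, chrom, params))
    return pd.DataFrame(out, columns=["animal_id", "chrom", "start_bp",
                                      "end_bp", "n_snps", "length_kb",
                                      "length_class"])


def _runs_to_segments(elig, pos, animal, chrom, params: RohParams):
    """Maximal eligible runs, gap-split and filtered to final segments."""
    segs = []
    n = len(elig)
    i = 0
    while i < n:
        if not elig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and elig[j + 1]:
            # split the run when the next eligible SNP is too far away
            if (pos[j + 1] - pos[j]) / 1000.0 > params.max_gap_kb:
                break
            j += 1
        n_snps = j - i + 1
        length_kb = (pos[j] - pos[i] + 1) / 1000.0
        if (length_kb >= params.min_length_kb
                and n_snps >= params.min_snps
                and length_kb / n_snps <= params.min_density_kb_per_snp):
            cls = ROH2_8 if length_kb < params.class_boundary_kb else ROH8
            segs.append((animal, chrom, int(pos[i]), int(pos[j]),
                         int(n_snps), float(length_kb), cls))
        i = j + 1
    return segs


@dataclass
class FrohResult:
    table: pd.DataFrame  # columns: animal, F_ROH2, F_ROH2_8, F_ROH8
    genome_length_kb: float


def froh(segments: pd.DataFrame, animals,
         genome_length_kb: float = GENOME_LENGTH_KB) -> FrohResult:
    """Per-animal genome fractions in ROH by length class.

    F_ROH2 is computed as the sum of the two class fractions so the partition
    identity F_ROH2 = F_ROH2_8 + F_ROH8 holds exactly.
    """
    tab = pd.DataFrame({"animal": list(animals)}).set_index("animal")
    for cls, col in ((ROH2_8, "F_ROH2_8"), (ROH8, "F_ROH8")):
        sub = segments[segments["length_class"] == cls]
        kb = sub.groupby("animal_id")["length_kb"].sum().astype(float)
        tab[col] = (kb.reindex(tab.index).astype(float).fillna(0.0)
                    / genome_length_kb)
    tab["F_ROH2"] = tab["F_ROH2_8"] + tab["F_ROH8"]
    tab = tab[["F_ROH2", "F_ROH2_8", "F_ROH8"]].reset_index()
    return FrohResult(tab, genome_length_kb)


def _segment_snp_spans(segments: pd.DataFrame, snp_map: pd.DataFrame):
    """Yield (animal_id, length_class, lo, hi) global SNP index spans
    (half-open) covered by each segment."""
    chrom_index = {}
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos_bp"].to_numpy()
    for chrom, a, b in _chrom_slices(snp_map):
        chrom_index[chrom] = (a, pos_arr[a:b])
    for r in segments.itertuples(index=False):
        if r.chrom not in chrom_index:
            continue
        off, pos = chrom_index[r.chrom]
        lo = int(np.searchsorted(pos, r.start_bp, side="left"))
        hi = int(np.searchsorted(pos, r.end_bp, side="right"))
        yield r.animal_id, r.length_class, off + lo, off + hi


def roh_state_matrix(segments: pd.DataFrame, geno: GenotypeMatrix,
                     length_class: str) -> np.ndarray:
    """Binary animals x SNPs matrix: 1 when the SNP lies inside a segment of
    the given length class (bp-inclusive on both ends)."""
    if length_class not in (ROH2_8, ROH8):
        raise ValueError(f"unknown length class {length_class!r}")
    H = np.zeros((geno.n_samples, geno.n_snps), dtype=np.int8)
    row = {s: i for i, s in enumerate(geno.samples)}
    for animal, cls, lo, hi in _segment_snp_spans(segments, geno.snp_map):
        if cls == length_class and animal in row:
            H[row[animal], lo:hi] = 1
    return H


def roh_islands(segments: pd.DataFrame, geno: GenotypeMatrix,
                freq_flag: float = 0.2) -> pd.DataFrame:
    """Per-SNP population frequency of overlapping ROH by length class.

    Frequency = animals whose segment of that class covers the SNP divided by
    the total number of animals; SNPs above ``freq_flag`` in either class (or
    in all classes combined) are flagged as ROH islands.
    """
    n = geno.n_samples
    out = geno.snp_map[["snp_id", "chrom", "pos_bp"]].copy()
    any_cov = np.zeros((n, geno.n_snps), dtype=bool)
    row = {s: i for i, s in enumerate(geno.samples)}
    for cls, col in ((ROH2_8, "freq_roh2_8"), (ROH8, "freq_roh8")):
        H = roh_state_matrix(segments, geno, cls)
        any_cov |= H.astype(bool)
        out[col] = H.sum(axis=0) / n
    out["freq_roh2"] = any_cov.sum(axis=0) / n
    out["island"] = ((out["freq_roh2_8"] > freq_flag)
                     | (out["freq_roh8"] > freq_flag))
    return out
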