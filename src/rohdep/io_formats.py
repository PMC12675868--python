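"""Readers and writers for the pipeline's tabular and PLINK-style formats.

Genotypes travel as a :class:`GenotypeMatrix`: an animals x SNPs matrix of
allele-B dosage codes (0/1/2, ``MISSING`` = -1) with an ordered SNP map over
autosomes.  Pedigrees and repeated-record phenotype tables are plain pandas
DataFrames with validated invariants.  All internal genomic coordinates are
1-based inclusive base pairs; BED export is the only 0-based surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
UNKNOWN = None  # unknown parent in a pedigree

#: canonical collection-interval classes (days between consecutive collections)
INTERVAL_CLASSES = ("≤3", "4", "5", "6", "≥7")

#: accepted aliases for interval-class labels in input files
INTERVAL_ALIASES = {
    "<=3": "≤3", "≤3": "≤3", "3-": "≤3", "le3": "≤3",
    "4": "4", "5": "5", "6": "6",
    ">=7": "≥7", "≥7": "≥7", "7+": "≥7", "ge7": "≥7",
}

TRAIT_NAMES = ("VOL", "NUM", "CON", "MOT", "aMOT")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def make_snp_map(snp_id, chrom, pos_bp, allele_a, allele_b,
                 n_autosomes: int = 29) -> pd.DataFrame:
    """Assemble and validate a SNP map table.

    Positions must be strictly increasing within each chromosome and
    chromosomes limited to the configured autosome count.
    """
    m = pd.DataFrame({
        "snp_id": np.asarray(snp_id, dtype=object),
        "chrom": np.asarray(chrom, dtype=np.int64),
        "pos_bp": np.asarray(pos_bp, dtype=np.int64),
        "allele_a": np.asarray(allele_a, dtype=object),
        "allele_b": np.asarray(allele_b, dtype=object),
    })
    validate_snp_map(m, n_autosomes=n_autosomes)
    return m


def validate_snp_map(m: pd.DataFrame, n_autosomes: int = 29) -> None:
    if m["snp_id"].duplicated().any():
        dup = m.loc[m["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"duplicate snp_id {dup!r}")
    bad = (m["chrom"] < 1) | (m["chrom"] > n_autosomes)
    if bad.any():
        raise ValidationError(
            f"chromosome outside 1..{n_autosomes} at SNP "
            f"{m.loc[bad, 'snp_id'].iloc[0]!r}")
    for c, grp in m.groupby("chrom", sort=False):
        d = np.diff(grp["pos_bp"].to_numpy())
        if (d <= 0).any():
            k = int(np.argmax(d <= 0)) + 1
            raise ValidationError(
                f"map not strictly increasing on chrom {c}: SNP "
                f"{grp['snp_id'].iloc[k]!r} at {grp['pos_bp'].iloc[k]}")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-B dosage codes with an ordered SNP map."""

    samples: list
    snp_map: pd.DataFrame
    codes: np.ndarray  # int8, values in {0,1,2,MISSING}

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snp_map)):
            raise ValidationError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snp_map)} SNPs")
        ok = np.isin(self.codes, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValidationError("genotype codes outside {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(self.samples,
                              self.snp_map.loc[keep_mask].reset_index(drop=True),
                              self.codes[:, keep_mask])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.snp_map,
                              self.codes[rows])


# ---------------------------------------------------------------------------
# PLINK text (ped/map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, allow_missing: bool = True,
                    n_autosomes: int = 29,
                    counted_alleles=None) -> GenotypeMatrix:
    """Read PLINK ped/map text files into a :class:`GenotypeMatrix`.

    Dosage counts copies of allele_b.  ``counted_alleles`` fixes allele_b per
    SNP explicitly; otherwise poling is lexicographic (the alphabetically
    later observed allele is counted, and a monomorphic SNP's lone allele is
    the counted one).  Poling is never frequency-based.  "0 0" pairs become
    MISSING.  An unsorted map is an error, never silently sorted.
    """
    map_rows = _read_whitespace_table(map_path, 4, "map")
    try:
        pos = [int(r[3]) for r in map_rows]
    except ValueError as e:
        raise FormatError(f"non-numeric bp position in {map_path}: {e}") from None
    try:
        chrom = [int(r[0]) for r in map_rows]
    except ValueError as e:
        raise FormatError(f"non-numeric chromosome in {map_path}: {e}") from None
    snp_id = [r[1] for r in map_rows]
    m = len(map_rows)

    samples, geno_alleles = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path} line {ln}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            samples.append(parts[1])
            geno_alleles.append(parts[6:])

    allele_a, allele_b = [], []
    codes = np.empty((len(samples), m), dtype=np.int8)
    for j in range(m):
        a1 = [row[2 * j] for row in geno_alleles]
        a2 = [row[2 * j + 1] for row in geno_alleles]
        observed = sorted({a for a in a1 + a2 if a != "0"})
        if len(observed) > 2:
            raise FormatError(f"SNP {snp_id[j]!r}: more than two alleles")
        if counted_alleles is not None:
            ab = counted_alleles[j]
            others = [a for a in observed if a != ab]
            aa = others[0] if others else "N"
        elif len(observed) == 2:
            aa, ab = observed
        elif len(observed) == 1:
            # monomorphic: the lone observed allele is the counted one
            aa, ab = "N", observed[0]
        else:
            aa, ab = "N", "N"
        allele_a.append(aa)
        allele_b.append(ab)
        for i in range(len(samples)):
            x, y = a1[i], a2[i]
            if x == "0" or y == "0":
                codes[i, j] = MISSING
            else:
                codes[i, j] = (x == ab) + (y == ab)

    snp_map = make_snp_map(snp_id, chrom, pos, allele_a, allele_b,
                           n_autosomes=n_autosomes)
    g = GenotypeMatrix(samples, snp_map, codes)
    if not allow_missing and g.has_missing():
        raise ValidationError("MISSING genotypes present but allow_missing=False")
    return g


def _read_whitespace_table(path, n_cols, what):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path} line {ln}: {what} rows need {n_cols} columns, "
                    f"got {len(parts)}")
            rows.append(parts)
    return rows


def write_plink_text(geno: GenotypeMatrix, prefix) -> None:
    """Write ped/map text files; monomorphic missing allele letters use 'N'."""
    prefix = Path(prefix)
    m = geno.snp_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in m.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\n")
    aa = m["allele_a"].to_numpy()
    ab = m["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(geno.samples):
            fields = [s, s, "0", "0", "0", "-9"]
            row = geno.codes[i]
            for j, c in enumerate(row):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [aa[j], aa[j]]
                elif c == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (bed/bim/fam), v1.9 SNP-major dialect
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit code -> dosage of allele_b (a2); 01 is the missing code
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink_binary(bed_path, bim_path, fam_path, allow_missing: bool = True,
                      n_autosomes: int = 29) -> GenotypeMatrix:
    """Read a SNP-major PLINK bed/bim/fam trio.

    Per-SNP bytes hold four samples, two bits each starting at the least
    significant pair: 00 = hom allele_a, 01 = missing, 10 = het,
    11 = hom allele_b.
    """
    bim = _read_whitespace_table(bim_path, 6, "bim")
    fam = _read_whitespace_table(fam_path, 6, "fam")
    samples = [r[1] for r in fam]
    try:
        snp_map = make_snp_map([r[1] for r in bim],
                               [int(r[0]) for r in bim],
                               [int(r[3]) for r in bim],
                               [r[4] for r in bim], [r[5] for r in bim],
                               n_autosomes=n_autosomes)
    except ValueError as e:
        if isinstance(e, ValidationError):
            raise
        raise FormatError(f"bad bim file {bim_path}: {e}") from None

    n, m = len(samples), len(snp_map)
    bytes_per_snp = (n + 3) // 4
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != 0x01:
        raise FormatError(f"{bed_path}: not SNP-major (mode byte != 0x01)")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}")
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit pairs, LSB first
    pairs = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)],
                     axis=2).reshape(m, bytes_per_snp * 4)[:, :n]
    codes = _BED_DECODE[pairs].T.copy()
    g = GenotypeMatrix(samples, snp_map, codes)
    if not allow_missing and g.has_missing():
        raise ValidationError("MISSING genotypes present but allow_missing=False")
    return g


def write_plink_binary(geno: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    m = geno.snp_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in m.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\t"
                     f"{r.allele_a}\t{r.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in geno.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    n = geno.n_samples
    bytes_per_snp = (n + 3) // 4
    enc = np.zeros((geno.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        lut[code % 4] = bits  # MISSING=-1 -> index 3
    enc[:, :n] = lut[geno.codes.T % 4]
    packed = (enc.reshape(geno.n_snps, bytes_per_snp, 4)
              * np.array([1, 4, 16, 64], dtype=np.uint8)).sum(
                  axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# pedigree and phenotype tables
# ---------------------------------------------------------------------------

def _norm_parent(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return None if s in ("0", "", "NA", ".") else s


def make_pedigree(records) -> pd.DataFrame:
    """Build a topologically ordered pedigree from (animal, sire, dam) triples.

    Unknown parents are None.  Raises on duplicate ids or cycles (the cycle is
    named in the error).  Input order is kept when already topological;
    otherwise rows are reordered parents-first.
    """
    ped = pd.DataFrame(records, columns=["animal", "sire", "dam"])
    ped["animal"] = ped["animal"].astype(str)
    ped["sire"] = ped["sire"].map(_norm_parent)
    ped["dam"] = ped["dam"].map(_norm_parent)
    if ped["animal"].duplicated().any():
        dup = ped.loc[ped["animal"].duplicated(), "animal"].iloc[0]
        raise ValidationError(f"duplicate animal id {dup!r}")
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order, state = [], {}

    def visit(a):  # iterative DFS with cycle detection
        stack = [(a, iter([p for p in parents.get(a, (None, None)) if p]))]
        state[a] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in parents:
                    continue  # parent outside table: treated as founder
                st = state.get(p, 0)
                if st == 1:
                    cyc = [n for n, _ in stack] + [p]
                    raise ValidationError(f"pedigree cycle: {' -> '.join(cyc)}")
                if st == 0:
                    state[p] = 1
                    stack.append((p, iter([q for q in parents[p] if q])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()

    for a in ped["animal"]:
        if state.get(a, 0) == 0:
            visit(a)
    pos = {a: i for i, a in enumerate(order)}
    ped = ped.iloc[np.argsort([pos[a] for a in ped["animal"]],
                              kind="stable")].reset_index(drop=True)
    return ped


def pedigree_indices(ped: pd.DataFrame):
    """Map a pedigree to integer sire/dam index arrays (-1 = unknown)."""
    idx = {a: i for i, a in enumerate(ped["animal"])}
    sire = np.array([idx.get(s, -1) if s else -1 for s in ped["sire"]],
                    dtype=np.int64)
    dam = np.array([idx.get(d, -1) if d else -1 for d in ped["dam"]],
                   dtype=np.int64)
    return idx, sire, dam


def normalize_interval_class(label) -> str:
    s = str(label).strip()
    if s not in INTERVAL_ALIASES:
        raise ValidationError(f"unknown collection-interval label {label!r}")
    return INTERVAL_ALIASES[s]


def make_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a repeated-records phenotype table.

    Required columns: animal, trait, value, cg, interval_class, age_months.
    One row per collection event.
    """
    need = {"animal", "trait", "value", "cg", "interval_class", "age_months"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
    out = df.copy()
    out["animal"] = out["animal"].astype(str)
    out["trait"] = out["trait"].astype(str)
    bad = ~out["trait"].isin(TRAIT_NAMES)
    if bad.any():
        raise ValidationError(
            f"unknown trait {out.loc[bad, 'trait'].iloc[0]!r}; "
            f"expected one of {TRAIT_NAMES}")
    out["cg"] = out["cg"].astype(str)
    out["interval_class"] = out["interval_class"].map(normalize_interval_class)
    out["value"] = out["value"].astype(float)
    out["age_months"] = out["age_months"].astype(float)
    if ((out["age_months"] <= 0) | (out["age_months"] > 200)).any():
        raise ValidationError("age_months must lie in (0, 200]")
    return out.reset_index(drop=True)


def read_tables(pedigree_path, phenotype_path):
    """Read pedigree and phenotype TSVs with headers; '0'/empty = unknown parent."""
    pdf = pd.read_csv(pedigree_path, sep="\t", dtype=str)
    ped = make_pedigree(pdf[["animal", "sire", "dam"]].itertuples(index=False))
    pheno = make_phenotype_table(pd.read_csv(phenotype_path, sep="\t"))
    return ped, pheno


def write_pedigree(ped: pd.DataFrame, path) -> None:
    out = ped.copy()
    out["sire"] = out["sire"].map(lambda s: s if s else "0")
    out["dam"] = out["dam"].map(lambda d: d if d else "0")
    out[["animal", "sire", "dam"]].to_csv(path, sep="\t", index=False)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage-output writers
# ---------------------------------------------------------------------------

F_COLUMNS = ["animal", "F_PED", "F_GRM", "F_ROH2", "F_ROH2_8", "F_ROH8", "F_HBD"]


def write_inbreeding(df: pd.DataFrame, path) -> None:
    """Per-animal inbreeding coefficients, fixed column order; absent
    coefficients are written as NA."""
    out = pd.DataFrame({"animal": df["animal"]})
    for c in F_COLUMNS[1:]:
        out[c] = df[c] if c in df.columns else np.nan
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_roh_segments(segments: pd.DataFrame, tsv_path, bed_path=None) -> None:
    """Segments as TSV (1-based inclusive) and optional BED (0-based half-open)."""
    cols = ["animal_id", "chrom", "start_bp", "end_bp", "n_snps",
            "length_kb", "length_class"]
    segments[cols].to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in segments.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                         f"{r.animal_id}_{r.length_class}\n")


GWAS_COLUMNS = ["snp_id", "chrom", "pos_bp", "n_carriers", "alpha",
                "beta_roh", "se", "z", "p"]


def write_gwas(rows: pd.DataFrame, path) -> None:
    out = rows[GWAS_COLUMNS] if len(rows) else pd.DataFrame(columns=GWAS_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


REGION_COLUMNS = ["trait", "length_class", "chrom", "start_bp", "end_bp",
                  "start_snp", "end_snp", "n_snp", "min_p", "tier"]


def write_regions(regions: pd.DataFrame, path) -> None:
    out = (regions[REGION_COLUMNS] if len(regions)
           else pd.DataFrame(columns=REGION_COLUMNS))
    out.to_csv(path, sep="\t", index=False)


def write_outputs(stage_result, out_dir) -> list:
    """Dispatch a stage result to its writer; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(stage_result, pd.DataFrame):
        cols = set(stage_result.columns)
        if {"start_bp", "end_bp", "length_class", "animal_id"} <= cols:
            tsv, bed = out_dir / "roh_segments.tsv", out_dir / "roh_segments.bed"
            write_roh_segments(stage_result, tsv, bed)
            written += [tsv, bed]
        elif "beta_roh" in cols:
            p = out_dir / "gwas.tsv"
            write_gwas(stage_result, p)
            written.append(p)
        elif "min_p" in cols or "tier" in cols:
            p = out_dir / "regions.tsv"
            write_regions(stage_result, p)
            written.append(p)
        elif "animal" in cols:
            p = out_dir / "inbreeding.tsv"
            write_inbreeding(stage_result, p)
            written.append(p)
        else:
            raise ValueError("unrecognized stage result columns")
    else:
        raise ValueError(f"unsupported stage result type {type(stage_result)}")
    return written
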