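"""Genomic I/O and site-table assembly.

Reads reference FASTA, BED region sets, and variant tables (VCF or TSV);
applies the neutral-model site filters (CpG removal, minimum coverage,
whole-site exclusion of common variants); and assembles the per-site,
per-alternative-allele ``SiteTable`` that every downstream module consumes.

Coordinates are 0-based half-open internally; conversion to/from 1-based
VCF coordinates happens only at the I/O boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import DataIntegrityError, ParseError, SchemaError, ValidationError

NUCLEOTIDES = ("A", "C", "G", "T")

#: fixed column order of the per-(site, alt) table
SITE_TABLE_COLUMNS = [
    "chrom",
    "pos0",
    "ref",
    "alt",
    "context7",
    "Y",
    "common",
    "coverage",
    "gc_frac",
    "cpg_island",
    "excluded",
    "reason",
    "P",
]

#: half-width of the window used for fractional G+C content
GC_WINDOW = 200


def alt_alleles(ref: str) -> tuple[str, str, str]:
    """The three alternative alleles for ``ref``, in canonical
    (alphabetical) order."""
    return tuple(b for b in NUCLEOTIDES if b != ref)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Regions


@dataclass
class RegionSet:
    """A merged, sorted set of genomic intervals (0-based half-open)."""

    records: list[tuple[str, int, int]] = field(default_factory=list)
    label: str = ""

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], label: str = ""
    ) -> "RegionSet":
        """Validate, sort and merge overlapping/adjacent intervals."""
        ivals = list(intervals)
        for chrom, start, end in ivals:
            if start < 0:
                raise ValidationError(f"negative coordinate in {chrom}:{start}-{end}")
            if start >= end:
                raise ValidationError(f"empty/inverted interval {chrom}:{start}-{end}")
        ivals.sort()
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in ivals:
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, start, end))
        return cls(records=merged, label=label)

    def total_span(self) -> int:
        return sum(end - start for _, start, end in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def membership(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Boolean vector: does each (chrom, pos) fall inside the set?"""
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.records:
            by_chrom.setdefault(chrom, []).append((start, end))
        chrom_arr = np.asarray(chroms)
        for chrom, ivals in by_chrom.items():
            mask = chrom_arr == chrom
            if not mask.any():
                continue
            starts = np.array([s for s, _ in ivals])
            ends = np.array([e for _, e in ivals])
            pos = positions[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            out[mask] = inside
        return out


def read_regions(path: str, format: str = "BED", label: str = "") -> RegionSet:
    """Read a BED3+ file into a merged, sorted :class:`RegionSet`."""
    if format != "BED":
        raise ValidationError(f"unsupported region format: {format!r}")
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            intervals.append((fields[0], start, end))
    return RegionSet.from_intervals(intervals, label=label or path)


def write_regions(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Variants


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with its population alternate-allele frequency."""

    chrom: str
    pos0: int  # 0-based
    ref: str
    alt: str
    af: float
    coverage: float = float("nan")

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos0}"
                " (indels must be removed upstream)"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos0}")
        if not 0.0 <= self.af <= 1.0:
            raise ValidationError(
                f"allele frequency {self.af} outside [0,1] at {self.chrom}:{self.pos0}"
            )


def read_variants_vcf(
    path: str, af_field: str = "AF", coverage_field: str = "mean_dp"
) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF; multi-allelic records must be pre-split.

    AF is taken from INFO[``af_field``]; per-site mean coverage from
    INFO[``coverage_field``] when present (NaN otherwise).
    """
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for rec in VCF(path):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split upstream"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indels are rejected silently at parse time
        af = rec.INFO.get(af_field)
        if af is None:
            raise SchemaError(f"INFO field {af_field!r} missing at {rec.CHROM}:{rec.POS}")
        cov = rec.INFO.get(coverage_field)
        out.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos0=rec.POS - 1,
                ref=ref.upper(),
                alt=alt.upper(),
                af=float(af),
                coverage=float(cov) if cov is not None else float("nan"),
            )
        )
    return out


def read_variants_tsv(path: str) -> list[VariantRecord]:
    """Read variants from a headered TSV: chrom, pos0, ref, alt, af[, coverage]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos0", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    has_cov = "coverage" in df.columns
    return [
        VariantRecord(
            chrom=str(r.chrom),
            pos0=int(r.pos0),
            ref=str(r.ref),
            alt=str(r.alt),
            af=float(r.af),
            coverage=float(r.coverage) if has_cov else float("nan"),
        )
        for r in df.itertuples()
    ]


def read_coverage_tsv(path: str) -> pd.Series:
    """Per-site coverage TSV (chrom, pos0, coverage) -> Series keyed by (chrom, pos0)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos0", "coverage"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index(["chrom", "pos0"])["coverage"]


# ---------------------------------------------------------------------------
# SiteTable


class SiteTable:
    """Per-site, per-alternative-allele observations.

    Backed by a :class:`pandas.DataFrame` with one row per (site, alt),
    exactly three alt rows per site in alphabetical order. ``Y`` is the
    rare-variant indicator, ``common`` flags alleles at frequency above the
    rare cutoff (such sites are excluded wholesale), and ``P`` holds the
    per-allele neutral rare-variant probability once a mutation model has
    been applied.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"SiteTable missing columns {sorted(missing)}")
        unknown = set(df.columns) - set(SITE_TABLE_COLUMNS)
        if unknown:
            raise SchemaError(f"SiteTable unknown columns {sorted(unknown)}")
        self.df = df.reset_index(drop=True)[SITE_TABLE_COLUMNS]
        if validate:
            self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls) -> "SiteTable":
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _COLUMN_DTYPES.items()})
        return cls(df, validate=False)

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if len(df) % 3 != 0:
            raise ValidationError("row count not a multiple of 3 (one row per alt)")
        dup = df.duplicated(subset=["chrom", "pos0", "alt"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise SchemaError(
                f"duplicate (chrom,pos,alt) rows, e.g. "
                f"{first.chrom}:{first.pos0}:{first.alt}"
            )
        # canonical alt order per site
        grouped = df.groupby(["chrom", "pos0"], sort=False)
        sizes = grouped.size()
        if (sizes != 3).any():
            raise ValidationError("every site must carry exactly 3 alt rows")
        both = (df["Y"].fillna(0).astype(int) == 1) & (df["common"])
        if both.any():
            row = df.loc[both.idxmax()]
            raise ValidationError(
                f"rare and common both set at {row.chrom}:{row.pos0}:{row.alt}"
            )
        retained = df[~df["excluded"]]
        if retained["P"].notna().any():
            psum = retained.groupby(["chrom", "pos0"])["P"].sum()
            if (psum >= 1.0).any():
                raise ValidationError("sum of per-allele P >= 1 at some site")

    # -- views -------------------------------------------------------------

    @property
    def retained(self) -> pd.DataFrame:
        """Rows of sites that survive every filter."""
        return self.df[~self.df["excluded"]]

    @property
    def n_sites(self) -> int:
        """M: number of retained sites (not rows)."""
        return len(self.retained) // 3

    @property
    def n_rare(self) -> int:
        """R': total retained rare-variant indicators."""
        return int(self.retained["Y"].sum())

    def __len__(self) -> int:
        return len(self.df) // 3

    def copy(self) -> "SiteTable":
        return SiteTable(self.df.copy(), validate=False)

    # -- serialization -----------------------------------------------------

    def write(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str) -> "SiteTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "reason": str})
        if len(df) == 0:
            return cls.empty()
        for col, dtype in _COLUMN_DTYPES.items():
            if col in ("chrom", "ref", "alt", "context7", "reason"):
                df[col] = df[col].astype("string").fillna("").astype(str)
            else:
                df[col] = df[col].astype(dtype)
        return cls(df)


_COLUMN_DTYPES = {
    "chrom": str,
    "pos0": np.int64,
    "ref": str,
    "alt": str,
    "context7": str,
    "Y": np.int64,
    "common": bool,
    "coverage": np.float64,
    "gc_frac": np.float64,
    "cpg_island": bool,
    "excluded": bool,
    "reason": str,
    "P": np.float64,
}


def write_site_table(table: SiteTable, path: str) -> None:
    table.write(path)


def read_site_table(path: str) -> SiteTable:
    return SiteTable.read(path)


# ---------------------------------------------------------------------------
# Assembly


def build_site_table(
    reference: str | Fasta,
    regions: RegionSet,
    variants: Iterable[VariantRecord],
    cpg_islands: RegionSet | None = None,
    min_coverage: float = 20.0,
    rare_max_af: float = 0.001,
    coverage: float | Mapping | pd.Series = 30.0,
) -> SiteTable:
    """Assemble the filtered SiteTable over ``regions``.

    A site is excluded (with a reason code) when its reference base or 7-mer
    context contains a non-ACGT character (``context``), when it is part of
    a CpG dinucleotide on either strand (``CpG``), when coverage is below
    ``min_coverage`` (``low_coverage``), or when any alternate allele
    reaches frequency >= ``rare_max_af`` (``common``: the whole site is
    dropped from the likelihood). At retained sites ``Y`` is 1 for alleles
    observed at 0 < AF < ``rare_max_af``.

    ``coverage`` may be a scalar applied everywhere, or a mapping / Series
    keyed by ``(chrom, pos0)``; per-variant coverage from the variant table
    overrides it at the variant's site.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))

    # index variants by site
    var_by_site: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        var_by_site.setdefault((v.chrom, v.pos0), []).append(v)

    cov_lookup = None
    if isinstance(coverage, pd.Series):
        cov_lookup = coverage.to_dict()
    elif isinstance(coverage, Mapping):
        cov_lookup = dict(coverage)

    site_frames = []
    for chrom, start, end in regions:
        if chrom not in fasta:
            raise ValidationError(f"region chromosome {chrom!r} not in reference")
        chrom_len = len(fasta[chrom])
        if end > chrom_len:
            raise ValidationError(
                f"region {chrom}:{start}-{end} outside contig (length {chrom_len})"
            )
        pad = max(3, GC_WINDOW // 2)
        lo = max(0, start - pad)
        hi = min(chrom_len, end + pad)
        seq = str(fasta[chrom][lo:hi]).upper()
        site_frames.append(
            _assemble_region(
                chrom, start, end, seq, lo, chrom_len, var_by_site, cov_lookup,
                coverage, cpg_islands, min_coverage, rare_max_af,
            )
        )
    if not site_frames:
        return SiteTable.empty()
    df = pd.concat(site_frames, ignore_index=True)
    return SiteTable(df)


def _assemble_region(
    chrom: str,
    start: int,
    end: int,
    seq: str,
    seq_offset: int,
    chrom_len: int,
    var_by_site: dict,
    cov_lookup: dict | None,
    coverage_default,
    cpg_islands: RegionSet | None,
    min_coverage: float,
    rare_max_af: float,
) -> pd.DataFrame:
    n = end - start
    positions = np.arange(start, end)
    seq_arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (seq_arr == b"G") | (seq_arr == b"C")

    # G+C fraction in a GC_WINDOW bp window (clipped at contig ends)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    half = GC_WINDOW // 2
    w_lo = np.clip(positions - half, 0, chrom_len) - seq_offset
    w_hi = np.clip(positions + half, 0, chrom_len) - seq_offset
    w_lo = np.clip(w_lo, 0, len(seq))
    w_hi = np.clip(w_hi, 0, len(seq))
    width = np.maximum(w_hi - w_lo, 1)
    gc_frac = (cum[w_hi] - cum[w_lo]) / width

    rel = positions - seq_offset
    refs = [seq[r] for r in rel]
    contexts = []
    for p, r in zip(positions, rel):
        if p - 3 < 0 or p + 4 > chrom_len:
            contexts.append("")
        else:
            contexts.append(seq[r - 3 : r + 4])

    # CpG on either strand
    cpg = np.zeros(n, dtype=bool)
    for k, (p, r) in enumerate(zip(positions, rel)):
        b = refs[k]
        if b == "C" and r + 1 < len(seq) and seq[r + 1] == "G":
            cpg[k] = True
        elif b == "G" and r - 1 >= 0 and seq[r - 1] == "C":
            cpg[k] = True

    if cpg_islands is not None and len(cpg_islands) > 0:
        island = cpg_islands.membership([chrom] * n, positions)
    else:
        island = np.zeros(n, dtype=bool)

    rows: dict[str, list] = {c: [] for c in SITE_TABLE_COLUMNS}
    for k in range(n):
        pos = int(positions[k])
        ref = refs[k]
        ctx = contexts[k]
        site_vars = var_by_site.get((chrom, pos), [])
        cov = float(coverage_default) if cov_lookup is None else float(
            cov_lookup.get((chrom, pos), coverage_default)
        )
        af_by_alt: dict[str, float] = {}
        for v in site_vars:
            if v.ref != ref:
                raise DataIntegrityError(
                    f"variant REF {v.ref} != reference base {ref} at {chrom}:{pos}"
                )
            af_by_alt[v.alt] = v.af
            if np.isfinite(v.coverage):
                cov = v.coverage

        bad_ctx = ref not in NUCLEOTIDES or len(ctx) != 7 or any(
            c not in NUCLEOTIDES for c in ctx
        )
        if bad_ctx:
            reason = "context"
        elif cpg[k]:
            reason = "CpG"
        elif cov < min_coverage:
            reason = "low_coverage"
        elif any(af >= rare_max_af for af in af_by_alt.values()):
            reason = "common"
        else:
            reason = ""
        excluded = reason != ""

        alts = alt_alleles(ref) if ref in NUCLEOTIDES else ("A", "C", "G")
        for alt in alts:
            af = af_by_alt.get(alt, 0.0)
            rows["chrom"].append(chrom)
            rows["pos0"].append(pos)
            rows["ref"].append(ref)
            rows["alt"].append(alt)
            rows["context7"].append(ctx if not bad_ctx else "")
            rows["Y"].append(int(0.0 < af < rare_max_af) if not excluded else 0)
            rows["common"].append(af >= rare_max_af)
            rows["coverage"].append(cov)
            rows["gc_frac"].append(float(gc_frac[k]))
            rows["cpg_island"].append(bool(island[k]))
            rows["excluded"].append(excluded)
            rows["reason"].append(reason)
            rows["P"].append(np.nan)
    df = pd.DataFrame(rows)
    for col, dtype in _COLUMN_DTYPES.items():
        if col not in ("chrom", "ref", "alt", "context7", "reason"):
            df[col] = df[col].astype(dtype)
    return df


def all_contexts() -> list[str]:
    """All 4^7 heptamer contexts in lexicographic order."""
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=7)]
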