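"""Synthetic genomic inputs and their plain-text file formats.

Generators for every data kind the framework consumes — SNP genotype profiles,
STR profiles with Mendelian father/mother/child trios, and small string-record
tables for linkage — plus simple tab/comma-separated readers and writers so
every pipeline stage is testable without external downloads.

The generators model exactly what the cryptographic pipeline needs and no
more: genotypes are independent binomial draws from a minor-allele frequency
(no linkage disequilibrium or population structure), STR alleles are uniform
integer repeat counts, and a child inherits one uniformly chosen allele per
locus from each parent, which guarantees at least one shared allele with each
true parent at every locus.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


DEFAULT_ALLELE_RANGE = (5, 50)
DEFAULT_K = 13


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class SNPProfile:
    """Biallelic SNP genotypes coded as minor-allele counts in {0,1,2}."""

    individual_id: str
    variant_ids: list
    chromosomes: list
    positions: list
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int64)
        if np.any((g < 0) | (g > 2)):
            raise FormatError("genotypes must be in {0,1,2}")
        if not (len(self.variant_ids) == len(self.chromosomes) == len(self.positions) == len(g)):
            raise FormatError("SNP profile columns must have equal length")
        self.genotypes = g

    def __len__(self) -> int:
        return len(self.genotypes)


@dataclass
class STRProfile:
    """Per-locus allele pairs (integer repeat counts), 13-20 core loci."""

    individual_id: str
    loci: tuple
    alleles: dict  # locus name -> (a1, a2)
    allele_range: tuple = DEFAULT_ALLELE_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.allele_range
        for name in self.loci:
            if name not in self.alleles:
                raise FormatError(f"missing alleles for locus {name!r}")
            a1, a2 = self.alleles[name]
            if not (lo <= a1 <= hi and lo <= a2 <= hi):
                raise FormatError(
                    f"allele repeat counts at {name!r} outside [{lo}, {hi}]"
                )

    def lanes(self) -> tuple:
        """Two slot-aligned allele vectors in locus order."""
        a1 = np.array([self.alleles[x][0] for x in self.loci], dtype=np.int64)
        a2 = np.array([self.alleles[x][1] for x in self.loci], dtype=np.int64)
        return a1, a2


@dataclass
class RecordTable:
    """Rows of string fields over a declared alphabet (for linkage)."""

    fields: list
    rows: list  # list of tuples of str

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.fields):
                raise FormatError(f"row {i} has {len(row)} fields, expected {len(self.fields)}")
            if any(not f for f in row):
                raise FormatError(f"row {i} contains an empty field")

    def joined(self, idx: int, sep: str = " ") -> str:
        return sep.join(self.rows[idx])


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def default_locus_names(K: int = DEFAULT_K) -> tuple:
    return tuple(f"locus_{i + 1:02d}" for i in range(K))


def gen_snp_profiles(
    n_individuals: int,
    n_snps: int,
    maf,
    rng: np.random.Generator,
    id_prefix: str = "IND",
) -> list:
    """Independent binomial(2, maf) genotypes per variant; seed-reproducible."""
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
    variant_ids = [f"rs{100000 + j}" for j in range(n_snps)]
    chroms = [str(1 + (j % 22)) for j in range(n_snps)]
    positions = [10_000 + 137 * j for j in range(n_snps)]
    out = []
    for i in range(n_individuals):
        g = rng.binomial(2, maf).astype(np.int64)
        out.append(
            SNPProfile(f"{id_prefix}{i:04d}", list(variant_ids), list(chroms), list(positions), g)
        )
    return out


def gen_str_population(
    n_individuals: int,
    K: int = DEFAULT_K,
    allele_range: tuple = DEFAULT_ALLELE_RANGE,
    rng: np.random.Generator | None = None,
    locus_names: Sequence[str] | None = None,
    id_prefix: str = "STR",
) -> list:
    """Unrelated individuals with uniform integer repeat counts per locus."""
    if rng is None:
        raise ValueError("rng is required")
    loci = tuple(locus_names) if locus_names else default_locus_names(K)
    if len(loci) != K:
        raise ValueError("locus_names must have length K")
    lo, hi = allele_range
    out = []
    for i in range(n_individuals):
        alleles = {
            name: (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
            for name in loci
        }
        out.append(STRProfile(f"{id_prefix}{i:04d}", loci, alleles, allele_range))
    return out


def gen_child(
    mother: STRProfile,
    father: STRProfile,
    rng: np.random.Generator,
    child_id: str = "CHILD",
) -> STRProfile:
    """Mendelian child: one uniformly chosen allele per locus from each parent."""
    if mother.loci != father.loci:
        raise ValueError("parent profiles cover different loci")
    alleles = {}
    for name in mother.loci:
        m = mother.alleles[name][int(rng.integers(0, 2))]
        f = father.alleles[name][int(rng.integers(0, 2))]
        alleles[name] = (m, f)
    return STRProfile(child_id, mother.loci, alleles, mother.allele_range)


def gen_record_pairs(
    n_pairs: int,
    typo_rate: float,
    rng: np.random.Generator,
    field_names: Sequence[str] = ("given", "family"),
    field_len: int = 7,
    alphabet: str = string.ascii_lowercase,
    match_fraction: float = 0.5,
) -> tuple:
    """Two record tables plus ground-truth match labels.

    Row i of table B refers to the same individual as row i of table A with
    probability ``match_fraction``; matched rows differ by independent
    per-character substitutions at ``typo_rate``, unmatched rows are drawn
    independently.
    """
    if not (0 <= typo_rate < 1):
        raise ValueError("typo_rate must lie in [0, 1)")

    def rand_field() -> str:
        return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), field_len))

    def corrupt(s: str) -> str:
        out = []
        for ch in s:
            if rng.random() < typo_rate:
                out.append(alphabet[int(rng.integers(0, len(alphabet)))])
            else:
                out.append(ch)
        return "".join(out)

    rows_a, rows_b, labels = [], [], []
    for _ in range(n_pairs):
        row_a = tuple(rand_field() for _ in field_names)
        is_match = bool(rng.random() < match_fraction)
        if is_match:
            row_b = tuple(corrupt(f) for f in row_a)
        else:
            row_b = tuple(rand_field() for _ in field_names)
        rows_a.append(row_a)
        rows_b.append(row_b)
        labels.append(is_match)
    return (
        RecordTable(list(field_names), rows_a),
        RecordTable(list(field_names), rows_b),
        labels,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_SNP_HEADER = ["variant_id", "chromosome", "position", "genotype"]
_STR_HEADER = ["locus", "allele1", "allele2"]


def write_snp_tsv(profile: SNPProfile, path) -> None:
    lines = [f"# SNP profile for {profile.individual_id}", "\t".join(_SNP_HEADER)]
    for vid, ch, pos, g in zip(
        profile.variant_ids, profile.chromosomes, profile.positions, profile.genotypes
    ):
        lines.append(f"{vid}\t{ch}\t{pos}\t{int(g)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_tsv(path, individual_id: str | None = None) -> SNPProfile:
    vids, chs, poss, gts = [], [], [], []
    header_seen = False
    name = individual_id or Path(path).stem
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "profile for" in line:
                name = individual_id or line.split("profile for", 1)[1].strip()
            continue
        cols = line.split("\t")
        if not header_seen:
            if cols != _SNP_HEADER:
                raise FormatError(f"{path}:{lineno}: expected header {_SNP_HEADER}, got {cols}")
            header_seen = True
            continue
        if len(cols) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
        try:
            g = int(cols[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: genotype {cols[3]!r} is not an integer")
        if g not in (0, 1, 2):
            raise FormatError(f"{path}:{lineno}: genotype {g} outside {{0,1,2}}")
        try:
            pos = int(cols[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: position {cols[2]!r} is not an integer")
        vids.append(cols[0])
        chs.append(cols[1])
        poss.append(pos)
        gts.append(g)
    if not header_seen:
        raise FormatError(f"{path}: missing header line")
    return SNPProfile(name, vids, chs, poss, np.array(gts, dtype=np.int64))


def write_str_csv(profile: STRProfile, path) -> None:
    lines = [f"# STR profile for {profile.individual_id}", ",".join(_STR_HEADER)]
    for name in profile.loci:
        a1, a2 = profile.alleles[name]
        lines.append(f"{name},{a1},{a2}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_str_csv(
    path,
    individual_id: str | None = None,
    allele_range: tuple = DEFAULT_ALLELE_RANGE,
) -> STRProfile:
    loci, alleles = [], {}
    header_seen = False
    name = individual_id or Path(path).stem
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "profile for" in line:
                name = individual_id or line.split("profile for", 1)[1].strip()
            continue
        cols = line.split(",")
        if not header_seen:
            if cols != _STR_HEADER:
                raise FormatError(f"{path}:{lineno}: expected header {_STR_HEADER}, got {cols}")
            header_seen = True
            continue
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected columns locus,allele1,allele2")
        try:
            a1, a2 = int(cols[1]), int(cols[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: allele repeat counts must be integers")
        lo, hi = allele_range
        if not (lo <= a1 <= hi and lo <= a2 <= hi):
            raise FormatError(f"{path}:{lineno}: allele outside [{lo}, {hi}]")
        loci.append(cols[0])
        alleles[cols[0]] = (a1, a2)
    if not header_seen:
        raise FormatError(f"{path}: missing header line")
    return STRProfile(name, tuple(loci), alleles, allele_range)


def write_records_csv(table: RecordTable, path) -> None:
    lines = [",".join(table.fields)]
    for row in table.rows:
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_records_csv(path) -> RecordTable:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty record table")
    fields = lines[0].split(",")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = tuple(line.split(","))
        if len(cols) != len(fields):
            raise FormatError(f"{path}:{lineno}: expected {len(fields)} fields, got {len(cols)}")
        rows.append(cols)
    return RecordTable(fields, rows)
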