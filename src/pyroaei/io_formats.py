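"""Readers, writers and configuration for every external format the pipeline touches.

No science lives here.  Formats:

* measurement TSV — one pyrosequencing allele-quantification row per
  (sample, gene, tissue, material) with the percent of each allele;
* REBASE-like restriction enzyme tables (``MseI  T^TAA`` or ``BceAI ACGGC(12/14)``);
* JASPAR position-frequency-matrix files (parsed with Bio.motifs);
* FASTA (Bio.SeqIO, wrapped at 60 columns) and 0-based half-open BED.

Positions written to BED are 0-based half-open; positions in human-readable
reports are 1-based (TSS-relative where applicable) and say so in the header.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._sequence import IUPAC, is_iupac
from .errors import FormatError, ValidationError

logger = logging.getLogger("pyroaei")

MEASUREMENT_COLUMNS = ["sample_id", "gene", "tissue", "material", "pct_a", "pct_b"]
MATERIALS = ("gDNA", "cDNA")

#: Tolerance on pct_a + pct_b == 100 for a valid measurement row.
PCT_SUM_TOL = 0.1


# ---------------------------------------------------------------------------
# measurement table
# ---------------------------------------------------------------------------

@dataclass
class MeasurementTable:
    """Validated table of pyrosequencing allele-percentage measurements.

    Each row reports the percent of allele A and allele B incorporated at the
    marker cSNP for one sample/gene/tissue/material.  The percent pair is
    stored (not a single number) so monoallelic 100/0 rows stay explicit.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_measurements(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def gdna(self, gene: str | None = None) -> pd.DataFrame:
        sub = self.df[self.df["material"] == "gDNA"]
        return sub if gene is None else sub[sub["gene"] == gene]

    def cdna(self, gene: str | None = None, tissue: str | None = None) -> pd.DataFrame:
        sub = self.df[self.df["material"] == "cDNA"]
        if gene is not None:
            sub = sub[sub["gene"] == gene]
        if tissue is not None:
            sub = sub[sub["tissue"] == tissue]
        return sub

    @classmethod
    def concat(cls, tables: Iterable["MeasurementTable"]) -> "MeasurementTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def validate_measurements(df: pd.DataFrame) -> None:
    """Raise with row-numbered diagnostics if any invariant fails.

    Row numbers refer to 1-based data rows (header excluded).
    """
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"measurement table is missing column {col!r}")
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 1
        if row["material"] not in MATERIALS:
            problems.append(f"row {rowno}: material {row['material']!r} not in {MATERIALS}")
            continue
        a, b = float(row["pct_a"]), float(row["pct_b"])
        if not (0.0 <= a <= 100.0 and 0.0 <= b <= 100.0):
            problems.append(f"row {rowno}: percentages ({a}, {b}) outside [0, 100]")
        elif abs(a + b - 100.0) > PCT_SUM_TOL:
            problems.append(f"row {rowno}: pct_a + pct_b = {a + b:g} deviates from 100 by more than {PCT_SUM_TOL}")
    key = df[["sample_id", "gene", "tissue", "material"]].astype(str)
    dup = key.duplicated()
    for i in np.flatnonzero(dup.to_numpy()):
        problems.append(f"row {i + 1}: duplicate (sample_id, gene, tissue, material) key")
    if problems:
        raise ValidationError("invalid measurement table:\n" + "\n".join(problems))


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read a tab-separated measurement table; invalid rows raise with diagnostics."""
    df = pd.read_csv(path, sep="\t")
    table = MeasurementTable(df)
    logger.info("read_measurements: %d rows from %s", len(table), path)
    return table


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    logger.info("write_measurements: %d rows to %s", len(table), path)


# ---------------------------------------------------------------------------
# restriction enzymes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeRecord:
    """One restriction endonuclease: IUPAC recognition site and cut offsets.

    ``cut_offset_top``/``cut_offset_bottom`` are 0-based offsets of the cut
    from the site start on the top strand (REBASE convention; values beyond
    the site length describe enzymes cutting distal to their site).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if not is_iupac(self.recognition):
            raise FormatError(f"{self.name}: recognition {self.recognition!r} is not IUPAC")
        lo, hi = -20, len(self.recognition) + 20
        for off in (self.cut_offset_top, self.cut_offset_bottom):
            if not lo <= off <= hi:
                raise ValidationError(f"{self.name}: cut offset {off} outside [{lo}, {hi}]")

    @property
    def is_palindromic(self) -> bool:
        from ._sequence import revcomp

        return revcomp(self.recognition) == self.recognition

    def __len__(self) -> int:
        return len(self.recognition)


def parse_enzyme_line(line: str) -> EnzymeRecord:
    """Parse ``NAME  SI^TE`` or ``NAME  SITE(t/b)`` into an EnzymeRecord.

    A caret marks the top-strand cut inside the site; the bottom cut defaults
    to the mirror position (len - top), which is the REBASE convention for
    sites written this way.  ``(t/b)`` gives explicit top/bottom offsets 3' of
    the site end.
    """
    parts = line.split()
    if len(parts) != 2:
        raise FormatError(f"cannot parse enzyme line {line!r}")
    name, site = parts
    if "^" in site:
        if site.count("^") != 1:
            raise FormatError(f"{name}: more than one caret in {site!r}")
        top = site.index("^")
        recognition = site.replace("^", "")
        bottom = len(recognition) - top
    elif "(" in site and site.endswith(")"):
        recognition, offsets = site[:-1].split("(", 1)
        try:
            t, b = (int(x) for x in offsets.split("/"))
        except ValueError as exc:
            raise FormatError(f"{name}: bad cut offsets in {site!r}") from exc
        top = len(recognition) + t
        bottom = len(recognition) + b
    else:
        raise FormatError(f"{name}: no cut position in {site!r}")
    if not is_iupac(recognition):
        raise FormatError(f"{name}: non-IUPAC character in recognition {recognition!r}")
    return EnzymeRecord(name, recognition, top, bottom)


def read_enzyme_table(path: str | Path) -> list[EnzymeRecord]:
    """Read a REBASE-like enzyme list (one ``name  site`` pair per line)."""
    records = _parse_enzyme_text(Path(path).read_text())
    if not records:
        logger.warning("read_enzyme_table: %s contained no enzymes", path)
    return records


def _parse_enzyme_text(text: str) -> list[EnzymeRecord]:
    records = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            records.append(parse_enzyme_line(line))
    return records


#: Every enzyme used by the study's RFLP / forced-RFLP assays, as a built-in
#: fixture so tests and examples run download-free.  Users may override with
#: read_enzyme_table on their own file.
BUILTIN_ENZYME_TABLE = """\
# name  recognition (caret = top-strand cut; (t/b) = offsets 3' of site)
AciI    C^CGC
AluI    AG^CT
AvaI    C^YCGRG
AvaII   G^GWCC
BaeGI   GKGCM^C
BccI    CCATC(4/5)
BceAI   ACGGC(12/14)
DdeI    C^TNAG
EarI    CTCTTC(1/4)
EcoRI   G^AATTC
HaeIII  GG^CC
HhaI    GCG^C
HinfI   G^ANTC
Kpn2I   T^CCGGA
MseI    T^TAA
MspI    C^CGG
NlaIII  CATG^
PagI    T^CATGA
PvuII   CAG^CTG
RsaI    GT^AC
SspI    AAT^ATT
"""


@lru_cache(maxsize=1)
def builtin_enzymes() -> dict[str, EnzymeRecord]:
    return {e.name: e for e in _parse_enzyme_text(BUILTIN_ENZYME_TABLE)}


def get_enzyme(name: str) -> EnzymeRecord:
    try:
        return builtin_enzymes()[name]
    except KeyError:
        raise KeyError(f"enzyme {name!r} not in built-in table; load it with read_enzyme_table") from None


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pwm:
    """Position frequency matrix, rows A/C/G/T, one column per motif position."""

    id: str
    counts: np.ndarray  # shape (4, length), non-negative
    source: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise FormatError(f"PWM {self.id}: counts must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise FormatError(f"PWM {self.id}: negative counts")

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        from ._sequence import BASES

        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def read_pwms(path: str | Path) -> list[Pwm]:
    """Read JASPAR-style PFM blocks into Pwm objects."""
    try:
        with open(path) as fh:
            parsed = motifs.parse(fh, "jaspar")
    except Exception as exc:  # Bio raises bare Exceptions on ragged input
        raise FormatError(f"cannot parse JASPAR file {path}: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        out.append(Pwm(id=m.matrix_id or m.name, counts=counts, source="jaspar"))
    logger.info("read_pwms: %d motifs from %s", len(out), path)
    return out


def pwm_from_consensus(pwm_id: str, consensus: str, weight: float = 20.0, background: float = 1.0) -> Pwm:
    """Build a sharp PFM whose maximum-scoring word is the given IUPAC consensus."""
    if not is_iupac(consensus):
        raise FormatError(f"consensus {consensus!r} is not IUPAC")
    counts = np.full((4, len(consensus)), background)
    for j, code in enumerate(consensus):
        allowed = IUPAC[code]
        for b in allowed:
            counts["ACGT".index(b), j] += weight / len(allowed)
    return Pwm(id=pwm_id, counts=counts, source="consensus")


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED.

    Coordinates are 0-based half-open, as everywhere BED is involved.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            fields = list(iv[:6])
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            row = [f[0], int(f[1]), int(f[2])] + f[3:]
            out.append(tuple(row))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat key/value configuration; defaults encode the study's thresholds.

    imbalance_threshold_pct: majority-allele percent at or above which a
        standardized cDNA sample is called imbalanced (60 => the 60:40 rule).
    min_het_fraction: minimum heterozygote fraction for a gene to enter the
        expression analysis (0.125 => 5 of 40 animals).
    """

    seed: int = 0
    imbalance_threshold_pct: float = 60.0
    min_het_fraction: float = 0.125
    island_min_len: int = 200
    island_min_gc: float = 0.5
    island_min_oe: float = 0.6
    pwm_score_fraction: float = 0.8
    gdna_qc_max_deviation_pct: float = 10.0

    def __post_init__(self) -> None:
        if not 50.0 < self.imbalance_threshold_pct <= 100.0:
            raise ValidationError("imbalance_threshold_pct must be in (50, 100]")
        if not 0.0 < self.min_het_fraction <= 1.0:
            raise ValidationError("min_het_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
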