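"""Probe-set genomic annotations and cis/trans locus classification.

A congenic strain carries a single donor-derived (introgressed) interval on an
otherwise identical genetic background, so any expression difference between
the congenic and background strains must arise either from sequence variation
inside that interval (*cis*) or from a regulator inside the interval acting on
a gene elsewhere (*trans*).  This module holds the genomic placement of each
probe set and partitions the probe-set universe accordingly:

* ``cis`` — the probe set's anchor position lies inside the introgressed
  interval (both bounds inclusive);
* ``trans`` — the probe set is placed anywhere else in the genome, including
  the same chromosome outside the interval;
* ``unplaced`` — no genomic placement is available (e.g. an EST aligning to
  multiple loci); such probe sets belong to neither multiple-testing family.

Coordinates are 1-based and inclusive on both ends.  Each probe set is
represented by a single anchor position (its alignment start), which avoids
ambiguity for targets straddling an interval boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CIS",
    "TRANS",
    "UNPLACED",
    "DEFAULT_INTERVAL",
    "GenomicInterval",
    "ProbeSetAnnotation",
    "classify_locus",
    "classify_table",
    "normalize_chromosome",
    "read_annotations",
    "write_annotations",
]

#: Locus classes. Plain strings so they survive round-trips through DataFrames
#: and TSV files unchanged.
CIS = "cis"
TRANS = "trans"
UNPLACED = "unplaced"


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label for comparison.

    Comparison is case-insensitive and tolerates an optional ``chr`` prefix,
    so ``"chr4"``, ``"Chr4"`` and ``"4"`` all denote the same chromosome.
    """
    s = str(label).strip().lower()
    if s.startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based and inclusive on both ends."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) must be >= start ({self.start})"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            normalize_chromosome(chromosome) == normalize_chromosome(self.chromosome)
            and self.start <= position <= self.end
        )

    def __str__(self) -> str:  # "4:29413686-128186835"
        return f"{self.chromosome}:{self.start}-{self.end}"

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (e.g. ``4:29413686-128186835``)."""
        try:
            chrom, rest = text.split(":")
            start, end = rest.split("-")
            return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))
        except (ValueError, AttributeError) as exc:
            raise ValidationError(f"cannot parse interval {text!r}; expected chrom:start-end") from exc


#: The introgressed alcohol-preference QTL interval on rat chromosome 4,
#: spanning the microsatellite markers flanking the transferred segment.
DEFAULT_INTERVAL = GenomicInterval("4", 29_413_686, 128_186_835)


@dataclass(frozen=True)
class ProbeSetAnnotation:
    """Genomic placement of one probe set (anchor position of its alignment)."""

    probe_set_id: str
    chromosome: Optional[str] = None
    position: Optional[int] = None
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position is not None and self.chromosome is None:
            raise ValidationError(
                f"{self.probe_set_id}: position given without a chromosome"
            )

    @property
    def placed(self) -> bool:
        return self.chromosome is not None and self.position is not None


def classify_locus(ann: ProbeSetAnnotation, interval: GenomicInterval = DEFAULT_INTERVAL) -> str:
    """Classify one probe set as ``cis``, ``trans`` or ``unplaced``.

    ``cis`` iff the anchor position lies inside *interval* (inclusive bounds);
    ``trans`` iff placed anywhere else, including the interval's chromosome
    outside the interval; ``unplaced`` iff chromosome or position is absent.
    """
    if not ann.placed:
        return UNPLACED
    if interval.contains(ann.chromosome, ann.position):
        return CIS
    return TRANS


def classify_table(
    annotations: Iterable[ProbeSetAnnotation],
    interval: GenomicInterval = DEFAULT_INTERVAL,
) -> pd.Series:
    """Classify a whole annotation set.

    Returns a Series indexed by probe_set_id with values in
    ``{cis, trans, unplaced}``.  The three classes are disjoint and exhaustive.
    """
    anns = list(annotations)
    ids = [a.probe_set_id for a in anns]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate probe_set_id(s) in annotation set: {dupes}")
    return pd.Series(
        [classify_locus(a, interval) for a in anns], index=pd.Index(ids, name="probe_set_id"),
        name="locus_class",
    )


_COLUMNS = ["probe_set_id", "chromosome", "position", "gene_symbol"]


def read_annotations(path) -> list[ProbeSetAnnotation]:
    """Read probe-set annotations from a tab-separated file.

    The file must carry the header ``probe_set_id  chromosome  position
    gene_symbol``; empty cells mean "absent".  Duplicate probe_set_id values
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str, "chromosome": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    dupes = df["probe_set_id"][df["probe_set_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate probe_set_id(s) {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        chrom = None if pd.isna(row.chromosome) else str(row.chromosome)
        pos = None if pd.isna(row.position) else int(row.position)
        sym = None if pd.isna(row.gene_symbol) else str(row.gene_symbol)
        out.append(ProbeSetAnnotation(str(row.probe_set_id), chrom, pos, sym))
    return out


def write_annotations(annotations: Iterable[ProbeSetAnnotation], path) -> None:
    """Write annotations in the dialect read by :func:`read_annotations`."""
    rows = [
        {
            "probe_set_id": a.probe_set_id,
            "chromosome": "" if a.chromosome is None else a.chromosome,
            "position": "" if a.position is None else a.position,
            "gene_symbol": "" if a.gene_symbol is None else a.gene_symbol,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(Path(path), sep="\t", index=False)
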