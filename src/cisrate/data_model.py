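"""Core data types, coordinate conventions, dataset I/O and cohort handling.

Coordinate convention (iAUG-anchored, used throughout the package):

* the A of the initiating AUG is position ``+1`` (U = ``+2``, G = ``+3``),
* the nucleotide immediately 5' of the iAUG is ``-1``,
* there is **no position 0**,
* the 5' cap is position ``-utr5_len``.

``coord_to_index`` / ``index_to_coord`` convert between these coordinates and
0-based string indices and round-trip exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

ONE_PART = "one_part"
TWO_PART = "two_part_arabidopsis"
THREE_PART = "three_part_cerevisiae"
SPECIES_SCHEMES = (ONE_PART, TWO_PART, THREE_PART)

#: 5'UTR-length thresholds splitting genes into regression parts.
PART_THRESHOLDS = {
    ONE_PART: (),
    TWO_PART: (65,),
    THREE_PART: (20, 35),
}


class ConfigurationError(ValueError):
    """A run/dataset configuration that cannot produce a valid analysis."""


def normalize_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MRnaRecord:
    """One gene: sequence, 5'UTR/CDS boundaries, translation rate, abundance."""

    gene_id: str
    seq: str
    utr5_len: int
    cds_len: int
    tr: float
    mrna_abundance: float

    def validate(self) -> None:
        if self.utr5_len < 0:
            raise ValueError(f"{self.gene_id}: negative utr5_len")
        if self.cds_len <= 0 or self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: cds_len must be a positive multiple of 3")
        if self.utr5_len + self.cds_len > len(self.seq):
            raise ValueError(f"{self.gene_id}: utr5_len + cds_len exceeds sequence length")
        if set(self.seq) - RNA_ALPHABET:
            raise ValueError(f"{self.gene_id}: non-ACGU characters in sequence")
        start = self.seq[self.utr5_len : self.utr5_len + 3]
        if start != "AUG":
            raise ValueError(f"{self.gene_id}: CDS does not start with AUG (found {start!r})")
        if not (self.tr > 0) or not math.isfinite(self.tr):
            raise ValueError(f"{self.gene_id}: tr must be positive and finite")
        if self.mrna_abundance < 0:
            raise ValueError(f"{self.gene_id}: negative mRNA abundance")

    # -- coordinate helpers ------------------------------------------------

    def coord_to_index(self, pos: int) -> int:
        """Map an iAUG-anchored coordinate (no 0) to a 0-based index."""
        if pos == 0:
            raise ValueError("position 0 does not exist in iAUG coordinates")
        return self.utr5_len + pos if pos < 0 else self.utr5_len + pos - 1

    def index_to_coord(self, idx: int) -> int:
        off = idx - self.utr5_len
        return off if off < 0 else off + 1

    @property
    def utr5_seq(self) -> str:
        return self.seq[: self.utr5_len]

    @property
    def cds_seq(self) -> str:
        return self.seq[self.utr5_len : self.utr5_len + self.cds_len]

    def slice_coords(self, start: int, end: int) -> str:
        """Subsequence covering iAUG coordinates ``start..end`` inclusive,
        truncated to the transcript (may be empty)."""
        if start == 0 or end == 0:
            raise ValueError("position 0 does not exist")
        if end < start:
            return ""
        i = self.coord_to_index(start)
        j = self.coord_to_index(end) + 1
        i = max(i, 0)
        j = min(j, len(self.seq))
        return self.seq[i:j] if j > i else ""


@dataclass
class Dataset:
    """An ordered collection of validated mRNA records."""

    records: list[MRnaRecord]
    species_scheme: str = ONE_PART
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.species_scheme not in SPECIES_SCHEMES:
            raise ConfigurationError(f"unknown species_scheme {self.species_scheme!r}")
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate gene ids in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def by_id(self, gene_id: str) -> MRnaRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def subset(self, gene_ids: Iterable[str]) -> "Dataset":
        keep = set(gene_ids)
        return Dataset(
            [r for r in self.records if r.gene_id in keep],
            species_scheme=self.species_scheme,
            name=self.name,
        )


@dataclass(frozen=True)
class Cohort:
    label: str  # "high_TR" or "low_TR"
    gene_ids: frozenset


REGION_NAMES = (
    "five_prime_of_APE",
    "uAPE",
    "dAPE",
    "CDS_3prime_of_APE",
    "UTR5",
    "five_prime_region",
)


@dataclass(frozen=True)
class RegionSpec:
    """A named mRNA region relative to APE bounds (iAUG coordinates, inclusive)."""

    name: str
    ape_bounds: tuple[int, int] = (-35, 28)

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region {self.name!r}")
        lo, hi = self.ape_bounds
        if lo >= 0 or hi <= 0:
            raise ValueError("ape_bounds must straddle the iAUG (lo<0<hi)")


# ---------------------------------------------------------------------------
# Loading


def _records_from_frames(
    seqs: Mapping[str, str], ann: pd.DataFrame
) -> tuple[list[MRnaRecord], list[tuple[str, str]]]:
    records, dropped = [], []
    for row in ann.itertuples(index=False):
        gid = str(row.gene_id)
        if gid not in seqs:
            dropped.append((gid, "sequence missing"))
            continue
        rec = MRnaRecord(
            gene_id=gid,
            seq=normalize_rna(seqs[gid]),
            utr5_len=int(row.utr5_len),
            cds_len=int(row.cds_len),
            tr=float(row.tr),
            mrna_abundance=float(row.rpkm),
        )
        try:
            rec.validate()
        except ValueError as exc:
            dropped.append((gid, str(exc)))
            continue
        records.append(rec)
    for gid, reason in dropped:
        logger.info("dropped gene %s: %s", gid, reason)
    return records, dropped


def load_dataset(
    seq_source: str | Path,
    annotation: str | Path | None = None,
    scheme: str = ONE_PART,
    name: str | None = None,
) -> Dataset:
    """Load a dataset from FASTA + TSV annotation, or a single combined table.

    The combined table has columns ``gene_id, utr5_seq, cds_seq, tr, rpkm``
    (tab-separated, header row). The FASTA route expects annotation columns
    ``gene_id, utr5_len, cds_len, tr, rpkm``.
    """
    seq_source = Path(seq_source)
    if not seq_source.exists():
        raise FileNotFoundError(seq_source)
    if annotation is None:
        tab = pd.read_csv(seq_source, sep="\t", dtype={"gene_id": str})
        required = {"gene_id", "utr5_seq", "cds_seq", "tr", "rpkm"}
        if not required.issubset(tab.columns):
            raise ConfigurationError(
                f"combined table missing columns {sorted(required - set(tab.columns))}"
            )
        tab = tab.fillna({"utr5_seq": ""})
        seqs = {
            str(r.gene_id): normalize_rna(str(r.utr5_seq) + str(r.cds_seq))
            for r in tab.itertuples(index=False)
        }
        ann = pd.DataFrame(
            {
                "gene_id": tab["gene_id"].astype(str),
                "utr5_len": [len(normalize_rna(str(s))) for s in tab["utr5_seq"]],
                "cds_len": [len(normalize_rna(str(s))) for s in tab["cds_seq"]],
                "tr": tab["tr"],
                "rpkm": tab["rpkm"],
            }
        )
    else:
        annotation = Path(annotation)
        if not annotation.exists():
            raise FileNotFoundError(annotation)
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(seq_source), "fasta")}
        ann = pd.read_csv(annotation, sep="\t", dtype={"gene_id": str})
        required = {"gene_id", "utr5_len", "cds_len", "tr", "rpkm"}
        if not required.issubset(ann.columns):
            raise ConfigurationError(
                f"annotation missing columns {sorted(required - set(ann.columns))}"
            )
    records, _ = _records_from_frames(seqs, ann)
    if not records:
        raise ConfigurationError("no valid records survived loading")
    return Dataset(records, species_scheme=scheme, name=name or seq_source.stem)


def write_dataset(d: Dataset, fasta_path: str | Path, annotation_path: str | Path) -> None:
    """Emit the FASTA + TSV annotation pair that :func:`load_dataset` reads."""
    with open(fasta_path, "w") as fh:
        for r in d.records:
            fh.write(f">{r.gene_id}\n{r.seq}\n")
    rows = [
        {
            "gene_id": r.gene_id,
            "utr5_len": r.utr5_len,
            "cds_len": r.cds_len,
            "tr": r.tr,
            "rpkm": r.mrna_abundance,
        }
        for r in d.records
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering, cohorts, regions, parts


def filter_dataset(
    d: Dataset,
    min_abundance: float = 1.0,
    allow_list: set[str] | None = None,
    replica_tables: Sequence[pd.DataFrame] | None = None,
) -> Dataset:
    """Average TR/abundance across replicas, threshold on abundance, intersect
    with an optional allow-list.

    Replica tables carry columns ``gene_id, tr, rpkm``; genes absent from any
    replica are removed and per-gene values are means across replicas.
    """
    records = list(d.records)
    if replica_tables:
        common: set[str] | None = None
        for tab in replica_tables:
            ids = set(tab["gene_id"].astype(str))
            common = ids if common is None else common & ids
        assert common is not None
        means: dict[str, tuple[float, float]] = {}
        for gid in common:
            trs = [float(t.loc[t["gene_id"].astype(str) == gid, "tr"].iloc[0]) for t in replica_tables]
            rps = [float(t.loc[t["gene_id"].astype(str) == gid, "rpkm"].iloc[0]) for t in replica_tables]
            means[gid] = (sum(trs) / len(trs), sum(rps) / len(rps))
        records = [
            replace(r, tr=means[r.gene_id][0], mrna_abundance=means[r.gene_id][1])
            for r in records
            if r.gene_id in means
        ]
    records = [r for r in records if r.mrna_abundance >= min_abundance]
    if allow_list is not None:
        records = [r for r in records if r.gene_id in allow_list]
    if not records:
        raise ConfigurationError("filter_dataset removed every gene")
    return Dataset(records, species_scheme=d.species_scheme, name=d.name)


def split_cohorts(d: Dataset, fraction: float = 0.10) -> tuple[Cohort, Cohort]:
    """Top/bottom ``fraction`` of genes by TR (ties broken by gene_id)."""
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    k = int(math.floor(fraction * len(d)))
    if k < 1:
        raise ConfigurationError("dataset too small to split cohorts")
    ranked = sorted(d.records, key=lambda r: (r.tr, r.gene_id))
    low = frozenset(r.gene_id for r in ranked[:k])
    high = frozenset(r.gene_id for r in ranked[-k:])
    return Cohort("high_TR", high), Cohort("low_TR", low)


def extract_region(r: MRnaRecord, spec: RegionSpec) -> str:
    """Extract the region's subsequence; truncation at transcript edges is the
    contract (an unreachable region yields the empty string)."""
    lo, hi = spec.ape_bounds
    if spec.name == "UTR5":
        return r.utr5_seq
    if spec.name == "five_prime_region":
        # 5'UTR plus CDS covered by the APE's 3' extent
        return r.slice_coords(-r.utr5_len, hi) if r.utr5_len else r.slice_coords(1, hi)
    if spec.name == "uAPE":
        return r.slice_coords(max(lo, -r.utr5_len), -1) if r.utr5_len else ""
    if spec.name == "dAPE":
        return r.slice_coords(4, hi)
    if spec.name == "five_prime_of_APE":
        if r.utr5_len + lo <= 0:  # UTR does not extend past the APE
            return ""
        return r.slice_coords(-r.utr5_len, lo - 1)
    if spec.name == "CDS_3prime_of_APE":
        end = r.cds_len
        return r.slice_coords(hi + 1, end) if hi < end else ""
    raise AssertionError(spec.name)


def part_label(utr5_len: int, scheme: str) -> str:
    thresholds = PART_THRESHOLDS[scheme]
    part = 1
    for t in thresholds:
        if utr5_len >= t:
            part += 1
    return f"part{part}"


def assign_parts(d: Dataset) -> dict[str, str]:
    """Map gene_id -> regression-part label under the dataset's scheme."""
    return {r.gene_id: part_label(r.utr5_len, d.species_scheme) for r in d.records}
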