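"""uAUG counts, CDS length, codon / amino-acid / synonymous-codon features.

Column naming contract: ``uAUG``, ``CDSlen``, ``codon.XXX`` (61), ``AA.X``
(20), ``syn.XXX`` (61), ``Ncodon.XXX`` / ``Ccodon.XXX``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .data_model import Dataset, MRnaRecord
from .fold_features import FeatureMatrix

_TABLE = CodonTable.unambiguous_rna_by_id[1]  # standard nuclear code
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))  # 61 non-stop codons
AMINO_ACIDS = tuple(sorted(set(_TABLE.forward_table.values())))  # 20 letters
CODON_TO_AA = dict(_TABLE.forward_table)
SYN_FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}


class InternalStopError(ValueError):
    """The CDS contains a premature stop codon."""


def count_uaugs(r: MRnaRecord) -> int:
    """Number of (possibly overlapping) AUGs strictly within the 5'UTR."""
    utr = r.utr5_seq
    return sum(1 for i in range(len(utr) - 2) if utr[i : i + 3] == "AUG")


def cds_length_feature(r: MRnaRecord) -> float:
    """log10 of the number of encoded amino acids (stop codon excluded)."""
    n_aa = r.cds_len // 3 - 1
    if n_aa < 1:
        raise ValueError(f"{r.gene_id}: CDS too short for a length feature")
    return math.log10(n_aa)


@dataclass(frozen=True)
class CodonProfile:
    codon_freq: dict[str, float]
    aa_freq: dict[str, float]
    syn_pref: dict[str, float]  # NaN for amino acids absent from the gene
    n_half_freq: dict[str, float]
    c_half_freq: dict[str, float]
    has_all_amino_acids: bool


def _freqs(codons: list[str]) -> dict[str, float]:
    n = len(codons)
    counts = {c: 0 for c in SENSE_CODONS}
    for c in codons:
        counts[c] += 1
    return {c: (k / n if n else 0.0) for c, k in counts.items()}


def codon_profile(r: MRnaRecord) -> CodonProfile:
    """Codon, amino-acid and synonymous-preference frequencies for one CDS.

    The stop codon is excluded from every tally. The N-terminal half gets the
    smaller share when the sense-codon count is odd. A premature stop raises
    :class:`InternalStopError` (the caller flags and excludes the gene).
    """
    cds = r.cds_seq
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in STOP_CODONS:
        raise InternalStopError(f"{r.gene_id}: CDS does not end with a stop codon")
    sense = codons[:-1]
    for i, c in enumerate(sense):
        if c in STOP_CODONS:
            raise InternalStopError(f"{r.gene_id}: internal stop codon at codon {i + 1}")
    codon_freq = _freqs(sense)
    aa_counts = {aa: 0 for aa in AMINO_ACIDS}
    for c in sense:
        aa_counts[CODON_TO_AA[c]] += 1
    n_sense = len(sense)
    aa_freq = {aa: k / n_sense for aa, k in aa_counts.items()}
    syn_pref: dict[str, float] = {}
    for aa, fam in SYN_FAMILIES.items():
        fam_total = aa_counts[aa]
        for c in fam:
            syn_pref[c] = (
                codon_freq[c] * n_sense / fam_total if fam_total else math.nan
            )
    half = n_sense // 2  # N-half gets the smaller half when odd
    return CodonProfile(
        codon_freq=codon_freq,
        aa_freq=aa_freq,
        syn_pref=syn_pref,
        n_half_freq=_freqs(sense[:half]),
        c_half_freq=_freqs(sense[half:]),
        has_all_amino_acids=all(v > 0 for v in aa_counts.values()),
    )


# ---------------------------------------------------------------------------
# Dataset-level matrices


def build_simple_matrix(d: Dataset) -> FeatureMatrix:
    """uAUG + CDSlen + codon.* columns for every gene (NaN on internal stops)."""
    cols: dict[str, list[float]] = {"uAUG": [], "CDSlen": []}
    for c in SENSE_CODONS:
        cols[f"codon.{c}"] = []
    for r in d.records:
        cols["uAUG"].append(float(count_uaugs(r)))
        cols["CDSlen"].append(cds_length_feature(r))
        try:
            prof = codon_profile(r)
            for c in SENSE_CODONS:
                cols[f"codon.{c}"].append(prof.codon_freq[c])
        except InternalStopError:
            for c in SENSE_CODONS:
                cols[f"codon.{c}"].append(math.nan)
    return FeatureMatrix.from_dict(d.gene_ids, cols)


def build_codon_detail_matrix(d: Dataset) -> tuple[FeatureMatrix, list[str]]:
    """AA.* / syn.* / Ncodon.* / Ccodon.* columns.

    Returns the matrix plus the gene ids containing all 20 amino acids (the
    subset on which syn.codon analyses are defined).
    """
    cols: dict[str, list[float]] = {}
    for aa in AMINO_ACIDS:
        cols[f"AA.{aa}"] = []
    for c in SENSE_CODONS:
        cols[f"syn.{c}"] = []
        cols[f"Ncodon.{c}"] = []
        cols[f"Ccodon.{c}"] = []
    complete: list[str] = []
    for r in d.records:
        try:
            prof = codon_profile(r)
        except InternalStopError:
            for k in cols:
                cols[k].append(math.nan)
            continue
        if prof.has_all_amino_acids:
            complete.append(r.gene_id)
        for aa in AMINO_ACIDS:
            cols[f"AA.{aa}"].append(prof.aa_freq[aa])
        for c in SENSE_CODONS:
            cols[f"syn.{c}"].append(prof.syn_pref[c])
            cols[f"Ncodon.{c}"].append(prof.n_half_freq[c])
            cols[f"Ccodon.{c}"].append(prof.c_half_freq[c])
    return FeatureMatrix.from_dict(d.gene_ids, cols), complete


def log10_tr(d: Dataset) -> np.ndarray:
    return np.log10(np.array([r.tr for r in d.records], dtype=float))
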