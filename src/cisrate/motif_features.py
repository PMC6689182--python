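"""PWM construction/scoring, APE boundary scanning, k-mer features and
high/low-TR tri-nucleotide ratio tables.

PWMs are anchored either at the iAUG (position +1 = A of AUG, no position 0)
or at the 5' cap (position 1 = first transcript nucleotide). They are always
built from the high-TR cohort, with a pseudocount so unseen bases score
finitely, and a gene is scored only when it completely contains the PWM's
span (otherwise the score is missing).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Cohort, Dataset, MRnaRecord, RegionSpec, extract_region, split_cohorts
from .fold_features import FeatureMatrix
from . import modeling

NUCLEOTIDES = "ACGU"
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))
TRINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))

PSEUDOCOUNT = 0.5

DEFAULT_FIVE_GRID = tuple(range(-5, -101, -5))
DEFAULT_THREE_GRID = (-1, 8, 13, 18, 23, 28, 33)


def _positions(from_pos: int, to_pos: int) -> list[int]:
    """Inclusive coordinate range skipping the nonexistent position 0."""
    return [p for p in range(from_pos, to_pos + 1) if p != 0]


@dataclass(frozen=True)
class Pwm:
    from_pos: int
    to_pos: int
    freqs: tuple[dict[str, float], ...]  # one mapping per position
    anchor: str = "iaug"  # "iaug" or "cap"

    def __post_init__(self) -> None:
        for i, f in enumerate(self.freqs):
            if abs(sum(f.values()) - 1.0) > 1e-9:
                raise ValueError(f"PWM position {i} frequencies do not sum to 1")

    @property
    def positions(self) -> list[int]:
        if self.anchor == "cap":
            return list(range(self.from_pos, self.to_pos + 1))
        return _positions(self.from_pos, self.to_pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{n: f[n] for n in NUCLEOTIDES} for f in self.freqs], index=self.positions
        )


def _base_at(r: MRnaRecord, pos: int, anchor: str) -> str | None:
    if anchor == "cap":
        idx = pos - 1
        if idx >= r.utr5_len:  # cap PWMs are 5'UTR features
            return None
    else:
        if pos < 0 and r.utr5_len < -pos:
            return None
        if pos > 0 and pos > r.cds_len:
            return None
        idx = r.coord_to_index(pos)
    if 0 <= idx < len(r.seq):
        return r.seq[idx]
    return None


def build_pwm(
    records: Sequence[MRnaRecord],
    from_pos: int,
    to_pos: int,
    anchor: str = "iaug",
    pseudocount: float = PSEUDOCOUNT,
) -> Pwm:
    """Per-position nucleotide frequencies over the genes covering each position.

    Genes shorter than the full span still contribute to the positions they
    contain (the denominator per position is the count of covering genes).
    """
    if not records:
        raise ValueError("empty cohort")
    positions = (
        list(range(from_pos, to_pos + 1)) if anchor == "cap" else _positions(from_pos, to_pos)
    )
    freqs = []
    for pos in positions:
        counts = {n: 0.0 for n in NUCLEOTIDES}
        covered = 0
        for r in records:
            base = _base_at(r, pos, anchor)
            if base is not None:
                counts[base] += 1
                covered += 1
        if covered == 0:
            raise ValueError(f"no gene in the cohort covers position {pos}")
        total = covered + 4 * pseudocount
        freqs.append({n: (counts[n] + pseudocount) / total for n in NUCLEOTIDES})
    return Pwm(from_pos, to_pos, tuple(freqs), anchor)


def pwm_score(r: MRnaRecord, pwm: Pwm) -> float:
    """Sum of log10 per-position frequencies; NaN unless the record fully
    contains the PWM span."""
    total = 0.0
    for pos, f in zip(pwm.positions, pwm.freqs):
        base = _base_at(r, pos, pwm.anchor)
        if base is None:
            return math.nan
        total += math.log10(f[base])
    return total


def cap_pwm(d: Dataset, width: int = 5, cohort: Cohort | None = None) -> Pwm:
    """PWM over the first ``width`` transcript nucleotides of the high-TR cohort."""
    if cohort is None:
        cohort, _ = split_cohorts(d)
    recs = [r for r in d.records if r.gene_id in cohort.gene_ids and r.utr5_len >= width]
    if not recs:
        recs = [r for r in d.records if r.gene_id in cohort.gene_ids]
    return build_pwm(recs, 1, width, anchor="cap")


# ---------------------------------------------------------------------------
# APE boundary scan


def scan_ape_boundaries(
    d: Dataset,
    five_grid: Sequence[int] = DEFAULT_FIVE_GRID,
    three_grid: Sequence[int] = DEFAULT_THREE_GRID,
) -> tuple[dict[tuple[int, int], float], tuple[int, int]]:
    """R^2 of single-part regressions of log10 TR on PWM scores, for PWMs of
    every (5' bound, 3' bound) extent built from the high-TR cohort.

    Returns the R^2 grid and the argmax extent. PWMs with a 3' bound of -1
    contain no CDS positions.
    """
    high, _ = split_cohorts(d)
    high_recs = [r for r in d.records if r.gene_id in high.gene_ids]
    y_all = np.log10(np.array([r.tr for r in d.records], dtype=float))
    grid: dict[tuple[int, int], float] = {}
    for lo in five_grid:
        for hi in three_grid:
            try:
                pwm = build_pwm(high_recs, lo, hi)
            except ValueError:
                grid[(lo, hi)] = math.nan
                continue
            scores = np.array([pwm_score(r, pwm) for r in d.records])
            ok = np.isfinite(scores)
            if ok.sum() < 10:
                grid[(lo, hi)] = math.nan
                continue
            fit = modeling.fit_multipart(
                scores[ok][:, None], y_all[ok], ["part1"] * int(ok.sum()), ["pwm"]
            )
            grid[(lo, hi)] = fit.r2
    best = max(
        (v, -abs(k[0]), -abs(k[1]), k) for k, v in grid.items() if math.isfinite(v)
    )[3]
    return grid, best


# ---------------------------------------------------------------------------
# k-mer features


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies (lexicographic order); zeros if too short."""
    kmers = DINUCLEOTIDES if k == 2 else TRINUCLEOTIDES if k == 3 else None
    if kmers is None:
        raise ValueError("k must be 2 or 3")
    counts = np.zeros(len(kmers), dtype=float)
    index = {m: i for i, m in enumerate(kmers)}
    for i in range(len(seq) - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return counts / max(len(seq) - k + 1, 1)


def _kmer_columns(d: Dataset, region: RegionSpec, prefix: str) -> dict[str, list[float]]:
    cols: dict[str, list[float]] = {}
    for m in DINUCLEOTIDES:
        cols[f"{prefix}.di.{m}"] = []
    for m in TRINUCLEOTIDES:
        cols[f"{prefix}.tri.{m}"] = []
    for r in d.records:
        seq = extract_region(r, region)
        di = kmer_frequencies(seq, 2)
        tri = kmer_frequencies(seq, 3)
        for m, v in zip(DINUCLEOTIDES, di):
            cols[f"{prefix}.di.{m}"].append(v)
        for m, v in zip(TRINUCLEOTIDES, tri):
            cols[f"{prefix}.tri.{m}"].append(v)
    return cols


def _uape_pwm_bound(utr5_len: int, ape_lo: int, thresholds: Sequence[int]) -> int:
    """5' bound of the uAPE PWM variant used for a gene's regression part."""
    passed = [t for t in thresholds if utr5_len >= t]
    if not passed:
        return -5
    return -min(abs(ape_lo), max(passed))


@dataclass
class MotifSets:
    """BIC-selected per-region feature sets plus their candidate pools."""

    selected: dict[str, FeatureMatrix] = field(default_factory=dict)
    candidates: dict[str, FeatureMatrix] = field(default_factory=dict)
    fits: dict[str, modeling.FitResult] = field(default_factory=dict)


def build_motif_sets(
    d: Dataset,
    ape_bounds: tuple[int, int],
    parts: Mapping[str, str] | None = None,
    max_features: int | None = None,
) -> MotifSets:
    """uAPE / dAPE / 5'ofAPE candidate pools (PWM score + 16 di + 64 tri) with
    BIC forward selection per region, and the combined ``fiveprime_motifs`` set.
    """
    from .data_model import PART_THRESHOLDS, assign_parts

    lo, hi = ape_bounds
    hi = max(hi, 4)  # dAPE needs a 3' extent
    if parts is None:
        parts = assign_parts(d)
    part_vec = [parts[g] for g in d.gene_ids]
    thresholds = PART_THRESHOLDS[d.species_scheme]
    high, _ = split_cohorts(d)
    high_recs = [r for r in d.records if r.gene_id in high.gene_ids]
    y = np.log10(np.array([r.tr for r in d.records], dtype=float))

    # uAPE PWM scores: one column, each gene scored with its part's PWM variant
    variant_bounds = sorted({_uape_pwm_bound(r.utr5_len, lo, thresholds) for r in d.records})
    variants = {b: build_pwm(high_recs, b, -1) for b in variant_bounds}
    uape_scores = [
        pwm_score(r, variants[_uape_pwm_bound(r.utr5_len, lo, thresholds)]) for r in d.records
    ]

    dape_pwm = build_pwm(high_recs, 4, hi)
    dape_scores = [pwm_score(r, dape_pwm) for r in d.records]

    cpwm = cap_pwm(d, width=5, cohort=high)
    cap_scores = [pwm_score(r, cpwm) for r in d.records]

    pools: dict[str, dict[str, list[float]]] = {
        "uAPE": {"uAPE.pwm": uape_scores},
        "dAPE": {"dAPE.pwm": dape_scores},
        "fiveprime_of_APE": {"cap.pwm": cap_scores},
    }
    region_map = {
        "uAPE": RegionSpec("uAPE", (lo, hi)),
        "dAPE": RegionSpec("dAPE", (lo, hi)),
        "fiveprime_of_APE": RegionSpec("five_prime_of_APE", (lo, hi)),
    }
    prefix_map = {"uAPE": "uAPE", "dAPE": "dAPE", "fiveprime_of_APE": "capreg"}
    out = MotifSets()
    for name, base_cols in pools.items():
        cols = dict(base_cols)
        cols.update(_kmer_columns(d, region_map[name], prefix_map[name]))
        cand = FeatureMatrix.from_dict(d.gene_ids, cols)
        fit = modeling.forward_select_bic(cand, y, part_vec, max_features=max_features)
        out.candidates[name] = cand
        out.fits[name] = fit
        out.selected[name] = cand.select(fit.selected_features)
    combined = None
    for name in ("fiveprime_of_APE", "uAPE", "dAPE"):
        fm = out.selected[name]
        combined = fm if combined is None else combined.join(fm)
    assert combined is not None
    out.selected["fiveprime_motifs"] = combined
    return out


# ---------------------------------------------------------------------------
# Tri-nucleotide high/low-TR ratio tables


@dataclass(frozen=True)
class RatioTable:
    region: str
    ratios: dict[str, float]  # NaN where the low-TR mean is 0

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.ratios.items() if math.isfinite(v)}


def trinuc_ratio_table(
    d: Dataset,
    region: RegionSpec,
    cohorts: tuple[Cohort, Cohort] | None = None,
) -> RatioTable:
    """Ratio of cohort-mean tri-nucleotide frequencies (high TR / low TR).

    Genes whose region is empty are excluded from that region's means.
    """
    if cohorts is None:
        cohorts = split_cohorts(d)
    high, low = cohorts
    means = {}
    for cohort in (high, low):
        rows = []
        for r in d.records:
            if r.gene_id not in cohort.gene_ids:
                continue
            seq = extract_region(r, region)
            if not seq:
                continue
            rows.append(kmer_frequencies(seq, 3))
        if not rows:
            raise ValueError(f"no genes with non-empty region {region.name} in {cohort.label}")
        means[cohort.label] = np.mean(rows, axis=0)
    hi, lo = means["high_TR"], means["low_TR"]
    ratios = {
        m: (hi[i] / lo[i] if lo[i] > 0 else math.nan) for i, m in enumerate(TRINUCLEOTIDES)
    }
    return RatioTable(region.name, ratios)


def ratio_correlation(ta: RatioTable, tb: RatioTable) -> float:
    """Pearson r over the tri-nucleotides defined in both tables."""
    shared = [m for m in TRINUCLEOTIDES if math.isfinite(ta.ratios[m]) and math.isfinite(tb.ratios[m])]
    if len(shared) < 3:
        raise ValueError("fewer than 3 tri-nucleotides defined in both tables")
    a = np.array([ta.ratios[m] for m in shared])
    b = np.array([tb.ratios[m] for m in shared])
    return float(np.corrcoef(a, b)[0, 1])


def write_ratio_table(table: RatioTable, path) -> None:
    pd.DataFrame(
        {"trinucleotide": list(table.ratios), "ratio": list(table.ratios.values())}
    ).to_csv(path, sep="\t", index=False)
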