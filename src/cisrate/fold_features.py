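"""RNA-structure feature families computed from per-gene window energies.

Column naming contract: ``fold.L{length}.{family}`` plus ``fold.whole``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, MRnaRecord
from .folding import BUILTIN, FoldWindow, enumerate_windows, fold_window, window_energies

#: default window-length grid ("21 window lengths from 6 to 100 nucleotides")
DEFAULT_LENGTH_GRID = (6, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50,
                       55, 60, 65, 70, 75, 80, 85, 90, 95, 100)

LOC_FAMILIES = {
    "loc_5cap": None,  # window starts at the cap, i.e. -utr5_len
    "loc_-65": -65,
    "loc_-35": -35,
    "loc_-30": -30,
    "loc_-6": -6,
    "loc_-1": -1,
}
RANK_FAMILIES = ("rank_min", "rank_10", "rank_25", "rank_75", "rank_90", "rank_max")
MULTI_FAMILIES = (
    "mean",
    "pct_le20", "pct_ge80", "pct_ge90",
    "sum_le5", "sum_le10", "sum_le20", "sum_ge80", "sum_ge90",
)
WINDOW_FAMILIES = tuple(LOC_FAMILIES) + RANK_FAMILIES + MULTI_FAMILIES


@dataclass(frozen=True)
class FoldFeatureSpec:
    family: str
    window_length: int | None = None  # None for "whole"

    @property
    def column(self) -> str:
        if self.family == "whole":
            return "fold.whole"
        return f"fold.L{self.window_length}.{self.family}"


class FeatureMatrix:
    """Genes x named features with explicit missing-value bookkeeping.

    Backed by a pandas DataFrame (NaN = missing). ``design`` produces a dense
    matrix with per-column dataset-mean imputation for model fitting; the
    missingness mask is retained and exposed separately.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @classmethod
    def from_dict(cls, gene_ids: Sequence[str], columns: Mapping[str, Sequence[float]]) -> "FeatureMatrix":
        return cls(pd.DataFrame(dict(columns), index=list(gene_ids)))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is missing."""
        return self.frame.isna()

    def select(self, names: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.frame[list(names)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.frame.loc[list(gene_ids)])

    def join(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if list(other.frame.index) != list(self.frame.index):
            other_frame = other.frame.reindex(self.frame.index)
        else:
            other_frame = other.frame
        return FeatureMatrix(pd.concat([self.frame, other_frame], axis=1))

    def design(self, impute: bool = True) -> np.ndarray:
        """Dense float matrix; missing values imputed with the column mean.

        A column that is entirely missing imputes to 0 (it then carries no
        information and is dropped as aliased at fit time).
        """
        x = self.frame.to_numpy(dtype=float)
        if impute:
            mu = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
            mu = np.where(np.isfinite(mu), mu, 0.0)
            idx = np.where(~np.isfinite(x))
            x = x.copy()
            x[idx] = np.take(mu, idx[1])
        return x

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


# ---------------------------------------------------------------------------
# Per-gene feature families


def nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty values")
    k = max(1, math.ceil(pct / 100.0 * n))
    return float(v[min(k, n) - 1])


def rank_features(windows: Sequence[FoldWindow]) -> dict[str, float]:
    """min/10%/25%/75%/90%/max of a gene's window energies (nearest-rank)."""
    if not windows:
        return {f: math.nan for f in RANK_FAMILIES}
    e = np.array([w.delta_g for w in windows], dtype=float)
    return {
        "rank_min": float(e.min()),
        "rank_10": nearest_rank(e, 10),
        "rank_25": nearest_rank(e, 25),
        "rank_75": nearest_rank(e, 75),
        "rank_90": nearest_rank(e, 90),
        "rank_max": float(e.max()),
    }


def location_features(
    r: MRnaRecord, L: int, backend: str = BUILTIN,
    windows: Sequence[FoldWindow] | None = None,
) -> dict[str, float]:
    """Energies of windows anchored at fixed 5'-end positions.

    A location feature is missing when the 5'UTR is too short for the window
    to exist. Precomputed ``windows`` (from :func:`enumerate_windows`) are
    reused when given.
    """
    by_start = {w.start: w.delta_g for w in windows} if windows is not None else None
    out: dict[str, float] = {}
    for family, pos in LOC_FAMILIES.items():
        start = -r.utr5_len if pos is None else pos
        if r.utr5_len == 0 or r.utr5_len < -start:
            out[family] = math.nan
            continue
        if by_start is not None:
            out[family] = by_start.get(start, math.nan)
        else:
            i = r.coord_to_index(start)
            if i + L > r.utr5_len + r.cds_len:
                out[family] = math.nan
            else:
                out[family] = float(window_energies(r.seq, np.array([i]), L, backend)[0])
    return out


def dataset_thresholds(all_energies: np.ndarray) -> dict[int, float]:
    """Pooled nearest-rank percentiles of all windows of all genes."""
    return {p: nearest_rank(all_energies, p) for p in (5, 10, 20, 80, 90)}


def threshold_features(
    windows: Sequence[FoldWindow], thresholds: Mapping[int, float]
) -> dict[str, float]:
    """mean/%-threshold/sum-threshold families against dataset-wide cutoffs."""
    if not windows:
        return {f: math.nan for f in MULTI_FAMILIES}
    e = np.array([w.delta_g for w in windows], dtype=float)
    n = len(e)
    le = {p: e[e <= thresholds[p]] for p in (5, 10, 20)}
    ge = {p: e[e >= thresholds[p]] for p in (80, 90)}
    return {
        "mean": float(e.mean()),
        "pct_le20": 100.0 * len(le[20]) / n,
        "pct_ge80": 100.0 * len(ge[80]) / n,
        "pct_ge90": 100.0 * len(ge[90]) / n,
        "sum_le5": float(le[5].sum()),
        "sum_le10": float(le[10].sum()),
        "sum_le20": float(le[20].sum()),
        "sum_ge80": float(ge[80].sum()),
        "sum_ge90": float(ge[90].sum()),
    }


def whole_feature(r: MRnaRecord, backend: str = BUILTIN) -> float:
    """Energy of folding the contiguous sequence from the 5' cap to +35."""
    end = min(r.utr5_len + 35, r.utr5_len + r.cds_len)
    seq = r.seq[:end]
    if len(seq) < 2:
        return 0.0
    return fold_window(seq, backend)[0]


def nonoverlap_min_windows(windows: Sequence[FoldWindow], k: int = 2) -> list[FoldWindow]:
    """Greedy most-folded windows sharing no position (ties -> 5'-most start)."""
    chosen: list[FoldWindow] = []
    pool = sorted(windows, key=lambda w: (w.delta_g, w.start))
    for w in pool:
        if len(chosen) >= k:
            break
        if all(w.start + w.length <= c.start or c.start + c.length <= w.start for c in chosen):
            chosen.append(w)
    return chosen


# ---------------------------------------------------------------------------
# Dataset-level matrix


def pombe_allowed(spec: FoldFeatureSpec) -> bool:
    """True if none of the feature's windows can extend 3' of +30."""
    if spec.family == "whole":
        return False
    L = spec.window_length
    assert L is not None
    pos = LOC_FAMILIES.get(spec.family, -1)  # rank/multi include the -1 window
    if spec.family == "loc_5cap":
        pos = -1  # the cap can sit at -1 for a 1-nt 5'UTR
    return L - abs(pos) <= 30


def fold_specs(
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID, pombe_constraint: bool = False
) -> list[FoldFeatureSpec]:
    specs = [FoldFeatureSpec(f, L) for L in lengths for f in WINDOW_FAMILIES]
    specs.append(FoldFeatureSpec("whole"))
    if pombe_constraint:
        specs = [s for s in specs if pombe_allowed(s)]
    return specs


def build_fold_matrix(
    d: Dataset,
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID,
    backend: str = BUILTIN,
    pombe_constraint: bool = False,
) -> FeatureMatrix:
    """Compute every fold feature for every gene (rows follow dataset order)."""
    specs = fold_specs(lengths, pombe_constraint)
    wanted_lengths = sorted({s.window_length for s in specs if s.window_length})
    columns: dict[str, list[float]] = {s.column: [] for s in specs}
    per_len_windows: dict[int, list[list[FoldWindow]]] = {}
    for L in wanted_lengths:
        gene_windows = [enumerate_windows(r, L, backend) for r in d.records]
        per_len_windows[L] = gene_windows
    pooled = {
        L: dataset_thresholds(
            np.array([w.delta_g for ws in per_len_windows[L] for w in ws], dtype=float)
        )
        if any(per_len_windows[L])
        else {p: math.nan for p in (5, 10, 20, 80, 90)}
        for L in wanted_lengths
    }
    need_whole = any(s.family == "whole" for s in specs)
    for gi, r in enumerate(d.records):
        for L in wanted_lengths:
            ws = per_len_windows[L][gi]
            vals = rank_features(ws)
            vals.update(threshold_features(ws, pooled[L]))
            vals.update(location_features(r, L, backend, windows=ws))
            for family, v in vals.items():
                col = f"fold.L{L}.{family}"
                if col in columns:
                    columns[col].append(v)
        if need_whole:
            columns["fold.whole"].append(whole_feature(r, backend))
    return FeatureMatrix.from_dict(d.gene_ids, columns)
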