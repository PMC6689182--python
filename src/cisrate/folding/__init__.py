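"""Free-energy computation: duplex energies, window MFE folding, stem stats.

Two folding backends satisfy the same contract:

``builtin_simplified``
    the deterministic simplified Zuker-style folder in :mod:`._zuker`,
    intended for tests and synthetic data.
``external_mfe``
    ViennaRNA's RNAfold via its Python bindings, for paper-scale runs; an
    explicit :class:`BackendUnavailableError` is raised when the bindings are
    not importable (never a silent fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..data_model import MRnaRecord
from . import params
from ._zuker import mfe_energies_batch, mfe_energy, mfe_fold
from .duplex import duplex_energy
from .stems import StemStats, parse_pairs, stem_statistics

__all__ = [
    "BackendUnavailableError",
    "FoldWindow",
    "StemStats",
    "duplex_energy",
    "enumerate_windows",
    "fold_window",
    "parse_pairs",
    "stem_statistics",
    "window_energies",
]

logger = logging.getLogger(__name__)

BUILTIN = "builtin_simplified"
EXTERNAL = "external_mfe"
BACKENDS = (BUILTIN, EXTERNAL)


class BackendUnavailableError(RuntimeError):
    """The requested external folding backend cannot be used."""


@dataclass(frozen=True)
class FoldWindow:
    """A positioned window with its folding energy (structure optional)."""

    gene_id: str
    start: int  # iAUG coordinate of the 5'-most nucleotide
    length: int
    delta_g: float
    structure: str | None = None


def _external_fold(seq: str) -> tuple[float, str]:
    try:
        import RNA  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            "external_mfe backend requires the ViennaRNA Python bindings (module 'RNA')"
        ) from exc
    structure, dg = RNA.fold(seq)
    return float(dg), structure


def fold_window(seq: str, backend: str = BUILTIN) -> tuple[float, str]:
    """Fold one window, returning (delta_g, dot-bracket structure)."""
    if backend == BUILTIN:
        return mfe_fold(seq)
    if backend == EXTERNAL:
        return _external_fold(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


def window_energies(seq: str, starts_idx: np.ndarray, length: int, backend: str = BUILTIN) -> np.ndarray:
    """Energies of ``seq[s:s+length]`` for each 0-based start (fast, no structures)."""
    if backend == BUILTIN:
        return mfe_energies_batch(params.encode(seq), np.asarray(starts_idx, dtype=np.int64), length)
    return np.array(
        [fold_window(seq[s : s + length], backend)[0] for s in starts_idx], dtype=np.float64
    )


def enumerate_windows(
    r: MRnaRecord, L: int, backend: str = BUILTIN, with_structure: bool = False
) -> list[FoldWindow]:
    """All length-``L`` windows whose 5' ends tile the 5'UTR (cap .. -1).

    The last window starts at -1 and extends to CDS position +(L-1). Windows
    that would run past the end of the annotated transcript (5'UTR + CDS) are
    dropped and logged; ``utr5_len == 0`` yields an empty list.
    """
    if L < 2:
        raise ValueError("window length must be >= 2")
    limit = r.utr5_len + r.cds_len
    starts = [s for s in range(r.utr5_len)]  # 0-based indices -utr5 .. -1
    kept = [s for s in starts if s + L <= limit]
    if len(kept) < len(starts):
        logger.info(
            "gene %s: dropped %d windows extending past the transcript 3' end",
            r.gene_id,
            len(starts) - len(kept),
        )
    if not kept:
        return []
    energies = window_energies(r.seq, np.array(kept, dtype=np.int64), L, backend)
    out = []
    for s, dg in zip(kept, energies):
        structure = None
        if with_structure:
            dg_tb, structure = fold_window(r.seq[s : s + L], backend)
            dg = dg_tb
        out.append(FoldWindow(r.gene_id, r.index_to_coord(s), L, float(dg), structure))
    return out
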