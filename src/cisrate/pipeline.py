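"""End-to-end orchestration: features -> selection -> models -> overlaps.

Every stage writes plain TSV into the run's output directory so intermediate
results can be inspected or re-entered. All randomness flows from the config
seed; reruns with the same config produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import modeling, motif_features, simple_features, synthetic_data
from .data_model import (
    Dataset,
    ONE_PART,
    RegionSpec,
    assign_parts,
    filter_dataset,
    load_dataset,
    split_cohorts,
)
from .fold_features import (
    DEFAULT_LENGTH_GRID,
    FeatureMatrix,
    build_fold_matrix,
    nonoverlap_min_windows,
)
from .folding import BUILTIN, enumerate_windows
from .simple_features import log10_tr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    seq_source: str | None = None
    annotation: str | None = None
    species_scheme: str = ONE_PART
    dataset_name: str = "run"
    synthetic: dict | None = None  # GeneratorConfig kwargs; used if no seq_source
    window_lengths: tuple[int, ...] = DEFAULT_LENGTH_GRID
    backend: str = BUILTIN
    pombe_3prime30_constraint: bool = False
    ape_bounds: tuple[int, int] | None = None  # None -> boundary scan
    min_window_length: int = 35  # window length for min/2nd/3rd-min overlaps
    bootstrap: int = 1000
    seed: int = 0
    min_abundance: float = 0.0
    output_dir: str = "cisrate_run"
    scan_five_grid: tuple[int, ...] = motif_features.DEFAULT_FIVE_GRID
    scan_three_grid: tuple[int, ...] = motif_features.DEFAULT_THREE_GRID
    reselect_combined: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_lengths", "ape_bounds", "scan_five_grid", "scan_three_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunResult:
    dataset: Dataset
    feature_sets: dict[str, FeatureMatrix]
    fits: dict[str, modeling.FitResult]
    combined: modeling.FitResult
    contributions: dict[str, dict[str, float]]
    overlaps: pd.DataFrame
    ratio_tables: dict[str, motif_features.RatioTable]
    ratio_correlations: pd.DataFrame
    ape_bounds: tuple[int, int]
    ground_truth: synthetic_data.GroundTruth | None = None
    extras: dict = field(default_factory=dict)


def _load(config: RunConfig) -> tuple[Dataset, synthetic_data.GroundTruth | None]:
    if config.seq_source:
        d = load_dataset(
            config.seq_source,
            config.annotation,
            scheme=config.species_scheme,
            name=config.dataset_name,
        )
        gt = None
    elif config.synthetic is not None:
        gen_cfg = synthetic_data.GeneratorConfig(seed=config.seed, **config.synthetic)
        d, gt = synthetic_data.generate(gen_cfg)
        d.species_scheme = config.species_scheme
    else:
        raise ValueError("config must provide seq_source or synthetic")
    if config.min_abundance > 0:
        d = filter_dataset(d, min_abundance=config.min_abundance)
    return d, gt


def minwindow_features(
    d: Dataset, L: int, backend: str = BUILTIN
) -> tuple[FeatureMatrix, dict[str, float]]:
    """Energies of the most folded and non-overlapping 2nd/3rd most folded
    windows, plus the fraction of genes long enough to contain each."""
    cols = {"win.min": [], "win.2ndmin": [], "win.3rdmin": []}
    for r in d.records:
        ws = enumerate_windows(r, L, backend)
        chosen = nonoverlap_min_windows(ws, k=3)
        for slot, name in enumerate(("win.min", "win.2ndmin", "win.3rdmin")):
            cols[name].append(chosen[slot].delta_g if len(chosen) > slot else math.nan)
    fm = FeatureMatrix.from_dict(d.gene_ids, cols)
    frac = {
        name: float(100.0 * fm.frame[name].notna().mean())
        for name in ("win.min", "win.2ndmin", "win.3rdmin")
    }
    return fm, frac


def build_feature_sets(d: Dataset, config: RunConfig) -> tuple[dict[str, FeatureMatrix], dict]:
    """All five general feature sets (BIC-selected where applicable)."""
    parts = assign_parts(d)
    part_vec = [parts[g] for g in d.gene_ids]
    y = log10_tr(d)
    info: dict = {"parts": parts}

    fold = build_fold_matrix(
        d, config.window_lengths, config.backend, config.pombe_3prime30_constraint
    )
    rnafold_fit = modeling.forward_select_bic(fold, y, part_vec)
    info["rnafold_fit"] = rnafold_fit

    if config.ape_bounds is not None:
        ape = tuple(config.ape_bounds)
    else:
        _, ape = motif_features.scan_ape_boundaries(
            d, config.scan_five_grid, config.scan_three_grid
        )
    info["ape_bounds"] = ape
    motifs = motif_features.build_motif_sets(d, ape, parts=parts)
    info["motif_fits"] = motifs.fits

    simple = simple_features.build_simple_matrix(d)
    sets = {
        "RNAfold": fold.select(rnafold_fit.selected_features),
        "fiveprime_motifs": motifs.selected["fiveprime_motifs"],
        "uAUG": simple.select(["uAUG"]),
        "CDS_length": simple.select(["CDSlen"]),
        "codon": simple.select([c for c in simple.feature_names if c.startswith("codon.")]),
    }
    return sets, info


def run_all(config: RunConfig) -> RunResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    d, gt = _load(config)
    parts = assign_parts(d)
    part_vec = [parts[g] for g in d.gene_ids]
    y = log10_tr(d)
    cohorts = split_cohorts(d)

    sets, info = build_feature_sets(d, config)
    ape = info["ape_bounds"]

    fits = {name: modeling.fit_multipart(fm, y, part_vec) for name, fm in sets.items() if fm.feature_names}
    combined, contributions = modeling.combined_model(
        sets, y, part_vec, bootstrap=config.bootstrap, seed=config.seed,
        reselect=config.reselect_combined,
    )

    # ---- overlap analyses
    rows = []

    def add_overlap(analysis: str, a_name: str, a: FeatureMatrix, b_name: str, b: FeatureMatrix, note: str = ""):
        if not a.feature_names or not b.feature_names:
            return
        ov = modeling.collinearity_overlap(a, b, y, part_vec)
        rows.append(
            {
                "analysis": analysis,
                "set_a": a_name,
                "set_b": b_name,
                "r2_a": ov.r2_a,
                "r2_b": ov.r2_b,
                "r2_ab": ov.r2_ab,
                "overlap_pct": ov.overlap_pct if ov.overlap_pct is not None else math.nan,
                "note": note,
            }
        )

    biochem = sets["uAUG"].join(sets["RNAfold"]) if sets["RNAfold"].feature_names else sets["uAUG"]
    add_overlap("motifs_vs_biochem", "fiveprime_motifs", sets["fiveprime_motifs"], "uAUG", sets["uAUG"])
    add_overlap("motifs_vs_biochem", "fiveprime_motifs", sets["fiveprime_motifs"], "RNAfold", sets["RNAfold"])
    add_overlap("motifs_vs_biochem", "fiveprime_motifs", sets["fiveprime_motifs"], "fiveprime_biochem", biochem)

    pairwise = ["RNAfold", "uAUG", "CDS_length", "codon"]
    for i, a_name in enumerate(pairwise):
        for b_name in pairwise[i + 1 :]:
            add_overlap("feature_pairs", a_name, sets[a_name], b_name, sets[b_name])

    minw, frac = minwindow_features(d, config.min_window_length, config.backend)
    for other, label in (("win.2ndmin", "2nd_min"), ("win.3rdmin", "3rd_min")):
        both = minw.frame[["win.min", other]].dropna()
        if len(both) >= 20:
            sub = minw.subset_genes(both.index)
            sub_parts = [parts[g] for g in both.index]
            y_sub = y[[d.gene_ids.index(g) for g in both.index]]
            ov = modeling.collinearity_overlap(
                sub.select(["win.min"]), sub.select([other]), y_sub, sub_parts
            )
            rows.append(
                {
                    "analysis": "min_windows",
                    "set_a": "min",
                    "set_b": label,
                    "r2_a": ov.r2_a,
                    "r2_b": ov.r2_b,
                    "r2_ab": ov.r2_ab,
                    "overlap_pct": ov.overlap_pct if ov.overlap_pct is not None else math.nan,
                    "note": f"pct_genes={frac[other]:.1f}",
                }
            )

    detail, complete = simple_features.build_codon_detail_matrix(d)
    ncols = [c for c in detail.feature_names if c.startswith("Ncodon.")]
    ccols = [c for c in detail.feature_names if c.startswith("Ccodon.")]
    add_overlap("codon_halves", "N_codon", detail.select(ncols), "C_codon", detail.select(ccols))
    if complete:
        sub = detail.subset_genes(complete)
        sub_parts = [parts[g] for g in complete]
        y_sub = y[[d.gene_ids.index(g) for g in complete]]
        aa = sub.select([c for c in sub.feature_names if c.startswith("AA.")])
        syn = sub.select([c for c in sub.feature_names if c.startswith("syn.")])
        ov = modeling.collinearity_overlap(aa, syn, y_sub, sub_parts)
        rows.append(
            {
                "analysis": "aa_vs_syncodon",
                "set_a": "AA",
                "set_b": "syn.codon",
                "r2_a": ov.r2_a,
                "r2_b": ov.r2_b,
                "r2_ab": ov.r2_ab,
                "overlap_pct": ov.overlap_pct if ov.overlap_pct is not None else math.nan,
                "note": f"pct_complete={100.0 * len(complete) / len(d):.1f}",
            }
        )
    overlaps = pd.DataFrame(rows)

    # ---- tri-nucleotide ratio tables and cross-region correlations
    ratio_tables: dict[str, motif_features.RatioTable] = {}
    for region_name in ("five_prime_of_APE", "uAPE", "dAPE", "CDS_3prime_of_APE", "UTR5"):
        try:
            ratio_tables[region_name] = motif_features.trinuc_ratio_table(
                d, RegionSpec(region_name, ape), cohorts
            )
        except ValueError as exc:
            logger.warning("ratio table %s skipped: %s", region_name, exc)
    corr_rows = []
    names = list(ratio_tables)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                r = motif_features.ratio_correlation(ratio_tables[a], ratio_tables[b])
            except ValueError:
                r = math.nan
            corr_rows.append({"region_a": a, "region_b": b, "pearson_r": r})
    ratio_corrs = pd.DataFrame(corr_rows)

    result = RunResult(
        dataset=d,
        feature_sets=sets,
        fits=fits,
        combined=combined,
        contributions=contributions,
        overlaps=overlaps,
        ratio_tables=ratio_tables,
        ratio_correlations=ratio_corrs,
        ape_bounds=ape,
        ground_truth=gt,
        extras={"minwindow_fractions": frac, "info": info},
    )
    _write_reports(result, outdir)
    return result


def _write_reports(res: RunResult, outdir: Path) -> None:
    summary = {
        "dataset": res.dataset.name,
        "n_genes": len(res.dataset),
        "ape_bounds": list(res.ape_bounds),
        "combined_r2": res.combined.r2,
        "combined_ci": list(res.combined.bootstrap_ci) if res.combined.bootstrap_ci else None,
        "set_r2": {k: v.r2 for k, v in res.fits.items()},
        "contributions": res.contributions,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    res.overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
    res.ratio_correlations.to_csv(outdir / "ratio_correlations.tsv", sep="\t", index=False)
    for name, table in res.ratio_tables.items():
        motif_features.write_ratio_table(table, outdir / f"ratios_{name}.tsv")
    coef_rows = []
    for part, (intercept, coefs) in res.combined.per_part_coefficients.items():
        coef_rows.append({"feature": "(intercept)", "part": part, "coefficient": intercept})
        for f, c in zip(res.combined.selected_features, coefs):
            coef_rows.append({"feature": f, "part": part, "coefficient": float(c)})
    pd.DataFrame(coef_rows).to_csv(outdir / "combined_coefficients.tsv", sep="\t", index=False)
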