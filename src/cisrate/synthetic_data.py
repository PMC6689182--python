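"""Synthetic datasets with planted, ground-truthed translational effects.

Each gene gets a latent score; five effects are planted so that their
*realized, measurable* values (the builtin folding energy of the planted
hairpin window, the final 5'UTR AUG count, the start-context score under the
generating "strong" PWM, log10 CDS codon count, and a linear codon-optimality
score) enter the latent log10 translation rate. Because the response is built
from realized values, the analysis pipeline can in principle recover the
explainable variance exactly; the noise standard deviation is calibrated so
the explainable fraction matches ``target_r2`` when set.

By default one latent per gene drives all effects (the collinear regime);
``independent_latents=True`` draws one latent per effect instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import Dataset, MRnaRecord, ONE_PART
from .folding import BUILTIN, window_energies
from .folding.params import encode
from .simple_features import SENSE_CODONS

EFFECTS = ("structure", "uaug", "kozak", "cds_length", "codon")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: start-context generating PWMs over positions -6..-1 (A-rich favorable
#: context vs G/C-rich unfavorable context)
_STRONG_CONTEXT = {"A": 0.55, "C": 0.15, "G": 0.10, "U": 0.20}
_WEAK_CONTEXT = {"A": 0.10, "C": 0.35, "G": 0.40, "U": 0.15}


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 500
    seed: int = 0
    utr5_len_lognormal: tuple[float, float] = (math.log(35.0), 0.25)
    cds_codons_lognormal: tuple[float, float] = (math.log(150.0), 0.4)
    gc_background: float = 0.38
    effect_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "structure": 1.0,
            "uaug": 1.0,
            "kozak": 0.6,
            "cds_length": 1.0,
            "codon": 1.0,
        }
    )
    noise_sd: float = 0.4
    target_r2: float | None = None
    independent_latents: bool = False
    hairpin_window: int = 35  # window length used for the realized fold effect
    max_stem: int = 9
    loop_len: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.gc_background < 1):
            raise ValueError("gc_background must lie in (0, 1)")
        if self.target_r2 is not None and not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must lie in (0, 1)")
        for k in self.effect_weights:
            if k not in EFFECTS:
                raise ValueError(f"unknown effect {k!r}")


@dataclass
class GroundTruth:
    latent: np.ndarray
    effect_values: dict[str, np.ndarray]      # realized raw effect values
    effect_contributions: dict[str, np.ndarray]  # signed standardized terms
    signal: np.ndarray
    noise_sd: float
    realized_fraction: float
    stem_lengths: np.ndarray
    hairpin_starts: np.ndarray  # 0-based index into the 5'UTR, -1 = none


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def plant_hairpin(
    seq: str,
    position: int,
    stem_len: int,
    loop_len: int,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, tuple[int, int]]:
    """Write a perfect stem/loop at ``position`` (0-based), returning the new
    sequence (same length) and the occupied interval.

    The 5' arm and loop keep the existing bases; the 3' arm is overwritten
    with the reverse complement of the 5' arm. Overlap with a previously
    planted interval raises.
    """
    total = 2 * stem_len + loop_len
    if position < 0 or position + total > len(seq):
        raise ValueError("hairpin does not fit within the sequence")
    interval = (position, position + total)
    for a, b in occupied or []:
        if interval[0] < b and a < interval[1]:
            raise ValueError("hairpin overlaps a previously planted element")
    if stem_len == 0:
        return seq, interval
    arm5 = seq[position : position + stem_len]
    new = (
        seq[: position + stem_len + loop_len]
        + revcomp(arm5)
        + seq[position + total :]
    )
    assert len(new) == len(seq)
    return new, interval


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=probs)])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset plus its ground truth, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    weights = {e: float(config.effect_weights.get(e, 0.0)) for e in EFFECTS}

    t = rng.standard_normal(n)
    latents = {e: (rng.standard_normal(n) if config.independent_latents else t) for e in EFFECTS}

    mu_u, sd_u = config.utr5_len_lognormal
    mu_c, sd_c = config.cds_codons_lognormal

    # planted stem length decreases with the structure latent
    stems = np.clip(np.round(5.0 - 2.0 * latents["structure"]), 0, config.max_stem).astype(int)

    # per-codon optimality directions (fixed per run)
    opt = rng.choice([-1.0, 1.0], size=len(SENSE_CODONS))
    base_logits = np.zeros(len(SENSE_CODONS))

    utr_lens = np.empty(n, dtype=int)
    hairpin_starts = np.full(n, -1, dtype=int)
    # CDS length anti-correlates with its latent (long CDS on slow genes)
    rho = 0.85
    z_cds = -rho * latents["cds_length"] + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    n_codons = np.clip(np.round(np.exp(mu_c + sd_c * z_cds)), 50, 2000).astype(int)

    seqs: list[str] = []
    uaug_counts = np.empty(n, dtype=float)
    kozak_scores = np.empty(n, dtype=float)
    codon_scores = np.empty(n, dtype=float)
    fold_targets: list[tuple[int, int]] = []  # (gene idx, window start in UTR)

    codon_array = np.array(SENSE_CODONS)
    aug_idx = SENSE_CODONS.index("AUG")

    for i in range(n):
        stem = stems[i]
        need = 2 * stem + config.loop_len + 8  # hairpin + start-context margin
        for attempt in range(200):
            ul = int(np.clip(round(math.exp(rng.normal(mu_u, sd_u))), 5, 500))
            if ul >= need:
                break
        else:
            raise RuntimeError("could not sample a 5'UTR long enough for the planted hairpin")
        utr_lens[i] = ul
        utr = _random_seq(rng, ul, config.gc_background)
        occupied: list[tuple[int, int]] = [(ul - 6, ul)]  # start-context zone

        # start context -6..-1 from a latent-interpolated mixture PWM
        p_strong = 1.0 / (1.0 + math.exp(-1.5 * latents["kozak"][i]))
        ctx = []
        for _ in range(6):
            source = _STRONG_CONTEXT if rng.random() < p_strong else _WEAK_CONTEXT
            bases, probs = zip(*source.items())
            ctx.append(str(rng.choice(bases, p=np.array(probs))))
        utr = utr[:-6] + "".join(ctx)
        kozak_scores[i] = sum(math.log10(_STRONG_CONTEXT[b]) for b in utr[-6:])

        # hairpin placement (random feasible position 5' of the context zone)
        total = 2 * stem + config.loop_len
        if stem > 0:
            hi = ul - 6 - total
            pos = int(rng.integers(0, hi + 1)) if hi > 0 else 0
            utr, interval = plant_hairpin(utr, pos, stem, config.loop_len, occupied)
            occupied.append(interval)
            hairpin_starts[i] = pos

        # uAUG insertion with rate decreasing in the latent
        lam = math.exp(0.3 - 0.9 * latents["uaug"][i])
        for _ in range(rng.poisson(lam)):
            for attempt in range(20):
                pos = int(rng.integers(0, max(ul - 9, 1)))
                if all(not (pos < b and a < pos + 3) for a, b in occupied):
                    utr = utr[:pos] + "AUG" + utr[pos + 3 :]
                    occupied.append((pos, pos + 3))
                    break

        # CDS: start codon + tempered sense codons + stop
        logits = base_logits + 0.8 * latents["codon"][i] * opt
        probs = np.exp(logits)
        probs /= probs.sum()
        body_idx = rng.choice(len(SENSE_CODONS), size=n_codons[i] - 1, p=probs)
        body = "".join(codon_array[body_idx])
        stop = str(rng.choice(["UAA", "UAG", "UGA"]))
        cds = "AUG" + body + stop

        freq = np.bincount(body_idx, minlength=len(SENSE_CODONS)).astype(float)
        freq[aug_idx] += 1  # the start codon is Met
        freq /= freq.sum()
        codon_scores[i] = float(freq @ opt)

        seq = utr + cds
        seqs.append(seq)
        uaug_counts[i] = sum(
            1 for j in range(ul - 2) if utr[j : j + 3] == "AUG"
        )
        # window (length hairpin_window) covering the planted element
        if stem > 0:
            start = min(max(hairpin_starts[i] - 2, 0), max(ul - 1, 0))
        else:
            start = max(ul // 2 - config.hairpin_window // 2, 0)
        fold_targets.append((i, start))

    # realized structure effect: builtin energy of the window over the hairpin
    fold_vals = np.empty(n)
    for i, start in fold_targets:
        seq = seqs[i]
        L = min(config.hairpin_window, len(seq) - start)
        fold_vals[i] = window_energies(seq, np.array([start]), L, BUILTIN)[0]

    effect_values = {
        "structure": fold_vals,
        "uaug": uaug_counts,
        "kozak": kozak_scores,
        "cds_length": np.log10(n_codons.astype(float)),
        "codon": codon_scores,
    }
    signs = {"structure": +1.0, "uaug": -1.0, "kozak": +1.0, "cds_length": -1.0, "codon": +1.0}
    contributions = {
        e: weights[e] * signs[e] * _standardize(effect_values[e]) for e in EFFECTS
    }
    signal = np.sum(list(contributions.values()), axis=0)

    sd_signal = float(signal.std())
    if config.target_r2 is not None and sd_signal > 0:
        noise_sd = sd_signal * math.sqrt((1 - config.target_r2) / config.target_r2)
    else:
        noise_sd = config.noise_sd
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    log_tr = signal + noise
    var_total = float(np.var(signal + noise))
    realized = float(np.var(signal)) / var_total if var_total > 0 else 0.0

    records = []
    for i in range(n):
        rec = MRnaRecord(
            gene_id=f"g{i:05d}",
            seq=seqs[i],
            utr5_len=int(utr_lens[i]),
            cds_len=int(3 * (n_codons[i] + 1)),
            tr=float(10.0 ** log_tr[i]),
            mrna_abundance=float(10.0 ** rng.normal(1.0, 0.5)),
        )
        rec.validate()
        records.append(rec)
    dataset = Dataset(records, species_scheme=ONE_PART, name=f"synthetic_seed{config.seed}")
    gt = GroundTruth(
        latent=t,
        effect_values=effect_values,
        effect_contributions=contributions,
        signal=signal,
        noise_sd=noise_sd,
        realized_fraction=realized,
        stem_lengths=stems,
        hairpin_starts=hairpin_starts,
    )
    return dataset, gt


def ground_truth_report(
    gt: GroundTruth,
    combined_r2: float,
    univariate_r2: Mapping[str, float] | None = None,
    selected_features: list[str] | None = None,
    planted_markers: Mapping[str, str] | None = None,
) -> dict:
    """Recovery summary: realized vs recovered variance and selection quality.

    ``planted_markers`` maps effect name -> feature-name substring regarded as
    the planted feature for sensitivity/specificity bookkeeping.
    """
    report: dict = {
        "realized_fraction": gt.realized_fraction,
        "combined_r2": combined_r2,
        "recovery_gap": combined_r2 - gt.realized_fraction,
    }
    if univariate_r2 is not None:
        report["univariate_r2"] = dict(univariate_r2)
    if selected_features is not None and planted_markers is not None:
        hits = {
            e: any(marker in f for f in selected_features)
            for e, marker in planted_markers.items()
        }
        planted = [e for e in planted_markers]
        report["selection_recall"] = (
            sum(hits.values()) / len(planted) if planted else math.nan
        )
        matched = [
            f for f in selected_features
            if any(m in f for m in planted_markers.values())
        ]
        report["n_nonplanted_selected"] = len(selected_features) - len(matched)
    return report
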