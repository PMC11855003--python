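"""Synthetic cohorts for end-to-end testing without any external data.

Two generators: per-CpG methylation tracks with a hypomethylated promoter gap
and planted tumor-specific hypermethylation, and somatic variant tables with
purity-modulated VAFs and known LOH truth.

The methylation model is the standard bisulfite sampling model: a latent
methylation fraction per CpG drawn from a beta background (high outside the
promoter gap, low inside), observed as k/d with k ~ Binomial(d, m) at a
Poisson read depth d.  Affected tumors add a constant per-CpG shift inside
the event window, clipped to 1 — emulating a focal promoter hypermethylation
event on top of sampling noise.

Variant VAFs are purity-scaled: a clonal heterozygous variant sits near
purity/2; after loss of the wild-type allele a clonal variant is hemizygous
and sits near the purity (or two *trans* variants share it), which is what
the VAF-based LOH rule detects.

All randomness flows from a single seed; fixed seed means byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CpGSite, GateRegion, MethylationProfile, write_bedgraph, write_gates
from .integrate import assign_class

__all__ = [
    "MethylSimConfig",
    "VariantSimConfig",
    "GeneEventRates",
    "MethylTruth",
    "simulate_methylation_cohort",
    "simulate_variant_table",
    "write_cohort",
    "DEFAULT_GENE_RATES",
]

#: fixed 10-bp spacing between simulated CpG sites.
CPG_SPACING = 10


@dataclass(frozen=True)
class MethylSimConfig:
    """Study conditions for the simulated methylation cohort.

    Defaults mirror the real cohort's shape: 32 tumor/normal pairs, a
    promoter-sized hypomethylation gap inside an otherwise methylated region,
    a focal hypermethylation event (+0.5 per CpG over 20 CpGs) in a quarter
    of the tumors, and ~50x read depth.
    """

    n_cpg: int = 200
    gap_interval: tuple[int, int] = (60, 140)  # CpG index range, half-open
    bg_high: tuple[float, float] = (20.0, 2.0)  # beta params outside the gap
    bg_low: tuple[float, float] = (2.0, 20.0)  # beta params inside the gap
    event_window: tuple[int, int] = (90, 110)  # CpG index range, half-open
    event_shift: float = 0.5
    event_fraction: float = 0.25
    mean_depth: float = 50.0
    n_normal: int = 32
    n_tumor: int = 32
    chrom: str = "chrS"
    origin: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.gap_interval, self.event_window):
            if not (0 <= lo < hi <= self.n_cpg):
                raise ValueError(f"interval ({lo}, {hi}) outside [0, {self.n_cpg})")
        if not 0.0 <= self.event_shift <= 1.0:
            raise ValueError("event_shift must lie in [0, 1]")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise ValueError("event_fraction must lie in [0, 1]")

    def positions(self) -> np.ndarray:
        return self.origin + np.arange(self.n_cpg) * CPG_SPACING

    def event_gate(self) -> GateRegion:
        pos = self.positions()
        lo, hi = self.event_window
        return GateRegion("event", self.chrom, int(pos[lo]), int(pos[hi - 1]) + 1)

    def search_gate(self) -> GateRegion:
        pos = self.positions()
        return GateRegion("search", self.chrom, int(pos[0]), int(pos[-1]) + 1)


@dataclass
class MethylTruth:
    """What was planted: affected tumors, the event window, the shift."""

    affected: list[str]
    event_window: tuple[int, int]
    event_gate: GateRegion
    event_shift: float


def _simulate_profile(
    rng: np.random.Generator, cfg: MethylSimConfig, sample_id: str, group: str, affected: bool
) -> MethylationProfile:
    gap_lo, gap_hi = cfg.gap_interval
    in_gap = np.zeros(cfg.n_cpg, dtype=bool)
    in_gap[gap_lo:gap_hi] = True
    m = np.empty(cfg.n_cpg)
    m[~in_gap] = rng.beta(*cfg.bg_high, size=(~in_gap).sum())
    m[in_gap] = rng.beta(*cfg.bg_low, size=in_gap.sum())
    if affected:
        lo, hi = cfg.event_window
        m[lo:hi] = np.clip(m[lo:hi] + cfg.event_shift, 0.0, 1.0)
    depth = np.maximum(rng.poisson(cfg.mean_depth, size=cfg.n_cpg), 1)
    k = rng.binomial(depth, m)
    ratios = k / depth
    positions = cfg.positions()
    sites = [
        CpGSite(cfg.chrom, int(positions[i]), float(ratios[i]), int(depth[i]))
        for i in range(cfg.n_cpg)
    ]
    return MethylationProfile(sample_id, group, sites)


def simulate_methylation_cohort(
    config: MethylSimConfig,
) -> tuple[list[MethylationProfile], MethylTruth]:
    """Simulate the paired cohort; affected tumors are chosen by the seed."""
    rng = np.random.default_rng(config.seed)
    n_affected = int(round(config.event_fraction * config.n_tumor))
    affected_idx = set(
        rng.choice(config.n_tumor, size=n_affected, replace=False).tolist()
    )
    profiles = []
    truth_affected = []
    for i in range(config.n_normal):
        profiles.append(
            _simulate_profile(rng, config, f"N{i + 1:02d}", "normal", affected=False)
        )
    for i in range(config.n_tumor):
        hit = i in affected_idx
        sample_id = f"T{i + 1:02d}"
        profiles.append(_simulate_profile(rng, config, sample_id, "tumor", affected=hit))
        if hit:
            truth_affected.append(sample_id)
    truth = MethylTruth(
        affected=truth_affected,
        event_window=config.event_window,
        event_gate=config.event_gate(),
        event_shift=config.event_shift,
    )
    return profiles, truth


# --- variant simulation ----------------------------------------------------

@dataclass(frozen=True)
class GeneEventRates:
    """Per-gene event probabilities for the variant simulator."""

    p_variant: float
    p_null_given_variant: float = 0.7
    p_loh_given_variant: float = 0.5
    p_hm: float = 0.1


#: per-gene rates shaped after the real cohort: APC/TP53 variants in ~3/4 of
#: tumors, APC mostly null and TP53 mostly missense, rarer SMAD4/MMR events,
#: MLH1 hypermethylation in ~1/3 of tumors.
DEFAULT_GENE_RATES: dict[str, GeneEventRates] = {
    "APC": GeneEventRates(0.75, 0.83, 0.62, 0.25),
    "TP53": GeneEventRates(0.75, 0.32, 0.46, 0.09),
    "SMAD4": GeneEventRates(0.22, 0.12, 0.57, 0.03),
    "MSH2": GeneEventRates(0.09, 0.67, 0.33, 0.16),
    "MSH6": GeneEventRates(0.06, 0.50, 1.00, 0.16),
    "MLH1": GeneEventRates(0.19, 0.50, 0.17, 0.31),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class VariantSimConfig:
    genes: tuple[str, ...] = tuple(DEFAULT_GENE_RATES)
    rates: dict[str, GeneEventRates] = field(
        default_factory=lambda: dict(DEFAULT_GENE_RATES)
    )
    n_samples: int = 32
    purity: float = 0.7
    jitter_sd: float = 0.03
    p_trans_pair_given_loh: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")


def _jitter(rng: np.random.Generator, value: float, sd: float) -> float:
    return float(np.clip(value + rng.normal(0.0, sd), 0.01, 0.99))


def _random_change(rng: np.random.Generator, null: bool) -> str:
    pos = int(rng.integers(10, 2000))
    ref = _AA[rng.integers(len(_AA))]
    if null:
        return f"{ref}{pos}*" if rng.random() < 0.5 else f"{ref}{pos}fs"
    alt = _AA[rng.integers(len(_AA))]
    while alt == ref:
        alt = _AA[rng.integers(len(_AA))]
    return f"{ref}{pos}{alt}"


def simulate_variant_table(
    config: VariantSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a somatic variant table with known per-gene truth.

    Returns (variants, truth).  ``variants`` has the standard TSV columns
    (sample, gene, change, vaf, phase); ``truth`` records per sample x gene
    the intended variant/LOH/hypermethylation flags and the implied class.
    """
    rng = np.random.default_rng(config.seed)
    var_rows = []
    truth_rows = []
    for i in range(config.n_samples):
        sample = f"S{i + 1:02d}"
        for gene in config.genes:
            rates = config.rates[gene]
            has_variant = rng.random() < rates.p_variant
            loh = has_variant and rng.random() < rates.p_loh_given_variant
            hm = rng.random() < rates.p_hm
            if has_variant:
                null = rng.random() < rates.p_null_given_variant
                if loh and rng.random() < config.p_trans_pair_given_loh:
                    # two clonal variants on opposite alleles share the purity
                    u = rng.uniform(0.35, 0.65)
                    for frac in (u, 1.0 - u):
                        var_rows.append(
                            {
                                "sample": sample,
                                "gene": gene,
                                "change": _random_change(rng, null),
                                "vaf": round(_jitter(rng, config.purity * frac, config.jitter_sd), 4),
                                "phase": "unknown",
                            }
                        )
                else:
                    vaf = config.purity if loh else config.purity / 2.0
                    var_rows.append(
                        {
                            "sample": sample,
                            "gene": gene,
                            "change": _random_change(rng, null),
                            "vaf": round(_jitter(rng, vaf, config.jitter_sd), 4),
                            "phase": "unknown",
                        }
                    )
            truth_rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "variant": has_variant,
                    "loh": loh,
                    "hm": hm,
                    "class": assign_class(has_variant, loh, hm),
                }
            )
    variants = pd.DataFrame(var_rows, columns=["sample", "gene", "change", "vaf", "phase"])
    truth = pd.DataFrame(truth_rows)
    return variants, truth


# --- file output -----------------------------------------------------------

def write_cohort(out_dir, methyl_cfg: MethylSimConfig, variant_cfg: VariantSimConfig) -> dict:
    """Write a complete simulated cohort: bedGraphs, variants.tsv, gates.bed,
    groups.tsv and truth.tsv under ``out_dir``.  Deterministic given the configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, mtruth = simulate_methylation_cohort(methyl_cfg)
    for p in profiles:
        write_bedgraph(p, out / f"{p.sample_id}.bedGraph")
    pd.DataFrame(
        {"sample": [p.sample_id for p in profiles], "group": [p.group for p in profiles]}
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    write_gates([mtruth.event_gate, methyl_cfg.search_gate()], out / "gates.bed")
    variants, vtruth = simulate_variant_table(variant_cfg)
    variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    vtruth.assign(
        methylation_affected=vtruth["sample"].isin(mtruth.affected)
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "truth_methylation.tsv", "w") as fh:
        fh.write("sample\tevent_start\tevent_end\tshift\n")
        for s in mtruth.affected:
            fh.write(
                f"{s}\t{mtruth.event_gate.start}\t{mtruth.event_gate.end}\t{mtruth.event_shift}\n"
            )
    return {"profiles": profiles, "methyl_truth": mtruth, "variants": variants, "variant_truth": vtruth}
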