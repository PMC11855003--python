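"""Join variant/LOH calls with methylation bands into second-hit classes A-F.

Under the two-hit model a tumor suppressor gene is inactivated by some
combination of somatic variant, loss of heterozygosity (LOH), and promoter
hypermethylation.  Each gene x sample is classified by its flag triple
(variant, LOH, hypermethylation):

    A (N,N,N)  no event            D (Y,N,Y)  variant + methylation
    B (Y,N,N)  variant only        E (Y,Y,Y)  variant + LOH + methylation
    C (Y,Y,N)  variant + LOH       F (N,N,Y)  methylation only

LOH is derived solely from variant VAFs, so LOH without a variant is an
invalid combination, not a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import FixtureCohort
from .somatic import LohCall, VariantRecord, call_loh_or_absent

__all__ = [
    "CLASSIFIED_GENES",
    "GATE_MAP",
    "HYPER_BANDS",
    "GeneSampleCall",
    "ClassSummary",
    "hm_flag",
    "assign_class",
    "classify_cohort",
    "summarize_classes",
    "msi_concordance",
    "run_fixture_pipeline",
]

#: genes entering the A-F classification (PMS2 is excluded: it was not
#: captured for methylation and contributes only to MMR-variant concordance).
CLASSIFIED_GENES = ("APC", "TP53", "SMAD4", "MSH2", "MSH6", "MLH1")

MMR_GENES = ("MSH2", "MSH6", "MLH1", "PMS2")

#: the gate(s) whose band governs each gene's hypermethylation flag.  APC has
#: two promoter regions (exon 1A and 1B), either one counts.  MSH2 is judged
#: on the EPCAM-MSH2 intervening 5'UTR gate only; the intron 1-2 gate is
#: reported but does not determine the class.
GATE_MAP: dict[str, tuple[str, ...]] = {
    "APC": ("APC_Ex1A", "APC_Ex1B"),
    "TP53": ("TP53",),
    "SMAD4": ("SMAD4",),
    "MSH2": ("MSH2_5UTR",),
    "MSH6": ("MSH6",),
    "MLH1": ("MLH1",),
}

#: bands counted as hypermethylated (z-score >= 2).
HYPER_BANDS = frozenset({"H", "VH", "EH"})

_CLASS_MAP = {
    (False, False, False): "A",
    (True, False, False): "B",
    (True, True, False): "C",
    (True, False, True): "D",
    (True, True, True): "E",
    (False, False, True): "F",
}


@dataclass(frozen=True)
class GeneSampleCall:
    sample_id: str
    gene: str
    variant_present: bool
    loh: bool
    hypermethylated: bool
    klass: str


@dataclass
class ClassSummary:
    """Class counts per gene plus row totals, Table-style."""

    counts: pd.DataFrame  # index A..F, columns CLASSIFIED_GENES
    n_samples: int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.totals
        return out


def hm_flag(sample: str, gene: str, bands: Mapping[tuple[str, str], str]) -> bool:
    """Is this gene hypermethylated in this sample?

    True when any governing gate's band is H or above.  ``bands`` maps
    (sample, gate_name) -> band; a gate absent from the mapping counts as
    unmethylated.
    """
    if gene not in GATE_MAP:
        raise ValueError(f"gene {gene!r} is not classified (known: {sorted(GATE_MAP)})")
    return any(bands.get((sample, gate), "none") in HYPER_BANDS for gate in GATE_MAP[gene])


def assign_class(variant_present: bool, loh: bool, hm: bool) -> str:
    """Map the (variant, LOH, hypermethylation) flag triple onto classes A-F."""
    if loh and not variant_present:
        raise ValueError("invalid combination: LOH is only asserted via variants")
    return _CLASS_MAP[(bool(variant_present), bool(loh), bool(hm))]


def classify_cohort(
    variants: Sequence[VariantRecord],
    bands: Mapping[tuple[str, str], str],
    samples: Sequence[str],
    genes: Sequence[str] = CLASSIFIED_GENES,
    loh_threshold: float = 0.5,
    loh_inclusive: bool = True,
) -> list[GeneSampleCall]:
    """Full second-hit classification: LOH from VAFs, methylation from bands."""
    by_key: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in variants:
        by_key.setdefault((v.sample_id, v.gene), []).append(v)
    calls = []
    for sample in samples:
        for gene in genes:
            recs = by_key.get((sample, gene), [])
            loh = call_loh_or_absent(
                recs, sample, gene, threshold=loh_threshold, inclusive=loh_inclusive
            )
            hm = hm_flag(sample, gene, bands)
            calls.append(
                GeneSampleCall(
                    sample_id=sample,
                    gene=gene,
                    variant_present=bool(recs),
                    loh=loh.loh,
                    hypermethylated=hm,
                    klass=assign_class(bool(recs), loh.loh, hm),
                )
            )
    return calls


def summarize_classes(calls: Iterable[GeneSampleCall]) -> ClassSummary:
    """Count gene x sample calls by class; duplicate gene x sample is an error."""
    calls = list(calls)
    seen = set()
    for c in calls:
        key = (c.sample_id, c.gene)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    genes = [g for g in CLASSIFIED_GENES if any(c.gene == g for c in calls)]
    counts = pd.DataFrame(0, index=list("ABCDEF"), columns=genes)
    for c in calls:
        counts.loc[c.klass, c.gene] += 1
    n_samples = len({c.sample_id for c in calls})
    return ClassSummary(counts=counts, n_samples=n_samples)


def msi_concordance(
    clinical: pd.DataFrame,
    variants: Sequence[VariantRecord],
    bands: Mapping[tuple[str, str], str],
) -> dict[str, int]:
    """Concordance of MSI-H status with mismatch-repair gene events.

    Counts MSI-H samples, those among them carrying any MMR gene variant
    (MSH2/MSH6/MLH1/PMS2), those with MLH1 hypermethylation, and the overall
    number of MLH1-hypermethylated samples.
    """
    msih = {r["sample"] for _, r in clinical.iterrows() if r["msi"] == "MSI-H"}
    with_mmr_variant = {v.sample_id for v in variants if v.gene in MMR_GENES}
    mlh1_hm = {
        s for s in clinical["sample"] if bands.get((s, "MLH1"), "none") in HYPER_BANDS
    }
    return {
        "msih_total": len(msih),
        "msih_with_mmr_variant": len(msih & with_mmr_variant),
        "msih_with_mlh1_hm": len(msih & mlh1_hm),
        "mlh1_hm_total": len(mlh1_hm),
    }


def run_fixture_pipeline(fixture: Optional[FixtureCohort] = None) -> dict:
    """Run LOH calling + methylation flags + class assignment on the packaged cohort.

    Returns the per-call list, the class summary, recomputed per-gene LOH
    calls, and the MSI concordance counts.
    """
    from .io import load_fixture

    fx = fixture if fixture is not None else load_fixture()
    bands = fx.band_lookup()
    calls = classify_cohort(fx.variants, bands, fx.samples)
    summary = summarize_classes(calls)
    loh_calls: dict[tuple[str, str], LohCall] = {}
    for (sample, gene) in {(v.sample_id, v.gene) for v in fx.variants}:
        loh_calls[(sample, gene)] = call_loh_or_absent(
            fx.variants_for(sample, gene), sample, gene
        )
    return {
        "fixture": fx,
        "calls": calls,
        "summary": summary,
        "loh_calls": loh_calls,
        "msi": msi_concordance(fx.clinical, fx.variants, bands),
    }
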