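"""Somatic variant interpretation: consequence classes, oncogenicity bands, and LOH calls.

Loss of heterozygosity (LOH) is inferred from variant allele frequencies alone:
a tumor sample has lost the second allele of a gene when a single somatic
variant reaches a VAF of 0.5, or when two variants presumed to lie on opposite
alleles (*trans*) jointly reach 0.5.  Tumor samples are never pure, so a clonal
hemizygous variant appears at VAF ~ purity and the threshold is conservative.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

__all__ = [
    "CONSEQUENCES",
    "EffectCall",
    "LohCall",
    "OncogenicityCall",
    "PhaseGroup",
    "VariantRecord",
    "apply_null_shortcut",
    "call_loh",
    "classify_variant_effect",
    "map_oncogenicity",
    "splice_filter",
]

#: Closed consequence vocabulary.
CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "missense",
    "inframe_indel",
    "splice",
    "utr",
    "synonymous",
    "other",
)

ONCOGENICITY_CATEGORIES = (
    "benign",
    "likely_benign",
    "VUS",
    "likely_oncogenic",
    "oncogenic",
)


@dataclass
class VariantRecord:
    """One somatic change in one sample.

    ``change`` is an HGVS-like protein or cDNA string as printed in clinical
    reports (``R252*``, ``N1818fs``, ``c.835-8A>G``...).  ``phase_tag`` records
    explicit phasing: variants annotated *cis* share an allele and cannot
    jointly inactivate both copies; anything else is presumed *trans*.
    ``known_splice`` marks a change annotated as a known splicing variant even
    when its position is not a canonical +/-1,2 site.
    """

    sample_id: str
    gene: str
    change: str
    vaf: float
    consequence: Optional[str] = None
    phase_tag: str = "unknown"
    oncogenicity: Optional[str] = None
    known_splice: bool = False
    splice_scores: Optional[tuple[float, float, float, float]] = None
    pop_af: Optional[float] = None
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(
                f"VAF must lie in [0, 1], got {self.vaf!r} "
                f"({self.sample_id} {self.gene} {self.change})"
            )
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.phase_tag not in ("cis", "trans", "unknown"):
            raise ValueError(f"phase_tag must be cis/trans/unknown, got {self.phase_tag!r}")


@dataclass
class PhaseGroup:
    """Two or more variants of one gene in one sample with known mutual phase."""

    variants: Sequence[VariantRecord]
    relation: str  # "cis" or "trans"

    def __post_init__(self) -> None:
        if len(self.variants) < 2:
            raise ValueError("a phase group needs at least two variants")
        keys = {(v.sample_id, v.gene) for v in self.variants}
        if len(keys) != 1:
            raise ValueError("phase group members must share sample and gene")
        if self.relation not in ("cis", "trans"):
            raise ValueError(f"relation must be cis or trans, got {self.relation!r}")


class EffectCall(NamedTuple):
    consequence: str
    is_null: bool


@dataclass(frozen=True)
class LohCall:
    sample_id: str
    gene: str
    loh: bool
    basis: str  # "single_vaf" | "trans_pair_sum" | "none"
    supporting_vafs: tuple[float, ...] = ()


@dataclass(frozen=True)
class OncogenicityCall:
    category: str
    points: Optional[int] = None
    via_null_shortcut: bool = False


# --- consequence parsing ---------------------------------------------------

# intronic / splice-region cDNA change, e.g. c.835-8A>G, c.306+1G>A, 1731+2T>C
_SPLICE_RE = re.compile(r"^(?:c\.)?\*?\d+([+-])(\d+)")
# protein missense, one- or three-letter residues, e.g. R71C, Ser123Thr
_MISSENSE_RE = re.compile(r"^([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])$")
# 5'UTR cDNA change, e.g. c.-32delA
_UTR_RE = re.compile(r"^c\.(-|\*)\d+")

#: canonical splice-site offsets (+/-1 donor, +/-2 acceptor boundaries)
_CANONICAL_OFFSETS = (1, 2)


def _parse_change(change: str) -> tuple[str, bool]:
    """Infer (consequence, canonical_site) from an HGVS-like change string."""
    s = change.strip()
    if not s:
        raise ValueError("empty change string")
    m = _UTR_RE.match(s)
    if m:
        return "utr", False
    m = _SPLICE_RE.match(s)
    if m:
        return "splice", int(m.group(2)) in _CANONICAL_OFFSETS
    if "fs" in s:
        return "frameshift", False
    if s.endswith("*") or s.endswith("Ter"):
        return "nonsense", False
    if s.endswith("="):
        return "synonymous", False
    if ("del" in s or "dup" in s or "ins" in s) and not s.startswith("c."):
        return "inframe_indel", False
    if _MISSENSE_RE.match(s):
        return "missense", False
    raise ValueError(f"cannot classify change string {change!r}")


def classify_variant_effect(record: VariantRecord) -> EffectCall:
    """Assign the consequence class and the null (complete loss-of-function) flag.

    An explicit ``record.consequence`` always wins over string parsing.  The
    null flag is true for nonsense and frameshift changes, and for splice
    changes at a canonical +/-1,2 position or annotated as known splicing
    variants; missense and in-frame indels are never null.
    """
    canonical = False
    if record.consequence is not None:
        consequence = record.consequence
        if consequence == "splice":
            m = _SPLICE_RE.match(record.change.strip())
            canonical = bool(m) and int(m.group(2)) in _CANONICAL_OFFSETS
    else:
        consequence, canonical = _parse_change(record.change)
        if record.known_splice and consequence in ("synonymous", "missense", "splice"):
            # exonic change annotated as a known splicing variant
            consequence = "splice"
    is_null = consequence in ("nonsense", "frameshift") or (
        consequence == "splice" and (canonical or record.known_splice)
    )
    return EffectCall(consequence, is_null)


# --- oncogenicity ----------------------------------------------------------

def map_oncogenicity(points: int) -> OncogenicityCall:
    """Map an evidence-point total onto the five oncogenicity categories.

    Bands: <= -7 benign; -6..-1 likely benign; 0..5 VUS; 6..9 likely
    oncogenic; >= 10 oncogenic.
    """
    points = int(points)
    if points <= -7:
        category = "benign"
    elif points <= -1:
        category = "likely_benign"
    elif points <= 5:
        category = "VUS"
    elif points <= 9:
        category = "likely_oncogenic"
    else:
        category = "oncogenic"
    return OncogenicityCall(category, points=points)


def apply_null_shortcut(record: VariantRecord) -> OncogenicityCall:
    """Oncogenicity with the null-variant shortcut.

    Complete loss-of-function variants of a tumor suppressor gene score enough
    evidence points on their own to be at least likely oncogenic, so null
    variants skip the full point tally.  An explicit annotation on the record
    always wins; unannotated non-null variants default to VUS.
    """
    if record.oncogenicity is not None:
        return OncogenicityCall(record.oncogenicity)
    effect = classify_variant_effect(record)
    if effect.is_null:
        return OncogenicityCall("likely_oncogenic", via_null_shortcut=True)
    return OncogenicityCall("VUS")


# --- splice-candidate filtering -------------------------------------------

def splice_filter(
    records: Iterable[VariantRecord],
    score_threshold: float = 0.5,
    max_pop_af: float = 1e-4,
) -> list[VariantRecord]:
    """Keep splice candidates with a strong predicted splicing effect that are
    rare in the general population.

    A record passes when the maximum of its four splice scores (donor
    gain/loss, acceptor gain/loss) exceeds ``score_threshold`` and its
    population allele frequency is below ``max_pop_af`` (absent pop_af is
    treated as 0, i.e. never seen).  Order-preserving and idempotent.
    """
    kept = []
    for rec in records:
        scores = rec.splice_scores if rec.splice_scores is not None else (0.0,) * 4
        pop_af = rec.pop_af if rec.pop_af is not None else 0.0
        if max(scores) > score_threshold and pop_af < max_pop_af:
            kept.append(rec)
    return kept


# --- LOH calling -----------------------------------------------------------

def call_loh(
    variants: Sequence[VariantRecord],
    threshold: float = 0.5,
    inclusive: bool = True,
) -> LohCall:
    """Call loss of heterozygosity for one gene in one sample from VAFs.

    LOH is called when a single variant's VAF reaches ``threshold``, or when
    the best pair of variants presumed *trans* sums to ``threshold``.  Pairs
    in which both members carry an explicit cis annotation share an allele and
    are excluded from summation; variants of unknown phase are presumed trans.
    Only pairs are ever summed (two different variants), never triples.
    """
    if not variants:
        return LohCall("", "", False, "none", ())
    keys = {(v.sample_id, v.gene) for v in variants}
    if len(keys) != 1:
        raise ValueError(f"variants span multiple gene/sample combinations: {sorted(keys)}")
    sample_id, gene = keys.pop()

    def reaches(x: float) -> bool:
        return x >= threshold if inclusive else x > threshold

    best_single = max(variants, key=lambda v: v.vaf)
    if reaches(best_single.vaf):
        return LohCall(sample_id, gene, True, "single_vaf", (best_single.vaf,))

    best_pair: tuple[float, ...] = ()
    best_sum = -1.0
    for a, b in itertools.combinations(variants, 2):
        if a.phase_tag == "cis" and b.phase_tag == "cis":
            continue  # same allele: cannot jointly inactivate both copies
        s = a.vaf + b.vaf
        if s > best_sum:
            best_sum, best_pair = s, (a.vaf, b.vaf)
    if best_pair and reaches(best_sum):
        return LohCall(sample_id, gene, True, "trans_pair_sum", best_pair)
    return LohCall(sample_id, gene, False, "none", ())


def call_loh_or_absent(
    variants: Sequence[VariantRecord],
    sample_id: str,
    gene: str,
    threshold: float = 0.5,
    inclusive: bool = True,
) -> LohCall:
    """Like :func:`call_loh` but an empty variant list yields a negative call."""
    if not variants:
        return LohCall(sample_id, gene, False, "none", ())
    return call_loh(variants, threshold=threshold, inclusive=inclusive)
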