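"""Readers and writers for the formats the pipeline touches.

bedGraph tracks (per-CpG methylation ratios, one file per sample), BED gate
definitions, somatic variant tables (TSV or VCF), and the packaged cohort
fixture transcribed from the published per-sample tables.

All genomic coordinates are 0-based half-open end to end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .somatic import VariantRecord, classify_variant_effect

__all__ = [
    "CpGSite",
    "MethylationProfile",
    "GateRegion",
    "FixtureCohort",
    "FixtureIntegrityError",
    "BedGraphParseError",
    "read_bedgraph",
    "write_bedgraph",
    "read_gates",
    "read_variants",
    "load_fixture",
]

PathLike = Union[str, Path]


class BedGraphParseError(ValueError):
    """A bedGraph line could not be parsed; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        self.path, self.lineno = str(path), lineno
        super().__init__(f"{path}:{lineno}: {message}")


class FixtureIntegrityError(RuntimeError):
    pass


@dataclass(frozen=True, order=True)
class CpGSite:
    """One CpG on the forward strand: methylation fraction and optional depth."""

    chrom: str
    pos: int  # 0-based coordinate of the C
    ratio: float
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"methylation ratio {self.ratio} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth} at {self.chrom}:{self.pos}")


@dataclass
class MethylationProfile:
    """One sample's per-CpG methylation ratios, sorted by (chrom, pos), unique."""

    sample_id: str
    group: str  # "tumor" | "normal"
    sites: list[CpGSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("tumor", "normal"):
            raise ValueError(f"group must be tumor or normal, got {self.group!r}")
        self.sites = sorted(self.sites)
        seen: dict[tuple[str, int], float] = {}
        deduped = []
        for s in self.sites:
            key = (s.chrom, s.pos)
            if key in seen:
                if seen[key] != s.ratio:
                    raise ValueError(
                        f"duplicate position {s.chrom}:{s.pos} with conflicting "
                        f"ratios {seen[key]} vs {s.ratio} in {self.sample_id}"
                    )
                continue
            seen[key] = s.ratio
            deduped.append(s)
        self.sites = deduped

    def positions(self, chrom: str) -> list[int]:
        return [s.pos for s in self.sites if s.chrom == chrom]

    def ratio_at(self) -> dict[tuple[str, int], float]:
        return {(s.chrom, s.pos): s.ratio for s in self.sites}


@dataclass(frozen=True)
class GateRegion:
    """A genomic window (0-based half-open) over which ratios are summed."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gate {self.name}: start {self.start} >= end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


# --- bedGraph --------------------------------------------------------------

def read_bedgraph(
    path: PathLike,
    value_scale: str = "auto",
    sample_id: Optional[str] = None,
    group: str = "tumor",
) -> MethylationProfile:
    """Read a 4-column bedGraph of per-CpG methylation values.

    ``value_scale``: ``ratio`` (values already 0-1), ``percent`` (0-100,
    divided by 100), or ``auto`` — any value > 1 anywhere in the file marks
    the whole file as percent-scaled, which is how Bismark emits it.
    """
    if value_scale not in ("auto", "ratio", "percent"):
        raise ValueError(f"value_scale must be auto/ratio/percent, got {value_scale!r}")
    path = Path(path)
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedGraphParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphParseError(path, lineno, str(exc)) from None
            if start < 0 or end <= start:
                raise BedGraphParseError(path, lineno, f"bad interval [{start}, {end})")
            if not 0.0 <= value <= 100.0:
                raise BedGraphParseError(path, lineno, f"value {value} outside [0, 100]")
            rows.append((chrom, start, value))
    scale = value_scale
    if scale == "auto":
        scale = "percent" if any(v > 1.0 for _, _, v in rows) else "ratio"
    divisor = 100.0 if scale == "percent" else 1.0
    for _, _, v in rows:
        if v / divisor > 1.0:
            raise ValueError(f"{path}: value {v} exceeds 1 on the {scale} scale")
    sites = [CpGSite(chrom, pos, v / divisor) for chrom, pos, v in rows]
    return MethylationProfile(sample_id or path.stem, group, sites)


def write_bedgraph(profile: MethylationProfile, path: PathLike, precision: int = 6) -> None:
    """Write a profile back out as a ratio-scaled single-base bedGraph."""
    with open(path, "w") as fh:
        for s in profile.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{round(s.ratio, precision):g}\n")


# --- BED gates -------------------------------------------------------------

def read_gates(path: PathLike) -> list[GateRegion]:
    """Read gate regions from a BED3/BED4 file (0-based half-open, preserved)."""
    gates: list[GateRegion] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{i + 1}: BED needs at least 3 columns")
            name = fields[3] if len(fields) >= 4 else f"gate_{len(gates) + 1}"
            gates.append(GateRegion(name, fields[0], int(fields[1]), int(fields[2])))
    return gates


def write_gates(gates: Iterable[GateRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in gates:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


# --- variant tables --------------------------------------------------------

_TSV_OPTIONAL = ("consequence", "phase", "ds_ag", "ds_al", "ds_dg", "ds_dl", "pop_af", "tags")


def _record_from_row(row: pd.Series) -> VariantRecord:
    vaf = float(row["vaf"])
    consequence = row.get("consequence")
    if isinstance(consequence, str):
        consequence = consequence.strip() or None
    else:
        consequence = None
    phase = row.get("phase")
    phase = phase.strip() if isinstance(phase, str) and phase.strip() in ("cis", "trans") else "unknown"
    tags_raw = row.get("tags")
    tags: tuple[str, ...] = ()
    if isinstance(tags_raw, str) and tags_raw.strip() not in ("", "-"):
        tags = tuple(t.strip() for t in tags_raw.split(","))
    scores = None
    if all(k in row.index and pd.notna(row[k]) for k in ("ds_ag", "ds_al", "ds_dg", "ds_dl")):
        scores = (float(row["ds_ag"]), float(row["ds_al"]), float(row["ds_dg"]), float(row["ds_dl"]))
    pop_af = float(row["pop_af"]) if "pop_af" in row.index and pd.notna(row.get("pop_af")) else None
    oncogenicity = None
    if "LO" in tags:
        oncogenicity = "likely_oncogenic"
    elif "V" in tags:
        oncogenicity = "VUS"
    rec = VariantRecord(
        sample_id=str(row["sample"]),
        gene=str(row["gene"]),
        change=str(row["change"]),
        vaf=vaf,
        consequence=consequence,
        phase_tag=phase,
        oncogenicity=oncogenicity,
        known_splice="Sp" in tags,
        splice_scores=scores,
        pop_af=pop_af,
        tags=tags,
    )
    if rec.consequence is None:
        # fail early on unclassifiable change strings
        rec.consequence = classify_variant_effect(rec).consequence
    return rec


def read_variants(path: PathLike) -> list[VariantRecord]:
    """Read somatic variants from a TSV (named header) or a VCF.

    The TSV needs columns sample, gene, change, vaf; optional columns
    consequence, phase, ds_ag/ds_al/ds_dg/ds_dl (splice scores), pop_af, tags.
    Consequence is inferred from the change string when absent.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _read_variants_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = {"sample", "gene", "change", "vaf"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["vaf"].isna().any():
        bad = df.index[df["vaf"].isna()][0]
        raise ValueError(f"{path}: missing VAF in row {bad + 2}")
    return [_record_from_row(row) for _, row in df.iterrows()]


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        gene = var.INFO.get("GENE")
        if gene is None:
            ann = var.INFO.get("ANN")
            gene = ann.split("|")[3] if ann and len(ann.split("|")) > 3 else "."
        change = var.INFO.get("HGVSP") or var.INFO.get("HGVSC") or f"{var.REF}>{var.ALT[0]}"
        for i, sample in enumerate(samples):
            vaf = _sample_vaf(var, i)
            if vaf is None:
                continue
            records.append(
                VariantRecord(
                    sample_id=sample,
                    gene=str(gene),
                    change=str(change),
                    vaf=vaf,
                    consequence="other",
                )
            )
    if not records:
        raise ValueError(f"{path}: no per-sample VAF could be read or derived")
    return records


def _sample_vaf(var, i: int) -> Optional[float]:
    try:
        af = var.format("AF")
        if af is not None:
            return float(af[i][0])
    except KeyError:
        pass
    try:
        ad = var.format("AD")
        if ad is not None:
            ref, alt = float(ad[i][0]), float(ad[i][1])
            total = ref + alt
            return alt / total if total > 0 else None
    except KeyError:
        pass
    return None


def write_variants(records: Sequence[VariantRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "gene": r.gene,
                "change": r.change,
                "vaf": r.vaf,
                "consequence": r.consequence or "",
                "phase": r.phase_tag,
                "tags": ",".join(r.tags) if r.tags else "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- packaged cohort fixture ----------------------------------------------

#: sha256 of the packaged per-sample tables; guards against silent edits.
_FIXTURE_SHA256 = {
    "table1_clinical.tsv": "a44ab44f643a769b00b4793e60f9eef77ea8de1441814f0db23dd2ef5d102e1b",
    "table2_variants.tsv": "2a571d715d11cbffd4d5a21564a0cbb639dbc23e00ab5441298ae8526d1aaf8d",
    "table3_variants.tsv": "e2559deb783fec2cd65f2b1ee663b4a3f5e8dede69382891bad4d8dd7fe2fd67",
    "mzs_bands.tsv": "536b6c019b38c299e4e485420caf22fe1b7665849add1884943f28fe1a1a2632",
}

BANDS = ("none", "H", "VH", "EH")


@dataclass
class FixtureCohort:
    """The packaged 32-sample colorectal cancer cohort.

    ``clinical`` is per-sample age/sex/tumor locus/KRAS/BRAF/MSI status;
    ``variants`` the somatic variant records of the seven tumor suppressor
    genes; ``mzs_bands`` the per sample x gate methylation z-score band
    (none/H/VH/EH); ``loh_printed`` the published LOH call per (sample, gene),
    kept for regression against the recomputed calls.
    """

    clinical: pd.DataFrame
    variants: list[VariantRecord]
    mzs_bands: pd.DataFrame
    loh_printed: dict[tuple[str, str], bool]

    @property
    def samples(self) -> list[str]:
        return list(self.clinical["sample"])

    def variants_for(self, sample: str, gene: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.sample_id == sample and v.gene == gene]

    def band_lookup(self) -> dict[tuple[str, str], str]:
        return {
            (r["sample"], r["gate"]): r["band"] for _, r in self.mzs_bands.iterrows()
        }


def _fixture_text(name: str) -> str:
    data = resources.files("methylhit").joinpath("data", name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {_FIXTURE_SHA256[name]}"
        )
    return data.decode()


def load_fixture() -> FixtureCohort:
    """Load and validate the packaged cohort tables."""
    import io as _io

    clinical = pd.read_csv(_io.StringIO(_fixture_text("table1_clinical.tsv")), sep="\t")
    bands = pd.read_csv(_io.StringIO(_fixture_text("mzs_bands.tsv")), sep="\t")
    frames = [
        pd.read_csv(
            _io.StringIO(_fixture_text(name)), sep="\t", dtype=str, keep_default_na=False
        )
        for name in ("table2_variants.tsv", "table3_variants.tsv")
    ]
    var_df = pd.concat(frames, ignore_index=True)
    variants = [_record_from_row(row) for _, row in var_df.iterrows()]
    loh_printed = {
        (row["sample"], row["gene"]): row["loh"] == "Y" for _, row in var_df.iterrows()
    }
    if len(clinical) != 32:
        raise FixtureIntegrityError(f"expected 32 samples, found {len(clinical)}")
    if not set(clinical["msi"]) <= {"MSS", "MSI-H"}:
        raise FixtureIntegrityError("MSI labels outside {MSS, MSI-H}")
    if not set(bands["band"]) <= set(BANDS):
        raise FixtureIntegrityError("band labels outside {none, H, VH, EH}")
    return FixtureCohort(clinical, variants, bands, loh_printed)
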