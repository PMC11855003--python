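"""Regional methylation scoring: grand sums, the Methylation Z-Score, and gate search.

The statistic is deliberately simple.  For a genomic window (the *gate*) the
per-CpG methylation ratios (0-1) of a sample are summed over a CpG set common
to the whole cohort (the *grand sum*).  The normal samples define a reference
distribution of grand sums with mean ``nd_mean`` and sample standard deviation
``nd_sd``; a tumor's methylation level is then expressed as the z-score

    MZS = (td_sum - nd_mean) / nd_sd

and banded: high (H) for 2 <= MZS < 5, very high (VH) for 5 <= MZS < 10,
extremely high (EH) for MZS >= 10.  Gates may be tuned to maximize the tumor
MZS over contiguous CpG windows; because the gate is tuned on the same cohort
it scores, optimized scores are optimistically biased (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GateRegion, MethylationProfile

__all__ = [
    "SD_FLOOR",
    "BAND_CUTS",
    "CohortMatrix",
    "MZSResult",
    "MZSResults",
    "MethylationZScoreModel",
    "DegenerateCohortError",
    "CoverageError",
    "region_sum",
    "build_cohort",
    "compute_mzs",
    "classify_band",
    "optimize_gate",
]

#: below this sample sd the normal cohort carries no variability and the gate
#: is uninformative; scoring it would produce arbitrarily large z-scores.
SD_FLOOR = 1e-9

#: band boundaries in SD units, half-open: [2,5) H, [5,10) VH, [10,inf) EH.
BAND_CUTS = (2.0, 5.0, 10.0)


class DegenerateCohortError(ValueError):
    """Normal grand sums have (near-)zero variance in the gate."""


class CoverageError(KeyError):
    """A required CpG position is absent from a profile."""


@dataclass(frozen=True)
class MZSResult:
    """Grand sums, cohort statistics, z-score and band for one tumor x gate."""

    sample_id: str
    gate: GateRegion
    td_sum: float
    nd_mean: float
    nd_sd: float
    mzs: float
    band: str
    n_cpg: int


@dataclass
class CohortMatrix:
    """Per-sample grand sums over one gate's common CpG set."""

    gate: GateRegion
    sample_ids: list[str]
    groups: list[str]  # parallel to sample_ids, "normal"/"tumor"
    sums: np.ndarray  # parallel to sample_ids
    common_positions: list[int]

    @property
    def n_cpg(self) -> int:
        return len(self.common_positions)

    def normal_sums(self) -> np.ndarray:
        return self.sums[np.array(self.groups) == "normal"]

    def tumor_sums(self) -> np.ndarray:
        return self.sums[np.array(self.groups) == "tumor"]


def classify_band(mzs: float) -> str:
    """Map a z-score onto the none/H/VH/EH bands (negative scores are none)."""
    if not np.isfinite(mzs):
        raise ValueError(f"non-finite MZS {mzs}")
    if mzs < BAND_CUTS[0]:
        return "none"
    if mzs < BAND_CUTS[1]:
        return "H"
    if mzs < BAND_CUTS[2]:
        return "VH"
    return "EH"


def region_sum(
    profile: MethylationProfile,
    gate: GateRegion,
    common_positions: Sequence[int],
) -> float:
    """Grand sum of the profile's methylation ratios at exactly the given positions."""
    if not common_positions:
        return 0.0
    lookup = {s.pos: s.ratio for s in profile.sites if s.chrom == gate.chrom}
    total = 0.0
    for pos in common_positions:
        if pos not in lookup:
            raise CoverageError(
                f"{profile.sample_id} lacks coverage at {gate.chrom}:{pos} in gate {gate.name}"
            )
        total += lookup[pos]
    return total


def build_cohort(
    profiles: Sequence[MethylationProfile],
    gate: GateRegion,
    min_depth: int = 1,
    site_policy: str = "intersection",
    min_fraction: float = 0.9,
) -> CohortMatrix:
    """Build the per-sample grand-sum matrix over one gate.

    The common CpG set contains the positions inside the gate covered (at
    depth >= ``min_depth`` where depths are recorded) in every sample
    (``intersection``) or in at least ``min_fraction`` of samples
    (``min_fraction`` policy) — under the latter, samples missing a retained
    site cannot be scored over the identical set and are dropped with a
    warning rather than summed over fewer sites.
    """
    if site_policy not in ("intersection", "min_fraction"):
        raise ValueError(f"unknown site_policy {site_policy!r}")
    n_normals = sum(p.group == "normal" for p in profiles)
    if n_normals < 2:
        raise ValueError(f"need at least 2 normal profiles, got {n_normals}")

    covered: list[set[int]] = []
    for p in profiles:
        sites = {
            s.pos
            for s in p.sites
            if s.chrom == gate.chrom
            and gate.contains(s.pos)
            and (s.depth is None or s.depth >= min_depth)
        }
        covered.append(sites)

    if site_policy == "intersection":
        common = set.intersection(*covered) if covered else set()
        kept = list(profiles)
        kept_cov = covered
    else:
        counts: dict[int, int] = {}
        for sites in covered:
            for pos in sites:
                counts[pos] = counts.get(pos, 0) + 1
        need = min_fraction * len(profiles)
        common = {pos for pos, c in counts.items() if c >= need}
        kept, kept_cov = [], []
        for p, sites in zip(profiles, covered):
            if common <= sites:
                kept.append(p)
                kept_cov.append(sites)
            else:
                warnings.warn(
                    f"{p.sample_id} dropped from gate {gate.name}: missing "
                    f"{len(common - sites)} retained CpG site(s)",
                    stacklevel=2,
                )
        remaining_normals = sum(p.group == "normal" for p in kept)
        if remaining_normals < 2:
            raise ValueError("fewer than 2 normal profiles remain after site filtering")
    if not common:
        raise ValueError(f"no CpG site common to the cohort within gate {gate.name}")

    positions = sorted(common)
    sums = np.array([region_sum(p, gate, positions) for p in kept])
    return CohortMatrix(
        gate=gate,
        sample_ids=[p.sample_id for p in kept],
        groups=[p.group for p in kept],
        sums=sums,
        common_positions=positions,
    )


def compute_mzs(
    td_sum: float,
    normal_sums: Sequence[float],
    sample_id: str = "",
    gate: Optional[GateRegion] = None,
    n_cpg: Optional[int] = None,
) -> MZSResult:
    """Z-score one tumor grand sum against the normal cohort's grand sums.

    Uses the sample (n-1) standard deviation.  A cohort whose normal sums are
    (near-)constant raises :class:`DegenerateCohortError` rather than emitting
    an arbitrarily large score.
    """
    normal_sums = np.asarray(normal_sums, dtype=float)
    if normal_sums.size < 2:
        raise ValueError(f"need at least 2 normal sums, got {normal_sums.size}")
    nd_mean = float(np.mean(normal_sums))
    nd_sd = float(np.std(normal_sums, ddof=1))
    if nd_sd < SD_FLOOR:
        raise DegenerateCohortError(
            f"normal grand sums have sd {nd_sd:.3g} < {SD_FLOOR}; gate is uninformative"
        )
    mzs = (float(td_sum) - nd_mean) / nd_sd
    return MZSResult(
        sample_id=sample_id,
        gate=gate if gate is not None else GateRegion("unnamed", ".", 0, 1),
        td_sum=float(td_sum),
        nd_mean=nd_mean,
        nd_sd=nd_sd,
        mzs=mzs,
        band=classify_band(mzs),
        n_cpg=int(n_cpg) if n_cpg is not None else 0,
    )


# --- gate search -----------------------------------------------------------

def _window_objectives(
    prefix: np.ndarray, normal_mask: np.ndarray, length: int, objective: str
) -> tuple[np.ndarray, np.ndarray]:
    """Objective value per window start for a fixed window length.

    ``prefix`` is the (n_samples, n_cpg+1) prefix-sum matrix; each window's
    grand sums come from one vectorized difference.  Returns (objectives,
    admissible) with inadmissible (sd below floor) windows masked.
    """
    sums = prefix[:, length:] - prefix[:, :-length]  # (n_samples, n_windows)
    nd = sums[normal_mask]
    td = sums[~normal_mask]
    nd_mean = nd.mean(axis=0)
    nd_sd = nd.std(axis=0, ddof=1)
    admissible = nd_sd >= SD_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (td - nd_mean) / nd_sd
    obj = z.mean(axis=0) if objective == "mean_tumor_mzs" else z.max(axis=0)
    obj = np.where(admissible, obj, -np.inf)
    return obj, admissible


def optimize_gate(
    profiles: Sequence[MethylationProfile],
    search_region: GateRegion,
    objective: str = "mean_tumor_mzs",
    min_cpg: int = 5,
    max_cpg: Optional[int] = None,
    min_depth: int = 1,
) -> tuple[GateRegion, float]:
    """Find the contiguous CpG window inside ``search_region`` maximizing tumor MZS.

    Scans every window of ``min_cpg`` to ``max_cpg`` consecutive common CpG
    sites using prefix sums, scoring each window's tumor z-scores against the
    normal cohort.  Ties are broken toward the smaller window, then the
    leftmost start.  Windows whose normal sums have (near-)zero sd are
    skipped.  The returned gate spans the first to last CpG of the winning
    window, half-open.
    """
    if objective not in ("mean_tumor_mzs", "max_tumor_mzs"):
        raise ValueError(f"unknown objective {objective!r}")
    if min_cpg < 2:
        raise ValueError("min_cpg must be >= 2")
    cohort = build_cohort(profiles, search_region, min_depth=min_depth)
    positions = cohort.common_positions
    n = len(positions)
    if n < min_cpg:
        raise ValueError(f"search region holds {n} common CpGs < min_cpg {min_cpg}")
    max_cpg = n if max_cpg is None else min(max_cpg, n)

    lookup_rows = []
    for p in profiles:
        lookup = {s.pos: s.ratio for s in p.sites if s.chrom == search_region.chrom}
        lookup_rows.append([lookup[pos] for pos in positions])
    ratios = np.array(lookup_rows)  # (n_samples, n_cpg)
    normal_mask = np.array([p.group == "normal" for p in profiles])
    if (~normal_mask).sum() == 0:
        raise ValueError("no tumor profiles to score")
    prefix = np.zeros((ratios.shape[0], n + 1))
    np.cumsum(ratios, axis=1, out=prefix[:, 1:])

    best: Optional[tuple[float, int, int]] = None  # (value, length, start_idx)
    for length in range(min_cpg, max_cpg + 1):
        obj, admissible = _window_objectives(prefix, normal_mask, length, objective)
        if not admissible.any():
            continue
        start = int(np.argmax(obj))  # argmax takes the leftmost maximum
        value = float(obj[start])
        if value == -np.inf:
            continue
        # strict > keeps the smaller window on ties (lengths scanned ascending)
        if best is None or value > best[0]:
            best = (value, length, start)
    if best is None:
        raise ValueError("no admissible window (every candidate has a degenerate normal cohort)")
    value, length, start = best
    first, last = positions[start], positions[start + length - 1]
    gate = GateRegion(
        f"{search_region.name}_opt", search_region.chrom, first, last + 1
    )
    return gate, value


# --- statsmodels-style front end -------------------------------------------

class MethylationZScoreModel:
    """Cohort methylation z-score model for one gate.

    Parameters
    ----------
    profiles : sequence of MethylationProfile
        Tumor and normal samples; the normals define the reference
        distribution of grand sums.
    gate : GateRegion
        Window over which per-CpG ratios are summed.
    min_depth, site_policy, min_fraction
        Passed to :func:`build_cohort`.

    Examples
    --------
    >>> model = MethylationZScoreModel(profiles, gate)
    >>> res = model.fit()
    >>> res.frame[["sample", "mzs", "band"]]
    """

    def __init__(
        self,
        profiles: Sequence[MethylationProfile],
        gate: GateRegion,
        min_depth: int = 1,
        site_policy: str = "intersection",
        min_fraction: float = 0.9,
    ):
        self.profiles = list(profiles)
        self.gate = gate
        self.min_depth = min_depth
        self.site_policy = site_policy
        self.min_fraction = min_fraction

    @classmethod
    def from_bedgraph_dir(
        cls,
        directory,
        groups: pd.DataFrame,
        gate: GateRegion,
        value_scale: str = "auto",
        **kwargs,
    ) -> "MethylationZScoreModel":
        """Build the model from a directory of per-sample bedGraph files.

        ``groups`` needs columns ``sample`` and ``group`` (tumor/normal);
        each sample maps to ``<directory>/<sample>.bedGraph``.
        """
        from pathlib import Path

        from .io import read_bedgraph

        directory = Path(directory)
        profiles = []
        for _, row in groups.iterrows():
            path = directory / f"{row['sample']}.bedGraph"
            profiles.append(
                read_bedgraph(path, value_scale, sample_id=row["sample"], group=row["group"])
            )
        return cls(profiles, gate, **kwargs)

    def fit(self) -> "MZSResults":
        cohort = build_cohort(
            self.profiles,
            self.gate,
            min_depth=self.min_depth,
            site_policy=self.site_policy,
            min_fraction=self.min_fraction,
        )
        return MZSResults(self, cohort)


class MZSResults:
    """Fitted cohort statistics and per-tumor methylation z-scores."""

    def __init__(self, model: MethylationZScoreModel, cohort: CohortMatrix):
        self.model = model
        self.cohort = cohort
        nd = cohort.normal_sums()
        self.nd_mean = float(np.mean(nd))
        self.nd_sd = float(np.std(nd, ddof=1))
        if self.nd_sd < SD_FLOOR:
            raise DegenerateCohortError(
                f"normal grand sums have sd {self.nd_sd:.3g} < {SD_FLOOR} "
                f"in gate {cohort.gate.name}"
            )
        self.n_cpg = cohort.n_cpg
        self.results: list[MZSResult] = []
        for sample_id, group, s in zip(cohort.sample_ids, cohort.groups, cohort.sums):
            if group != "tumor":
                continue
            mzs = (s - self.nd_mean) / self.nd_sd
            self.results.append(
                MZSResult(
                    sample_id=sample_id,
                    gate=cohort.gate,
                    td_sum=float(s),
                    nd_mean=self.nd_mean,
                    nd_sd=self.nd_sd,
                    mzs=float(mzs),
                    band=classify_band(float(mzs)),
                    n_cpg=self.n_cpg,
                )
            )

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [r.sample_id for r in self.results],
                "gate": [r.gate.name for r in self.results],
                "n_cpg": [r.n_cpg for r in self.results],
                "td_sum": [r.td_sum for r in self.results],
                "nd_mean": [r.nd_mean for r in self.results],
                "nd_sd": [r.nd_sd for r in self.results],
                "mzs": [r.mzs for r in self.results],
                "band": [r.band for r in self.results],
            }
        )

    def normal_zscores(self) -> np.ndarray:
        """Z-scores of the normal samples against the full normal cohort."""
        nd = self.cohort.normal_sums()
        return (nd - self.nd_mean) / self.nd_sd

    def summary(self) -> str:
        lines = [
            "Methylation Z-Score results",
            "=" * 60,
            f"gate:       {self.cohort.gate.name} "
            f"({self.cohort.gate.chrom}:{self.cohort.gate.start}-{self.cohort.gate.end})",
            f"common CpG: {self.n_cpg}",
            f"normals:    n={len(self.cohort.normal_sums())}  "
            f"mean grand sum={self.nd_mean:.3f}  sd={self.nd_sd:.3f}",
            "-" * 60,
            f"{'sample':<12}{'td_sum':>10}{'mzs':>10}  band",
        ]
        for r in self.results:
            lines.append(f"{r.sample_id:<12}{r.td_sum:>10.3f}{r.mzs:>10.2f}  {r.band}")
        return "\n".join(lines)
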