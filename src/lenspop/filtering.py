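"""SNP site filtering and distance thinning.

The first-pass filter keeps a site only if it clears, jointly: site quality,
per-site mean depth, per-site missingness, biallelic status, minor-allele
count, and exclusion regions (e.g. called CNV intervals).  A removal report
attributes each dropped site to the first rule it fails, in the fixed order
quality -> depth -> missingness -> biallelic -> MAC -> region, so counts are
reproducible even when a site fails several rules.

The second-pass thinning (used before outlier scans) is a greedy
left-to-right scan keeping sites at least ``min_distance_bp`` apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

RULE_ORDER = ["quality", "depth", "missingness", "biallelic", "mac", "region"]


@dataclass
class FilterParams:
    """Thresholds for the site filter.

    Defaults are the standard exome-panel values: quality >= 30, mean depth
    >= 3x, missingness <= 0.10, minor-allele count >= 5, biallelic only.
    """

    min_quality: float = 30.0
    min_mean_depth: float = 3.0
    max_missingness: float = 0.10
    min_allele_count: int = 5
    biallelic_only: bool = True
    exclude_regions: pd.DataFrame | None = None  # chrom/start/end, 0-based half-open
    min_distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.min_quality < 0 or self.min_mean_depth < 0 or self.min_allele_count < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.max_missingness <= 1.0:
            raise ValueError("max_missingness must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal counts; each removed site counted once."""

    input_sites: int
    output_sites: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, self.removed_by_rule.get(r, 0)) for r in RULE_ORDER]
        return pd.DataFrame(rows, columns=["rule", "n_removed"])


def _in_regions(sites: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites (1-based pos) falling inside half-open regions."""
    mask = np.zeros(len(sites), dtype=bool)
    if regions is None or len(regions) == 0:
        return mask
    pos0 = sites["pos"].to_numpy() - 1  # 0-based point
    chroms = sites["chrom"].to_numpy()
    for chrom, sub in regions.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="stable")]
        p = pos0[sel]
        hit = np.zeros(p.shape, dtype=bool)
        for s, e in zip(starts, ends):
            hit |= (p >= s) & (p < e)
        mask[np.flatnonzero(sel)] = hit
    return mask


def filter_variants(
    gm: GenotypeMatrix, params: FilterParams
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site filter; returns the surviving matrix and a report."""
    qual = gm.sites["qual"].to_numpy(dtype=float)
    depth = gm.sites["mean_depth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        fail = {
            "quality": ~(qual >= params.min_quality),
            "depth": ~(depth >= params.min_mean_depth),
            "missingness": gm.missingness() > params.max_missingness,
            "biallelic": (
                ~gm.sites["biallelic"].to_numpy(dtype=bool)
                if params.biallelic_only
                else np.zeros(gm.n_sites, dtype=bool)
            ),
            "mac": gm.minor_allele_counts() < params.min_allele_count,
            "region": _in_regions(gm.sites, params.exclude_regions),
        }
    removed = np.zeros(gm.n_sites, dtype=bool)
    counts: dict[str, int] = {}
    for rule in RULE_ORDER:
        newly = fail[rule] & ~removed
        counts[rule] = int(newly.sum())
        removed |= fail[rule]
    keep = ~removed
    out = gm.take_sites(keep)
    if params.min_distance_bp:
        out = thin_variants(out, params.min_distance_bp)
    if out.n_sites == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    report = FilterReport(
        input_sites=gm.n_sites,
        output_sites=int(keep.sum()),
        removed_by_rule=counts,
    )
    return out, report


def thin_variants(gm: GenotypeMatrix, min_distance_bp: int) -> GenotypeMatrix:
    """Greedy per-chromosome thinning: keep a site iff its position is at
    least ``min_distance_bp`` past the last kept site; the first site on a
    chromosome is always kept."""
    if min_distance_bp <= 0:
        return gm
    keep = np.zeros(gm.n_sites, dtype=bool)
    pos = gm.sites["pos"].to_numpy()
    chroms = gm.sites["chrom"].to_numpy()
    last_chrom = None
    last_pos = None
    for j in range(gm.n_sites):
        if chroms[j] != last_chrom or pos[j] >= last_pos + min_distance_bp:
            keep[j] = True
            last_chrom = chroms[j]
            last_pos = pos[j]
    return gm.take_sites(keep)
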