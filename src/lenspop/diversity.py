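"""Per-cluster diversity: segregating sites, rarefied (private) allelic
richness, observed site-frequency spectra for SNPs and CNVs, and the
neutral expectation from the Watterson estimator.

Rarefaction uses the exact hypergeometric form: at a locus where allele a
has N_a copies out of N sampled gene copies, the probability that a random
subsample of g copies contains the allele is 1 - C(N-N_a, g)/C(N, g).
Allelic richness at size g is the sum of those probabilities over alleles,
averaged over loci; private richness additionally multiplies by the
probability that size-g subsamples from every *other* cluster miss the
allele entirely.

The expected neutral spectrum puts theta_W = S / sum_{i=1}^{n-1} 1/i mass
theta_W / i in derived-count class i, which totals S exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .cnv import CnvRegion
from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class SfsSpectrum:
    """Counts over derived-allele (or carrier) count classes 1..n-1."""

    n: int                 # sampled chromosomes (SNPs) or samples (CNVs)
    counts: np.ndarray     # length n-1, classes 1..n-1
    kind: str              # observed_snp | observed_cnv | expected_watterson

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n - 1:
            raise ValueError("counts must cover classes 1..n-1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def segregating_sites(self) -> float:
        return float(self.counts.sum())

    def folded(self) -> np.ndarray:
        """Minor-allele-count spectrum (classes 1..n-1; mass above n/2 is 0)."""
        n = self.n
        out = np.zeros(n - 1)
        for i, c in enumerate(self.counts, start=1):
            out[min(i, n - i) - 1] += c
        return out


@dataclass
class RarefactionCurve:
    cluster: str
    g: np.ndarray
    allelic_richness: np.ndarray
    private_richness: np.ndarray
    n_loci_used: int


def segregating_sites(gm: GenotypeMatrix, popmap: PopulationMap) -> dict[str, int]:
    """Per-cluster count of sites with >= 2 alleles among non-missing calls."""
    out: dict[str, int] = {}
    for cl in popmap.clusters():
        sub = gm.take_samples(popmap.samples_in(cl))
        out[cl] = int(sub.is_polymorphic().sum())
    return out


def _presence_prob(N: int, Na: int, g: int) -> float:
    """P(subsample of g out of N gene copies contains the allele with Na copies)."""
    if Na <= 0:
        return 0.0
    if N - Na < g:
        return 1.0
    return 1.0 - comb(N - Na, g) / comb(N, g)


def _absence_prob(N: int, Na: int, g: int) -> float:
    if Na <= 0:
        return 1.0
    if N - Na < g:
        return 0.0
    return comb(N - Na, g) / comb(N, g)


def rarefied_richness(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    g: int | list[int],
) -> dict[str, RarefactionCurve]:
    """Rarefied allelic and private allelic richness per cluster.

    A locus is used only if every cluster has >= max(g) callable gene
    copies there (skipped loci are reported via ``n_loci_used``).
    """
    g_values = np.atleast_1d(np.asarray(g, dtype=int))
    if np.any(g_values < 1):
        raise ValueError("g must be >= 1")
    g_max = int(g_values.max())
    clusters = popmap.clusters()
    # per-cluster allele counts per site
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cl in clusters:
        sub = gm.take_samples(popmap.samples_in(cl))
        counts[cl] = (sub.alt_counts(), sub.allele_numbers())
    usable = np.ones(gm.n_sites, dtype=bool)
    for cl in clusters:
        usable &= counts[cl][1] >= g_max
    site_idx = np.flatnonzero(usable)
    out: dict[str, RarefactionCurve] = {}
    for cl in clusters:
        ac, an = counts[cl]
        rich = np.zeros(len(g_values))
        priv = np.zeros(len(g_values))
        for j in site_idx:
            N = int(an[j])
            for which, Na in (("alt", int(ac[j])), ("ref", N - int(ac[j]))):
                if Na == 0:
                    continue
                for k, gv in enumerate(g_values):
                    pres = _presence_prob(N, Na, int(gv))
                    rich[k] += pres
                    absent = 1.0
                    for other in clusters:
                        if other == cl:
                            continue
                        ac_o, an_o = counts[other]
                        Na_o = int(ac_o[j]) if which == "alt" else int(an_o[j]) - int(ac_o[j])
                        absent *= _absence_prob(int(an_o[j]), Na_o, int(gv))
                    priv[k] += pres * absent
        n_used = len(site_idx)
        if n_used:
            rich /= n_used
            priv /= n_used
        out[cl] = RarefactionCurve(
            cluster=cl,
            g=g_values.copy(),
            allelic_richness=rich,
            private_richness=priv,
            n_loci_used=n_used,
        )
    return out


def _project_down(k: int, n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric down-projection of derived count k from n_from to n_to
    chromosomes; returns mass over classes 0..n_to."""
    out = np.zeros(n_to + 1)
    denom = comb(n_from, n_to)
    for j in range(max(0, n_to - (n_from - k)), min(k, n_to) + 1):
        out[j] = comb(k, j) * comb(n_from - k, n_to - j) / denom
    return out


def observed_sfs_snp(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    cluster: str,
    n: int | None = None,
    folded: bool = False,
) -> SfsSpectrum:
    """Observed SNP spectrum for one cluster (alt allele as derived).

    Sites with varying missingness are standardized to a common number of
    chromosomes ``n`` (default: the minimum across sites) by hypergeometric
    down-projection; classes 0 and n (fixed) are dropped.
    """
    members = popmap.samples_in(cluster)
    if not members:
        raise ValueError(f"cluster {cluster!r} is empty")
    sub = gm.take_samples(members)
    ac = sub.alt_counts()
    an = sub.allele_numbers()
    ok = an >= 2
    ac, an = ac[ok], an[ok]
    if n is None:
        n = int(an.min()) if len(an) else 2 * len(members)
    counts = np.zeros(n + 1)
    for k, m in zip(ac, an):
        if m == n:
            counts[k] += 1.0
        elif m > n:
            counts += _project_down(int(k), int(m), n)
        # sites with fewer than n chromosomes are skipped
    spec = SfsSpectrum(n=n, counts=counts[1:n], kind="observed_snp")
    if folded:
        return SfsSpectrum(n=n, counts=_fold_counts(spec), kind="observed_snp_folded")
    return spec


def _fold_counts(spec: SfsSpectrum) -> np.ndarray:
    n = spec.n
    out = np.zeros(n - 1)
    for i, c in enumerate(spec.counts, start=1):
        out[min(i, n - i) - 1] += c
    return out


def observed_sfs_cnv(
    regions: list[CnvRegion], popmap: PopulationMap, cluster: str
) -> SfsSpectrum:
    """Observed CNV spectrum: per region, carrier count among the cluster's
    samples (dosage is not resolved by depth-based calls, so the unit is the
    carrier accession and n is the cluster sample count)."""
    members = set(popmap.samples_in(cluster))
    if not members:
        raise ValueError(f"cluster {cluster!r} is empty")
    n = len(members)
    counts = np.zeros(n + 1)
    for r in regions:
        k = len(r.carriers & members)
        if 0 < k <= n:
            counts[k] += 1
    # carrier count may equal n (region fixed in the cluster); keep within 1..n-1
    return SfsSpectrum(n=n, counts=counts[1:n], kind="observed_cnv")


def expected_sfs_watterson(n: int, S: float) -> SfsSpectrum:
    """Neutral expectation: theta_W / i variants in derived-count class i,
    with theta_W = S / sum_{i=1}^{n-1} 1/i; the classes total S exactly."""
    if n < 2:
        raise ValueError("need n >= 2 sampled chromosomes")
    if S < 0:
        raise ValueError("S must be >= 0")
    harmonic = np.sum(1.0 / np.arange(1, n))
    theta_w = S / harmonic
    counts = theta_w / np.arange(1, n)
    return SfsSpectrum(n=n, counts=counts, kind="expected_watterson")
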