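"""Core containers: genotype matrix and population map.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1`` for
missing calls, one row per sample and one column per site.  Site metadata
(chromosome, 1-based position, alleles, quality, mean depth) lives in a
pandas DataFrame aligned with the genotype columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "mean_depth", "biallelic"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites matrix of alt-allele dosages.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, qual,
        mean_depth, biallelic``; ``pos`` is 1-based and strictly increasing
        within each chromosome.
    geno : ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage codes; ``-1`` marks a missing genotype.
    """

    samples: list[str]
    sites: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("geno must be 2-D (samples x sites)")
        if self.geno.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.sites = self.sites.reset_index(drop=True)
        for chrom, pos in self.sites.groupby("chrom", sort=False)["pos"]:
            arr = pos.to_numpy()
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic shape -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            geno=self.geno[:, index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            geno=self.geno[idx],
        )

    # -- per-site summaries ----------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.geno == MISSING

    def missingness(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.geno == MISSING).mean(axis=0)

    def allele_numbers(self) -> np.ndarray:
        """Per-site number of called chromosomes (2 x non-missing samples)."""
        return 2 * (self.geno != MISSING).sum(axis=0)

    def alt_counts(self) -> np.ndarray:
        """Per-site alt-allele copy count among non-missing genotypes."""
        g = np.where(self.geno == MISSING, 0, self.geno)
        return g.sum(axis=0)

    def minor_allele_counts(self) -> np.ndarray:
        ac = self.alt_counts()
        an = self.allele_numbers()
        return np.minimum(ac, an - ac)

    def is_polymorphic(self) -> np.ndarray:
        ac = self.alt_counts()
        an = self.allele_numbers()
        return (ac > 0) & (ac < an)


@dataclass
class PopulationMap:
    """Mapping from sample id to population-cluster label."""

    assignments: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationMap":
        out: dict[str, str] = {}
        for sample, cluster in pairs:
            if sample in out:
                raise ValueError(f"sample {sample!r} assigned twice")
            out[sample] = str(cluster)
        return cls(out)

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample", "cluster"}.issubset(df.columns):
            raise ValueError("popmap TSV needs 'sample' and 'cluster' columns")
        return cls.from_pairs(zip(df["sample"], df["cluster"]))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignments), "cluster": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c, None)
        return list(seen)

    def samples_in(self, cluster: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == str(cluster)]

    def cluster_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in population map") from None

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.assignments.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments
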