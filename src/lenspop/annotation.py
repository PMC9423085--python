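"""Gene annotation: intervals, functional categories, resistance flags.

Coordinates are 0-based half-open throughout (BED convention).  Functional
categories follow a MapMan-style closed vocabulary supplied by the user as a
TSV; a gene may carry several category labels and genes without any label
are reported under ``"Not assigned"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NOT_ASSIGNED = "Not assigned"


def interval_overlap_ids(
    q_chrom: np.ndarray,
    q_start: np.ndarray,
    q_end: np.ndarray,
    t_chrom: np.ndarray,
    t_start: np.ndarray,
    t_end: np.ndarray,
) -> list[tuple[int, int]]:
    """All (query_index, target_index) pairs of half-open interval overlaps."""
    pairs: list[tuple[int, int]] = []
    t_chrom = np.asarray(t_chrom)
    t_start = np.asarray(t_start)
    t_end = np.asarray(t_end)
    for chrom in np.unique(np.asarray(q_chrom)):
        qi = np.flatnonzero(np.asarray(q_chrom) == chrom)
        ti = np.flatnonzero(t_chrom == chrom)
        if len(ti) == 0:
            continue
        ts, te = t_start[ti], t_end[ti]
        order = np.argsort(ts, kind="stable")
        ts, te, ti_s = ts[order], te[order], ti[order]
        for i in qi:
            qs, qe = q_start[i], q_end[i]
            # candidate targets: start < qe, end > qs
            hi = np.searchsorted(ts, qe, side="left")
            for j in range(hi):
                if te[j] > qs:
                    pairs.append((int(i), int(ti_s[j])))
    return pairs


@dataclass
class GeneAnnotation:
    """Gene intervals with functional-category labels and resistance flags.

    ``table`` columns: gene_id, chrom, start, end (0-based half-open),
    categories (list of str, possibly empty), resistance (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if (t["end"] <= t["start"]).any():
            raise ValueError("gene intervals must have end > start")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        t["categories"] = [list(c) if isinstance(c, (list, tuple)) else [] for c in t["categories"]]
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def categories_of(self, gene_id: str) -> list[str]:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        cats = row.iloc[0]["categories"]
        return list(cats) if cats else [NOT_ASSIGNED]

    def category_vocabulary(self) -> list[str]:
        vocab: dict[str, None] = {}
        any_unassigned = False
        for cats in self.table["categories"]:
            if not cats:
                any_unassigned = True
            for c in cats:
                vocab.setdefault(c, None)
        out = list(vocab)
        if any_unassigned:
            out.append(NOT_ASSIGNED)
        return out

    def resistance_genes(self) -> set[str]:
        return set(self.table.loc[self.table["resistance"].astype(bool), "gene_id"])

    def genes_overlapping(self, chrom, start: int, end: int) -> list[str]:
        """Genes whose interval overlaps [start, end) on ``chrom`` (half-open)."""
        t = self.table
        mask = (t["chrom"] == chrom) & (t["start"] < end) & (t["end"] > start)
        return list(t.loc[mask, "gene_id"])

    def genes_containing_position(self, chrom, pos_1based: int) -> list[str]:
        """Genes containing a 1-based point position (e.g. a SNP)."""
        return self.genes_overlapping(chrom, pos_1based - 1, pos_1based)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def read(cls, bed_path, categories_path) -> "GeneAnnotation":
        """Assemble from a BED4 of gene intervals and a category TSV.

        The TSV has columns ``gene_id, category, resistance_flag``; one row
        per (gene, category) pair, resistance constant per gene.  Genes in
        the BED but absent from the TSV get no category and flag False.
        """
        bed = pd.read_csv(
            bed_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
        )
        cats = pd.read_csv(categories_path, sep="\t", dtype=str)
        need = {"gene_id", "category", "resistance_flag"}
        if not need.issubset(cats.columns):
            raise ValueError(f"categories TSV needs columns {sorted(need)}")
        cat_map: dict[str, list[str]] = {}
        res_map: dict[str, bool] = {}
        for _, row in cats.iterrows():
            g = row["gene_id"]
            if pd.notna(row["category"]) and row["category"] != "":
                cat_map.setdefault(g, []).append(row["category"])
            res_map[g] = str(row["resistance_flag"]).lower() in {"1", "true", "yes"}
        table = bed.assign(
            categories=[cat_map.get(g, []) for g in bed["gene_id"]],
            resistance=[res_map.get(g, False) for g in bed["gene_id"]],
        )
        return cls(table=table)

    def write(self, bed_path, categories_path) -> None:
        self.table[["chrom", "start", "end", "gene_id"]].to_csv(
            bed_path, sep="\t", header=False, index=False
        )
        rows = []
        for _, row in self.table.iterrows():
            cats = row["categories"] or [""]
            for c in cats:
                rows.append((row["gene_id"], c, int(bool(row["resistance"]))))
        pd.DataFrame(rows, columns=["gene_id", "category", "resistance_flag"]).to_csv(
            categories_path, sep="\t", index=False
        )
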