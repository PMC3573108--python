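"""Aligned nucleotide matrices for single genes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NUC_INDEX

COMPARTMENTS = ("mitochondrial", "plastid_origin", "nuclear")

#: integer code for a gap/ambiguous character (treated as missing data)
MISSING = 4


@dataclass
class GeneAlignment:
    """One gene's aligned nucleotide matrix.

    rows maps taxon -> gapped uppercase nucleotide string; all rows must
    have equal length.  ``regions`` optionally partitions the columns
    into labelled, non-overlapping, ascending half-open intervals
    (0-based), e.g. the exon/intron structure of a chimeric gene.
    """

    gene_id: str
    rows: dict[str, str]
    compartment: str = "mitochondrial"
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows of unequal length in {self.gene_id}: {sorted(lengths)}")
        self.rows = {t: s.upper() for t, s in self.rows.items()}
        n = self.n_sites
        prev_end = 0
        for label, start, end in self.regions:
            if not (0 <= start < end <= n):
                raise ValueError(f"region {label!r} [{start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError(f"region {label!r} overlaps or is out of order")
            prev_end = end

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values())))

    def codes(self, taxa: list[str] | None = None) -> np.ndarray:
        """Integer matrix (n_taxa, n_sites); non-ACGT becomes MISSING."""
        taxa = taxa or self.taxa
        mat = np.full((len(taxa), self.n_sites), MISSING, dtype=np.int8)
        for i, taxon in enumerate(taxa):
            row = self.rows[taxon]
            mat[i] = [NUC_INDEX.get(c, MISSING) for c in row]
        return mat

    def subset_columns(self, columns) -> "GeneAlignment":
        cols = list(columns)
        rows = {t: "".join(s[c] for c in cols) for t, s in self.rows.items()}
        return GeneAlignment(self.gene_id, rows, self.compartment)

    def region_alignment(self, label: str) -> "GeneAlignment":
        for name, start, end in self.regions:
            if name == label:
                sub = self.subset_columns(range(start, end))
                sub.gene_id = f"{self.gene_id}:{label}"
                return sub
        raise KeyError(f"no region {label!r} in {self.gene_id}")

    def drop_columns(self, columns) -> "GeneAlignment":
        """Remove the given 0-based columns (e.g. declared editing sites)."""
        drop = set(columns)
        keep = [c for c in range(self.n_sites) if c not in drop]
        return GeneAlignment(self.gene_id, {t: "".join(s[c] for c in keep)
                                            for t, s in self.rows.items()},
                             self.compartment)

    def subset_taxa(self, taxa) -> "GeneAlignment":
        missing = [t for t in taxa if t not in self.rows]
        if missing:
            raise KeyError(f"taxa absent from alignment: {missing}")
        return GeneAlignment(self.gene_id, {t: self.rows[t] for t in taxa},
                             self.compartment)

    def empirical_freqs(self) -> np.ndarray:
        counts = np.zeros(4)
        mat = self.codes()
        for i in range(4):
            counts[i] = np.sum(mat == i)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        # small pseudocount keeps frequencies strictly positive
        return (counts + 0.5) / (total + 2.0)


def compress_patterns(align: GeneAlignment, taxa: list[str]):
    """Unique site patterns, their multiplicities, and the site->pattern map.

    Returns (patterns, weights, inverse): patterns is (n_taxa,
    n_patterns) int8, weights the number of alignment columns showing
    each pattern, inverse the pattern index of each original column.
    """
    mat = align.codes(taxa)
    cols, inverse, weights = np.unique(mat, axis=1, return_inverse=True,
                                       return_counts=True)
    return cols, weights.astype(float), inverse.ravel()
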