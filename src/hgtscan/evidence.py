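"""Corroborating evidence streams for transfer calls.

Copy-number estimation by unique k-mer mapping (organellar genes sit at
tens-to-hundreds of copies per cell against two nuclear copies),
expression quantification as RPKM, reading-frame checks, C-to-U RNA
editing detection from genomic/cDNA comparison, and a contamination
screen based on sequence divergence between transgenes and their
current-host homologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import ReadSet, revcomp

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# copy number from unique k-mer mapping


@dataclass
class CoverageRecord:
    gene_id: str
    mapped_kmer_count: int
    length: int
    reads_per_bp: float
    compartment: str | None = None


def estimate_copy_number(reads, genes: dict[str, str], k: int = 25,
                         compartment_of: dict[str, str] | None = None) -> list[CoverageRecord]:
    """Per-gene coverage from zero-mismatch, uniquely mapping k-mers.

    Each read is cut into floor(len/k) non-overlapping k-mers; a k-mer
    contributes to a gene only if it matches exactly one location
    across all supplied genes, on either strand.
    """
    if k < 11:
        raise ValueError("k must be at least 11")
    if not genes:
        raise ValueError("no gene sequences supplied")
    index: dict[str, tuple[str, int] | None] = {}
    for gene_id, seq in genes.items():
        seq = seq.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            canon = min(kmer, revcomp(kmer))
            if canon in index:
                index[canon] = None          # multi-mapping: disqualified
            else:
                index[canon] = (gene_id, pos)
    counts = {g: 0 for g in genes}
    seqs = reads.sequences() if isinstance(reads, ReadSet) else list(reads)
    for read in seqs:
        read = read.upper()
        for i in range(len(read) // k):
            kmer = read[i * k:(i + 1) * k]
            hit = index.get(min(kmer, revcomp(kmer)))
            if hit is not None:
                counts[hit[0]] += 1
    compartment_of = compartment_of or {}
    return [CoverageRecord(g, counts[g], len(genes[g]), counts[g] / len(genes[g]),
                           compartment_of.get(g))
            for g in genes]


@dataclass
class WelchResult:
    mean_a: float
    mean_b: float
    fold: float
    t_statistic: float
    df: float
    p_value: float


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance two-sample t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = np.isclose(a.mean(), b.mean())
        fold = a.mean() / b.mean() if b.mean() != 0 else float("inf")
        return WelchResult(a.mean(), b.mean(), fold,
                           0.0 if equal else float("inf"), float(a.size + b.size - 2),
                           1.0 if equal else 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    fold = a.mean() / b.mean() if b.mean() != 0 else float("inf")
    return WelchResult(float(a.mean()), float(b.mean()), fold, float(t),
                       float(df), float(p))


def compare_compartments(records_a: list[CoverageRecord],
                         records_b: list[CoverageRecord]) -> WelchResult:
    """Welch's t on reads-per-bp between two compartments (e.g.
    organellar vs nuclear gene sets)."""
    return welch_t([r.reads_per_bp for r in records_a],
                   [r.reads_per_bp for r in records_b])


# ---------------------------------------------------------------------------
# expression


def compute_rpkm(counts: dict[str, int], lengths: dict[str, int],
                 total_reads: int) -> dict[str, float]:
    """Reads per kilobase of gene per million library reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    out = {}
    for gene, count in counts.items():
        length = lengths[gene]
        if length <= 0:
            raise ValueError(f"zero length for {gene}")
        out[gene] = count * 1e9 / (total_reads * length)
    return out


def rpkm_from_reads(reads, genes: dict[str, str], k: int = 25,
                    total_reads: int | None = None) -> dict[str, float]:
    """Map cDNA reads by unique k-mers and normalise to RPKM.

    k-mer hits per gene are converted back to read-equivalents before
    normalisation.  The denominator is the total library read count.
    """
    seqs = reads.sequences() if isinstance(reads, ReadSet) else list(reads)
    total = total_reads if total_reads is not None else len(seqs)
    records = estimate_copy_number(reads, genes, k=k)
    kmers_per_read = max(len(seqs[0]) // k, 1) if seqs else 1
    counts = {r.gene_id: r.mapped_kmer_count / kmers_per_read for r in records}
    return compute_rpkm(counts, {g: len(s) for g, s in genes.items()}, total)


# ---------------------------------------------------------------------------
# reading frame


def check_reading_frame(seq: str, frame: int = 0) -> str:
    """'intact' or 'pseudogene' for a declared-frame coding sequence.

    An internal stop codon or a length not divisible by three (a
    frameshift) marks a pseudogene; a trailing stop is allowed.
    """
    seq = seq.upper().replace("-", "")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    coding = seq[frame:]
    if len(coding) % 3 != 0:
        return "pseudogene"
    codons = [coding[i:i + 3] for i in range(0, len(coding), 3)]
    for codon in codons[:-1]:
        if codon in STOPS:
            return "pseudogene"
    return "intact"


# ---------------------------------------------------------------------------
# RNA editing


def detect_c2u_editing(genomic: str, cdna: str):
    """C-to-U editing sites from a genomic/cDNA pairwise alignment.

    Returns (edited, non_canonical): 1-based positions on the genomic
    coordinate where genomic C faces cDNA T, and all other mismatch
    positions.  Gapped positions are skipped.
    """
    if len(genomic) != len(cdna):
        raise ValueError("genomic and cDNA sequences differ in length")
    edited, other = [], []
    pos = 0
    for g, c in zip(genomic.upper(), cdna.upper()):
        if g != "-":
            pos += 1
        if g in "-N" or c in "-N":
            continue
        if g == c:
            continue
        if g == "C" and c == "T":
            edited.append(pos)
        else:
            other.append(pos)
    return edited, other


# ---------------------------------------------------------------------------
# divergence-based contamination screen


def p_distance(a: str, b: str) -> float | None:
    """Uncorrected distance over unambiguous compared sites; None when
    no site is comparable."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    diffs = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        diffs += x != y
    if compared == 0:
        return None
    return diffs / compared


@dataclass
class ContaminationReport:
    transgene_distances: dict
    mean_transgene_distance: float
    host_distances: dict
    mean_host_distance: float
    welch: WelchResult | None
    flagged_identical: list = field(default_factory=list)


def contamination_screen(transgene_pairs: dict[str, tuple[str, str]],
                         host_pairs: dict[str, tuple[str, str]]) -> ContaminationReport:
    """Compare transgene-to-current-host divergence against the
    divergence between the two host species.

    Transgenes identical to the host homolog (distance zero) are
    flagged as possible contamination; pairs with no comparable sites
    are excluded with a warning.
    """

    def distances(pairs):
        out = {}
        for name, (x, y) in pairs.items():
            d = p_distance(x, y)
            if d is None:
                warnings.warn(f"no comparable sites for {name}; excluded")
                continue
            out[name] = d
        return out

    td = distances(transgene_pairs)
    hd = distances(host_pairs)
    if not td or not hd:
        raise ValueError("need at least one usable pair in each group")
    welch = None
    if len(td) >= 2 and len(hd) >= 2:
        welch = welch_t(list(td.values()), list(hd.values()))
    return ContaminationReport(
        td, float(np.mean(list(td.values()))),
        hd, float(np.mean(list(hd.values()))),
        welch, sorted(n for n, d in td.items() if d == 0.0))
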