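"""Dating transfers and reading synteny.

A transfer shared by both parasite genera whose transgenes form a
supported clade predates their split (ancient); transgenes confined to
one genus are recent; transgenes from two genera (or several copies in
one species) that fail to form a clade mark repeated independent
transfers of the same gene.  Contig gene orders compared against donor
and recipient references reveal whether a transgene kept the donor's
neighbourhood — the signature of displacement of the native copy by
homologous recombination — and per-region classifications of a
partitioned gene localise the recombination breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import GeneAlignment
from .classify import base_taxon, classify_sequence
from .io import HGTCall
from .panel import TaxonPanel
from .phylo import SupportTree, bootstrap_support


def genus_of(taxon: str) -> str:
    return base_taxon(taxon).split("_")[0].split("|")[0]


@dataclass
class TimingCall:
    gene_id: str
    verdict: str                       # ancient | recent | repeated_independent
    transgene_taxa: set = field(default_factory=set)
    monophyletic: bool | None = None
    support: int | None = None
    synteny_agreement: bool | None = None


def classify_timing(stree: SupportTree, calls: list[HGTCall],
                    panel: TaxonPanel, min_bp: int = 50) -> TimingCall:
    """Ancient / recent / repeated verdict for one gene's transfers.

    ``calls`` are this gene's calls; at least one must be an HGT call.
    Transgene leaves are matched to calls by species name (dual-homolog
    copies carry a ``|hgt`` suffix in the tree).
    """
    hgt_calls = [c for c in calls if c.identity == "HGT"]
    if not hgt_calls:
        raise ValueError("no HGT call for this gene")
    gene_id = hgt_calls[0].gene_id
    hgt_species = {c.species for c in hgt_calls}
    leaves = set()
    missing = []
    for sp in hgt_species:
        if sp + "|hgt" in stree.taxa:      # dual-homolog: the moved copy
            leaves.add(sp + "|hgt")
        elif sp in stree.taxa:
            leaves.add(sp)
        else:
            missing.append(sp)
    if missing:
        raise KeyError(f"transgene taxa absent from tree: {sorted(missing)}")
    genera = {genus_of(l) for l in leaves}
    n_copies_per_species = {}
    for c in hgt_calls:
        n_copies_per_species[c.species] = n_copies_per_species.get(c.species, 0) + 1
    multi_copy = any(n > 1 for n in n_copies_per_species.values())
    mono = stree.tree.has_clade(leaves)
    support = stree.support_of(leaves) if len(leaves) > 1 else None
    if len(genera) >= 2:
        if mono and (support or 0) >= min_bp:
            verdict = "ancient"
        else:
            verdict = "repeated_independent"
    elif multi_copy and not mono:
        verdict = "repeated_independent"
    else:
        verdict = "recent"
    return TimingCall(gene_id, verdict, leaves, mono, support)


# ---------------------------------------------------------------------------
# synteny


@dataclass
class Contig:
    """An assembled contig as an ordered run of gene segments."""

    contig_id: str
    segments: list              # (gene_id, strand '+'/'-', class)
    length_kb: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("contig must contain at least one segment")

    @property
    def gene_order(self) -> list[str]:
        return [g for g, _, _ in self.segments]


def read_contig_table(path) -> list[Contig]:
    """Contig TSV: contig_id, position, gene_id, strand, class."""
    rows: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            cid = parts[idx["contig_id"]]
            rows.setdefault(cid, []).append(
                (int(parts[idx["position"]]), parts[idx["gene_id"]],
                 parts[idx["strand"]], parts[idx["class"]]))
    out = []
    for cid, segs in rows.items():
        segs.sort()
        out.append(Contig(cid, [(g, s, k) for _, g, s, k in segs]))
    return out


def _adjacencies(order, strands=None, match_strand=False):
    pairs = set()
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        if match_strand and strands is not None:
            key = tuple(sorted([(a, strands[i]), (b, strands[i + 1])]))
        else:
            key = frozenset((a, b)) if a != b else (a, b)
        pairs.add(key)
    return pairs


def shared_adjacencies(contig: Contig, reference_orders: dict[str, list],
                       match_strand: bool = False) -> dict[str, set]:
    """Which reference source shares each adjacent gene pair of the contig.

    ``reference_orders`` maps source name -> gene order (list of gene
    ids, or (gene, strand) tuples).  Adjacency is unordered; strand
    agreement is only required with ``match_strand``.
    """
    strands = [s for _, s, _ in contig.segments]
    contig_pairs = _adjacencies(contig.gene_order, strands, match_strand)
    out: dict[str, set] = {}
    for source, order in reference_orders.items():
        if order and isinstance(order[0], (tuple, list)):
            genes = [g for g, *_ in order]
            ref_strands = [s for _, s, *_ in order]
        else:
            genes = list(order)
            ref_strands = None
        ref_pairs = _adjacencies(genes, ref_strands, match_strand)
        out[source] = contig_pairs & ref_pairs
    return out


# ---------------------------------------------------------------------------
# breakpoint localisation


@dataclass
class BreakpointReport:
    gene_id: str
    region_classes: list        # (label, identity, bp)
    breakpoints: list           # (column_lo, column_hi) candidate junctions


def localize_breakpoint(align: GeneAlignment,
                        region_calls: dict[str, HGTCall],
                        min_columns: int = 100) -> BreakpointReport:
    """Region-level breakpoint localisation of a chimeric gene.

    Each labelled region of the alignment carries a classification;
    adjacent regions with differing (assigned) classes delimit a
    candidate recombination breakpoint at their junction.  Regions
    shorter than ``min_columns`` are reported unassigned.
    """
    if len(align.regions) < 2:
        raise ValueError("need at least 2 labelled regions")
    classes = []
    for label, start, end in align.regions:
        call = region_calls.get(label)
        if end - start < min_columns or call is None:
            classes.append((label, "unassigned", call.bp if call else None))
            continue
        classes.append((label, call.identity, call.bp))
    # candidate junctions lie between consecutive *assigned* regions of
    # differing class; unassigned regions in between widen the interval
    assigned = [(i, cls) for i, (_, cls, _) in enumerate(classes)
                if cls != "unassigned"]
    breakpoints = []
    for (i, a), (j, b) in zip(assigned, assigned[1:]):
        if a != b:
            breakpoints.append((align.regions[i][2], align.regions[j][1]))
    return BreakpointReport(align.gene_id, classes, breakpoints)


def localize_breakpoint_from_alignment(align: GeneAlignment, panel: TaxonPanel,
                                       query: str, threshold: int = 70,
                                       reps: int = 100, seed: int = 0,
                                       min_columns: int = 100) -> BreakpointReport:
    """Classify each labelled region by its own ML tree and localise
    breakpoints between differing region classes.

    Substitution-model parameters are estimated once on the whole
    alignment and shared across the region fits."""
    from .phylo import _start_tree, estimate_parameters

    taxa = sorted(align.rows)
    params = estimate_parameters(align, _start_tree(align, taxa),
                                 engine_taxa=taxa)
    region_calls = {}
    for i, (label, start, end) in enumerate(align.regions):
        if end - start < min_columns:
            continue
        sub = align.region_alignment(label)
        stree = bootstrap_support(sub, params=params, reps=reps, seed=seed + i)
        region_calls[label] = classify_sequence(stree, query, panel,
                                                threshold=threshold,
                                                gene_id=sub.gene_id)
    return localize_breakpoint(align, region_calls, min_columns=min_columns)
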