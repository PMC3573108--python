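"""The core decision procedure: VGT / HGT / unassigned calls.

A parasite sequence is classified from its position in an
outgroup-rooted, bootstrap-annotated gene tree.  Walking rootward from
the query, the first ancestor whose descendants include a non-parasite
leaf defines the placement clade; its bootstrap percentage is the
support of the placement.  Below the threshold the sequence is left
unassigned; at or above it, placement with the parasites' closest
autotrophic relative is a vertical call, and any other placement is a
horizontal call whose donor is the narrowest named lineage covering the
non-parasite leaves of the placement clade (current-host genus, then
host family, then other reference lineages; a composite name when no
single lineage covers them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import GeneAlignment
from .io import HGTCall, PipelineConfig
from .panel import TaxonPanel
from .phylo import SupportTree, bootstrap_support
from .treeutil import RootedNode, root_on_outgroup


def base_taxon(leaf_name: str) -> str:
    """Panel taxon behind a leaf label (dual-homolog copies carry a
    ``|hgt`` suffix)."""
    return leaf_name.split("|")[0]


@dataclass
class PlacementEvidence:
    """Where a query sequence sits in its gene tree."""

    query: str
    placement_clade: set          # leaf labels of the placement clade
    bp: int                       # support of that clade (0 if none recorded)
    donor_taxa: set               # non-parasite leaves in it (panel names)
    nested: bool = False          # attaches inside (vs sister to) the donors
    outgroup_monophyletic: bool = True


def placement_evidence(stree: SupportTree, query: str,
                       panel: TaxonPanel) -> PlacementEvidence:
    """Locate the first reference-containing ancestor of ``query``."""
    leaf_taxa = {base_taxon(l) for l in stree.taxa}
    panel.check_taxa(leaf_taxa)
    if query not in stree.taxa:
        raise KeyError(f"query {query!r} not in tree")
    outgroup = {l for l in stree.taxa if panel.role(base_taxon(l)) == "outgroup"}
    rooted, mono = root_on_outgroup(stree.tree, outgroup, stree.supports)
    node = rooted.find_leaf(query)
    current = node.parent
    while current is not None:
        leaves = current.leaves()
        non_parasite = {l for l in leaves
                        if panel.role(base_taxon(l)) != "parasite"}
        if non_parasite:
            break
        node, current = current, current.parent
    if current is None:
        raise RuntimeError("no non-parasite leaf in tree")
    bp = current.support
    if bp is None and current.parent is None:
        # the rooting edge: both root children carry the same bipartition
        bp = next((c.support for c in current.children if c.support is not None), None)
    donors = {base_taxon(l) for l in non_parasite}
    nested = _nested_in_donors(current, donors, panel)
    return PlacementEvidence(query, set(leaves), int(bp) if bp is not None else 0,
                             donors, nested, mono)


def _nested_in_donors(placement: RootedNode, donors: set, panel: TaxonPanel) -> bool:
    """True when the parent of the placement clade still draws all its
    non-parasite leaves from the same named lineage, i.e. the query sits
    inside the donor group rather than sister to it."""
    lineages = {panel.lineage(t) for t in donors}
    parent = placement.parent
    if parent is None or len(lineages) != 1:
        return False
    parent_refs = {panel.lineage(base_taxon(l)) for l in parent.leaves()
                   if panel.role(base_taxon(l)) != "parasite"}
    return parent_refs == lineages


def donor_lineage_name(donor_taxa: set, panel: TaxonPanel) -> str:
    """Narrowest named lineage covering the donors: current-host genus,
    then host family, then a single reference lineage, else the
    composite of the lineages involved."""
    current_host = panel.with_role("current_host")
    if donor_taxa <= current_host:
        return panel.lineage(next(iter(donor_taxa)))
    lineages = sorted({panel.lineage(t) for t in donor_taxa})
    if len(lineages) == 1:
        return lineages[0]
    if donor_taxa <= panel.hosts:
        host_family = {panel.lineage(t) for t in panel.with_role("host_clade")}
        if len(host_family) == 1:
            return next(iter(host_family))
    return "+".join(lineages)


def classify_sequence(stree: SupportTree, query: str, panel: TaxonPanel,
                      threshold: int = 70, gene_id: str | None = None,
                      compartment: str = "mitochondrial") -> HGTCall:
    """Call one parasite sequence VGT, HGT, or unassigned."""
    evidence = placement_evidence(stree, query, panel)
    gene_id = gene_id or "gene"
    species = base_taxon(query)
    vgt_lineages = {panel.lineage(t) for t in panel.vgt_sister}
    if evidence.bp < threshold:
        return HGTCall(gene_id, species, "unassigned", bp=evidence.bp,
                       compartment=compartment)
    if evidence.donor_taxa <= panel.vgt_sister or \
            {panel.lineage(t) for t in evidence.donor_taxa} <= vgt_lineages:
        return HGTCall(gene_id, species, "VGT", bp=evidence.bp,
                       compartment=compartment)
    donor = donor_lineage_name(evidence.donor_taxa, panel)
    return HGTCall(gene_id, species, "HGT", donor_lineage=donor,
                   bp=evidence.bp, compartment=compartment,
                   attachment="nested within" if evidence.nested else "sister to")


# ---------------------------------------------------------------------------
# per-gene pipeline convenience


def analyze_gene(align: GeneAlignment, panel: TaxonPanel,
                 config: PipelineConfig | None = None, seed: int = 0,
                 reps: int | None = None, threshold: int | None = None,
                 queries: list[str] | None = None,
                 exclude_editing_sites: list[int] | None = None):
    """Fit the ML tree with bootstrap supports and classify every
    parasite sequence in the alignment.

    ``exclude_editing_sites`` drops the given 1-based columns before
    inference (the RNA-editing robustness mode).  Returns
    (SupportTree, list of HGTCall).
    """
    config = config or PipelineConfig()
    reps = reps if reps is not None else config.bootstrap_reps
    threshold = threshold if threshold is not None else config.bp_threshold_strict
    if exclude_editing_sites:
        align = align.drop_columns([p - 1 for p in exclude_editing_sites])
    stree = bootstrap_support(align, reps=reps, seed=seed)
    if queries is None:
        queries = sorted(l for l in stree.taxa
                         if panel.role(base_taxon(l)) == "parasite")
    calls = [classify_sequence(stree, q, panel, threshold=threshold,
                               gene_id=align.gene_id,
                               compartment=align.compartment)
             for q in queries]
    return stree, calls


# ---------------------------------------------------------------------------
# summaries


@dataclass
class CallSummary:
    """Counts over a filtered set of calls at one bootstrap threshold."""

    threshold: int
    n_hgt_sequences: int = 0
    n_hgt_genes: int = 0
    n_vgt_sequences: int = 0
    n_dual_homolog_genes: int = 0
    n_au_rejections: int = 0
    n_intact_transgenes: int = 0
    n_pseudogene_transgenes: int = 0
    hgt_genes: list = field(default_factory=list)
    dual_homolog_genes: list = field(default_factory=list)
    fraction_hgt: float | None = None


def summarize_calls(calls: list[HGTCall], threshold: int = 70,
                    species: str | None = None, compartment: str | None = None,
                    alpha: float = 0.05,
                    denominator: int | None = None) -> CallSummary:
    """Tabulate HGT evidence at a bootstrap threshold.

    Counts HGT sequences and distinct HGT genes meeting the threshold,
    genes retaining both a vertical and a horizontal homolog, AU
    rejections among threshold-passing transgenes, and reading-frame
    status of transgenes.  ``fraction_hgt`` is filled only when a
    denominator (number of threshold-passing sequences) is supplied.
    """
    if species is not None:
        known = {c.species for c in calls}
        if species not in known:
            raise ValueError(f"unknown species filter {species!r}")
        calls = [c for c in calls if c.species == species]
    if compartment is not None:
        calls = [c for c in calls if c.compartment == compartment]
    summary = CallSummary(threshold)
    hgt = [c for c in calls if c.identity == "HGT" and c.bp >= threshold]
    vgt = [c for c in calls if c.identity == "VGT" and c.bp >= threshold]
    summary.n_hgt_sequences = len(hgt)
    summary.n_vgt_sequences = len(vgt)
    summary.hgt_genes = sorted({c.gene_id for c in hgt})
    summary.n_hgt_genes = len(summary.hgt_genes)
    vgt_genes = {c.gene_id for c in vgt}
    summary.dual_homolog_genes = sorted(set(summary.hgt_genes) & vgt_genes)
    summary.n_dual_homolog_genes = len(summary.dual_homolog_genes)
    summary.n_au_rejections = sum(
        1 for c in hgt if c.au_p is not None and not c.au_ns and c.au_p <= alpha)
    summary.n_intact_transgenes = sum(1 for c in hgt if c.frame == "intact")
    summary.n_pseudogene_transgenes = sum(1 for c in hgt if c.frame == "pseudogene")
    if denominator:
        summary.fraction_hgt = summary.n_hgt_sequences / denominator
    return summary
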