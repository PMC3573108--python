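"""Synthetic study-shaped datasets with known ground truth.

The generator emulates the structure of a host/parasite phylogenomic
study: an ultrametric seed-plant species tree whose taxa carry panel
roles (outgroup, autotrophic references, the parasites' closest
autotrophic relative, the host family, the current host genus, and the
holoparasites), per-gene histories that are either vertical or involve
one or more host-to-parasite transfers (prune-and-regraft on the dated
tree), GTR+G sequence evolution with discrete-gamma rate variation,
pseudogenisation by nonsense mutations, C-to-U RNA editing visible as
genomic C versus cDNA T, shotgun reads at compartment-specific depths,
and contigs mixing native genes and transgenes.  Every emitted gene is
recorded in a machine-readable truth table for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import GeneAlignment
from .model import GTRGammaParams, GTRModel, NUC
from .panel import TaxonPanel

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# dated (ultrametric) species and gene trees


@dataclass
class Clade:
    """Node of a rooted dated tree; ``age`` in arbitrary time units
    (leaves at age 0), ``blen`` in expected substitutions per site once
    the tree has been rate-scaled."""

    name: str | None = None
    age: float = 0.0
    children: list = field(default_factory=list)
    blen: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_clades(self):
        yield self
        for c in self.children:
            yield from c.iter_clades()

    def copy(self) -> "Clade":
        return Clade(self.name, self.age,
                     [c.copy() for c in self.children], self.blen)

    def find_clade(self, taxa: frozenset | set) -> "Clade":
        taxa = frozenset(taxa)
        for node in self.iter_clades():
            if frozenset(node.leaves()) == taxa:
                return node
        raise KeyError(f"no clade with exactly {sorted(taxa)}")

    def prune_to(self, taxa) -> "Clade":
        """Restriction of the dated tree to a taxon subset."""
        keep = set(taxa)

        def walk(node):
            if node.is_leaf:
                return node.copy() if node.name in keep else None
            kids = [w for w in (walk(c) for c in node.children) if w is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return Clade(node.name, node.age, kids)

        out = walk(self)
        if out is None:
            raise ValueError("no requested taxa in tree")
        return out

    def scale_to_substitutions(self, rate: float) -> "Clade":
        """Set branch lengths to (age difference) x rate."""
        out = self.copy()

        def walk(node, parent_age):
            node.blen = max((parent_age - node.age) * rate, 0.0)
            for c in node.children:
                walk(c, node.age)

        walk(out, out.age)
        return out

    def newick(self, lengths: str = "blen") -> str:
        def fmt(node, parent):
            if node.is_leaf:
                label = node.name
            else:
                label = "(" + ",".join(fmt(c, node) for c in node.children) + ")"
                if node.name:
                    label += node.name
            if parent is not None:
                value = node.blen if lengths == "blen" else parent.age - node.age
                label += f":{value:.6f}"
            return label

        return fmt(self, None) + ";"


def species_tree_15() -> Clade:
    """Reduced 15-taxon panel: ultrametric, ages in Ma-like units."""
    tet = Clade(age=15, children=[Clade("Tetrastigma_A"), Clade("Tetrastigma_B")])
    vit = Clade(age=60, children=[Clade("Vitis"), tet])
    vitaceae = Clade(age=95, children=[Clade("Leea"), vit])
    raff = Clade(age=72, children=[
        Clade(age=20, children=[Clade("Rafflesia_A"), Clade("Rafflesia_B")]),
        Clade("Sapria")])
    malp = Clade(age=90, children=[Clade("Ricinus"), raff])
    malvid = Clade(age=112, children=[Clade("Arabidopsis"), malp])
    fabid = Clade(age=118, children=[Clade("Cucumis"), malvid])
    rosid = Clade(age=125, children=[vitaceae, fabid])
    asterid = Clade(age=132, children=[Clade("Daucus"), rosid])
    eudicot = Clade(age=140, children=[Clade("Beta"), asterid])
    monocot = Clade(age=100, children=[Clade("Spirodela"), Clade("Oryza")])
    angio = Clade(age=160, children=[monocot, eudicot])
    return Clade(age=300, children=[Clade("Cycas"), angio])


def species_tree_33() -> Clade:
    """Full-size 33-taxon angiosperm panel with family structure."""
    poaceae = Clade(age=50, children=[
        Clade("Oryza"),
        Clade(age=30, children=[
            Clade("Triticum"),
            Clade(age=15, children=[
                Clade("Sorghum"),
                Clade(age=8, children=[Clade("Zea"), Clade("Tripsacum")])])])])
    monocot = Clade(age=110, children=[
        Clade("Spirodela"), Clade(age=95, children=[Clade("Phoenix"), poaceae])])
    brassicaceae = Clade(age=25, children=[
        Clade("Arabidopsis"),
        Clade(age=15, children=[Clade("Brassica"), Clade("Raphanus")])])
    brassicales = Clade(age=70, children=[Clade("Carica"), brassicaceae])
    fabaceae = Clade(age=50, children=[
        Clade("Lotus"),
        Clade(age=35, children=[Clade("Millettia"), Clade("Vigna")])])
    cucurbitaceae = Clade(age=35, children=[
        Clade("Cucurbita"),
        Clade(age=20, children=[Clade("Citrullus"), Clade("Cucumis")])])
    rosaceae = Clade(age=100, children=[Clade("Malus"), cucurbitaceae])
    raff = Clade(age=75, children=[
        Clade(age=20, children=[Clade("Rafflesia_cantleyi"),
                                Clade("Rafflesia_tuanmudae")]),
        Clade("Sapria_himalayana")])
    malpighiales = Clade(age=95, children=[Clade("Ricinus"), raff])
    malvids = Clade(age=105, children=[brassicales, malpighiales])
    fabids = Clade(age=112, children=[fabaceae, Clade(age=108, children=[rosaceae, malvids])])
    tet = Clade(age=15, children=[Clade("Tetrastigma_rafflesiae"),
                                  Clade("Tetrastigma_cruciatum")])
    vit = Clade(age=60, children=[Clade("Vitis"), tet])
    vitaceae = Clade(age=95, children=[Clade("Leea"), vit])
    rosids = Clade(age=122, children=[vitaceae, fabids])
    asterids = Clade(age=100, children=[
        Clade("Daucus"),
        Clade(age=80, children=[
            Clade("Nicotiana"),
            Clade(age=60, children=[Clade("Mimulus"), Clade("Boea")])])])
    caryo = Clade(age=70, children=[Clade("Beta"), Clade("Silene")])
    core = Clade(age=130, children=[caryo, Clade(age=126, children=[asterids, rosids])])
    angio = Clade(age=160, children=[monocot, core])
    return Clade(age=300, children=[Clade("Cycas"), angio])


_LINEAGES_15 = {
    "Cycas": "Cycadaceae", "Spirodela": "Araceae", "Oryza": "Poaceae",
    "Beta": "Caryophyllales", "Daucus": "Apiaceae", "Cucumis": "Cucurbitaceae",
    "Arabidopsis": "Brassicaceae", "Ricinus": "Euphorbiaceae",
    "Leea": "Vitaceae", "Vitis": "Vitaceae",
    "Tetrastigma_A": "Tetrastigma", "Tetrastigma_B": "Tetrastigma",
    "Rafflesia_A": "Rafflesiaceae", "Rafflesia_B": "Rafflesiaceae",
    "Sapria": "Rafflesiaceae",
}


def panel_15() -> TaxonPanel:
    roles = {
        "Cycas": "outgroup", "Spirodela": "outgroup",
        "Oryza": "reference", "Beta": "reference", "Daucus": "reference",
        "Cucumis": "reference", "Arabidopsis": "reference",
        "Ricinus": "vgt_sister",
        "Leea": "host_clade", "Vitis": "host_clade",
        "Tetrastigma_A": "current_host", "Tetrastigma_B": "current_host",
        "Rafflesia_A": "parasite", "Rafflesia_B": "parasite",
        "Sapria": "parasite",
    }
    return TaxonPanel(roles, dict(_LINEAGES_15))


def panel_33() -> TaxonPanel:
    tree = species_tree_33()
    fam = {
        "Cycas": "Cycadaceae", "Spirodela": "Araceae", "Phoenix": "Arecaceae",
        "Oryza": "Poaceae", "Triticum": "Poaceae", "Sorghum": "Poaceae",
        "Zea": "Poaceae", "Tripsacum": "Poaceae",
        "Arabidopsis": "Brassicaceae", "Brassica": "Brassicaceae",
        "Raphanus": "Brassicaceae", "Carica": "Caricaceae",
        "Lotus": "Fabaceae", "Millettia": "Fabaceae", "Vigna": "Fabaceae",
        "Cucurbita": "Cucurbitaceae", "Citrullus": "Cucurbitaceae",
        "Cucumis": "Cucurbitaceae",
        "Malus": "Rosaceae", "Ricinus": "Euphorbiaceae",
        "Nicotiana": "Solanaceae", "Mimulus": "Phrymaceae", "Boea": "Gesneriaceae",
        "Beta": "Caryophyllales", "Silene": "Caryophyllales", "Daucus": "Apiaceae",
        "Leea": "Vitaceae", "Vitis": "Vitaceae",
        "Tetrastigma_rafflesiae": "Tetrastigma", "Tetrastigma_cruciatum": "Tetrastigma",
        "Rafflesia_cantleyi": "Rafflesiaceae", "Rafflesia_tuanmudae": "Rafflesiaceae",
        "Sapria_himalayana": "Rafflesiaceae",
    }
    roles = {}
    for taxon in tree.leaves():
        if taxon in ("Cycas", "Spirodela"):
            roles[taxon] = "outgroup"
        elif taxon == "Ricinus":
            roles[taxon] = "vgt_sister"
        elif taxon.startswith("Tetrastigma"):
            roles[taxon] = "current_host"
        elif taxon in ("Leea", "Vitis"):
            roles[taxon] = "host_clade"
        elif taxon.startswith(("Rafflesia", "Sapria")):
            roles[taxon] = "parasite"
        else:
            roles[taxon] = "reference"
    return TaxonPanel(roles, {t: fam.get(t, t) for t in tree.leaves()})


# ---------------------------------------------------------------------------
# transfer events and gene trees


@dataclass
class TransferEvent:
    """One host-to-parasite transfer on the dated species tree.

    ``donor_branch`` names the species-tree branch by the leaf set of
    the clade immediately below it; ``transfer_time`` is a relative
    depth in (0, 1) as a fraction of the root age.  When
    ``displaces_native`` is False the recipients keep their vertical
    copy and the transferred copy appears as extra leaves suffixed
    ``|hgt`` (a dual-homolog gene)."""

    gene_id: str
    recipient_clade: frozenset
    donor_branch: frozenset
    transfer_time: float
    displaces_native: bool = True
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.transfer_time < 1.0:
            raise ValueError("transfer_time must be a relative depth in (0, 1)")


def simulate_gene_tree(species_tree: Clade, events=None) -> Clade:
    """Gene tree implied by zero or more transfers (prune + regraft).

    Each event detaches the recipient clade and reattaches its stem on
    the donor branch at the transfer depth; elapsed-time branch lengths
    are preserved, so an ultrametric species tree yields an ultrametric
    gene tree."""
    tree = species_tree.copy()
    if not events:
        return tree
    if isinstance(events, TransferEvent):
        events = [events]
    for event in events:
        age = event.transfer_time * species_tree.age
        recipient = tree.find_clade(event.recipient_clade)
        if recipient.age >= age:
            raise ValueError(
                f"recipient crown ({recipient.age}) is older than the "
                f"transfer ({age:.1f})")
        suffix = "" if event.displaces_native else "|hgt"
        moved = recipient.copy() if event.displaces_native else _relabel(recipient, suffix)
        if event.displaces_native:
            _detach(tree, recipient)
        donor = _find_donor(tree, event.donor_branch)
        parent = _parent_of(tree, donor)
        if parent is None:
            raise ValueError("cannot regraft onto the root branch")
        if not (donor.age < age < parent.age):
            raise ValueError(
                f"transfer depth {age:.1f} outside donor branch "
                f"interval ({donor.age}, {parent.age})")
        joint = Clade(age=age, children=[donor, moved])
        parent.children[parent.children.index(donor)] = joint
    return tree


def _relabel(clade: Clade, suffix: str) -> Clade:
    out = clade.copy()
    for node in out.iter_clades():
        if node.is_leaf:
            node.name = node.name + suffix
    return out


def _find_donor(tree: Clade, donor_leaves: frozenset) -> Clade:
    """Donor clade by original leaf set, tolerant of |hgt decorations."""
    want = frozenset(donor_leaves)
    for node in tree.iter_clades():
        base = frozenset(l.split("|")[0] for l in node.leaves())
        if base == want and not any("|" in l for l in node.leaves()):
            return node
    raise KeyError(f"no donor clade {sorted(want)} in gene tree")


def _parent_of(tree: Clade, target: Clade) -> Clade | None:
    for node in tree.iter_clades():
        if target in node.children:
            return node
    return None


def _detach(tree: Clade, target: Clade) -> None:
    parent = _parent_of(tree, target)
    if parent is None:
        raise ValueError("cannot detach the root")
    parent.children.remove(target)
    if len(parent.children) == 1:
        # suppress the unary node
        only = parent.children[0]
        grand = _parent_of(tree, parent)
        if grand is None:
            # root becomes the remaining child
            parent.name, parent.age = only.name, only.age
            parent.children = only.children
        else:
            grand.children[grand.children.index(parent)] = only


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_alignment(tree: Clade, params: GTRGammaParams, n_sites: int,
                       seed=None, gene_id: str = "gene") -> GeneAlignment:
    """Evolve ``n_sites`` independent sites along a substitution-scaled
    tree (``blen`` in expected substitutions/site) under GTR+G."""
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model = GTRModel(params)
    cats = rng.integers(0, model.n_cat, size=n_sites)
    root_states = rng.choice(4, size=n_sites, p=model.pi)
    rows: dict[str, str] = {}

    def evolve(node: Clade, states: np.ndarray) -> None:
        if node.blen > 0:
            P = model.pmats(node.blen)
            out = np.empty_like(states)
            for k in range(model.n_cat):
                mask = cats == k
                if not mask.any():
                    continue
                cum = P[k].cumsum(axis=1)
                u = rng.random(int(mask.sum()))
                out[mask] = (u[:, None] > cum[states[mask]]).sum(axis=1)
            states = out
        if node.is_leaf:
            rows[node.name] = "".join(NUC[s] for s in states)
        else:
            for child in node.children:
                evolve(child, states)

    for child in ([tree] if tree.is_leaf else tree.children):
        evolve(child, root_states)
    if tree.is_leaf:
        rows[tree.name] = "".join(NUC[s] for s in root_states)
    return GeneAlignment(gene_id, rows)


def pseudogenize(seq: str, rng: np.random.Generator, n_stops: int | None = None) -> str:
    """Inject 1-3 premature stop codons at random internal codons."""
    n_codons = len(seq) // 3
    if n_codons < 3:
        return seq
    if n_stops is None:
        n_stops = int(rng.integers(1, 4))
    positions = rng.choice(np.arange(1, n_codons - 1), size=min(n_stops, n_codons - 2),
                           replace=False)
    out = list(seq)
    for p in positions:
        stop = STOP_CODONS[rng.integers(0, 3)]
        out[3 * p:3 * p + 3] = stop
    return "".join(out)


def inject_editing(genomic: str, rng: np.random.Generator,
                   n_sites: int) -> tuple[str, list[int]]:
    """C-to-U editing: returns (cdna, 1-based genomic positions edited).

    The genomic sequence keeps its C; the cDNA shows T at edited sites."""
    c_positions = [i for i, b in enumerate(genomic) if b == "C"]
    if not c_positions or n_sites == 0:
        return genomic, []
    chosen = sorted(rng.choice(c_positions, size=min(n_sites, len(c_positions)),
                               replace=False).tolist())
    cdna = list(genomic)
    for p in chosen:
        cdna[p] = "T"
    return "".join(cdna), [p + 1 for p in chosen]


def simulate_chimeric_alignment(species_tree: Clade, event: TransferEvent,
                                params: GTRGammaParams, rate: float,
                                regions: list[tuple[str, int, int]],
                                transferred_regions: set[str],
                                seed=None, gene_id: str = "chimera") -> GeneAlignment:
    """A gene whose labelled regions follow different histories.

    Two alignments of the full length are simulated — one on the
    vertical species tree, one on the transferred gene tree — and
    spliced at the region boundaries: columns of regions named in
    ``transferred_regions`` come from the transferred history
    (emulating displacement of part of a gene by homologous
    recombination, with the breakpoint at the region junction)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_sites = regions[-1][2]
    vertical = simulate_alignment(species_tree.scale_to_substitutions(rate),
                                  params, n_sites, seed=rng)
    gtree = simulate_gene_tree(species_tree, event)
    transferred = simulate_alignment(gtree.scale_to_substitutions(rate),
                                     params, n_sites, seed=rng)
    rows = {}
    for taxon in vertical.rows:
        chunks = []
        for label, start, end in regions:
            src = transferred if label in transferred_regions else vertical
            chunks.append(src.rows[taxon][start:end])
        rows[taxon] = "".join(chunks)
    return GeneAlignment(gene_id, rows, regions=list(regions))


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    """Simulated shotgun reads labelled with their true source."""

    reads: list  # (read_id, sequence, source_id)

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self):
        return [r[1] for r in self.reads]

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, seq, src in self.reads:
                fh.write(f">{rid} source={src}\n{seq}\n")


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(source_seqs: dict[str, str], depth_of: dict[str, float],
                   read_len: int = 100, error_rate: float = 0.0,
                   seed=None) -> ReadSet:
    """Uniformly positioned error-bearing reads from both strands.

    The read count per source is Poisson with mean depth x length /
    read_len; sources shorter than the read length are skipped."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    reads = []
    for src, seq in source_seqs.items():
        depth = depth_of.get(src, 0.0)
        if depth < 0:
            raise ValueError(f"negative depth for {src}")
        if depth == 0:
            continue
        if len(seq) < read_len:
            continue
        n_reads = rng.poisson(depth * len(seq) / read_len)
        starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i, (start, minus) in enumerate(zip(starts, strands)):
            read = seq[start:start + read_len]
            if minus:
                read = revcomp(read)
            if error_rate > 0:
                arr = list(read)
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                for e in errs:
                    arr[e] = NUC[(NUC.index(arr[e]) + rng.integers(1, 4)) % 4] \
                        if arr[e] in NUC else arr[e]
                read = "".join(arr)
            reads.append((f"{src}_r{i}", read, src))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# whole-dataset orchestration


@dataclass
class Scenario:
    """Shape of a simulated study.

    Defaults are the desk-scale study conditions: a 15-taxon panel, 20
    genes of 1,000 sites, 40% of genes transferred, a mitochondrial to
    nuclear copy-number contrast of 75:1, plant-mitochondria-flavoured
    GTR+G parameters and a clock rate of 1e-3 substitutions/site/My."""

    name: str = "study-small"
    n_taxa: int = 15
    n_genes: int = 20
    n_sites: int = 1000
    frac_transferred: float = 0.4
    pseudogene_fraction: float = 0.3
    editing_fraction: float = 0.3
    mean_editing_sites: float = 2.5
    rate: float = 1e-3
    params: GTRGammaParams = field(default_factory=lambda: GTRGammaParams(
        exchangeabilities=(1.2, 3.8, 0.9, 1.1, 4.5, 1.0),
        base_freqs=(0.28, 0.21, 0.23, 0.28),
        alpha=0.5, n_categories=4))
    organellar_depth: float = 150.0
    nuclear_depth: float = 2.0
    read_len: int = 100
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_transferred <= 1.0:
            raise ValueError("frac_transferred must lie in [0, 1]")
        if self.n_taxa not in (15, 33):
            raise ValueError("panel size must be 15 or 33")


@dataclass
class GeneTruth:
    gene_id: str
    history: str                       # vertical | transferred | chimeric
    events: list = field(default_factory=list)
    timing: str | None = None          # ancient | recent | repeated_independent
    pseudogenized: bool = False
    editing_sites: list = field(default_factory=list)
    breakpoint: int | None = None      # splice column of a chimeric gene


@dataclass
class SimTruth:
    genes: dict
    copy_number_of: dict = field(default_factory=dict)
    expression_of: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": {g: _truth_dict(t) for g, t in self.genes.items()},
            "copy_number_of": self.copy_number_of,
            "expression_of": self.expression_of,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _truth_dict(t: GeneTruth) -> dict:
    d = asdict(t)
    d["events"] = [
        {**asdict(e), "recipient_clade": sorted(e.recipient_clade),
         "donor_branch": sorted(e.donor_branch)}
        for e in t.events]
    return d


@dataclass
class SimulatedDataset:
    scenario: Scenario
    panel: TaxonPanel
    species_tree: Clade
    alignments: list
    gene_trees: dict
    truth: SimTruth
    cdna: dict = field(default_factory=dict)   # gene -> {taxon: cDNA seq}

    def write(self, out_dir) -> None:
        from pathlib import Path
        from .io import write_fasta
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_fasta(out / f"{aln.gene_id}.fasta", aln.rows)
        self.truth.to_json(out / "truth.json")
        self.panel.to_tsv(out / "panel.tsv")
        with open(out / "species_tree.nwk", "w", encoding="utf-8") as fh:
            fh.write(self.species_tree.newick() + "\n")


def _default_events(gene_id: str, i: int, panel: TaxonPanel,
                    tree: Clade) -> tuple[list[TransferEvent], str]:
    """A rotating schedule of transfer histories mirroring the study:
    ancient whole-family transfers, recent single-genus transfers, and
    repeated independent transfers of the same gene."""
    parasites = sorted(panel.parasites)
    sapria = frozenset(t for t in parasites if t.startswith("Sapria"))
    rafflesia = frozenset(t for t in parasites if t.startswith("Rafflesia"))
    hosts = frozenset(sorted(panel.hosts))
    tets = frozenset(sorted(panel.with_role("current_host")))
    vitis = frozenset(t for t in panel.with_role("host_clade") if t.startswith("Vitis"))
    root_age = tree.age
    schedule = [
        # ancient: the whole parasite clade attaches to the host-family stem
        ([TransferEvent(gene_id, frozenset(parasites), hosts, 110.0 / root_age)],
         "ancient"),
        # recent: Sapria alone onto the current-host stem
        ([TransferEvent(gene_id, sapria, tets, 30.0 / root_age)], "recent"),
        # recent: the Rafflesia genus onto the current-host stem
        ([TransferEvent(gene_id, rafflesia, tets, 35.0 / root_age)], "recent"),
        # repeated: the two genera transferred independently
        ([TransferEvent(gene_id, rafflesia, tets, 40.0 / root_age),
          TransferEvent(gene_id, sapria, vitis, 30.0 / root_age)],
         "repeated_independent"),
        # recent: Sapria onto the Vitis terminal branch
        ([TransferEvent(gene_id, sapria, vitis, 25.0 / root_age)], "recent"),
    ]
    return schedule[i % len(schedule)]


def generate_dataset(scenario: Scenario | None = None, seed: int = 0) -> SimulatedDataset:
    """Simulate a complete study: alignments, truth table, expression
    and copy-number expectations, and cDNA for edited genes."""
    scenario = scenario or Scenario()
    rng = np.random.default_rng(seed)
    panel = panel_15() if scenario.n_taxa == 15 else panel_33()
    tree = species_tree_15() if scenario.n_taxa == 15 else species_tree_33()
    n_transferred = int(round(scenario.frac_transferred * scenario.n_genes))
    alignments, gene_trees, genes = [], {}, {}
    expression, cdna_store = {}, {}
    query = sorted(panel.parasites)[0]
    for i in range(scenario.n_genes):
        gene_id = f"g{i:03d}"
        if i < n_transferred:
            events, timing = _default_events(gene_id, i, panel, tree)
            history = "transferred"
        else:
            events, timing, history = [], None, "vertical"
        gtree = simulate_gene_tree(tree, events)
        scaled = gtree.scale_to_substitutions(scenario.rate)
        aln = simulate_alignment(scaled, scenario.params, scenario.n_sites,
                                 seed=rng, gene_id=gene_id)
        truth = GeneTruth(gene_id, history, events, timing)
        if history == "transferred" and rng.random() < scenario.pseudogene_fraction:
            recipients = set().union(*(e.recipient_clade for e in events))
            for taxon in recipients:
                aln.rows[taxon] = pseudogenize(aln.rows[taxon], rng)
            truth.pseudogenized = True
        if rng.random() < scenario.editing_fraction:
            n_edit = max(1, rng.poisson(scenario.mean_editing_sites))
            cdna, sites = inject_editing(aln.rows[query], rng, n_edit)
            truth.editing_sites = sites
            if sites:
                cdna_store[gene_id] = {query: cdna}
        expression[gene_id] = float(rng.lognormal(np.log(800), 1.0))
        alignments.append(aln)
        gene_trees[gene_id] = gtree
        genes[gene_id] = truth
    return SimulatedDataset(scenario, panel, tree, alignments, gene_trees,
                            SimTruth(genes,
                                     {"mitochondrial": scenario.organellar_depth,
                                      "nuclear": scenario.nuclear_depth},
                                     expression),
                            cdna=cdna_store)
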