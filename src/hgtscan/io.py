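"""Readers and writers: FASTA, Newick, gene-call tables, configuration.

The gene-call table is the tabular end product of the pipeline: one row
per gene x species sequence with its vertical/horizontal call, bootstrap
percentage, donor lineage, AU-test p-value, reading-frame status,
expression level and editing sites.  The packaged reference table (the
published call set for the three Rafflesiaceae species) ships as a TSV
fixture and parses into the same row type.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy

from .phylo import SupportTree
from .treeutil import UnrootedTree

IDENTITIES = ("VGT", "HGT", "unassigned")
FRAMES = ("intact", "pseudogene", "not_applicable")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Ordered mapping header -> uppercased sequence.

    Rejects duplicate headers (naming the offender) and empty files.
    """
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_text) -> SupportTree:
    """Parse a Newick tree; numeric internal-node labels become edge
    supports keyed by bipartition."""
    if isinstance(path_or_text, Path) or (
            isinstance(path_or_text, str) and "(" not in path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    tree = UnrootedTree.from_dendropy(dtree)
    all_taxa = set(labels)
    ref = min(all_taxa)
    supports: dict[frozenset, int] = {}
    for node in dtree.preorder_internal_node_iter():
        if node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if not below or below == all_taxa:
            continue
        key = frozenset(below if ref not in below else all_taxa - below)
        supports[key] = int(round(value))
    return SupportTree(tree, supports)


def write_newick(stree: SupportTree | UnrootedTree, path) -> None:
    text = stree.newick() if isinstance(stree, (SupportTree, UnrootedTree)) else str(stree)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text + "\n")


# ---------------------------------------------------------------------------
# gene-call rows


@dataclass
class HGTCall:
    """One gene x species call in the published table layout.

    ``au_p`` of None with ``au_ns`` True means the AU test did not
    reject (printed "NS"); ``au_upper_bound`` marks a "<x" entry, with
    ``au_p`` holding x.  ``bp_upper_bound`` marks a "<50" bootstrap
    entry (stored as 49).  Editing sites are 1-based genomic positions.
    """

    gene_id: str
    species: str
    identity: str
    donor_lineage: str | None = None
    bp: int = 0
    au_p: float | None = None
    au_ns: bool = False
    au_upper_bound: bool = False
    bp_upper_bound: bool = False
    seq_length: int | None = None
    frame: str = "not_applicable"
    rpkm: float | None = None
    editing_sites: list[int] = field(default_factory=list)
    compartment: str = "mitochondrial"
    attachment: str | None = None      # "sister to" | "nested within"

    def __post_init__(self) -> None:
        if self.identity not in IDENTITIES:
            raise ValueError(f"unknown identity {self.identity!r}")
        if not 0 <= self.bp <= 100:
            raise ValueError(f"bootstrap percentage {self.bp} outside [0, 100]")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame token {self.frame!r}")
        if self.au_p is not None and not 0.0 <= self.au_p <= 1.0:
            raise ValueError(f"AU p-value {self.au_p} outside [0, 1]")
        if self.identity == "HGT" and not self.donor_lineage:
            raise ValueError(f"{self.gene_id}/{self.species}: HGT call needs a donor lineage")
        if self.identity != "HGT" and self.donor_lineage:
            raise ValueError(f"{self.gene_id}/{self.species}: non-HGT call with donor lineage")

    @property
    def au_rejects(self) -> bool:
        """Did the AU test reject the vertical placement at 0.05?"""
        return self.au_p is not None and not self.au_ns and self.au_p <= 0.05


_TABLE_COLUMNS = ["gene", "species", "identity", "donor_lineage", "bp", "au",
                  "length", "frame", "rpkm", "editing_sites", "compartment"]


def _parse_au(token: str) -> tuple[float | None, bool, bool]:
    token = token.strip()
    if token in ("", "-", "–"):
        return None, False, False
    if token.upper() == "NS":
        return None, True, False
    if token.startswith("<"):
        return float(token[1:]), False, True
    return float(token), False, False


def _parse_bp(token: str) -> tuple[int, bool]:
    token = token.strip()
    if token.startswith("<"):
        bound = int(token[1:])
        return bound - 1, True
    bp = int(token)
    if not 0 <= bp <= 100:
        raise ValueError(f"bootstrap percentage {bp} outside [0, 100]")
    return bp, False


_FRAME_TOKENS = {"I": "intact", "ψ": "pseudogene", "psi": "pseudogene",
                 "-": "not_applicable", "–": "not_applicable", "": "not_applicable"}
_IDENTITY_TOKENS = {"HGT": "HGT", "VGT": "VGT", "-": "unassigned",
                    "–": "unassigned", "unassigned": "unassigned"}


def read_gene_call_table(path) -> list[HGTCall]:
    """Parse a gene-call TSV into :class:`HGTCall` rows."""
    with open(path, encoding="utf-8") as fh:
        return _parse_gene_call_rows(fh)


def _parse_gene_call_rows(lines) -> list[HGTCall]:
    rows: list[HGTCall] = []
    header: dict[str, int] | None = None
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = {name: i for i, name in enumerate(parts)}
            continue

        def get(col: str, default: str = "") -> str:
            i = header.get(col)
            return parts[i].strip() if i is not None and i < len(parts) else default

        identity_token = get("identity")
        if identity_token not in _IDENTITY_TOKENS:
            raise ValueError(f"unknown identity token {identity_token!r}")
        bp, bp_ub = _parse_bp(get("bp", "0") or "0")
        au_p, au_ns, au_ub = _parse_au(get("au"))
        frame_token = get("frame")
        if frame_token not in _FRAME_TOKENS:
            raise ValueError(f"unknown frame token {frame_token!r}")
        editing = [int(x) for x in re.split(r"[,;]\s*", get("editing_sites")) if x.strip()]
        rpkm_token = get("rpkm")
        rows.append(HGTCall(
            gene_id=get("gene"),
            species=get("species"),
            identity=_IDENTITY_TOKENS[identity_token],
            donor_lineage=get("donor_lineage") or None,
            bp=bp, bp_upper_bound=bp_ub,
            au_p=au_p, au_ns=au_ns, au_upper_bound=au_ub,
            seq_length=int(get("length")) if get("length") else None,
            frame=_FRAME_TOKENS[frame_token],
            rpkm=float(rpkm_token) if rpkm_token else None,
            editing_sites=editing,
            compartment=get("compartment", "mitochondrial") or "mitochondrial",
        ))
    return rows


def format_gene_call_table(calls: list[HGTCall]) -> str:
    lines = ["\t".join(_TABLE_COLUMNS)]
    for c in calls:
        au = ("NS" if c.au_ns else
              "" if c.au_p is None else
              f"<{c.au_p:g}" if c.au_upper_bound else f"{c.au_p:.4f}")
        frame = {"intact": "I", "pseudogene": "ψ", "not_applicable": "-"}[c.frame]
        identity = c.identity if c.identity != "unassigned" else "-"
        lines.append("\t".join([
            c.gene_id, c.species, identity, c.donor_lineage or "",
            f"<{c.bp + 1}" if c.bp_upper_bound else str(c.bp),
            au, str(c.seq_length or ""), frame,
            f"{c.rpkm:g}" if c.rpkm is not None else "",
            ", ".join(str(p) for p in c.editing_sites),
            c.compartment,
        ]))
    return "\n".join(lines) + "\n"


def write_gene_call_table(path, calls: list[HGTCall]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_gene_call_table(calls))


def load_reference_calls() -> list[HGTCall]:
    """The packaged published call set for the three parasite species."""
    text = resources.files("hgtscan.data").joinpath("table1.tsv").read_text(encoding="utf-8")
    return _parse_gene_call_rows(text.splitlines())


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Tunable thresholds of the detection pipeline."""

    bp_threshold_strict: int = 70
    bp_threshold_relaxed: int = 50
    bootstrap_reps: int = 500
    au_alpha: float = 0.05
    kmer_len: int = 25
    rng_seed: int = 0
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        for thr in (self.bp_threshold_strict, self.bp_threshold_relaxed):
            if not 0 < thr <= 100:
                raise ValueError(f"bootstrap threshold {thr} outside (0, 100]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0 < self.au_alpha < 1 or math.isnan(self.au_alpha):
            raise ValueError("au_alpha must lie in (0, 1)")
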