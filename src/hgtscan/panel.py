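"""Taxon panels: the species and their phylogenetic roles.

Every classification in the pipeline is made relative to a panel that
declares, for each taxon, which role it plays:

``outgroup``
    Taxa used only to root gene trees (e.g. a gymnosperm plus an early
    diverging monocot).
``reference``
    Autotrophic reference species spanning the major seed-plant clades.
``vgt_sister``
    The closest autotrophic relative of the parasites; a parasite
    sequence grouping here is a vertically inherited (native) gene.
``host_clade``
    The host family, excluding the current host genus.
``current_host``
    The extant host genus of the parasites.
``parasite``
    The holoparasite taxa whose sequences are being screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROLES = ("outgroup", "reference", "vgt_sister", "host_clade", "current_host", "parasite")


@dataclass
class TaxonPanel:
    """Taxa with declared roles and named lineages.

    Parameters
    ----------
    role_of
        Mapping taxon -> role; roles must come from :data:`ROLES`.
    lineage_of
        Mapping taxon -> named lineage (typically a family or genus)
        used when reporting HGT donors.  Taxa missing from the mapping
        report their own name as lineage.
    """

    role_of: dict[str, str]
    lineage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, role in self.role_of.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for taxon {taxon!r}")
        for needed in ("outgroup", "vgt_sister", "parasite"):
            if not self.with_role(needed):
                raise ValueError(f"panel must contain at least one {needed} taxon")

    @property
    def taxa(self) -> list[str]:
        return list(self.role_of)

    def with_role(self, *roles: str) -> set[str]:
        return {t for t, r in self.role_of.items() if r in roles}

    @property
    def outgroup(self) -> set[str]:
        return self.with_role("outgroup")

    @property
    def parasites(self) -> set[str]:
        return self.with_role("parasite")

    @property
    def vgt_sister(self) -> set[str]:
        return self.with_role("vgt_sister")

    @property
    def hosts(self) -> set[str]:
        """Host-clade taxa including the current host genus."""
        return self.with_role("host_clade", "current_host")

    def lineage(self, taxon: str) -> str:
        return self.lineage_of.get(taxon, taxon)

    def role(self, taxon: str) -> str:
        try:
            return self.role_of[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} is not in the panel") from None

    def check_taxa(self, taxa) -> None:
        """Reject any taxon that is not declared in the panel."""
        unknown = sorted(set(taxa) - set(self.role_of))
        if unknown:
            raise ValueError(f"taxa absent from panel: {', '.join(unknown)}")

    @classmethod
    def from_tsv(cls, path) -> "TaxonPanel":
        """Read a panel from a TSV with columns taxon, role, lineage."""
        role_of: dict[str, str] = {}
        lineage_of: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                taxon = parts[idx["taxon"]]
                if taxon in role_of:
                    raise ValueError(f"duplicate taxon {taxon!r} in panel")
                role_of[taxon] = parts[idx["role"]]
                if "lineage" in idx and len(parts) > idx["lineage"] and parts[idx["lineage"]]:
                    lineage_of[taxon] = parts[idx["lineage"]]
        return cls(role_of, lineage_of)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxon\trole\tlineage\n")
            for taxon, role in self.role_of.items():
                fh.write(f"{taxon}\t{role}\t{self.lineage(taxon)}\n")
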