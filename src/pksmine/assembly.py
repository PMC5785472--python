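"""Grouping domain hits into modules and ordering them into an assembly line.

The collinearity convention for cis-AT systems is applied throughout: a new
module opens at each ketosynthase (KS) anchor and runs to the next KS; a
leading carrier protein before the first KS of the first gene is the loading
module; genes are ordered by chromosomal position (reversed on the minus
strand) and module indices are renumbered globally along that order.
Terminal regions outside the first/last domain are tested with a
length-plus-heptad-periodicity heuristic for docking domains, the
protein-protein adapters that hold consecutive PKS subunits together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .io_model import GeneRecord, sort_genes
from .config import default_config
from .signatures import (
    ActivityCall,
    ATCall,
    DomainHit,
    KRCall,
    check_catalytic_activity,
    classify_at_substrate,
    classify_kr_type,
    scan_domains,
)

__all__ = [
    "PKSModule",
    "DockingEnd",
    "AssemblyLine",
    "build_modules",
    "detect_docking",
    "order_assembly_line",
    "mine_cluster",
]


@dataclass
class PKSModule:
    """One extension (or loading) module: an ordered run of domains."""

    module_index: int
    gene_id: str
    domains: list[DomainHit]
    at_call: ATCall | None = None
    kr_call: KRCall | None = None
    is_loading: bool = False
    activity: dict[str, ActivityCall] = field(default_factory=dict)

    @property
    def domain_classes(self) -> tuple[str, ...]:
        return tuple(h.domain_class for h in self.domains)

    def has(self, domain_class: str) -> bool:
        return domain_class in self.domain_classes

    def domain_active(self, domain_class: str) -> bool:
        """A domain counts as active if present and its residue rules pass."""
        if not self.has(domain_class):
            return False
        call = self.activity.get(domain_class)
        return call is None or call.active


@dataclass(frozen=True)
class DockingEnd:
    gene_id: str
    terminus: str  # N | C
    present: bool
    dock_class: str | None = None

    def __post_init__(self) -> None:
        if self.present != bool(self.dock_class):
            raise ValueError("dock_class must be set iff a docking end is present")


@dataclass
class AssemblyLine:
    """A collinear chain of modules across chromosomally ordered genes."""

    modules: list[PKSModule]
    gene_order: list[str]
    docking_links: list[tuple[str, str, bool]]
    te_present: bool = False

    @property
    def extension_modules(self) -> list[PKSModule]:
        return [m for m in self.modules if not m.is_loading]

    @property
    def n_extension_modules(self) -> int:
        return len(self.extension_modules)


def _classify_module(
    module: PKSModule, protein_seq: str, config: Mapping[str, Any]
) -> None:
    for hit in module.domains:
        module.activity[hit.domain_class] = check_catalytic_activity(
            hit, protein_seq, config
        )
        if hit.domain_class == "AT":
            module.at_call = classify_at_substrate(hit.region(protein_seq), config)
        elif hit.domain_class == "KR":
            module.kr_call = classify_kr_type(hit.region(protein_seq), config)


def build_modules(
    genes: Sequence[GeneRecord],
    hits_by_gene: Mapping[str, Sequence[DomainHit]],
    config: Mapping[str, Any] | None = None,
) -> list[PKSModule]:
    """Group per-gene domain hits into modules in the given gene order.

    A module opens at each KS hit and collects domains up to (not including)
    the next KS.  A leading carrier protein (with any flanking non-KS
    domains) before the first KS of the *first* gene forms loading module 0;
    extension modules are numbered 1..n along the gene order.  A KS-opened
    module lacking an AT is recorded with ``at_call=None`` and a warning.
    """
    config = config or default_config()
    modules: list[PKSModule] = []
    index = 1
    for gi, gene in enumerate(genes):
        hits = sorted(hits_by_gene.get(gene.gene_id, []), key=lambda h: h.start_aa)
        groups: list[list[DomainHit]] = []
        leading: list[DomainHit] = []
        for hit in hits:
            if hit.domain_class == "KS":
                groups.append([hit])
            elif groups:
                groups[-1].append(hit)
            else:
                leading.append(hit)
        if leading:
            if gi == 0 and any(h.domain_class == "ACP" for h in leading):
                loading = PKSModule(0, gene.gene_id, leading, is_loading=True)
                _classify_module(loading, gene.protein_seq, config)
                modules.append(loading)
            else:
                warnings.warn(
                    f"{gene.gene_id}: {len(leading)} leading domain(s) before the "
                    "first KS do not form a loading module; ignored"
                )
        for group in groups:
            module = PKSModule(index, gene.gene_id, group)
            _classify_module(module, gene.protein_seq, config)
            if not module.has("AT"):
                warnings.warn(
                    f"{gene.gene_id}: malformed module {index} lacks an AT domain"
                )
            modules.append(module)
            index += 1
    return modules


def _heptad_score(region: str, hydrophobic: str) -> float:
    """Best-phase fraction of hydrophobic residues at heptad a/d positions."""
    best = 0.0
    for phase in range(7):
        positions = [i for i in range(len(region)) if (i - phase) % 7 in (0, 3)]
        if not positions:
            continue
        frac = sum(region[i] in hydrophobic for i in positions) / len(positions)
        best = max(best, frac)
    return best


def detect_docking(
    gene: GeneRecord,
    hits: Sequence[DomainHit],
    config: Mapping[str, Any] | None = None,
) -> tuple[DockingEnd, DockingEnd]:
    """Test the terminal regions outside the first/last domain for docking.

    The heuristic (a stand-in for structural prediction, thresholds in
    config) requires a minimum terminal length and a heptad-periodicity
    score: coiled-coil-like docking helices place hydrophobic residues at
    the a/d positions of a seven-residue repeat.
    """
    cfg = (config or default_config())["docking"]
    min_len, threshold = int(cfg["min_len"]), float(cfg["score_threshold"])
    hydrophobic = str(cfg["hydrophobic"])
    seq = gene.protein_seq
    hits = sorted(hits, key=lambda h: h.start_aa)
    n_region = seq[: hits[0].start_aa - 1] if hits else seq
    c_region = seq[hits[-1].end_aa :] if hits else ""

    ends = []
    for terminus, region in (("N", n_region), ("C", c_region)):
        present = len(region) >= min_len and _heptad_score(region, hydrophobic) >= threshold
        ends.append(
            DockingEnd(gene.gene_id, terminus, present, "CC0" if present else None)
        )
    return ends[0], ends[1]


def _compatible(
    up_c: DockingEnd, down_n: DockingEnd, pairing: Mapping[str, Sequence[str]]
) -> bool:
    if not (up_c.present and down_n.present):
        return False
    return down_n.dock_class in pairing.get(up_c.dock_class, [])


def order_assembly_line(
    genes: Sequence[GeneRecord],
    hits_by_gene: Mapping[str, Sequence[DomainHit]],
    config: Mapping[str, Any] | None = None,
) -> AssemblyLine:
    """Order genes chromosomally, build and renumber modules, link docking.

    All pks genes must share a strand (minus-strand clusters are read in
    descending coordinate order); mixed strands require an explicit
    ``order.override`` gene list in the config.
    """
    config = config or default_config()
    override = (config.get("order") or {}).get("override")
    if override:
        by_id = {g.gene_id: g for g in genes}
        ordered = [by_id[g] for g in override]
    else:
        strands = {g.strand for g in genes}
        if len(strands) > 1:
            raise ValueError(
                "mixed strands among pks genes; set order.override in the config "
                "to state the assembly-line gene order explicitly"
            )
        ordered = sort_genes(genes)
        if strands == {"-"}:
            ordered = ordered[::-1]

    modules = build_modules(ordered, hits_by_gene, config)

    pairing = config["docking"]["pairing"]
    docking = {
        g.gene_id: detect_docking(g, hits_by_gene.get(g.gene_id, []), config)
        for g in ordered
    }
    links = [
        (
            up.gene_id,
            down.gene_id,
            _compatible(docking[up.gene_id][1], docking[down.gene_id][0], pairing),
        )
        for up, down in zip(ordered, ordered[1:])
    ]

    last_gene = ordered[-1].gene_id if ordered else None
    te_present = any(
        h.domain_class == "TE" for h in hits_by_gene.get(last_gene, [])
    )
    return AssemblyLine(
        modules=modules,
        gene_order=[g.gene_id for g in ordered],
        docking_links=links,
        te_present=te_present,
    )


def mine_cluster(
    genes: Sequence[GeneRecord],
    config: Mapping[str, Any] | None = None,
    annotations: Mapping[str, Sequence[DomainHit]] | None = None,
) -> AssemblyLine:
    """Convenience pipeline: scan every gene, then build the assembly line."""
    config = config or default_config()
    hits_by_gene = {
        g.gene_id: scan_domains(
            g.protein_seq,
            annotations.get(g.gene_id) if annotations else None,
            config,
        )
        for g in genes
    }
    return order_assembly_line(genes, hits_by_gene, config)
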