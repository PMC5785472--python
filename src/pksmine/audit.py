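"""Auditing an assembly line against a target product, and explaining
module deficits.

The collinearity rule says the number (and chromosomal order) of extension
modules should match the number (and order) of chain extensions in the
product.  The audit counts the required extensions from the ring size
(``E_req = (R - A) / 2``), compares against the encoded module count, and —
when the line is short by exactly one module — enumerates the two families
of rescue hypotheses:

* a *trans* module: a stand-alone KS-AT-ACP protein elsewhere in the genome
  with docking ends that could insert into the complex;
* an *iterative* module: one cis module catalyzing two successive
  extensions, possibly with different reductive outcomes per pass
  ("programmed iteration": activity toggles may only switch OFF domains the
  module physically has — a pass can never gain a domain the protein lacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import Any, Iterable, Mapping, Sequence

from .assembly import AssemblyLine, build_modules, detect_docking
from .chem import Backbone, BackboneUnit, Formula, StarterUnit, predict_backbone
from .io_model import GeneRecord
from .config import default_config
from .signatures import scan_domains

__all__ = [
    "ProductSpec",
    "AuditReport",
    "Hypothesis",
    "load_product_spec",
    "required_extensions",
    "audit_collinearity",
    "find_trans_candidates",
    "enumerate_iterative_hypotheses",
]


@dataclass
class ProductSpec:
    """Structured description of the target polyketide."""

    name: str
    formula: Formula
    ring_size: int
    starter: StarterUnit
    target_units: list[BackboneUnit]
    branch_positions: tuple[int, ...] = ()
    position_annotations: dict[str, int] = field(default_factory=dict)
    tailoring: list = field(default_factory=list)
    geometry_overrides: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r, a = self.ring_size, self.starter.ring_atom_count
        if (r - a) % 2 != 0 or (r - a) <= 0:
            raise ValueError(
                f"{self.name}: ring size {r} and starter ring atoms {a} are "
                "inconsistent — (R - A) must be a positive even number"
            )
        e_req = (r - a) // 2
        if len(self.target_units) != e_req:
            raise ValueError(
                f"{self.name}: {len(self.target_units)} target units but "
                f"(R - A)/2 = {e_req}"
            )
        n_methyl = sum(1 for u in self.target_units if u.alpha_substituent == "CH3")
        if len(self.branch_positions) != n_methyl:
            raise ValueError(
                f"{self.name}: {len(self.branch_positions)} branch positions but "
                f"{n_methyl} methyl-branched target units"
            )


@dataclass
class AuditReport:
    e_req: int
    m_enc: int
    match_table: list[dict[str, Any]] | None
    verdict: str  # collinear | deficit | excess

    @property
    def deficit(self) -> int:
        return self.e_req - self.m_enc


@dataclass
class Hypothesis:
    kind: str  # trans_module | iterative
    module_ref: tuple[str, int | None]  # (gene_id, module_index or None)
    pass_states: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    resulting_backbone: Backbone | None = None
    consistent: bool = False
    notes: tuple[str, ...] = ()


def load_product_spec(source: str | None = None) -> ProductSpec:
    """Load a product specification from a YAML file, or the packaged
    sceliphrolactam definition when ``source`` is omitted."""
    import yaml
    from importlib import resources

    from .chem import TailoringEvent, starter_from_library

    if source is None:
        text = resources.files("pksmine.data").joinpath(
            "sceliphrolactam.yaml"
        ).read_text(encoding="utf-8")
    else:
        text = open(source, encoding="utf-8").read()
    doc = yaml.safe_load(text)
    units = [
        BackboneUnit(
            position=int(u["position"]),
            alpha_substituent=str(u["alpha"]),
            beta_state=str(u["beta"]),
            stereo=str(u.get("stereo", "none")),
            geometry=str(u.get("geometry", "E" if u["beta"] == "enoyl" else "none")),
        )
        for u in doc["target_units"]
    ]
    return ProductSpec(
        name=doc["name"],
        formula=Formula(doc["formula"]),
        ring_size=int(doc["ring_size"]),
        starter=starter_from_library(doc["starter"]),
        target_units=units,
        branch_positions=tuple(doc.get("branch_positions", [])),
        position_annotations=dict(doc.get("position_annotations", {})),
        tailoring=[TailoringEvent(**e) for e in doc.get("tailoring", [])],
        geometry_overrides={
            int(k): str(v) for k, v in (doc.get("geometry_overrides") or {}).items()
        },
    )


def required_extensions(spec: ProductSpec) -> tuple[int, int, int]:
    """(E_req, n_malonyl, n_methylmalonyl) required by the product."""
    e_req = (spec.ring_size - spec.starter.ring_atom_count) // 2
    n_methylmalonyl = len(spec.branch_positions)
    return e_req, e_req - n_methylmalonyl, n_methylmalonyl


def _units_match(
    predicted: Sequence[BackboneUnit],
    target: Sequence[BackboneUnit],
    granularity: str = "state",
) -> list[bool]:
    if granularity == "strict":
        key = lambda u: (u.alpha_substituent, u.beta_state, u.stereo, u.geometry)
    else:
        key = lambda u: u.state_key
    return [key(p) == key(t) for p, t in zip(predicted, target)]


def audit_collinearity(
    line: AssemblyLine,
    spec: ProductSpec,
    granularity: str = "state",
) -> AuditReport:
    """Compare encoded module count (and, at parity, per-position states)
    against the product requirement."""
    e_req, _, _ = required_extensions(spec)
    m_enc = line.n_extension_modules
    if m_enc < e_req:
        return AuditReport(e_req, m_enc, None, "deficit")
    if m_enc > e_req:
        return AuditReport(e_req, m_enc, None, "excess")
    predicted = predict_backbone(line, spec.starter)
    matches = _units_match(predicted.units, spec.target_units, granularity)
    table = [
        {
            "position": t.position,
            "target": t.state_key,
            "predicted": p.state_key,
            "match": ok,
        }
        for p, t, ok in zip(predicted.units, spec.target_units, matches)
    ]
    # counts agree; a per-position state disagreement is reported as
    # "mismatch" so that collinear strictly means count AND states agree
    return AuditReport(e_req, m_enc, table, "collinear" if all(matches) else "mismatch")


def find_trans_candidates(
    genome_genes: Iterable[GeneRecord],
    required_composition: Sequence[str] = ("KS", "AT", "ACP"),
    require_docking: bool = True,
    config: Mapping[str, Any] | None = None,
) -> list[Hypothesis]:
    """Scan genes outside the audited cluster for stand-alone trans-module
    candidates.

    A candidate gene must carry *exactly* the required domain composition as
    one contiguous module and, when ``require_docking`` is set, docking ends
    at both termini.  Candidates are returned ``consistent=False`` — only a
    backbone-level check can promote them.
    """
    config = config or default_config()
    required = tuple(required_composition)
    out: list[Hypothesis] = []
    for gene in genome_genes:
        try:
            hits = scan_domains(gene.protein_seq, None, config)
        except ValueError:  # sequence below the scan minimum
            continue
        if tuple(h.domain_class for h in hits) != required:
            continue
        notes = []
        if require_docking:
            n_end, c_end = detect_docking(gene, hits, config)
            if not (n_end.present and c_end.present):
                continue
            notes.append("docking_both_ends")
        out.append(
            Hypothesis(
                kind="trans_module",
                module_ref=(gene.gene_id, None),
                consistent=False,
                notes=tuple(notes),
            )
        )
    return out


def _reductive_subsets(module) -> list[frozenset]:
    present = [d for d in ("KR", "DH", "ER") if module.has(d)]
    subsets = []
    for mask in iter_product([False, True], repeat=len(present)):
        subsets.append(frozenset(d for d, on in zip(present, mask) if on))
    # deterministic order: by size, then lexicographic
    return sorted(set(subsets), key=lambda s: (len(s), tuple(sorted(s))))


def enumerate_iterative_hypotheses(
    line: AssemblyLine,
    spec: ProductSpec,
    granularity: str = "state",
) -> list[Hypothesis]:
    """Exhaustive single-deficit search for a programmed iterative module.

    For every extension module *m* and every ordered pair (S1, S2) of
    activity subsets of m's reductive domains, simulate the backbone with
    module *m* run twice (AT class fixed; toggles may only switch off
    domains present) and keep hypotheses whose unit states equal the target.
    Hypotheses with the same module and resulting backbone are collapsed;
    results are ordered by module index, then pass states.
    """
    report = audit_collinearity(line, spec, granularity)
    if report.deficit != 1:
        raise ValueError(
            f"iterative search is defined for a deficit of exactly 1 module "
            f"(got {report.deficit}); multi-iteration semantics are not implemented"
        )
    target = spec.target_units
    seen: set[tuple[int, tuple]] = set()
    out: list[Hypothesis] = []
    for module in line.extension_modules:
        for s1, s2 in iter_product(_reductive_subsets(module), repeat=2):
            try:
                backbone = predict_backbone(
                    line, spec.starter, pass_plan={module.module_index: (s1, s2)}
                )
            except ValueError:
                continue  # e.g. unknown AT elsewhere; surfaced by the audit
            if not all(_units_match(backbone.units, target, granularity)):
                continue
            signature = (
                module.module_index,
                tuple(u.state_key for u in backbone.units),
            )
            if signature in seen:
                continue
            seen.add(signature)
            toggles = []
            for d in ("KR", "DH", "ER"):
                if module.has(d) and ((d in s1) != (d in s2)):
                    toggles.append(d)
            out.append(
                Hypothesis(
                    kind="iterative",
                    module_ref=(module.gene_id, module.module_index),
                    pass_states=(tuple(sorted(s1)), tuple(sorted(s2))),
                    resulting_backbone=backbone,
                    consistent=True,
                    notes=tuple(f"toggles:{d}" for d in toggles),
                )
            )
    out.sort(key=lambda h: (h.module_ref[1], h.pass_states))
    return out
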