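"""Polyketide backbone prediction, macrolactamization and mass chemistry.

The backbone model follows assembly-line logic: extension unit *i* derives
from module *i*, its alpha substituent from the AT call (methylmalonyl-CoA
contributes the methyl branch) and its beta-keto processing state from the
reductive domains present and active (none -> ketone, KR -> hydroxyl with
the stereochemistry implied by the KR type, KR+DH -> enoyl, KR+DH+ER ->
methylene).  Cyclization onto a beta-amino-acid starter closes a macrolactam
of ``2*E + A`` ring atoms, where ``E`` is the extension count and ``A`` the
ring atoms (including the amide nitrogen) contributed by the starter.

Molecular formulas are not tabulated but derived from an explicit molecular
graph of the macrocycle (heavy atoms and bond orders, hydrogens filled by
valence), so the degrees-of-unsaturation of the graph and of the formula can
be cross-checked.  Monoisotopic adduct masses use neutral-atom masses with
the electron mass neglected — the convention behind printed "calcd" values
in natural-product isolation work — with half-even rounding applied only at
the reporting boundary.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .assembly import AssemblyLine, PKSModule
from .config import default_config

__all__ = [
    "StarterUnit",
    "BackboneUnit",
    "Backbone",
    "TailoringEvent",
    "Formula",
    "starter_from_library",
    "module_beta_state",
    "predict_backbone",
    "macrolactamize",
    "apply_tailoring",
    "backbone_graph",
    "carbon_labels",
    "molecular_formula",
    "monoisotopic_mz",
]

BETA_STATES = ("ketone", "hydroxyl", "enoyl", "methylene")


@dataclass(frozen=True)
class StarterUnit:
    """A beta-amino-acid starter priming the assembly line.

    ``ring_atom_count`` counts the atoms this unit contributes to the
    macrolactam ring *including* the amide nitrogen (4 for
    3-amino-2-methylpropionate); ``methyl_positions`` index ring carbons from
    the starter carboxyl carbon.
    """

    name: str
    ring_atom_count: int
    methyl_positions: tuple[int, ...] = ()
    amine_protected: bool = False

    def __post_init__(self) -> None:
        if self.ring_atom_count < 2:
            raise ValueError("a ring-forming starter needs at least 2 ring atoms")

    @property
    def alpha_methyl(self) -> bool:
        return 2 in self.methyl_positions

    @property
    def formula_contribution(self) -> "Formula":
        """Element counts of the incorporated residue (beta-state oxygens and
        the amide oxygen are booked at cyclization, not here)."""
        n_ring_c = self.ring_atom_count - 1
        n_methyl = len(self.methyl_positions)
        # interior ring carbons carry 2 H, methyl-bearing ones 1 H + CH3;
        # the carboxyl carbon's hydrogens depend on the first extension state
        n_h = 2 * (n_ring_c - 1) - n_methyl + 4 * n_methyl + 1  # +1 amide N-H
        return Formula({"C": n_ring_c + n_methyl, "H": n_h, "N": 1})


def starter_from_library(
    name: str, config: Mapping[str, Any] | None = None
) -> StarterUnit:
    cfg = (config or default_config())["starters"]
    if name not in cfg:
        raise KeyError(f"starter {name!r} not in library ({sorted(cfg)})")
    entry = cfg[name]
    return StarterUnit(
        name=name,
        ring_atom_count=int(entry["ring_atoms"]),
        methyl_positions=tuple(entry.get("methyl_positions", [])),
        amine_protected=bool(entry.get("amine_protected", False)),
    )


@dataclass(frozen=True)
class BackboneUnit:
    """Chemical state of one chain extension."""

    position: int
    alpha_substituent: str  # H | CH3
    beta_state: str  # ketone | hydroxyl | enoyl | methylene
    stereo: str = "none"  # R | S | none, hydroxyl only
    geometry: str = "none"  # E | Z | none, enoyl only

    def __post_init__(self) -> None:
        if self.beta_state not in BETA_STATES:
            raise ValueError(f"unknown beta_state {self.beta_state!r}")
        if (self.stereo != "none") != (self.beta_state == "hydroxyl"):
            raise ValueError("stereo is set iff beta_state is hydroxyl")
        if (self.geometry != "none") != (self.beta_state == "enoyl"):
            raise ValueError("geometry is set iff beta_state is enoyl")

    @property
    def state_key(self) -> tuple[str, str]:
        """Comparison granularity ignoring stereo/geometry."""
        return (self.alpha_substituent, self.beta_state)


@dataclass(frozen=True)
class TailoringEvent:
    kind: str  # hydroxylation | amide_deprotection
    site: str = ""  # carbon label, e.g. "C-10"
    agent: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("hydroxylation", "amide_deprotection"):
            raise ValueError(f"unknown tailoring kind {self.kind!r}")
        if self.kind == "hydroxylation" and not self.site:
            raise ValueError("hydroxylation requires a carbon site")


@dataclass
class Backbone:
    """Per-extension chemical states of a (possibly cyclized) polyketide."""

    starter: StarterUnit
    units: list[BackboneUnit]
    ring_size: int | None = None
    tailoring: list[TailoringEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, unit in enumerate(self.units, start=1):
            if unit.position != i:
                raise ValueError("backbone unit positions must run 1..E contiguously")

    @property
    def n_extensions(self) -> int:
        return len(self.units)


class Formula(dict):
    """Element-count map with non-negative integer counts."""

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        for element, count in (counts or {}).items():
            if count < 0:
                raise ValueError(f"negative count for element {element}")
            if count:
                self[element] = int(count)

    def __add__(self, other: Mapping[str, int]) -> "Formula":
        out = dict(self)
        for element, count in other.items():
            out[element] = out.get(element, 0) + count
        return Formula(out)

    def __sub__(self, other: Mapping[str, int]) -> "Formula":
        out = dict(self)
        for element, count in other.items():
            out[element] = out.get(element, 0) - count
            if out[element] < 0:
                raise ValueError(
                    f"negative {element} count — inconsistent tailoring ledger"
                )
        return Formula(out)

    def dbe(self) -> float:
        """Degrees of unsaturation (rings + pi bonds) from the formula."""
        return self.get("C", 0) - self.get("H", 0) / 2 + self.get("N", 0) / 2 + 1

    def hill(self) -> str:
        symbols = sorted(self, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self[s] if self[s] > 1 else ''}" for s in symbols)


def module_beta_state(kr_active: bool, dh_active: bool, er_active: bool) -> str:
    """Map reductive-domain activity to the beta-keto processing outcome.

    Dehydration and enoyl reduction require the upstream product, so DH or
    ER without an active KR still leaves the ketone.
    """
    if not kr_active:
        return "ketone"
    if not dh_active:
        return "hydroxyl"
    if not er_active:
        return "enoyl"
    return "methylene"


def _unit_from_module(
    module: PKSModule,
    position: int,
    active_override: Iterable[str] | None = None,
    geometry_overrides: Mapping[int, str] | None = None,
) -> BackboneUnit:
    if module.at_call is None or module.at_call.substrate == "unknown":
        raise ValueError(
            f"module {module.module_index} ({module.gene_id}) has no usable AT "
            "substrate call; override it in the config to proceed"
        )
    alpha = "CH3" if module.at_call.substrate == "methylmalonyl" else "H"

    if active_override is not None:
        chosen = set(active_override)
        kr = "KR" in chosen and module.has("KR")
        dh = "DH" in chosen and module.has("DH")
        er = "ER" in chosen and module.has("ER")
    else:
        kr = (
            module.domain_active("KR")
            and module.kr_call is not None
            and module.kr_call.kr_type in ("A", "B")
        )
        dh = module.domain_active("DH")
        er = module.domain_active("ER")

    state = module_beta_state(kr, dh, er)
    stereo = "none"
    if state == "hydroxyl":
        stereo = module.kr_call.beta_oh_config if module.kr_call else "none"
        if stereo == "none":
            stereo = "R"  # iteration toggles cannot re-type the KR
    geometry = "none"
    if state == "enoyl":
        geometry = (geometry_overrides or {}).get(position, "E")
    return BackboneUnit(position, alpha, state, stereo, geometry)


def predict_backbone(
    line: AssemblyLine,
    starter: StarterUnit,
    geometry_overrides: Mapping[int, str] | None = None,
    pass_plan: Mapping[int, tuple[frozenset, frozenset]] | None = None,
) -> Backbone:
    """Predict the uncyclized backbone an assembly line would synthesize.

    ``geometry_overrides`` maps extension positions to enoyl geometries (the
    default is E; cis double bonds confirmed spectroscopically can be
    declared here since no domain rule predicts them).  ``pass_plan`` maps a
    module index to two per-pass activity sets for simulating an iteratively
    used module.
    """
    extensions = line.extension_modules
    if not extensions:
        raise ValueError("assembly line has no extension modules")
    units: list[BackboneUnit] = []
    position = 1
    for module in extensions:
        passes = (pass_plan or {}).get(module.module_index)
        if passes is None:
            units.append(
                _unit_from_module(module, position, None, geometry_overrides)
            )
            position += 1
        else:
            for chosen in passes:
                units.append(
                    _unit_from_module(module, position, chosen, geometry_overrides)
                )
                position += 1
    return Backbone(starter=starter, units=units)


def macrolactamize(backbone: Backbone) -> Backbone:
    """Close the macrolactam: ring size = 2*E + A ring atoms."""
    if backbone.n_extensions == 0:
        raise ValueError("cannot cyclize a backbone with no extensions")
    if backbone.starter.ring_atom_count < 2:
        raise ValueError("starter cannot form a ring")
    ring = 2 * backbone.n_extensions + backbone.starter.ring_atom_count
    return replace_backbone(backbone, ring_size=ring)


def replace_backbone(backbone: Backbone, **changes: Any) -> Backbone:
    out = Backbone(
        starter=backbone.starter,
        units=list(backbone.units),
        ring_size=backbone.ring_size,
        tailoring=list(backbone.tailoring),
    )
    for key, value in changes.items():
        setattr(out, key, value)
    return out


def apply_tailoring(backbone: Backbone, events: Iterable[TailoringEvent]) -> Backbone:
    """Record declarative tailoring events (each applies exactly once)."""
    events = list(events)
    labels = None
    seen_sites = {e.site for e in backbone.tailoring if e.kind == "hydroxylation"}
    out_events = list(backbone.tailoring)
    for event in events:
        if event.kind == "hydroxylation":
            if labels is None:
                labels = carbon_labels(backbone)
            if event.site not in labels:
                raise ValueError(
                    f"tailoring site {event.site} not on the backbone carbon map"
                )
            if event.site in seen_sites:
                raise ValueError(f"duplicate tailoring event at site {event.site}")
            seen_sites.add(event.site)
        out_events.append(event)
    return replace_backbone(backbone, tailoring=out_events)


def backbone_graph(
    backbone: Backbone,
) -> tuple[list[str], list[tuple[int, int, int]], dict[str, int]]:
    """Explicit molecular graph (heavy atoms, bonds with orders) of the
    cyclized macrolactam.

    Atom 0 is the amide nitrogen; ring carbons follow chain order from the
    starter; substituent and tailoring atoms are appended.  Hydrogens are
    implicit (filled by valence in :func:`molecular_formula`).
    """
    if backbone.ring_size is None:
        raise ValueError("backbone must be cyclized first")
    E = backbone.n_extensions
    A = backbone.starter.ring_atom_count

    atoms: list[str] = ["N"]
    bonds: list[tuple[int, int, int]] = []

    # starter ring carbons: N - s_{A-2} - ... - s_1(carboxyl C) - alpha_1 ...
    starter_c = [len(atoms) + i for i in range(A - 1)]  # s_1 .. s_{A-1}, chain order
    atoms.extend("C" for _ in starter_c)
    bonds.append((0, starter_c[-1], 1))  # N to the amine-bearing carbon
    for a, b in zip(starter_c, starter_c[1:]):
        bonds.append((a, b, 1))
    for pos in backbone.starter.methyl_positions:
        methyl = len(atoms)
        atoms.append("C")
        bonds.append((starter_c[pos - 1], methyl, 1))

    # extension units: beta carbon of unit i is the carbonyl C donated by
    # unit i-1 (or the starter carboxyl carbon for unit 1)
    beta = starter_c[0]
    alpha_atoms: dict[int, int] = {}
    carbonyl_atoms: dict[int, int] = {}
    for unit in backbone.units:
        alpha = len(atoms)
        atoms.append("C")
        carbonyl = len(atoms)
        atoms.append("C")
        alpha_atoms[unit.position] = alpha
        carbonyl_atoms[unit.position] = carbonyl

        if unit.beta_state == "enoyl":
            bonds.append((beta, alpha, 2))
        else:
            bonds.append((beta, alpha, 1))
        if unit.beta_state == "ketone":
            oxo = len(atoms)
            atoms.append("O")
            bonds.append((beta, oxo, 2))
        elif unit.beta_state == "hydroxyl":
            hydroxyl = len(atoms)
            atoms.append("O")
            bonds.append((beta, hydroxyl, 1))
        bonds.append((alpha, carbonyl, 1))
        if unit.alpha_substituent == "CH3":
            methyl = len(atoms)
            atoms.append("C")
            bonds.append((alpha, methyl, 1))
        beta = carbonyl

    # amide closure: final carbonyl to N, with the amide oxygen
    amide_o = len(atoms)
    atoms.append("O")
    bonds.append((beta, amide_o, 2))
    bonds.append((beta, 0, 1))

    # tailoring hydroxylations add one O each
    labels = _carbon_label_atoms(backbone, alpha_atoms, carbonyl_atoms, starter_c)
    for event in backbone.tailoring:
        if event.kind == "hydroxylation":
            oh = len(atoms)
            atoms.append("O")
            bonds.append((labels[event.site], oh, 1))
    return atoms, bonds, labels


def _carbon_label_atoms(
    backbone: Backbone,
    alpha_atoms: Mapping[int, int],
    carbonyl_atoms: Mapping[int, int],
    starter_c: list[int],
) -> dict[str, int]:
    """Map conventional carbon labels (C-1 = amide carbonyl, numbering along
    the chain toward the starter) to graph atom indices."""
    E = backbone.n_extensions
    labels: dict[str, int] = {}
    for unit in backbone.units:
        labels[f"C-{2 * (E + 1 - unit.position) - 1}"] = carbonyl_atoms[unit.position]
        labels[f"C-{2 * (E + 1 - unit.position)}"] = alpha_atoms[unit.position]
    # starter ring carbons continue the numbering: carboxyl C first
    for offset, atom in enumerate(starter_c):
        labels[f"C-{2 * E + 1 + offset}"] = atom
    return labels


def carbon_labels(backbone: Backbone) -> dict[str, int]:
    """Carbon-label map of a cyclized backbone: ``C-1`` is the amide
    carbonyl, numbering runs along the chain toward the starter."""
    return backbone_graph(backbone)[2]


_VALENCE = {"C": 4, "N": 3, "O": 2}


def molecular_formula(backbone: Backbone) -> Formula:
    """Assemble the molecular formula from the explicit atom ledger.

    Hydrogens are filled to valence; the amide nitrogen keeps one N-H.  A
    protected starter amine carries the configured protecting-group delta
    until an ``amide_deprotection`` tailoring event removes it.  The
    graph-derived degrees of unsaturation are checked against the
    formula-derived value before returning.
    """
    if backbone.ring_size is None:
        raise ValueError("backbone must be cyclized before formula assembly")
    atoms, bonds, _ = backbone_graph(backbone)

    order_sum = [0] * len(atoms)
    for a, b, order in bonds:
        order_sum[a] += order
        order_sum[b] += order

    counts: dict[str, int] = {}
    n_h = 0
    for element, used in zip(atoms, order_sum):
        counts[element] = counts.get(element, 0) + 1
        free = _VALENCE[element] - used
        if free < 0:
            raise ValueError("inconsistent tailoring: atom exceeds valence")
        n_h += free
    counts["H"] = counts.get("H", 0) + n_h
    formula = Formula(counts)

    deprotected = any(e.kind == "amide_deprotection" for e in backbone.tailoring)
    if backbone.starter.amine_protected and not deprotected:
        delta = Formula(default_config()["protecting_group_delta"])
        formula = formula + delta

    # cross-check: one ring + pi bonds vs the formula DBE
    graph_dbe = 1 + sum(order - 1 for *_, order in bonds)
    if backbone.starter.amine_protected and not deprotected:
        graph_dbe += 1  # the protecting amide carbonyl
    if abs(formula.dbe() - graph_dbe) > 1e-9:
        raise AssertionError(
            f"DBE mismatch: graph {graph_dbe} vs formula {formula.dbe()}"
        )
    return formula


def monoisotopic_mz(
    formula: Mapping[str, int],
    adduct: str = "[M+H]+",
    config: Mapping[str, Any] | None = None,
    ndigits: int | None = 4,
) -> float:
    """Monoisotopic mass of ``formula`` plus the adduct atoms, in Da.

    Neutral-atom adduct masses (electron mass neglected); half-even rounding
    at ``ndigits`` decimals (``None`` for full precision).
    """
    cfg = config or default_config()
    masses = cfg["element_masses"]
    adducts = cfg["adducts"]
    if adduct not in adducts:
        raise ValueError(f"unknown adduct {adduct!r} (have {sorted(adducts)})")
    total = 0.0
    for element, count in list(formula.items()) + list(adducts[adduct].items()):
        if element not in masses:
            raise ValueError(f"unknown element symbol {element!r}")
        total += count * masses[element]
    if ndigits is None:
        return total
    return float(
        decimal.Decimal(repr(total)).quantize(
            decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_EVEN
        )
    )
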