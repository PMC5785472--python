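"""Synthetic fixtures with known ground truth for every pipeline stage.

Proteins are concatenations of fixed-width synthetic domain scaffolds —
neutral filler plus the anchor, catalytic and specificity motifs of the
signature tables at known offsets — partitioned across genes with
coiled-coil docking termini where requested.  The filler alphabet
(``AEILRTV``) deliberately excludes every residue that the shipped anchor
motifs require (G, S, H, C, D, N, P, Q, W, Y, M, K, F), so anchors cannot
arise by chance; an explicit generation-time scan of the realized protein
against the anchor table guards the invariant.  These are synthetic stand-in
sequences, not real PKS domains: they carry the classification-relevant
motifs and nothing else.

All randomness flows through one seeded ``random.Random``; regenerating with
the same seed and parameters reproduces byte-identical sequences and truth.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

from .chem import BackboneUnit, module_beta_state
from .config import default_config
from .io_model import ClusterInterval, ClusterTable, GeneRecord

__all__ = [
    "ModuleSpec",
    "GeneSpec",
    "TruthRecord",
    "Fixture",
    "generate_assembly_line",
    "mutate_fixture",
    "generate_cluster_table",
    "sce_architecture",
    "sce_fixture",
    "generate_decoy_genome",
]

FILLER_ALPHABET = "AEILRTV"
DOCK_REPEAT = "LEALEKA"  # heptad with hydrophobic a/d positions
N_DOCK_REPEATS = 7

_EXTENSION_ORDER = ("KS", "AT", "DH", "ER", "KR", "ACP")


@dataclass(frozen=True)
class ModuleSpec:
    """Requested domain content and signature identity of one module."""

    domains: tuple[str, ...]
    at_substrate: str = "malonyl"  # malonyl | methylmalonyl | unknown
    kr_type: str | None = None  # A | B | inactive | None
    ablate: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kr_type is not None and "KR" not in self.domains:
            raise ValueError("kr_type requested for a module without a KR domain")
        if "KR" in self.domains and self.kr_type is None:
            raise ValueError("module with a KR domain needs a kr_type")
        bad = [d for d in self.domains if d not in _EXTENSION_ORDER + ("TE",)]
        if bad:
            raise ValueError(f"unknown domain classes {bad}")

    @property
    def is_loading(self) -> bool:
        return "KS" not in self.domains

    def expected_unit(self, position: int) -> BackboneUnit:
        """Ground-truth backbone unit this module should contribute."""
        alpha = "CH3" if self.at_substrate == "methylmalonyl" else "H"
        kr = (
            "KR" in self.domains
            and self.kr_type in ("A", "B")
            and "KR_tyr" not in self.ablate
        )
        dh = "DH" in self.domains and "DH_his" not in self.ablate
        er = "ER" in self.domains
        state = module_beta_state(kr, dh, er)
        stereo = ("R" if self.kr_type == "B" else "S") if state == "hydroxyl" else "none"
        geometry = "E" if state == "enoyl" else "none"
        return BackboneUnit(position, alpha, state, stereo, geometry)


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    modules: tuple[ModuleSpec, ...]
    n_dock: bool = False
    c_dock: bool = False
    te: bool = False


@dataclass
class TruthRecord:
    """Everything the generator knows about a fixture."""

    architecture: tuple[GeneSpec, ...]
    seed: int
    expected_units: list[BackboneUnit] = field(default_factory=list)
    docking: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    expected_hits: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_extension_modules(self) -> int:
        return sum(
            1 for gene in self.architecture for m in gene.modules if not m.is_loading
        )


@dataclass
class Fixture:
    genes: list[GeneRecord]
    truth: TruthRecord
    name: str = "synthetic"

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for g in self.genes:
                handle.write(f">{g.gene_id}\n{g.protein_seq}\n")

    def write_gene_table(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("gene\tstart\tend\tstrand\trole\n")
            for g in self.genes:
                handle.write(
                    f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.role}\n"
                )

    def write_genbank(self, path: str | Path) -> None:
        """Write a minimal GenBank flat file with CDS /translation features."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord

        length = max(g.end for g in self.genes) + 100
        record = SeqRecord(Seq("A" * length), id=self.name, name=self.name[:16])
        record.annotations["molecule_type"] = "DNA"
        for g in self.genes:
            feature = SeqFeature(
                FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "gene": [g.gene_id],
                    "product": [g.role],
                    "translation": [g.protein_seq],
                },
            )
            record.features.append(feature)
        SeqIO.write([record], str(path), "genbank")


def _filler(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(FILLER_ALPHABET) for _ in range(n))


def _scaffold(cls: str, spec: ModuleSpec, rng: random.Random) -> str:
    """Fixed-layout synthetic scaffold for one domain."""
    f = lambda n: _filler(rng, n)
    if cls == "KS":
        cat = "DTAASSSLVA" if "KS_cys" in spec.ablate else "DTACSSSLVA"
        return f(5) + "EPIAIVGM" + f(10) + cat + f(37)
    if cls == "AT":
        active = "GHAQG" if "AT_ser" in spec.ablate else "GHSQG"
        window = {"methylmalonyl": "YASH", "malonyl": "HAFH"}.get(
            spec.at_substrate, "TATT"
        )
        return f(5) + "GQGAQ" + f(6) + active + f(9) + window + f(46)
    if cls == "DH":
        cat = "AALLADEVLA" if "DH_his" in spec.ablate else "HALLGDEVLP"
        return f(5) + cat + f(45)
    if cls == "ER":
        return f(5) + "GGVGMA" + f(49)
    if cls == "KR":
        type_motif = {"B": "LDD", "A": "AWA"}.get(spec.kr_type, f(3))
        cat = f(5) if ("KR_tyr" in spec.ablate or spec.kr_type == "inactive") else "YGAAN"
        return f(5) + "GGTGALG" + f(8) + type_motif + f(12) + cat + f(30)
    if cls == "ACP":
        return f(5) + "GVDSL" + f(30)
    if cls == "TE":
        return f(5) + "GWSAG" + f(40)
    raise ValueError(f"no scaffold for domain class {cls}")


def _build_protein(gene: GeneSpec, rng: random.Random) -> tuple[str, tuple[str, ...]]:
    parts: list[str] = []
    classes: list[str] = []
    if gene.n_dock:
        parts.append(DOCK_REPEAT * N_DOCK_REPEATS)
    else:
        parts.append(_filler(rng, rng.randint(6, 14)))
    for module in gene.modules:
        for cls in module.domains:
            parts.append(_scaffold(cls, module, rng))
            parts.append(_filler(rng, 10))
            # a DH-histidine ablation destroys the anchor itself, so the
            # domain is expected to be invisible to the scanner
            if not (cls == "DH" and "DH_his" in module.ablate):
                classes.append(cls)
    if gene.te:
        te_spec = ModuleSpec(domains=("TE",), at_substrate="malonyl")
        parts.append(_scaffold("TE", te_spec, rng))
        parts.append(_filler(rng, 10))
        classes.append("TE")
    if gene.c_dock:
        parts.append(DOCK_REPEAT * N_DOCK_REPEATS)
    else:
        parts.append(_filler(rng, rng.randint(0, 8)))
    return "".join(parts), tuple(classes)


def _verify_anchors(
    protein: str, expected: Sequence[str], config: Mapping[str, Any]
) -> None:
    """Guard against accidental anchor creation by filler or junctions."""
    found = []
    for cls, rules in config["domains"].items():
        for match in re.finditer(rules["anchor"], protein):
            found.append((match.start(), cls))
    found.sort()
    realized = tuple(cls for _, cls in found)
    if realized != tuple(expected):
        raise RuntimeError(
            f"scaffold anchor collision: expected {expected}, found {realized}"
        )


def generate_assembly_line(
    n_modules: int,
    spec: str | Sequence[ModuleSpec] = "random",
    seed: int = 0,
    n_genes: int | None = None,
    name: str = "synthetic",
    gene_prefix: str = "pksA",
) -> Fixture:
    """Generate a multi-gene PKS cluster fixture plus its truth record.

    ``spec`` is either an explicit per-extension-module list of
    :class:`ModuleSpec` (loading module, docking and TE are added
    automatically) or ``"random"``.  Modules are partitioned across
    ``n_genes`` genes (random 1..4 when omitted).
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = random.Random(seed)

    if spec == "random":
        choices = [
            ("KS", "AT", "ACP"),
            ("KS", "AT", "KR", "ACP"),
            ("KS", "AT", "DH", "KR", "ACP"),
            ("KS", "AT", "DH", "ER", "KR", "ACP"),
        ]
        modules = []
        for _ in range(n_modules):
            domains = rng.choice(choices)
            modules.append(
                ModuleSpec(
                    domains=domains,
                    at_substrate=rng.choice(["malonyl", "malonyl", "methylmalonyl"]),
                    kr_type=("B" if rng.random() < 0.8 else "A")
                    if "KR" in domains
                    else None,
                )
            )
    else:
        modules = list(spec)
        if len(modules) != n_modules:
            raise ValueError(
                f"spec lists {len(modules)} modules but n_modules={n_modules}"
            )
        for m in modules:
            if m.is_loading:
                raise ValueError("spec must list extension modules only")

    if n_genes is None:
        n_genes = rng.randint(1, min(4, n_modules))
    if not 1 <= n_genes <= n_modules:
        raise ValueError("n_genes must be between 1 and n_modules")

    # contiguous partition of modules over genes
    bounds = sorted(rng.sample(range(1, n_modules), n_genes - 1)) + [n_modules]
    genespecs: list[GeneSpec] = []
    start_idx = 0
    for gi, stop in enumerate(bounds):
        gene_modules = tuple(modules[start_idx:stop])
        if gi == 0:
            loading = ModuleSpec(domains=("ACP",))
            gene_modules = (loading,) + gene_modules
        genespecs.append(
            GeneSpec(
                gene_id=f"{gene_prefix}{gi + 1}" if n_genes > 1 else gene_prefix,
                modules=gene_modules,
                n_dock=gi > 0,
                c_dock=gi < n_genes - 1,
                te=gi == n_genes - 1,
            )
        )
        start_idx = stop
    return _realize(tuple(genespecs), seed, name)


def _realize(
    architecture: tuple[GeneSpec, ...], seed: int, name: str
) -> Fixture:
    """Deterministically realize sequences and truth from an architecture."""
    rng = random.Random(seed)  # single seeded stream
    config = default_config()
    genes: list[GeneRecord] = []
    truth = TruthRecord(architecture=architecture, seed=seed)
    position = 1
    offset = 1000
    for genespec in architecture:
        protein, classes = _build_protein(genespec, rng)
        _verify_anchors(protein, classes, config)
        genes.append(
            GeneRecord(
                gene_id=genespec.gene_id,
                protein_seq=protein,
                start=offset,
                end=offset + 3 * len(protein) - 1,
                strand="+",
                role="Polyketide synthase",
            )
        )
        offset += 3 * len(protein) + 200
        truth.docking[genespec.gene_id] = (genespec.n_dock, genespec.c_dock)
        truth.expected_hits[genespec.gene_id] = classes
        for module in genespec.modules:
            if not module.is_loading:
                truth.expected_units.append(module.expected_unit(position))
                position += 1
    return Fixture(genes=genes, truth=truth, name=name)


def mutate_fixture(fixture: Fixture, op: str, **kwargs: Any) -> Fixture:
    """Architecture-level mutations with consistently updated truth.

    ``delete_module`` (k: global extension-module index), ``inject_orphan_trans``
    (docking: bool), ``ablate_residue`` (rule: str, k: module index).
    """
    arch = fixture.truth.architecture
    if op == "delete_module":
        k = kwargs["k"]
        if fixture.truth.n_extension_modules <= 1:
            raise ValueError("cannot delete the only extension module")
        new_arch, index = [], 0
        found = False
        for gene in arch:
            kept = []
            for module in gene.modules:
                if not module.is_loading:
                    index += 1
                    if index == k:
                        found = True
                        continue
                kept.append(module)
            new_arch.append(replace(gene, modules=tuple(kept)))
        if not found:
            raise ValueError(f"no extension module with index {k}")
        return _realize(tuple(new_arch), fixture.truth.seed, fixture.name)

    if op == "inject_orphan_trans":
        docking = kwargs.get("docking", True)
        orphan = GeneSpec(
            gene_id=kwargs.get("gene_id", "orphan1"),
            modules=(ModuleSpec(domains=("KS", "AT", "ACP")),),
            n_dock=docking,
            c_dock=docking,
        )
        rng = random.Random(fixture.truth.seed + 7919)
        protein, classes = _build_protein(orphan, rng)
        _verify_anchors(protein, classes, default_config())
        start = max(g.end for g in fixture.genes) + 50_000
        gene = GeneRecord(
            gene_id=orphan.gene_id,
            protein_seq=protein,
            start=start,
            end=start + 3 * len(protein) - 1,
            strand="+",
            role="Polyketide synthase",
        )
        out = Fixture(
            genes=fixture.genes + [gene],
            truth=replace_truth(fixture.truth, architecture=arch + (orphan,)),
            name=fixture.name,
        )
        out.truth.docking[orphan.gene_id] = (docking, docking)
        out.truth.expected_hits[orphan.gene_id] = classes
        return out

    if op == "ablate_residue":
        rule, k = kwargs["rule"], kwargs["k"]
        new_arch, index = [], 0
        for gene in arch:
            new_modules = []
            for module in gene.modules:
                if not module.is_loading:
                    index += 1
                    if index == k:
                        module = replace(
                            module, ablate=module.ablate | {rule}
                        )
                new_modules.append(module)
            new_arch.append(replace(gene, modules=tuple(new_modules)))
        if index < k:
            raise ValueError(f"no extension module with index {k}")
        return _realize(tuple(new_arch), fixture.truth.seed, fixture.name)

    raise ValueError(f"unknown mutation op {op!r}")


def replace_truth(truth: TruthRecord, **changes: Any) -> TruthRecord:
    out = TruthRecord(
        architecture=changes.get("architecture", truth.architecture),
        seed=truth.seed,
        expected_units=list(truth.expected_units),
        docking=dict(truth.docking),
        expected_hits=dict(truth.expected_hits),
    )
    return out


def sce_architecture() -> tuple[GeneSpec, ...]:
    """The shipped sceliphrolactam-cluster architecture (figure-derived).

    Five module-bearing proteins, a loading carrier protein on the first,
    ten extension modules with methylmalonyl signatures at modules 3 and 8,
    all-B-type KRs, one KR-less module (8) and one DH-less module (6), and a
    terminal thioesterase.  This transcription of the drawn biosynthetic
    scheme is marked figure-derived: the per-protein module distribution is
    not tabulated in any text source.
    """
    full = ("KS", "AT", "DH", "KR", "ACP")
    m = lambda domains, at="malonyl", kr="B": ModuleSpec(
        domains=domains, at_substrate=at, kr_type=kr if "KR" in domains else None
    )
    loading = ModuleSpec(domains=("ACP",))
    return (
        GeneSpec("sceN", (loading, m(full), m(full)), n_dock=False, c_dock=True),
        GeneSpec("sceO", (m(full, at="methylmalonyl"), m(full)), n_dock=True, c_dock=True),
        GeneSpec("sceQ", (m(full),), n_dock=True, c_dock=True),
        GeneSpec("sceR", (m(("KS", "AT", "KR", "ACP")),), n_dock=True, c_dock=True),
        GeneSpec(
            "sceS",
            (m(full), m(("KS", "AT", "ACP"), at="methylmalonyl"), m(full), m(full)),
            n_dock=True,
            c_dock=False,
            te=True,
        ),
    )


def sce_fixture(seed: int = 85) -> Fixture:
    """Realize the sceliphrolactam-cluster fixture."""
    return _realize(sce_architecture(), seed, name="sce")


def generate_decoy_genome(
    seed: int = 0, n_decoys: int = 6, include_partial: bool = True
) -> list[GeneRecord]:
    """Non-cluster genes with no complete orphan module (filler proteins plus,
    optionally, an incomplete KS-AT gene without a carrier protein)."""
    rng = random.Random(seed)
    genes: list[GeneRecord] = []
    offset = 2_000_000
    for i in range(n_decoys):
        protein = _filler(rng, rng.randint(200, 400))
        genes.append(
            GeneRecord(
                gene_id=f"decoy{i + 1}",
                protein_seq=protein,
                start=offset,
                end=offset + 3 * len(protein) - 1,
                role="hypothetical protein",
            )
        )
        offset += 3 * len(protein) + 500
    if include_partial:
        partial = GeneSpec(
            gene_id="partial1", modules=(ModuleSpec(domains=("KS", "AT")),)
        )
        protein, classes = _build_protein(partial, rng)
        _verify_anchors(protein, classes, default_config())
        genes.append(
            GeneRecord(
                gene_id="partial1",
                protein_seq=protein,
                start=offset,
                end=offset + 3 * len(protein) - 1,
                role="Polyketide synthase",
            )
        )
    return genes


def generate_cluster_table(
    n_clusters: int,
    genome_length: int,
    overlap_prob: float = 0.0,
    seed: int = 0,
) -> tuple[ClusterTable, int]:
    """Random cluster coordinate table plus bit-vector truth occupancy."""
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    rng = random.Random(seed)
    min_len, max_len = 1_000, max(2_000, genome_length // max(n_clusters, 1) // 2)
    if n_clusters and genome_length < n_clusters * min_len:
        raise ValueError("genome too small for the requested clusters")
    intervals: list[ClusterInterval] = []
    prev: tuple[int, int] | None = None
    for i in range(1, n_clusters + 1):
        length = rng.randint(min_len, max_len)
        if prev is not None and rng.random() < overlap_prob:
            start = rng.randint(prev[0], prev[1])  # force an overlap
        else:
            start = rng.randint(1, max(1, genome_length - length))
        end = min(genome_length, start + length - 1)
        intervals.append(ClusterInterval(i, rng.choice(["NRPS", "T1PKS", "Terpene"]), start, end))
        prev = (start, end)
    covered = bytearray(genome_length + 1)
    for iv in intervals:
        for pos in range(iv.from_bp, iv.to_bp + 1):
            covered[pos] = 1
    truth_bp = sum(covered)
    return ClusterTable(intervals=intervals, genome_length=genome_length), truth_bp


def write_cluster_tsv(table: ClusterTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("cluster\tproduct\tfrom\tto\n")
        for iv in table.intervals:
            handle.write(f"{iv.cluster_id}\t{iv.product_type}\t{iv.from_bp}\t{iv.to_bp}\n")
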