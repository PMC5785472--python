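"""Collinearity auditing, trans-module search and iterative-module inference."""

import random

import pytest

from pksmine.assembly import mine_cluster
from pksmine.audit import (
    ProductSpec,
    audit_collinearity,
    enumerate_iterative_hypotheses,
    find_trans_candidates,
    load_product_spec,
    required_extensions,
)
from pksmine.chem import BackboneUnit, Formula, predict_backbone, starter_from_library
from pksmine.synthetic import (
    ModuleSpec,
    generate_assembly_line,
    generate_decoy_genome,
    mutate_fixture,
    sce_fixture,
)

AMP = starter_from_library("3-amino-2-methylpropionate")


def spec_from_units(units, name="target"):
    return ProductSpec(
        name=name,
        formula=Formula({"C": 1}),
        ring_size=2 * len(units) + AMP.ring_atom_count,
        starter=AMP,
        target_units=list(units),
        branch_positions=tuple(
            u.position for u in units if u.alpha_substituent == "CH3"
        ),
    )


# --- required extensions ----------------------------------------------------


def test_required_extensions_sceliphrolactam(sce_spec):
    assert required_extensions(sce_spec) == (11, 9, 2)


def test_required_extensions_minimal():
    units = [BackboneUnit(1, "H", "ketone")]
    assert required_extensions(spec_from_units(units)) == (1, 1, 0)


@pytest.mark.parametrize("seed", range(10))
def test_required_extensions_equals_unit_count(seed):
    rng = random.Random(seed)
    units = []
    for i in range(1, rng.randint(2, 14) + 1):
        alpha = rng.choice(["H", "CH3"])
        units.append(BackboneUnit(i, alpha, "ketone"))
    spec = spec_from_units(units)
    e_req, n_mal, n_mm = required_extensions(spec)
    assert e_req == len(units)
    assert n_mm == sum(1 for u in units if u.alpha_substituent == "CH3")
    assert n_mal + n_mm == e_req


def test_inconsistent_ring_size_rejected():
    units = [BackboneUnit(1, "H", "ketone")]
    with pytest.raises(ValueError, match="even"):
        ProductSpec("bad", Formula({}), 7, AMP, units)


# --- audit ------------------------------------------------------------------


def test_sce_audit_is_one_module_short(sce_line, sce_spec):
    report = audit_collinearity(sce_line, sce_spec)
    assert (report.e_req, report.m_enc) == (11, 10)
    assert report.deficit == 1
    assert report.verdict == "deficit"


def test_collinear_line_audits_clean():
    fx = generate_assembly_line(5, seed=21)
    line = mine_cluster(fx.genes)
    spec = spec_from_units(fx.truth.expected_units)
    report = audit_collinearity(line, spec)
    assert report.deficit == 0
    assert report.verdict == "collinear"
    assert all(row["match"] for row in report.match_table)


@pytest.mark.parametrize("seed", range(8))
def test_deleting_any_module_yields_unit_deficit(seed):
    rng = random.Random(seed)
    e = rng.randint(3, 9)
    fx = generate_assembly_line(e, seed=seed)
    spec = spec_from_units(fx.truth.expected_units)
    k = rng.randint(1, e)
    deleted = mutate_fixture(fx, "delete_module", k=k)
    report = audit_collinearity(mine_cluster(deleted.genes), spec)
    assert report.deficit == 1
    assert report.verdict == "deficit"


# --- trans-module search ----------------------------------------------------


def test_orphan_free_genome_has_no_trans_candidates():
    genome = generate_decoy_genome(seed=2)
    assert find_trans_candidates(genome) == []


def test_injected_orphan_is_found_exactly():
    fx = sce_fixture(seed=5)
    with_orphan = mutate_fixture(fx, "inject_orphan_trans")
    genome = generate_decoy_genome(seed=2) + [
        g for g in with_orphan.genes if g.gene_id == "orphan1"
    ]
    hits = find_trans_candidates(genome)
    assert [h.module_ref for h in hits] == [("orphan1", None)]
    assert all(h.kind == "trans_module" and not h.consistent for h in hits)


def test_orphan_without_docking_filtered_and_monotonicity():
    fx = sce_fixture(seed=5)
    undocked = mutate_fixture(fx, "inject_orphan_trans", docking=False)
    genome = generate_decoy_genome(seed=2) + [
        g for g in undocked.genes if g.gene_id == "orphan1"
    ]
    strict = find_trans_candidates(genome, require_docking=True)
    relaxed = find_trans_candidates(genome, require_docking=False)
    assert strict == []
    assert [h.module_ref for h in relaxed] == [("orphan1", None)]
    # relaxing the docking requirement can only grow the candidate set
    strict_ids = {h.module_ref for h in strict}
    relaxed_ids = {h.module_ref for h in relaxed}
    assert strict_ids <= relaxed_ids


# --- iterative hypothesis enumeration ---------------------------------------


def brute_force_iterative(line, target_units):
    """Independent exhaustive enumerator over (module, S1, S2) triples."""

    def outcome(module, active):
        alpha = "CH3" if module.at_call.substrate == "methylmalonyl" else "H"
        has = set(module.domain_classes)
        if "KR" not in has or "KR" not in active:
            return (alpha, "ketone")
        if "DH" not in has or "DH" not in active:
            return (alpha, "hydroxyl")
        if "ER" not in has or "ER" not in active:
            return (alpha, "enoyl")
        return (alpha, "methylene")

    def subsets(module):
        present = [d for d in ("KR", "DH", "ER") if d in module.domain_classes]
        out = []
        for mask in range(2 ** len(present)):
            out.append(frozenset(d for i, d in enumerate(present) if mask >> i & 1))
        return out

    target = [u.state_key for u in target_units]
    modules = line.extension_modules
    natural = [outcome(m, {"KR", "DH", "ER"}) for m in modules]
    found = set()
    for mi, module in enumerate(modules):
        for s1 in subsets(module):
            for s2 in subsets(module):
                simulated = (
                    natural[:mi]
                    + [outcome(module, s1), outcome(module, s2)]
                    + natural[mi + 1 :]
                )
                if simulated == target:
                    found.add((module.module_index, tuple(simulated)))
    return found


def test_sce_iterative_candidates_are_sceq_and_scer(sce_line, sce_spec):
    """Exactly two candidate modules, with KR toggling off (first protein)
    or on (second protein) between the two passes."""
    hyps = enumerate_iterative_hypotheses(sce_line, sce_spec)
    assert [h.module_ref for h in hyps] == [("sceQ", 5), ("sceR", 6)]
    sceq, scer = hyps
    # first pass reduced+dehydrated, second pass unprocessed ketone
    assert sceq.pass_states == (("DH", "KR"), ())
    # first pass unprocessed ketone, second pass reduced to the hydroxyl
    assert scer.pass_states == ((), ("KR",))
    for h in hyps:
        assert h.consistent
        assert "toggles:KR" in h.notes


def test_sce_hypotheses_self_consistent(sce_line, sce_spec):
    for h in enumerate_iterative_hypotheses(sce_line, sce_spec):
        replay = predict_backbone(
            sce_line,
            sce_spec.starter,
            pass_plan={h.module_ref[1]: (frozenset(h.pass_states[0]), frozenset(h.pass_states[1]))},
        )
        assert [u.state_key for u in replay.units] == [
            u.state_key for u in sce_spec.target_units
        ]


def test_iterative_search_requires_unit_deficit(sce_line):
    fx = generate_assembly_line(5, seed=21)
    spec = spec_from_units(fx.truth.expected_units)
    line = mine_cluster(fx.genes)
    with pytest.raises(ValueError, match="deficit of exactly 1"):
        enumerate_iterative_hypotheses(line, spec)


@pytest.mark.parametrize("batch", range(4))
def test_enumeration_equals_brute_force_on_random_deficit_fixtures(batch):
    """Exact set equality with the independent enumerator, 100 instances."""
    rng = random.Random(1000 + batch)
    for _ in range(25):
        seed = rng.randrange(2**20)
        e = rng.randint(4, 12)
        fx = generate_assembly_line(e, seed=seed)
        spec = spec_from_units(fx.truth.expected_units, name=f"t{seed}")
        deleted = mutate_fixture(fx, "delete_module", k=rng.randint(1, e))
        line = mine_cluster(deleted.genes)
        hyps = enumerate_iterative_hypotheses(line, spec)
        ours = {
            (h.module_ref[1], tuple(u.state_key for u in h.resulting_backbone.units))
            for h in hyps
        }
        assert ours == brute_force_iterative(line, spec.target_units)


def test_candidates_adjacent_to_deletion_site():
    """With period-3 distinct states, only the deletion's neighbours rescue."""
    pattern = [
        ModuleSpec(("KS", "AT", "DH", "KR", "ACP"), kr_type="B"),
        ModuleSpec(("KS", "AT", "KR", "ACP"), kr_type="B"),
        ModuleSpec(("KS", "AT", "ACP")),
    ] * 3
    fx = generate_assembly_line(9, spec=pattern, seed=31, n_genes=2)
    spec = spec_from_units(fx.truth.expected_units)
    for k in (3, 6):  # delete a ketone module
        deleted = mutate_fixture(fx, "delete_module", k=k)
        line = mine_cluster(deleted.genes)
        hyps = enumerate_iterative_hypotheses(line, spec)
        candidates = {h.module_ref[1] for h in hyps}
        assert candidates
        assert candidates <= {k - 1, k, k + 1}
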