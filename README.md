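# pksmine

Genome mining for **type I modular polyketide synthase (PKS)** biosynthetic
gene clusters, built around the sceliphrolactam system of *Streptomyces* sp.
SD85: a 26-membered polyene macrolactam whose cluster encodes one module
fewer than the collinearity rule demands.

The package turns the inference chain a natural-product chemist performs by
hand into a reusable, tested pipeline:

1. **Domain signatures** — locate KS/AT/DH/ER/KR/ACP/TE domains by anchor
   motifs, call acyltransferase substrate choice from the specificity window
   downstream of the GHSxG serine (YASH → methylmalonyl-CoA, HAFH →
   malonyl-CoA), type ketoreductases (B-type `(L/V)D(D/N)` motif → *R*
   β-hydroxyl; A-type tryptophan criterion → *S*), and check per-class
   essential catalytic residues.
2. **Assembly line** — group domains into modules (one module per KS), order
   modules across genes by chromosomal position, and test protein termini
   for coiled-coil docking domains that hold the megacomplex together.
3. **Backbone chemistry** — predict each extension's α-substituent and
   β-keto processing state, macrolactamize (`R = 2E + A` ring atoms for `E`
   extensions on a starter contributing `A` ring atoms), apply declarative
   tailoring, and derive the molecular formula from an explicit molecular
   graph, with monoisotopic adduct *m/z* to 4 decimals.
4. **Collinearity audit** — compare the line against a product spec
   (`E_req = (R − A)/2`), quantify the module deficit, search a genome for
   orphan *trans*-module candidates (KS-AT-ACP with docking ends), and
   exhaustively enumerate **programmed-iteration** hypotheses: one module
   catalyzing two successive extensions with independently toggled
   reductive-domain activity.
5. **Genome summary** — BGC occupancy (merged coverage) and per-type counts
   from an antiSMASH-style cluster coordinate table.
6. **Synthetic data** — fixture generator emitting multi-gene PKS clusters
   with all motifs at known offsets and full ground truth, plus mutation
   operators (module deletion, orphan injection, active-site ablation).

## Worked example

```python
import pksmine
from pksmine.synthetic import sce_fixture
from pksmine.audit import load_product_spec, audit_collinearity, enumerate_iterative_hypotheses
from pksmine.chem import predict_backbone, macrolactamize, apply_tailoring, molecular_formula, monoisotopic_mz

fx = sce_fixture()                     # 5 proteins: sceN, sceO, sceQ, sceR, sceS
line = pksmine.mine_cluster(fx.genes)  # scan + module grouping + docking
spec = load_product_spec()             # packaged sceliphrolactam definition

report = audit_collinearity(line, spec)
print(report.e_req, report.m_enc, report.deficit)   # 11 10 1

for h in enumerate_iterative_hypotheses(line, spec):
    print(h.module_ref, h.pass_states)
# ('sceQ', 5) (('DH', 'KR'), ())   — KR (and DH) on in pass 1, off in pass 2
# ('sceR', 6) ((), ('KR',))        — KR off in pass 1, on in pass 2

h = enumerate_iterative_hypotheses(line, spec)[0]
bb = predict_backbone(line, spec.starter, spec.geometry_overrides,
                      pass_plan={h.module_ref[1]: tuple(map(frozenset, h.pass_states))})
bb = macrolactamize(bb)
print(bb.ring_size)                                  # 26
bb = apply_tailoring(bb, spec.tailoring)
f = molecular_formula(bb)
print(f.hill(), monoisotopic_mz(f, "[M+H]+"))        # C28H35NO6 482.2543
```

The audit reports a ten-module line against eleven required extensions
(nine malonyl + two methylmalonyl): a deficit of one. Exactly two modules —
the single-module proteins SceQ and SceR — can rescue the deficit by
iterating with a KR activity switch between passes, and either hypothesis
completes the 26-membered macrolactam whose tailored formula matches the
isolated compound (C28H35NO6, monoisotopic [M+H]⁺ 482.2543 Da at CODATA
masses; printed isolation values truncate to 482.2542).

A command-line layer mirrors the library:

```bash
pksmine summarize-bgcs --table src/pksmine/data/sd85_bgc_table.tsv --genome-length 8625724
pksmine audit --cluster sce.gbk
pksmine trans-search --genome genome_proteins.faa --composition KS-AT-ACP
pksmine simulate line --sce --outdir scratch/fixtures
pksmine mass --formula C28H35NO6 --adduct "[M+H]+"
```

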