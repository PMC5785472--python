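# Methods

## The biological model

Type I modular PKS systems are assembly lines: each module minimally carries
a ketosynthase (KS), an acyltransferase (AT) and an acyl carrier protein
(ACP) and performs one chain extension with a malonyl-CoA or
methylmalonyl-CoA extender; optional ketoreductase (KR), dehydratase (DH)
and enoylreductase (ER) domains process the new β-keto group stepwise to a
hydroxyl, an enoyl double bond or a fully saturated methylene. Under the
collinearity rule the chromosomal order of modules mirrors the order of
extensions, and the module count equals the extension count. Polyene
macrolactams of the sceliphrolactam/vicenistatin family are primed with a
β-amino-acid starter whose amine, kept protected as an amide during
elongation, closes the macrolactam.

The package implements this model as rule tables plus combinatorics, not as
statistical inference: every call is a deterministic function of sequence
and configuration.

## Signature rules and their provenance

* **Domain location** is anchor-motif scanning (regex over the protein) with
  fixed-width windows around each anchor (widths in `signatures.yaml`),
  not profile-HMM search. Pre-annotated coordinates, when supplied, are
  validated and take precedence. Overlapping later hits are discarded in
  favour of the earlier anchor.
* **AT substrate**: the 4-residue specificity window 14 residues downstream
  of the GHSxG active-site match; YASH → methylmalonyl, HAFH → malonyl,
  anything else → unknown. The residue sets live in an editable YAML table
  because the primary literature points at binding-pocket residues without
  enumerating them; the shipped YASH/HAFH convention is the canonical one.
* **KR type**: B-type `[LV]D[DN]` motif in a configured window after the
  Rossmann anchor implies an *R*-configured β-hydroxyl. The A-type call
  (tryptophan in the same window → *S*) extrapolates the standard KR-typing
  convention and is flagged as such; a failed catalytic-tyrosine rule
  yields `inactive` and suppresses any configuration call.
* **Catalytic activity**: per-class residue regexes (KS cysteine of TACSSS,
  AT serine of GHSxG, DH histidine of HxxxGxxxxP, KR tyrosine, carrier
  serine of the phosphopantetheine site). `active` is true iff nothing is
  missing.
* **Docking**: terminal regions outside the first/last domain count as
  docking ends when at least 25 aa long with a best-phase heptad
  hydrophobicity score ≥ 0.8 (fraction of hydrophobic residues at coiled-coil
  a/d positions). This is a deliberate stand-in for structural prediction;
  both thresholds are configuration. Detected ends carry a generic class
  `CC0` and the shipped pairing table declares `CC0`–`CC0` compatible — the
  literature provides no dock-class vocabulary to encode.

## Backbone and mass conventions

* Extension *i* derives from module *i*; β-state mapping: no active KR →
  ketone; KR only → hydroxyl (stereo from the KR type); KR+DH → enoyl
  (default geometry E, per-position overrides for spectroscopically assigned
  cis bonds); KR+DH+ER → methylene. DH or ER without an active KR still
  leaves the ketone, since they act downstream of the reduction.
* Macrolactamization: ring size `R = 2E + A` with `A` the starter's ring-atom
  count including the nitrogen (4 for 3-amino-2-methylpropionate).
* Formulas are derived from an explicit molecular graph (heavy atoms, bond
  orders, hydrogens filled by valence), so the degrees of unsaturation
  computed from the graph and from the formula can be asserted equal on
  every call. The β-state oxygen ledger (ketone 1 O, hydroxyl 1 O, enoyl
  and methylene 0) and the one amide oxygen at closure fall out of the
  graph automatically. Carbon labels number the chain from the amide
  carbonyl (C-1) toward the starter, so tailoring sites like C-10/C-12 are
  addressable.
* A protected starter amine carries a configurable protecting-group delta
  (default glycyl amide, +C2H3NO) until an `amide_deprotection` event
  removes it.
* Monoisotopic adduct masses add *neutral* atom masses (H 1.00782503207,
  Na 22.98976928; electron mass neglected), matching the printed "calcd"
  convention of isolation papers. Internal arithmetic is full precision;
  half-even rounding to 4 decimals happens only at the reporting boundary.
  For C28H35NO6 + H this yields 482.254263 → 482.2543; printed isolation
  values for the same ion truncate to 482.2542.

## Collinearity audit and hypothesis search

`E_req = (R − A)/2` must be a positive integer; methylmalonyl extensions are
counted from the spec's branch positions. When the encoded module count
falls short by exactly one, two rescue families are enumerated:

* **Trans module**: every gene outside the cluster is scanned; a candidate
  must carry exactly the required composition (default KS-AT-ACP) as one
  contiguous module and, unless relaxed, docking ends at both termini.
  Relaxing the docking requirement can only grow the candidate set.
* **Programmed iteration**: exhaustive search over every module *m* and
  every ordered pair (S1, S2) of activity subsets of *m*'s reductive
  domains. A pass can only switch OFF domains the protein has — it can
  never gain one. The AT class is fixed across passes. Surviving
  hypotheses reproduce the target unit states exactly; duplicates with the
  same module and resulting backbone are collapsed, and the report labels
  which domains each hypothesis toggles (the search space deliberately
  includes DH toggles, since nothing rules them out). Comparison
  granularity is state-only by default (α-substituent + β-state), because
  stereochemistry is assigned by motif, not by iteration logic; a strict
  mode also compares stereo and geometry. Deficits ≥ 2 raise a clear
  not-implemented error rather than guessing multi-iteration semantics.

## Genome summary

Occupancy merges overlapping intervals before summation (coverage
semantics; merging is the only convention that cannot double-count) with
inclusive spans `to − from + 1`. The genome fraction is rounded to one
decimal percent. The megabase total is truncated (floored) at two
decimals — the convention consistent with how such totals are printed, and
one that never overstates coverage. Type-group counts match configurable
substring lists case-insensitively, because coordinate tables mix product
names with class labels; matched cluster ids are returned for audit. The
genome length is always an explicit input, never inferred (published
sources for SD85 print both 8,625,724 and 8,625,764 bp; the packaged table
uses the former).

## The synthetic generator

Fixture proteins concatenate fixed-layout scaffolds: neutral filler plus
the anchor, catalytic and specificity motifs at known offsets, partitioned
across genes, with `LEALEKA`-heptad docking termini at internal protein
junctions and a terminal TE. The filler alphabet (`AEILRTV`) excludes every
residue the anchor motifs require, so anchors cannot arise by chance; an
explicit generation-time scan enforces this. All randomness flows through
one seeded `random.Random`; identical seeds give byte-identical output.

The shipped `sce` fixture realizes the five-protein, ten-module
sceliphrolactam architecture: loading ACP on sceN, methylmalonyl AT
signatures at modules 3 and 8, B-type KRs throughout, a DH-less module 6
(sceR) and a KR-less module 8, TE on sceS. The per-protein module
distribution and per-position β-states are **figure-derived**: the drawn
biosynthetic scheme was transcribed under the hard constraint that eleven
extensions with these states, two P450 hydroxylations (C-10, C-12) and
amide deprotection must yield C28H35NO6 — a constraint with essentially one
solution (8 enoyl + 2 ketone + 1 hydroxyl).

What the fixtures do *not* emulate: real domain sequence diversity
(profile-HMM detectable domains), intergenic DNA, sequencing noise, or
non-modular PKS grammars (trans-AT, NRPS). Passing tests therefore
demonstrate the correctness of the grouping, auditing and chemical
bookkeeping logic on annotation-faithful input, not the sensitivity of
motif detection on wild sequences.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on the 5-gene /
10-module fixture, random 1–12-module fixtures (a few hundred instances),
and a 52-row coordinate table; the iterative search space is at most
11 modules × 8×8 pass-state pairs. All tie-breaks are deterministic: gene
order by (start, gene_id), hit order by position with earlier-anchor
precedence, hypothesis order by module index then pass states. Degenerate
inputs (empty tables, short sequences, mixed strands, inconsistent ring
arithmetic, valence-violating tailoring) raise typed errors with the
offending row, gene or site named.

## Known limitations

* Motif scanning will not find domains in real proteins whose anchors
  diverge from the configured regexes; annotation passthrough is the
  intended route for real data.
* The docking heuristic scores heptad periodicity only; it cannot assign
  real dock compatibility classes.
* Only the single-deficit iterative search is implemented.
* Stereochemistry is per-unit R/S and per-bond E/Z bookkeeping, not a
  conformational model; P450 regioselectivity is declared, never predicted.
* SMILES/structure export is not implemented; the formula/mass layer is the
  chemical endpoint.
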