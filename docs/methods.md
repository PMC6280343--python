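# Methods

## Data model and pipeline

`keggdraft` reconstructs draft metabolic networks from three kinds of KEGG
data: per-organism gene→EC links, the global EC→reaction link table, and
the flat-file annotation records of reactions, compounds and glycans. The
stages are strictly layered:

1. **Linkage.** For each query organism the gene→EC table is composed with
   the EC→reaction table. The result is the binary Organisms–Reactions
   (OR) matrix — `OR[o, r] = 1` iff some gene of organism *o* is annotated
   with an EC that catalyzes reaction *r* — plus, per (organism, reaction)
   cell, the sorted set of genes that establish the link (the ORG matrix).
   The ORG report renders each reaction row with its per-organism gene
   lists and three summaries: **Sum** (number of organisms containing the
   reaction), **Total** (Sum divided by the number of query organisms, an
   exact fraction) and **Genes** (the distinct per-organism gene counts in
   ascending order joined by `;`, so counts (6,6,4,6,6) print `4;6`; `0`
   when absent everywhere). For mixed-species queries Total retains the
   same definition (share of query organisms), which reduces to the
   published convention when the organisms are strains of one species.
2. **Record retrieval.** Only the reaction universe — reactions present in
   at least one query organism — is downloaded, then every participant
   compound/glycan record, then any compounds reached through glycan
   "Same as" cross-references. Fetches are cached one plain-text file per
   record; cache hits bypass the source, so a populated cache replays a
   run byte-identically offline.
3. **Filtering** (first match wins): generic-comment → polymer →
   possible-polymer → glycan handling → ill-defined, then a compound-mass
   screen over the survivors. Details below.
4. **Assembly.** Kept verdicts become reactions of the consolidated model;
   single models are restrictions of it; the community model is the
   disjoint union of the singles with organism-suffixed IDs.
5. **Reporting.** Omission accounting, ORG report, per-organism gene
   histograms, and graph statistics of the assembled network.

## Filtering semantics

* Trigger strings for generic reactions ("Generic", "General", "General
  reaction") are matched case-insensitively as substrings in **both** the
  REMARK and COMMENT fields. The alternative conjunction reading — only
  filter on the comment when it mentions the remark — was rejected because
  glycan-only and polymer reactions are excluded unconditionally anyway,
  making the permissive reading the only self-consistent one.
* A **polymer** is detected structurally: any stoichiometric coefficient
  that is a symbolic expression in `n`/`m` (`n`, `(n+1)`, `2n`, …) rather
  than a number. Comments that merely announce polymerization (numeric
  coefficients) fall into the separate **possible_polymer** category, so
  the two exclusion modes stay individually countable.
* **Glycan handling.** Every glycan participant is translated through its
  "Same as" cross-reference when one exists. If the fully translated
  equation matches an existing all-compound reaction in the global
  reaction universe (either orientation — all reactions are reversible),
  that reaction substitutes for the glycan one and the verdict records the
  replacement. If translation is impossible and the reaction still has
  ordinary compounds, it is kept with an attention flag for the curator.
  Reactions consisting solely of glycans are omitted even without an
  alternative, as are translatable reactions whose translated compounds
  are themselves generic. The match is against the global universe, not
  the per-organism reaction sets, because the substitute is a property of
  the reaction database, not of any one genome.
* A compound is **generic (massless)** when every mass field — compound
  `EXACT_MASS`/`MOL_WEIGHT`, glycan `MASS` — is absent or 0. A glycan with
  only a positive `MASS` is *not* generic. The mass screen runs over the
  participants of the reactions that survived the reaction-level filters
  (for a replaced glycan reaction, over the translated participants), so
  the "compounds evaluated" denominator matches what the model would
  actually contain. Participants missing from the compound map are treated
  as massless — a conservative omission — and listed separately.
* Percentages in the accounting are **truncated** to two decimals; that is
  the convention the reference renderings follow (390/1626 → 23.98).

## Model construction choices

* All reactions are reversible with bounds ±1000 mmol·gDW⁻¹·h⁻¹ (the
  conventional "effectively unbounded" magnitude in constraint-based
  models); KEGG has no directionality annotation and assigning directions
  is downstream curation work.
* GPR rules are plain OR-joins of sorted gene IDs. No AND complexes are
  inferred — KEGG does not state how gene products interact.
* Single/consolidated models use compartment id `c`, label "cytosol";
  KEGG does not localize reactions. Community models use the organism code
  as compartment id and suffix `_<org>` on every metabolite and reaction
  ID (underscores keep SBML SIds valid); stripping the suffix recovers
  the single models exactly, which is property-tested.
* Gene IDs are stored verbatim (`org:locus`); the colon is replaced by an
  underscore only at SBML serialization, with verbatim forms kept in the
  notes.
* Ordering is deterministic everywhere (metabolites, reactions, GPR genes
  sorted lexicographically), so rebuilt models compare equal byte-for-byte
  in the JSON serialization.
* SBML export goes through cobrapy (L3V1 + fbc). A draft has no objective,
  and an empty flux objective is an fbc consistency error, so the empty
  objective list is stripped after writing; the files then validate with
  zero SBML errors. Reaction notes embed the attention text, gene list, EC
  numbers and source equation (XML-escaped — the `<=>` arrow is not valid
  XHTML text).

## Network statistics

All metrics operate on the bipartite metabolite–reaction graph (edge ⇔
nonzero S-matrix entry); this choice is stated explicitly because mean
degree and path length differ on the metabolite projection. Mean degree is
2|E|/(|M|+|R|); a coefficient of 2 still contributes one edge. Mean
shortest path averages geodesics over unordered same-component pairs,
excluding cross-component pairs, so it remains defined on the disconnected
graphs drafts typically are. The giant component is the component with the
most reactions (ties: more metabolites, then lexicographically smallest
member). A *blocked* metabolite occurs in exactly one reaction; a
*same-sign* metabolite occurs in exactly two reactions with equal-signed
entries — both are dead-end indicators meaningful only because drafts
carry no transport reactions.

## Synthetic source

The fixture generator emulates the KEGG structures the pipeline consumes:
flat-file reaction/compound/glycan records (including "Same as"
cross-references, symbolic polymer equations, trigger-string remarks and
massless compounds), per-organism gene→EC tables and the EC→reaction
table. Defaults: 3 organisms, 40 reactions, 30 compounds (15% massless),
1–4 genes per (organism, reaction), organism overlap probability 0.6, and
category fractions 10% generic-comment, 5% polymer, 5% possible-polymer,
5% pure-glycan, 10% glycan-with-alternative, 5% glycan-no-alternative, 5%
ill-defined, 10% massless — every filter branch is exercised with at least
two instances while clean reactions remain the plurality, roughly echoing
the real-data proportion of ~30% omissions. One seeded `numpy` generator
drives all randomness; identical seeds yield byte-identical directories.

What the fixture does **not** emulate: realistic degree distributions,
pathway topology, mass-balanced chemistry, or EC numbers shared between
reactions (each synthetic reaction gets its own EC, so gene multiplicity
per reaction is exact by construction). A green fixture test therefore
establishes the correctness of the bookkeeping and graph machinery, not
biological plausibility of any network, and real-KEGG runs depend on the
live database snapshot.

## Known limitations

* Genes are linked to reactions through direct gene→EC annotations; KEGG
  orthology (KO) is not used as an intermediate. Reactions annotated in
  KEGG only via KO would be missed in live runs.
* Headline counts from live KEGG depend on the database snapshot and are
  not reproducible offline; the test suite asserts worked examples,
  arithmetic identities and structural properties instead.
* No mass/charge re-balancing is attempted; KEGG's balance status is
  trusted.
* Partial EC numbers (trailing `-`) are kept and linked like full ECs;
  dropping them would silently shrink reactomes.
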