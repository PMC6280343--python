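# keggdraft

First-draft genome-scale metabolic reconstructions built from KEGG
annotation data alone.

Constraint-based metabolic modeling starts from a genome-scale network
reconstruction, and assembling one by hand is slow. `keggdraft` automates
the first step for any list of KEGG organism IDs (e.g. the five *E. coli*
K-12 strains `eco ecj ecd ebw ecok`): it pulls each organism's gene→EC and
EC→reaction links, composes them into the binary **Organisms–Reactions
(OR)** incidence matrix and its gene-bearing **Organisms–Reactions–Genes
(ORG)** extension, downloads the reaction and compound annotations for the
resulting reaction universe, filters out reactions a draft cannot safely
contain, and assembles three kinds of draft model:

* **consolidated** — one network holding the union of all query organisms'
  reactions, everything in a single cytosol compartment;
* **single** — one network per organism, obtained by restricting the
  consolidated model;
* **community** — the disjoint union of the single models with each
  organism in its own compartment (no transport reactions are invented, so
  compartments stay unconnected until the modeler adds them).

The tool is aimed at modelers who want a transparent, fully KEGG-traceable
starting point for manual curation — deliberately **without** biomass, ATP
maintenance, transport/exchange reactions or directionality assignment.
Because KEGG records no reaction directionality, every reaction is
reversible with symmetric bounds ±1000. Gene–protein–reaction rules are
pure OR-joins of the linked genes, since KEGG does not describe how gene
products interact.

## Filtering rules

Reactions are screened before assembly; every exclusion is recorded with a
category and a human-readable `rxnAttention` explanation:

| rule | trigger | outcome |
|---|---|---|
| generic comment | REMARK/COMMENT contains "Generic"/"General"/"General reaction" | omitted |
| polymer | symbolic `n`/`m` stoichiometric coefficients | omitted |
| possible polymer | comment announces polymerization | omitted |
| glycan, translatable | all `G#####` participants cross-reference `C#####` IDs and the all-compound twin reaction exists | twin reaction used instead |
| glycan, no alternative | glycans lack compound equivalents | kept, flagged for attention |
| pure glycan | every participant is a glycan | omitted |
| ill-defined | same compound on both equation sides | omitted |
| massless compound | a surviving reaction contains a compound whose every mass field is absent or 0 | omitted |

The omission report keeps per-category counts and renders the accounting
percentages (reaction-level filter share, generic-compound share, total
omitted share), truncated to two decimals.

## Worked example

```python
from pathlib import Path
from keggdraft.fixtures import FixtureSpec, generate_fixture
from keggdraft.kegg_io import KeggSource
from keggdraft.pipeline import RunConfig, run
from keggdraft.reporting import network_stats, omission_summary

manifest = generate_fixture(FixtureSpec(seed=1), Path("scratch/source"))
result = run(RunConfig(
    organisms=manifest["organisms"],
    flags={"consolidated", "single", "community", "omitted_data"},
    source=KeggSource(mode="local", root="scratch/source"),
    out_dir=Path("scratch/run"),
))
print(omission_summary(result.report))
stats = network_stats(result.consolidated)
print(stats.n_reactions, stats.n_metabolites, stats.giant_reaction_fraction)
```

prints

```
{'total_input': 44, 'reaction_filter_omitted': 12, 'remaining_after_reaction_filters': 32,
 'compounds_evaluated': 29, 'generic_compounds': 3, 'massless_reactions': 4,
 'total_omitted': 16, 'total_kept': 28, 'filter_percent': 27.27,
 'generic_compound_percent': 10.34, 'omitted_percent': 36.36,
 'category_counts': {'generic_comment': 4, 'glycan_only_omitted': 2, 'ill_defined': 2,
                     'massless_compound': 4, 'polymer': 2, 'possible_polymer': 2}}
24 26 100.0
```

— of 44 synthetic reactions, 12 fall to the reaction-level filters and 4
more contain massless (generic) compounds, leaving 28 kept verdicts that
assemble into a 24-reaction / 26-metabolite consolidated draft (glycan
reactions enter through their compound-ID twins, hence fewer model
reactions than kept verdicts) whose bipartite metabolite–reaction graph is
fully connected. The run directory contains schema-valid SBML L3+fbc files
for every requested model, a lossless JSON serialization, the ORG report
TSV, and the omitted-reaction bookkeeping (JSON + TSV).

The same pipeline runs from a shell:

```bash
keggdraft eco ecj --source rest --cache-dir cache --out run \
    --single-models --community --omitted-data --disconnected-reactions
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the seeded synthetic source, executes the complete pipeline
(matrices, filtering, all three model builds, SBML export, network
statistics), prints the run summary, and writes the results file.
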