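# crossfeed

Targeted ortholog-based functional annotation of microbial genomes and
prediction of synergistic species interactions.

## The problem

Microbial communities often perform an ecosystem process — e.g., the
degradation of an aromatic compound — through the *combined* genomic
potential of several species: no single member encodes every enzyme of
the pathway, but a consortium does. Full-genome annotation of every
member is expensive and most of it is irrelevant to the process under
study. `crossfeed` narrows the problem to a user-defined set of
reactions:

1. **Database construction.** From a list of KEGG-style identifiers
   (KO `K#####`, reaction `R#####`, or EC numbers), an
   ortholog–reaction association database (**ORAdb**) is assembled:
   per-KO reference protein sets, a reaction→KO map, and
   **gene–protein–reaction (GPR) rules** — boolean expressions where
   `AND` joins the subunits of a protein complex and `OR` joins
   isoenzymes or alternative complexes.
2. **Ortholog clustering.** Per-species protein FASTA files are
   grouped into ortholog clusters, either imported from an external
   orthogroup inference tool (`Orthogroups.tsv` format) or produced by
   the built-in single-linkage clusterer over reciprocal bit-score
   edges.
3. **Two-stage annotation and interaction prediction.** A *relaxed*
   search aligns 50% of each cluster's sequences (sampled
   deterministically) against every KO set and keeps KOs reaching
   E ≤ 10⁻³; a *restrictive* search aligns **all** sequences of the
   surviving clusters against the candidate KO sets and annotates a
   sequence when its best hit has E ≤ 10⁻⁹ and bit score > 50.
   Evaluating each reaction's GPR rule on each species' annotated KO
   set yields a binary species × reaction capability table, from
   which the engine reports *complete* species (able to run a pathway
   alone) and enumerates all species *combinations* whose joint
   capabilities cover the pathway, subject to user constraints
   (reaction subsets that must reside in one member, transporter
   requirements, combination size, pathway-completeness fraction).

Alignment statistics follow the Karlin–Altschul convention:
`bit = (λ·S − ln K)/ln 2` with gapped BLOSUM62 defaults
(λ = 0.267, K = 0.041, gap open 11, extend 1) and `E = m·n·2^(−bit)`
over the plain search-space product (no effective-length correction).

A synthetic-data module generates planted ground truth for validation:
protein families diverged from common ancestors, communities whose
proteomes encode a known capability table, and an in-silico
point-mutation simulator that substitutes DNA bases (never in the
first or last codon) and translates the longest surviving open
reading frame.

## Worked example

```python
from crossfeed import (
    parse_gpr, evaluate_gpr, reaction_capabilities, ORAdb,
    PathwayDef, ConstraintSet, enumerate_combinations,
)

# benzoyl-CoA reductase: a four-subunit complex OR a two-subunit one
rule = parse_gpr(
    "(K04112 AND K04113 AND K04114 AND K04115) OR (K19515 AND K19516)",
    reaction_id="R02451",
)
evaluate_gpr(rule, {"K19515", "K19516"})          # True
evaluate_gpr(rule, {"K04112", "K04113", "K04114"})  # False: complex incomplete

db = ORAdb(reaction_kos={"R02451": rule.kos(), "R01422": {"K04105"}},
           gpr={"R02451": rule})
species_kos = {
    "degraderA": {"K04105"},
    "degraderB": {"K19515", "K19516"},
    "generalist": {"K04105", "K19515", "K19516"},
}
table = reaction_capabilities(species_kos, db)
print(table.to_dataframe())

pathway = PathwayDef("anaerobic_entry", ("R01422", "R02451"))
result = enumerate_combinations(
    table, pathway, ConstraintSet(include_complete_in_combinations=False))
print("complete degraders:", result.complete_species)
for combo in result.combinations:
    print("combination:", combo.members, dict(combo.contributors))
```

Output:

```
            R01422  R02451
degraderA        1       0
degraderB        0       1
generalist       1       1
complete degraders: ['generalist']
combination: ('degraderA', 'degraderB') {'R01422': ('degraderA',), 'R02451': ('degraderB',)}
```

`generalist` satisfies both reactions alone and is reported
separately; `degraderA` + `degraderB` is the one two-member consortium
whose joint potential covers the pathway, with the per-reaction
attribution showing which member contributes which step.

## Command line

The same workflow is available as three subcommands:

```bash
crossfeed build-db --ids ids.txt --out oradb/ --fetcher offline:refs/
crossfeed cluster --proteomes proteomes/ --out clusters/
crossfeed annotate-and-predict \
    --db oradb/ --clusters clusters/Orthogroups.tsv \
    --proteomes proteomes/ --pathways pathways.tsv \
    --constraints constraints.tsv --out results/
```

`annotate-and-predict` writes `Species_KO_table.csv`,
`Reactions_mapped_to_species.csv`, an `interactions/` folder with the
complete species and covering combinations per pathway, a bipartite
species–reaction network (`network.json` + `network.html`), and a run
log recording every threshold and seed. Outputs are byte-identical
across reruns with the same inputs and seed. Pre-computed alignments
(12-column BLAST tabular) may replace the internal aligner via
`--hits`; pre-computed orthogroups via `cluster --engine import`.

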