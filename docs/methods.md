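# Methods

## Model and workflow

`crossfeed` treats an ecosystem process as a set of reactions, each
guarded by a gene–protein–reaction (GPR) rule: a boolean expression
over KEGG Orthology groups (KOs) in which `AND` joins the subunits of
a protein complex and `OR` joins isoenzymes or alternative complexes.
A species can perform a reaction exactly when its annotated KO set
satisfies the rule; rules contain no negation, so capability is
monotone in the KO set. Reactions with no explicit rule default to OR
over their associated KOs (one protein suffices); this fallback is
recorded in the database load report.

Annotation is cluster-based. Ortholog clusters (imported or computed)
are screened in two stages against the ortholog–reaction association
database (ORAdb):

* **Relaxed stage.** `ceil(0.5 × cluster size)` sequences (minimum
  one, uniform without replacement) are aligned against every KO
  reference set. A KO becomes a *candidate* for the cluster when any
  sampled sequence reaches E ≤ `relaxed_evalue` (default 10⁻³).
  Clusters without candidates are dropped and reported.
* **Restrictive stage.** Every sequence of a surviving cluster is
  aligned against each candidate KO's full reference set. The best
  reference per (sequence, KO) — highest bit score, ties broken to
  the lexicographically first reference id — supports an annotation
  when E ≤ `restrictive_evalue` (default 10⁻⁹) **and**
  bit > `min_bit_score` (default 50, strictly greater: a hit of
  exactly 50 bits is rejected). A sequence may carry several KO
  annotations; no best-KO collapse is applied.

Candidate granularity is the KO, not the reaction set: re-aligning a
cluster against every KO of a reaction when only one KO was hit would
add alignments without adding evidence.

Species-level KO sets are the union over the species' annotated
sequences; GPR evaluation then yields the binary species × reaction
capability table (rows and columns sorted lexicographically, so the
table and every file derived from it are deterministic).

## Alignment statistics

Local alignment is Smith–Waterman with affine gaps
(BLOSUM62, gap open 11, extend 1), computed by
`Bio.Align.PairwiseAligner`; the ambiguity code `X` is rescored to 0
against every residue. Raw scores are normalised with the standard
gapped Karlin–Altschul parameters (λ = 0.267, K = 0.041):
`bit = (λS − ln K)/ln 2`, `E = m·n·2^(−bit)`. Three deliberate
simplifications, acceptable because thresholds rather than absolute
agreement with BLAST drive the pipeline:

* the search space is plain `m·n` with no effective-length
  correction;
* one hit per (query, subject) — the maximal-scoring alignment, no
  HSP tiling;
* `n` is the total residue count of the ORAdb in **both** annotation
  stages. Using per-candidate reference subsets in the restrictive
  stage would shrink `n` and make the same alignment's E-value differ
  between stages; with a common `n`, a pair's E-value is
  stage-independent, and with full sampling the relaxed candidates
  are exactly the KOs the restrictive stage could confirm at the
  relaxed threshold.

Percent identity and alignment length come from one optimal
traceback (the aligner's canonical first), which is deterministic for
fixed inputs. E-value thresholds are inclusive (≤); the bit filter is
strict (>).

## Fallback clusterer

The built-in clusterer is single-linkage over reciprocal bit-score
edges: two sequences join when both alignment directions reach
`min_bit` (default 50); connected components of size ≥ 2 become
clusters, singletons are reported unassigned. It is a self-contained
approximation, **not** a re-implementation of normalised-score + MCL
orthogroup inference — notably it does not normalise scores by
sequence length, so severely truncated sequences sit closer to the
bit threshold than they would under a length-normalised scheme.
Faithful replication of an external tool's clustering is obtained by
importing its `Orthogroups.tsv`. Only clustered sequences are
annotated; unassigned singletons never reach the annotation stage.

## Interaction prediction

Given the capability table, a pathway (ordered reaction set) and a
constraint set, the engine reports species whose own row covers every
pathway reaction (*complete* species, always listed separately) and
enumerates all subsets of 2 … `max_combination_size` species whose
joint capabilities cover at least `completeness_fraction` of the
pathway (default 1.0) and satisfy every constraint:

* each *single-species subset* of reactions must be fully carried by
  at least one member alone (modelling steps whose intermediate is
  not exchanged);
* transporter modes: `off` (default — transporter semantics vary
  between study designs, so no check is imposed unless asked),
  `any_member`, `every_member`;
* complete species are included in combinations by default (they both
  count as consortia members and stand alone); a flag excludes them
  from the candidate pool.

All covering subsets are emitted, not only minimal covers: community
growth data are reported for arbitrary consortia, so supersets of a
cover are themselves valid predictions. Enumeration is bounded at 30
species (beyond that the subset space is no longer exhaustively
enumerable in reasonable time; constraints should shrink the pool
first). Output order — by size, then lexicographic — and all CSV/TSV
dialects (comma-separated, UTF-8, header row, species sorted) are
fixed so reruns are byte-identical.

Observed consortia are *explained* when they contain a complete
species or when the coverage-plus-constraints predicate holds on the
observed set itself.

## Evaluation metrics

Clustering quality uses pair semantics: precision is the fraction of
co-clustered unordered pairs with equal function labels; recall is
the fraction of all same-label pairs that are co-clustered.
Unassigned sequences contribute no clustered pairs but their
same-label pairs stay in the recall denominator. Zero denominators
raise an explicit error rather than returning 0 — a silent 0 would be
indistinguishable from a real worst case. Annotation performance is
the fraction of reference (sequence, KO) pairs recovered.

## Synthetic data

The fixture generator emulates a targeted-annotation study:

* **KO families**: one random ancestor (length 120 aa by default, a
  typical bacterial protein), members at an exact substitution
  count `round(divergence × length)`; reference sets use 3 members at
  5% divergence.
* **Communities**: each species carries, per planted reaction, the
  KOs of one satisfying rule branch; community members are diverged
  8% from the ancestor by default. Two structural guarantees keep the
  planted truth recoverable by a cluster-level annotator: a reaction
  carried at all is carried by ≥ 2 species, and all carriers of a
  reaction share the same branch — mirroring real study sets, where
  ortholog families recur across genomes (a family present in a
  single genome forms a singleton that cluster-level annotation
  cannot see). Decoy proteins (5 per species) are random sequences
  re-sampled until global edit-distance identity to every family
  member is < 30%.
* **Point mutations**: `max(1, round(rate × length))` DNA
  substitutions (half-up rounding, floor of one so every nonzero rate
  mutates something), drawn without replacement from the bases of
  codons 2…(n−1); the first and last codon are never touched. Each
  substituted base becomes one of the three other bases uniformly.
  The protein is the longest in-frame ORF: translation from position
  0 to the first stop, and from every in-frame ATG to the next stop;
  ties go to the earliest start. Only the original frame is scanned —
  substitution-only mutation cannot shift frames. Newly created stop
  codons therefore truncate the observed protein, which is the main
  way high mutation rates perturb downstream clustering.

What the fixtures do **not** model: indels, codon-usage bias,
selection, phylogenetic structure, paralogy, or uneven mutation
distribution across gene families. Passing the planted-recovery and
mutation benchmarks therefore demonstrates internal correctness of
the pipeline's algorithmic chain under idealised homology structure,
not annotation accuracy on real genomes, where reference databases
are incomplete and homology is confounded by domain shuffling.

## Benchmark problem sizes

The standard validation scenarios (`crossfeed.benchmarks`) are sized
so the whole suite runs in seconds on one CPU while still exercising
every code path: 100 random interaction instances of ≤ 12 species ×
≤ 8 reactions checked against exhaustive 2ⁿ subset scans (the scale
of typical isolate panels); a 3-cluster × 4-KO annotation fixture
checked against brute-force filtering; a 6-species / 8-reaction /
≤ 15-KO planted community for end-to-end recovery; and a mutation
benchmark of three stop-free genes of 800/550/550 codons — the
length scale of real bacterial catabolic genes — each mutated at
rates 0.01–0.25 with fixed seeds. At those lengths every mutated
variant retains a long, strongly aligning ORF (worst case in the
benchmark: 70% identity, 82 bits), so all variants co-cluster with
their sources at the default bit threshold; with much shorter genes
an early nonsense mutation can shrink the longest ORF below the edge
threshold, which is a real property of single-linkage clustering on
unnormalised scores (see the fallback-clusterer note above).

## Known limitations

* Internal E-values approximate, but do not reproduce, BLAST/DIAMOND
  statistics; imported tabular hits are taken at face value.
* The fallback clusterer is order-independent and deterministic but
  not a substitute for dedicated orthogroup inference on real
  proteomes.
* GPR rules support AND/OR only: no stoichiometry, directionality,
  compound graph, or KEGG-module shorthand (`+`, `,`) — a fetcher
  must pre-normalise module notation, and auto-derived rule tables
  should be manually curated.
* Interaction predictions are genomic-potential statements; they say
  nothing about expression, kinetics, or growth conditions.
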