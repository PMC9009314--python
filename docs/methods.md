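# Methods

This note documents the models and procedures implemented in
`phyloconcord`, the parameters that matter, the numerical conventions that
make every run reproducible, and the limits of what the synthetic-data
tests demonstrate.

## Inputs and quality control

Three data modalities are read from plain-text formats: a rooted cell
phylogeny (Newick), a site-by-cell SNV genotype matrix (TSV; calls
`REF`/`ALT`/`HET`/`NA`), and a normalized gene-by-cell expression matrix
(TSV or MatrixMarket with gene/cell index files). Trees without branch
lengths — typical of mutation-tree methods that output topology only —
receive unit lengths on every edge, so patristic distances degrade to
node-count distances and every downstream dissimilarity stays defined.

SNV filtering assumes a designated set of normal (non-cancerous) cells and
removes a site when (a) every normal call is missing, (b) the non-missing
normal calls disagree, (c) the normal consensus is `HET` or `ALT`
(potential germline heterozygosity), or (d) the fraction of non-missing
calls across **all** cells — normal cells included in the denominator — is
below a completeness cutoff (default 0.7; 0.6–0.7 are typical working
values for scRNA-seq SNVs). Cell filtering removes cells whose missing
fraction is **strictly** greater than the cutoff (default 0.5), so a cell
exactly at the boundary is retained. Both filters preserve input order and
are idempotent.

## Tree-shape classification (beta-splitting)

Aldous' beta-splitting model assigns an internal node subtending `n` tips
the split `(i, n−i)` with probability

    q_n(i; β) = w_n(i; β) / Σ_{j=1}^{n−1} w_n(j; β),
    w_n(i; β) = Γ(β+1+i) Γ(β+1+n−i) / (Γ(i+1) Γ(n−i+1)),   β > −2.

β = 0 is the Yule process, β = −1.5 the PDA model, β → −2 the caterpillar
limit. The log-likelihood is the sum of `log q` over internal nodes
(cherries contribute 0) and is evaluated in log space (`gammaln`,
`logsumexp`). The MLE is found by bounded 1-D optimization over
(−1.999, 10) with tolerance 1e-4 on β. The upper bound stands in for the
balanced asymptote — the likelihood is extremely flat there, and only the
sign of β̂ + 1.5 matters for classification. Trees with β̂ < −1.5 are
called *unbalanced*, otherwise *balanced* (a tie at the threshold is
balanced). Estimates within 1e-3 of a bound are flagged `at_bound`.
Polytomies are rejected rather than randomly resolved, keeping the
estimate deterministic; trees with fewer than 4 tips carry no balance
information and are rejected. Splits are stored with the smaller child
first; the likelihood is symmetric in `i ↔ n−i`, so the convention does
not affect the estimate (verified against a 0.01-step grid search).

## Ancestry annotation

A genetic ancestry is a tip set whose within-group genetic distances are
smaller than between-group distances. "Genetic dissimilarity" of a clade
is its mean pairwise patristic distance (0 for singletons) — defined for
both branch-length and topology-only trees via the unit-length fallback.

**Balanced strategy.** Over all pairs of disjoint clades (internal-node
tip sets) satisfying `|A|, |B| ≥ min_each_frac·N` (default 0.1) and
`|A|+|B| ≥ min_total_frac·N` (default 0.75), the pair minimizing
`diss(A)+diss(B)` is selected; further ancestries (up to `n_clades`,
default 3) are the largest clades disjoint from everything already chosen,
ties resolved by least dissimilarity then smallest preorder node ID.
Unselected cells are `unassigned`. Note a structural consequence of the
rule: since sub-clades never have larger dissimilarity, the first pair is
as small as the coverage constraint allows; with k near-equal true clades
the default `min_total_frac = 0.75` is infeasible for k = 3 equal thirds
(2/3 < 3/4), and 0.66 is the natural setting.

**Unbalanced strategy.** For ladder-like trees: iteratively select the
clade (including single tips) whose size is nearest to
`remaining cells / remaining groups`, ties by least dissimilarity then
node ID; remove it (the pruned tree re-forms clades from what is left) and
repeat; after `n_clades − 1` selections the remainder is the final
ancestry. Every cell is assigned.

Normal cells are excluded from clade candidacy in both strategies and kept
in the output with the label `normal`. Both procedures are fully
deterministic. An `auto` mode runs the tree-shape classifier first and
dispatches accordingly.

## Annotation agreement and consensus

Agreement between two annotations is computed on the contingency table of
their shared cells; cells labeled `normal` or `unassigned` are not genetic
ancestries and are excluded by default. Pearson's χ² (no Yates correction,
no simulation) with `dof = (r−1)(c−1)` gives Cramér's
`V = sqrt(χ² / (n·(min(r,c)−1)))`; V > 0.2 together with p < 0.01 marks a
pair *supported*. A warning is emitted when any expected count is below 5,
and another when any pair is unsupported, since trajectory analysis is
best run on concordant annotations.

For the consensus, every annotation's labels are aligned to the first
annotation by optimal one-to-one assignment (Hungarian algorithm on the
negated overlap counts); surplus labels keep uniquely suffixed names. Each
cell then takes the majority label among the annotations containing it;
voting ties give `unassigned`. The heatmap orders cells by consensus label
and shows one row per (aligned) annotation plus the consensus, with a
companion TSV of the plotted label matrix.

## Expression trajectory, states and concordance

Genes are first filtered (non-zero in ≥ 3 cells) and ranked by the
Kruskal–Wallis H statistic across ancestry groups (midrank ties, χ²
approximation; `normal`/`unassigned` cells excluded; groups need ≥ 3
cells). The ranking is vectorized over genes and is checked against
`scipy.stats.kruskal` per gene in the test suite. Rank-based testing is
distribution-free and deterministic, which suits its only role here:
ordering genes.

For a gene scale k, the top-k genes are z-scored per gene and the cells
projected onto `n_dims = 2` principal components via SVD with a fixed sign
convention (the largest-magnitude loading of each component is made
positive). A minimum spanning tree is built over pairwise Euclidean
distances with Kruskal's algorithm, equal-length edges ordered by the
lexicographic cell-ID pair, so the tree is unique. Pseudotime is the MST
path length from the designated root cell — a normal cell, whose
pseudotime is exactly 0.

**States** are the maximal paths of the MST delimited by the root, leaves
and branch vertices (degree ≥ 3); a branch vertex belongs to the path on
its root side. States smaller than `max(3, ⌈0.05·n⌉)` cells are merged
into their rootward neighbor (a small root-side state absorbs into its
earliest child path), which prevents MST noise from fragmenting into
singleton states. States are numbered 1..K by increasing mean pseudotime.
These states are *analogous to, not identical with*, the states a
model-based trajectory tool such as Monocle would call: in particular this
path decomposition typically splits one well-separated cell cluster into a
few states (each still pure in composition), where a principal-graph
method would often return one.

**Concordance.** With uniqueness threshold `u = 0.8` (strict inequality):

- `SCI(ancestry)` counts states whose composition is > u that ancestry.
  Normal cells are excluded from state composition for SCI (they would
  otherwise trivially own a state); unassigned cells are always excluded.
  SCI > 1 indicates the ancestry has diverged into several expression
  states. An alternative *ancestry-coverage* definition — states holding
  > u of the ancestry's cells — is exposed as
  `uniqueness_mode="ancestry-coverage"`; it measures dispersal of an
  ancestry rather than purity of states and is not the default because the
  path-state decomposition splits clusters, making coverage rarely exceed
  0.8 even for perfectly concordant data.
- `OCI` is the fraction of all states unique (at u) to any single label;
  here the normal cells' state counts in the denominator and may be unique
  to `normal`.

Both indices are invariant to state relabeling and cell order, and
non-increasing in u. The sweep repeats ranking restriction and trajectory
construction for scales 200–1,000 in steps of 100 (9 scales), per
annotation; scales exceeding the number of rankable genes are dropped with
a warning. Adding genes beyond those carrying ancestry-linked signal
dilutes concordance; with a weak 99-gene program (0.4 log-units) the mean
OCI at scales ≤ 400 exceeds that at scales ≥ 800, while strong programs
(≥ 2 log-units) survive dilution across the whole sweep.

## Synthetic data

The generator produces the regimes the pipeline must distinguish, from a
single seed (sub-streams for tree, genotypes, expression):

- **Tree**: 60 cells by default (3 normal, 3 ancestries of near-equal
  size). Balanced mode joins per-ancestry balanced subtrees; unbalanced
  mode is a caterpillar with the ancestries as consecutive segments.
  Within-ancestry branches are ~0.1 (jittered ±50%); ancestry-separating
  and normal-separating branches are 10, so true clades are separated by
  two orders of magnitude.
- **Genotypes**: 200 sites; each site's mutation lands on a tumor branch
  with probability proportional to length; a cell is `ALT` iff the
  mutation is on its root path. `ALT` flips to `REF` with probability 0.2
  (allelic dropout) and any call to missing with probability 0.4 —
  matching the heavy missingness of scRNA-seq variant calls. No `HET`
  calls are simulated.
- **Expression**: 1,200 genes, log-normal noise (σ = 0.5 in log space);
  120 signal genes split evenly into per-ancestry programs shifted by 3
  log-units; normal cells carry background only. `convergence_frac`
  regenerates that fraction of ancestry 2's cells from ancestry 1's
  program (recorded in the ground truth).

Presets: `concordant` (effect 3, no convergence), `convergent`
(convergence 0.5) and `null` (effect 0).

**What the simulations do and do not show.** The generator reproduces the
qualitative failure modes that motivate the method — missingness, dropout,
ancestry-linked programs, convergent cells — but not realistic scRNA-seq
counts: there is no library-size or UMI model, no dropout zeros in
expression, no doublets, no CNA dosage effects, and programs are disjoint
gene blocks rather than correlated modules. Passing the recovery tests
shows the algorithms are correct and well-calibrated under their stated
assumptions, not that real tumors are this easy. One consequence of the
disjoint-program design worth knowing: with partial convergence (e.g. half
of ancestry 2), the non-converged cells still express their own program
and retain at least one pure expression state, so composition-based SCI of
the converging ancestry stays ≥ 1; the convergence signal appears instead
as mixed ancestry-1/2 states and OCI < 1, which the tests assert.

## Numerical and design choices

- All tie-breaks are explicit (node IDs, lexicographic cell pairs, gene
  IDs), so every result is bit-reproducible for identical inputs.
- PCA signs are fixed by the largest-magnitude loading; zero-variance
  genes z-score to 0.
- The β search bounds (−1.999, 10) respect β > −2; estimates at the
  bounds are flagged rather than extrapolated.
- χ² p-values use the asymptotic distribution; small-count tables trigger
  a warning instead of switching to exact tests, keeping results
  deterministic.
- The consensus vote treats `normal` like any other label; a cell normal
  in every annotation stays normal.

## Known limitations

- The trajectory algorithm is deterministic by design and does not model
  branching expression dynamics beyond MST path structure; pseudotime is a
  tree distance, not a fitted latent time.
- Polytomies must be resolved upstream for tree-shape estimation (they are
  accepted everywhere else).
- The balanced annotator's first-pair rule prefers the smallest feasible
  clades; coverage constraints, not dissimilarity, are what force it to
  pick major clades. Choose `min_total_frac` with the expected number of
  clades in mind (see above).
- Problem sizes in the test suite and the acceptance script (60-cell
  datasets, 20–100 seeds per property, gene scales up to 1,000) were
  chosen to characterize behaviour at the scale of the single-cell
  datasets this method targets.
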