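# Methods

## Model and assumptions

The pipeline targets translational regulators: proteins that bind target
mRNAs and change protein output without changing transcript abundance. Its
central assumption is therefore that in a mutant of the query gene the
mRNA level of a *direct* target is unchanged, while genes further
downstream may move. Everything else is boolean annotation filtering over
curated extracts — no expression model is fitted and no edge weights are
inferred.

### Ratio classification

For gene *i*, R_i = y_i / x_i (mutant over wild type, RPKM scale). One
median M and one quartile deviation Q = (Q3 − Q1)/2 are computed over the
whole dataset's defined ratios — the subscripted notation sometimes used
for these quantities notwithstanding, they are global constants of the
comparison, not per-gene values. Classification uses strict inequalities
on the raw ratio scale:

* fluctuating: R_i < M − Q or M + Q < R_i
* stable: M − Q < R_i < M + Q

Two degenerate classes make the partition total: `boundary` (R_i exactly
equals a bound — strictness means neither condition holds, and silently
dropping such genes would break the bookkeeping) and `undefined`
(x_i = 0, where the ratio does not exist). Undefined ratios are excluded
from the M/Q estimation. An optional pseudocount ε added to both levels
(default off, i.e. 0.0) makes every ratio defined for users who prefer
that convention. Bounds are reported both on the ratio scale and as log2
values, the scale on which fluctuation windows are conventionally quoted;
a non-positive lower bound maps to −∞ in log2.

Quartiles use linear interpolation between order statistics
(`numpy.percentile` default), the common inclusive convention; the method
is switchable (`lower`, `higher`, `nearest`, `midpoint`) because the
convention materially changes class counts near the bounds. At least 4
defined ratios are required, below which quartiles are not meaningful.

### Direct-target criteria

A candidate direct target must be (1) stable, (2) in the supplied
transcription-factor list, (3) annotated with at least one life-stage
term shared with the query, and (4) annotated with at least
`min_phenotype_overlap` phenotype terms shared with the query (default 1
— the timing and phenotype data are categorical terms, so set
intersection is the natural similarity; a graded score would
over-interpret them). The query gene is never its own target. A query
without stage annotation is an error, since criterion 3 cannot be
evaluated. `find_direct_targets` accepts a `skip_criteria` set purely for
ablation studies.

### Cascade expansion

From each direct target, a breadth-first fixpoint collects downstream
genes: from every accepted gene, the targets of outgoing regulatory edges
and the partners of genetic/physical edges (undirected — protein-protein
interactions carry no orientation) are candidates, and a candidate is
accepted iff its stage terms intersect `allowed_stages` (default
`{"early embryo", "embryo"}`, a configurable vocabulary). The visited set
guarantees termination on cyclic graphs. All interaction edges between
accepted nodes are retained, including cycle-closing ones, so the
exported graph is the full induced subgraph. Only the stage filter is
applied downstream; the TF/phenotype criteria are direct-target criteria,
not traversal criteria. Each node carries a tier: `early_embryo` when the
"early embryo" term is present, otherwise `embryo` (the presumptive
early-embryonic tier).

Bottom genes are nodes with zero *regulatory* out-degree inside the
cascade — genetic/physical edges carry no downstream meaning. If a
cascade is one big regulatory cycle, no node qualifies; the nodes of the
terminal strongly-connected components (networkx condensation) are used
as the natural generalisation.

### Domain enrichment and category scores

For a cascade's bottom genes, each domain present among them is scored
with the binomial upper tail P(X ≥ k), X ~ Binomial(n, p0), where n is
the number of annotated bottom genes, k of them carry the domain, and
p0 = K/N_bg is the domain's frequency among annotated background genes —
the classic over-representation test popularised by PANTHER's GO
analysis. Fisher's exact test (hypergeometric) is a config alternative
for users who prefer sampling without replacement. The background is all
genes of the input expression table carrying at least one domain
annotation: the measured universe, the least arbitrary choice given that
no background is prescribed. Significance is p < α with α = 0.05 by
default and no multiple-testing correction (an optional consideration for
the user; the upstream procedure applies none).

Category scores: significant domains map to functional categories via the
supplied domain→category table; a category's score is the number of
distinct bottom genes hit by its significant domains; unmapped domains
tally under "Unknown" and categories below an integer reporting threshold
(default 1) fold into "Others". Output follows a fixed canonical order
(Transcription, Signal transduction, Development, Cell cycle, Cell
division, DNA replication, Transport, then other categories
alphabetically, then Others, Unknown).

Cascades whose significant bottom-gene domains include a user-supplied
transcription-related accession can be discarded (such a cascade would
act only after the early-embryo stage). The filter defaults to on but
only acts when an accession list is supplied — no hard-coded list exists,
and category scoring runs on the pre-filter cascade set by default, since
the interplay between this filter and the category table is a genuinely
open design point.

## Synthetic data generator

`gcfinder.fixtures` emulates the tool's input boundary — an RPKM table
plus WormBase/Pfam-style extracts — with planted truth:

* background log2 ratios ~ Normal(0, `stable_noise_sd`=0.5), i.e. a
  log-normal, realistically skewed ratio distribution; a fraction
  (`frac_fluctuating`=0.2) displaced by ±`fluct_shift`=3.0 log2 units
  plants unambiguous fluctuation; wild-type levels are log-normal around
  e³ RPKM;
* planted targets get ratio exactly 1 (well inside M ± Q for any sane
  noise level), TF status, and the query's stage and phenotype terms;
* one decoy per criterion violates exactly that criterion, making the
  filter ablation testable;
* each target roots a uniform regulatory tree (depth 4, branching 2 by
  default → 30 downstream genes) over embryo-annotated genes; cascades
  are node-disjoint, distractor edges lead from leaves to non-embryonic
  genes (the stage filter must drop them), and extra TFs needed to meet
  `frac_tf`=0.15 are drawn from non-embryonic genes so they can never
  satisfy the stage criterion;
* bottom genes carry a signal domain that is rare in the background, so
  enrichment has a planted positive; ~80% of genes carry 1–3 domains from
  a 30-accession pool mapped onto the canonical categories (every fifth
  accession deliberately unmapped).

Defaults (200 genes, 3 targets, depth 4) are the standard test condition;
they keep the full pipeline and its oracles inside seconds while leaving
every class (stable/fluctuating, embryonic/not, mapped/unmapped)
populated. What the generator does **not** emulate: count noise and
library-size effects behind RPKM values, correlated annotation errors,
hub-dominated interaction topology, and overlapping cascades. Passing the
planted-recovery tests therefore demonstrates algorithmic correctness of
the filters and traversal, not robustness of the biology on real
WormBase-scale data.

## Numerical choices

* Quartile oracle agreement is asserted to 1e-12; binomial tails are
  clamped into (0, 1] against round-off at the extremes and match
  exhaustive summation to 1e-12 for n ≤ 25.
* Determinism everywhere: lexicographic ordering of targets, nodes, edges
  and output rows; cascade ids `C<k>_<root>` follow target order; floats
  are serialised with `repr` (shortest round-trip form), so re-runs are
  byte-identical and written tables read back exactly.
* The boundary class makes ties explicit rather than resolving them; with
  continuous data it is almost always empty.

## Known limitations

* RPKM ratio thresholding is deliberately simple; count-based models
  (DESeq2/edgeR) are out of scope at this input boundary.
* The traversal is a boolean filter cascade — no edge confidence, no
  probabilistic scoring.
* Published full-scale results depend on specific WormBase/UniProt
  snapshots and on supplementary RPKM tables that are not
  redistributable; the test asserting them runs only when the user
  supplies those tables (see tests/test_acceptance.py), and otherwise
  reports their absence.
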