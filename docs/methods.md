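# Methods

## Problem and model

Untargeted, high-resolution MS metabolomics detects thousands of mass
features below ~1 500 Da, a range that overlaps the low-molecular-weight
peptidome but is poorly covered by peptide databases. `pepnet` annotates
such features database-free: a neutral mass M is decomposed into every
multiset of amino acids (a *composition*, e.g. `A2P2`) whose condensed
mass matches within an absolute tolerance t,

    mass(n_1..n_k) = Σ_i n_i·m_i − (N − 1)·w,   N = Σ_i n_i,

where m_i are free-molecule monoisotopic masses and w the condensation
loss (one water per peptide bond, 18.010565 Da). This is a real-valued
Money Changing Problem. Peaks are classified by their number of
solutions: exactly one (UAAC), several (MAAP), or none.

The *peptide degradation network* (PDN) is then the directed acyclic
graph over UAAC peaks with an edge u→v whenever u's composition strictly
contains v's; the label is the multiset difference ΔAA (the residues
lost). Co-occurring nested compositions are read as snapshots of
stepwise peptide hydrolysis, so edge labels are candidate peptidase
reactions and high in-degree nodes are shared "common patterns" of many
longer peptides.

### Assumptions

- Input masses carry no adducts; ionized inputs differ from neutral by
  exactly one proton (±1.0072765 Da; electron mass neglected beyond this
  constant).
- Compositions, not sequences: residue order is never inferred.
- Intensities are non-negative; missing cells mean absence (0), the
  usual convention for direct-infusion peak matrices.
- Peak identity is the ID, not the composition: isomeric features (same
  mass, different retention time) are distinct nodes, and equal
  compositions never connect (their ΔAA is empty).

## Alphabets

The default alphabet holds 19 subunits: the 20 proteinogenic amino
acids with Leu/Ile merged under `L` (identical elemental formula).
Masses are computed from molecular formulas with IUPAC monoisotopic
atomic masses (C 12, H 1.0078250319, N 14.0030740052, O 15.9949146221,
S 31.97207069) and stored to six decimals. For monomer-level analyses a
17-subunit variant drops Gln and Asn: at monoisotopic precision
Q = G+A and N = G+G once condensed, so retaining them makes every mass
containing those formula sums ambiguous by construction. Custom
alphabets (non-standard residues, modifications, other polymer classes)
load from a two-column file whose first line is the condensation loss;
a loss of 0 models non-condensing monomers.

## Decomposition algorithm

Decomposition works in residue space: with residue masses
r_i = m_i − w and target T = M − w the condition becomes
|Σ n_i r_i − T| ≤ t. The solver splits the alphabet into two halves
(alternating along descending residue mass, to balance sizes),
enumerates every residue combination of each half up to a ceiling
once per alphabet, sorts one half's sums, and answers a query by a
vectorized binary search for complements of the other half's sums
(meet in the middle). Each candidate is then re-checked against the
exact condensed-mass formula, so a ~1e-9 guard band absorbs float
accumulation in the tables without admitting false positives. This is
exact for real-valued masses — no integer scaling, no precision blur —
and answers sub-millisecond queries below 1 600 Da after a one-off
table build (a few seconds, a few hundred MB at the extreme ceiling;
tables grow lazily with the largest query seen). A hard row cap fails
loudly for alphabets/ceilings whose combinatorics would exhaust memory.

Numerical choices: the tolerance is a symmetric absolute window in Da
applied to the neutral mass (0 is valid for theoretical masses);
reported ppm errors are absolute values; results are ordered by length,
then expanded-symbol lexicographic order (count vectors over the
alphabet order), so output files are byte-stable; the zero-length
composition is never reported. Correctness is established in the test
suite against an independent exhaustive-enumeration oracle on random
alphabets and by planted-composition round trips.

## Network construction and simplification

The builder walks UAAC annotations in descending mass order and tests
every ordered pair for a strictly positive ΔAA — O(n²) exact search,
acyclic by construction since edges strictly decrease mass. Four
composable simplifications:

1. *remove_isolated* — drop degree-0 nodes.
2. *triangle_reduce* — delete every edge u→w for which some v has u→v
   and v→w **in the input graph**; detection against the input edge set
   and one simultaneous deletion pass make the result order-independent.
   For containment DAGs this single pass already equals the transitive
   reduction (any shortcut closes a triangle with a covering relation),
   and it provably preserves reachability on arbitrary DAGs.
3. *drop_free_amino_acids* — remove length-1 nodes, which connect to
   nearly everything and drown the topology.
4. *correlation_filter* — keep edges whose endpoint intensity profiles
   have Spearman ρ ≥ threshold (inclusive; 0.8 is the conventional
   evidence level). Undefined correlations (fewer than 3 paired
   samples, constant profiles) fail the filter by default — the filter
   demands evidence and an uncomputable ρ provides none — with a
   `keep_undefined` escape hatch.

Edge correlations use Spearman's ρ with average ranks for ties,
pairwise deletion of missing values, and NaN (flagged, not raised) for
undefined cases.

## Topological statistics

- **Zipf/power-law fits**: OLS on (log10 rank, log10 value) for the
  degree and edge-label frequency distributions — the Zipf-plot
  regression, matching how such networks are conventionally displayed,
  not a maximum-likelihood tail estimator. Zero-degree nodes are
  excluded (rank only over positive degrees); fewer than 3 positive
  values yields an explicit undefined-fit flag.
- **Long paths**: maximal directed simple paths with ≥ 3 edges, where
  maximal means the first node has no predecessor and the last no
  successor (so sub-paths are suppressed); the distinct start vertices
  are reported separately because degradation cascades tend to share a
  few initiating peptides.
- **Correlation densities**: ρ vectors for (a) random peak pairs,
  (b) random UAAC pairs, (c) PDN edges — unordered pairs sampled
  without replacement, seed-reproducible, defaulting to the edge count
  so the three densities are size-matched.
- **Gaussian mixtures**: 1- or 2-component EM, hand-rolled so the
  contract is explicit: fixed initialisation for k = 2 at means
  (0, 0.8), σ (0.2, 0.2), equal weights — the bimodal structure typical
  of edge-correlation densities — making fits deterministic without
  restarts (a seed governs optional random restarts only); convergence
  when the log-likelihood gain drops below 1e-8 or after 500
  iterations; σ floored at 1e-3 against degenerate spikes; the full
  log-likelihood trace is returned and is non-decreasing by
  construction (asserted in tests); means reported ascending.

## Phenotype screen

Samples belong to groups (strains) with ordinal phenotype scores.
A feature is *discriminant* when (i) Spearman ρ between its
group-averaged intensity and the group scores is ≥ 0.4 — one-sided by
default (positive trackers), with an absolute-value option — and
(ii) Kruskal–Wallis across the phenotype *levels*, pooling all
replicates without averaging, gives p < 0.1. The KW groups are the
score levels, not the strains; tie correction is applied and p comes
from the χ² approximation. No multiple-testing correction gates the
flag (the thresholds are deliberately permissive screens); a
Benjamini–Hochberg column is emitted for information. Undefined ρ
(constant group means) makes a feature non-discriminant and is flagged.
Flags project onto the PDN as node attributes, and per-hub ego-graph
enrichment (flagged/total) summarizes network regions associated with
the phenotype.

## Synthetic data generator

The generator emulates a direct-infusion fermentation metabolomics
study: 45 samples (15 groups × 3 replicates, scores cycling 5…1 over
five levels), compositions of length 1–7 over the 17-AA alphabet,
working tolerance 1e-4 Da with Gaussian mass noise of 2e-5 Da
(sub-0.1-ppm, FT-ICR-like). It plants:

- *degradation chains* (default 4 chains × 4 nodes): nested
  composition series losing one residue per step, rejection-sampled so
  every member is uniquely decomposable at the working tolerance —
  necessary because CH2-transfer identities (e.g. A+D = G+E
  elementally) make many random compositions ambiguous, and ambiguous
  peaks cannot be PDN nodes;
- *standalone peptides* (default 40): random compositions, UAAC or
  MAAP as chance dictates;
- *decoys* (default 20): masses rejection-sampled uniformly on
  150–900 Da until no decomposition exists at the working tolerance,
  guaranteeing the NONE class (an error is raised if 10⁵ attempts fail,
  which signals a tolerance too wide to leave gaps).

Intensities are log-normal around latent per-chain signals: chain
members load on a shared standard-normal latent with loading
a = √(2·sin(π·ρ_target/6)), the bivariate-normal map from a target
Spearman correlation; unrelated peaks load on an independent background
latent (default target 0). The chain target is 0.9: planted edges must
sit clearly above the ρ ≥ 0.8 evidence filter, because a latent
correlation equal to the threshold would scatter half the realized
sample correlations (SD ≈ 0.03–0.05 at n = 45) below it and no
generator could then be recovered reliably. Observed edge correlations
consequently spread around ~0.87 at n = 45, consistent with a strong
co-degradation mode near 0.8–0.9.

The phenotype simulator reuses the peptidome, spikes 25 % of planted
peptide features with a log-intensity shift of `effect_size` (default
1.5) per standardized score unit, and writes the design table.

### What the generator does not emulate

No isotope patterns, adducts, charge states > 1, chromatographic
artefacts, batch effects, censored (missing-not-at-random) intensities,
or realistic composition frequencies. Passing the end-to-end tests
therefore shows the pipeline's correctness and statistical behaviour
under clean, known-truth conditions — not annotation accuracy on real
instruments, which depends on mass accuracy and on how densely the
composition space is populated at a given tolerance.

## Problem sizes and defaults

Library defaults: tolerance user-specified (compulsory), correlation
filter 0.8, screen thresholds ρ ≥ 0.4 and p < 0.1, edge-frequency
report top-20, long paths ≥ 3 edges. The test and acceptance suites use
the generator defaults above (76 peaks, 45 samples), 1 000-case oracle
and round-trip sweeps up to ~1 500 Da, and dominance/reachability
oracles on graphs of 100–200 nodes; the full suite runs in well under a
minute on one core.

## Known limitations

- MAAP peaks are discarded before network construction; a
  probabilistic treatment of ambiguous annotations is out of scope.
- The O(n²) pair search is exact but quadratic; ~10⁴ UAAC nodes is a
  practical ceiling.
- The power-law analysis fits, it does not test: no model comparison
  against alternatives is attempted.
- Decomposition above ~1 600 Da is supported but warned against —
  ambiguity grows combinatorially and table memory with it.
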