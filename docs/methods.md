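# Methods

## The decomposition

Phylogenetic beta diversity (PBD) between two communities *j* and *k* is
measured on the branch lengths of a rooted regional phylogeny *T*. Writing

- *a* — total length of branches on root-to-tip paths of **both**
  communities,
- *b* — length unique to *j*,
- *c* — length unique to *k*,

the two classical indices are the Sørensen and Jaccard forms of this
partition:

```
PhyloSor = (b + c) / (2a + b + c)        UniFrac = (b + c) / (a + b + c)
```

PhyloSor's denominator is PD(j) + PD(k), i.e. it double-weights the shared
branch length; UniFrac relates the unique branch length to the total
branch length spanning both communities. Both range over [0, 1] and, for
the same partition, PhyloSor ≤ UniFrac.

Each index is split additively into a *true turnover* term that ignores
phylogenetic-diversity (PD) differences and a *PD-difference* term, by the
same algebra used to split compositional dissimilarity into turnover and
nestedness. With *m* = min(*b*, *c*):

```
PhyloSor_Turn = m / (a + m)              UniFrac_Turn = 2m / (a + 2m)
PhyloSor_PD   = PhyloSor − PhyloSor_Turn UniFrac_PD   = UniFrac − UniFrac_Turn
```

Applied to species counts instead of branch lengths these are exactly the
Baselga partitions β_sor = β_sim + β_sne and β_jac = β_jtu + β_jne; the
package exposes both through one code path.

## Branch partition and the PD convention

The partition is computed through Faith's PD via the identities
`a = PD(j) + PD(k) − PD(j∪k)`, `b = PD(j∪k) − PD(k)`,
`c = PD(j∪k) − PD(j)`, which coincide with classifying every edge by
whether it lies on a root-to-tip path of each community. PD is
**root-inclusive**: a community's branch set includes basal/stem edges up
to the root. This is the convention under which two communities occupying
the two basal clades of a balanced eight-tip unit-length tree each have
PD = 7 and share nothing (PhyloSor = 1); a root-exclusive convention would
not reproduce those reference values. The test suite checks the PD-identity
route against a brute-force per-edge classification on thousands of random
trees.

`RootedPhylogeny` pre-indexes an edge × tip boolean incidence matrix at
construction, so PD and partition queries are vectorised mask operations;
this is what makes the 10 000-pair simulation study and the shuffle-heavy
null model cheap.

## Numerical choices

- The second component is always obtained by subtraction
  (`total − turnover`), so additivity holds to machine precision by
  construction; the closed forms of the nestedness components are used as
  independent oracles in tests, not as the implementation.
- Index formulas are evaluated on the sorted pair `(min(b,c), max(b,c))`,
  making every result bitwise symmetric under swapping the communities.
- Turnover is a function of `(a, min(b,c))` only and is never adjusted;
  at an exact tie `b == c` the total is snapped to the turnover value
  (they are analytically equal) so the PD component of a tie is exactly 0,
  and otherwise `total` is clamped to `max(total, turnover)` to keep the
  analytic bound `turnover ≤ total` under floating-point rounding. These
  adjustments change values by at most one ulp.
- An all-zero partition raises an undefined-index error in the single-pair
  API; the pairwise drivers instead emit NaN rows for empty communities
  with a logged warning, so one bad site does not abort a whole matrix.
- Zero-length edges are legal and contribute nothing; missing branch
  lengths in newick are an error unless `missing_length_as_zero=True` is
  passed explicitly.
- Abundance tables are collapsed to incidence (any value > 0 is presence)
  with a logged notice; all indices here are incidence-based.

## Null model and standardized effect size

The null model shuffles species labels uniformly across the tips of the
regional tree while leaving the community table untouched. Per-site
richness and every compositional index are therefore conserved *exactly*
(the test suite asserts this bit-exactly across 999 shuffles), and the null
distribution answers: is the observed PBD higher or lower than expected
given the compositional dissimilarity? For each pair × family × component:

```
SES = (X_obs − mean(X_null)) / sd(X_null)
```

with the **sample** (n−1) standard deviation — the usual convention in
community phylogenetics; the convention is recorded in the output so the
population-sd alternative remains auditable. The observed value is not
appended to the null vector. |SES| > 1.96 is reported as a significance
flag alongside the raw SES. When the null distribution is constant (e.g.
any community pair on an equal-branch-length star tree, where the label
permutation is a symmetry) the SES is undefined and reported as NaN with
both flags false; constancy is detected by comparing extremes rather than
thresholding the standard deviation, because the floating-point standard
deviation of a constant vector need not be exactly zero.

The production default is 9 999 randomizations; tests and examples use
49–999 for speed. All randomness flows from an explicit integer seed
through `numpy.random.default_rng`; outputs are reproducible across runs
and platforms.

## Simulators

`yule_tree` implements the pure-birth process (two initial lineages, a
uniformly chosen lineage splits at each event, exponential waiting times
with total rate equal to the lineage count), yielding an ultrametric tree.
`pda_tree` draws uniformly over labelled rooted binary topologies by
attaching each new tip to an insertion point chosen uniformly among the
existing branches plus a new-root position ((2n−3)!! topologies, verified
by enumeration at n = 3 and 4 in tests). Yule trees are more balanced than
PDA trees on average (checked via Colless imbalance).

Neither model prescribes branch lengths; the defaults are each model's
natural construction — waiting-time (ultrametric) lengths for Yule, unit
lengths for PDA — and both can be overridden (`unit` / `exponential`).
The compositional/phylogenetic correlation levels of the simulation study
are somewhat sensitive to this choice, which is why the study's checks use
a tolerance band rather than a point value.

The community-pair simulator draws *a*, *b*, *c* independently and
uniformly on [1, 100] from a pool of 100 species and redraws the whole
triple until *a* + *b* + *c* ≤ pool size, so the pair is realisable with
distinct species; marginals stay uniform conditional on feasibility. The
study driver (`run_simulation_study`) generates **one** regional Yule tree
and **one** regional PDA tree per study, scores 10 000 pairs (default)
with all six compositional and six phylogenetic quantities on both trees,
and summarises Pearson correlations between matched indices and between
tree models. At these defaults the study takes a few seconds on one CPU.

What the simulation does *not* emulate: spatial autocorrelation,
abundance structure, phylogenetic signal in community assembly (species
are assigned to communities independently of their tree position), or
non-ultrametric empirical trees. Passing the study's checks therefore
validates the algebra and the index implementations under neutral
assembly, not ecological realism.

## Fixtures

`build_fixture` reconstructs the archetypal examples programmatically:

- `fig1a` / `fig1b`: a fully balanced eight-tip tree, all branch lengths 1
  (total 14). `fig1a` pairs the two basal clades (PD 7 each, partition
  (0,7,7), PhyloSor 1 — pure turnover between clustered communities);
  `fig1b` interleaves one tip per cherry (PD 10 each, partition (6,4,4),
  PhyloSor 0.4 — overdispersed communities sharing most branches).
- `fig2_toy`: a ten-species unit-length tree with six communities A–F.
  A–B…A–F form a series with constant turnover (0.166/0.286) and growing
  PD component; B–C…B–F are fully nested pairs (turnover exactly 0). The
  usual narrative for this example has all six communities
  sharing two species, but that is algebraically inconsistent with the
  reference partition (a,b,c) = (5,1,1) for the first pair (a community containing
  both shared species would leave the two-species community with no unique
  branch); the fixture here (A = {s1,s2}, B = {s2,s3}, C–F nested
  supersets of B) reproduces every reference partition and index value
  exactly, which is the property the fixture exists to pin down.

## Known limitations

- Pairwise only: multi-site generalisations, abundance-weighted UniFrac
  and nearest-taxon metrics are out of scope.
- Trees are used as given: no rerooting, dating or polytomy resolution; a
  basal multifurcation is accepted as a rooted tree with a logged warning.
- The null model is the richness- and CBD-preserving tip shuffle only;
  randomizations that perturb the table (and hence CBD) are deliberately
  not provided.
- The pairwise drivers materialise all site pairs in long format; for very
  large site counts (thousands) memory grows quadratically.
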