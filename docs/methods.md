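# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs. Coordinates are 1-based inclusive
throughout; sequences are stored as DNA (U folded to T on input) and read
as RNA wherever base pairing is evaluated.

## Polymorphism with IUPAC semantics

A direct Sanger read of a multi-copy rDNA template superimposes all copies,
so intragenomic variation surfaces as IUPAC ambiguity codes. The package
therefore defines a column as polymorphic when the **union of expanded
states** across the selected sequences contains two or more bases — a
single `Y` in one sequence suffices. Gaps and `N` are excluded from state
unions, and columns varying only by gaps are not polymorphic: the counts
are nucleotide polymorphisms, not alignment artifacts. Sites are reported
in both full-template and region-local coordinates, because ITS literature
mixes the two numbering schemes.

**Consensus calling** (`call_consensus`) emulates direct sequencing: per
column, every base reaching the `minor_threshold` frequency (default 0.25,
the smallest secondary peak a Sanger trace is typically scored at) enters
the minimal covering IUPAC code; rarer variants vanish. By construction the
consensus can only under-report the copy pool's polymorphism, which is the
phenomenon that makes cloning informative.

**Additivity classes.** At a polymorphic site with maternal state set M,
paternal set P and hybrid set H:

- *additive_combination*: H contains at least one maternal-specific
  (M − P) and one paternal-specific (P − M) state;
- *parental_shared*: H repeats a polymorphism already present within one
  parent (H = M or H = P, |H| ≥ 2), or lies entirely inside the parents'
  shared states;
- *maternal_only* / *paternal_only*: H ⊆ one parent exclusively;
- *novel*: H carries a state absent from both parents.

The checks run in the order novel → additive → shared → single-parent, so
every informative site maps to exactly one class.

**Regions.** ITS1/5.8S/ITS2 spans are passed through verbatim when given
explicitly; otherwise the 5.8S is anchored by locating its first (M1) and
last (M3) conserved blocks IUPAC-aware with a configurable mismatch budget,
ITS1 being everything upstream and ITS2 everything downstream.

**GC content** counts G, C and S fully and other ambiguity codes at their
expected GC fraction (R → 0.5); gaps and N leave the denominator. GC is
therefore invariant to gap insertion.

## Distances, ribotypes and networks

All distances use **pairwise gap deletion** (the MEGA default) and handle
ambiguities "as average": a column contributes the expected mismatch over
the joint expansion of its two characters, `1 − |S_a ∩ S_b| / (|S_a||S_b|)`.
K2P uses expected transition (P) and transversion (Q) fractions computed
the same way, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; a non-positive log argument
is reported as saturation, never stored as infinity. Group identities are
1 − mean p-distance over all qualifying pairs, unweighted, rounded half-up
to 3 decimals when reported (the convention of the identity tables this
output mirrors).

**Ribotypes** are exact-identity classes of aligned sequences. By default
`N` matches nothing (a cloned sequence with an undetermined base is its own
type unless literally identical to another); a permissive mode merges
compatible sequences greedily instead.

**Statistical parsimony.** The connection limit is the largest step count
j whose probability of being non-homoplastic still reaches the chosen
level (95% by convention). We model homoplasy as multiple hits: j changes
placed uniformly over L sites are all parsimony-interpretable when they hit
j distinct sites, so

&nbsp;&nbsp;&nbsp;&nbsp;P(j) = ∏_{i=1}^{j−1} (1 − i/L),&nbsp;&nbsp;limit = max { j : P(j) ≥ 0.95 }.

For L = 501 and 95% this gives 7 steps; the limit grows roughly with √L.
This finite-sites/uniform-rate form is the defensible core of the
published connection-limit machinery without its coalescent-estimated
nuisance quantities; the test suite pins it against an independent
exact-rational recursion. The network itself is built agglomeratively:
ribotype pairs join in ascending step order, an edge is accepted only when
its endpoints are not already connected through strictly shorter steps
(ties at one level join simultaneously), multi-step edges materialize
unlabeled intermediate nodes, and components further apart than the limit
stay disconnected. For small inputs this provably equals the
from-definition minimum spanning network, which the package also ships as
a cross-check.

**NeighborNet.** The circular ordering uses the two-stage
neighbor-joining-style agglomeration over clusters of one or two linked
nodes: cluster pairs are chosen by the Q-criterion on cluster-averaged
distances, the node pair within them by the same criterion with the chosen
clusters' nodes treated as temporary singletons, and the resulting
three-node path is contracted with the (2/3, 1/3) distance reduction
(four-node paths contract twice). Reversing the contractions yields the
circular taxon ordering. Split weights are fitted by non-negative least
squares over all n(n−1)/2 splits of the circular ordering against the
observed distances; weights below 1e-6 are dropped (SplitsTree behaviour —
it suppresses numerically void splits). On additive tree metrics this
reproduces exactly the tree's splits and branch lengths, which the test
suite verifies to 1e-6 on random 4–8-taxon trees. Bootstrap supports
resample alignment columns with replacement and report the fraction of
replicates whose network contains the same bipartition; supports are
computed on splits (not on a companion NJ tree).

## Secondary-structure QC

The bond set on the transcript is {A-U, G-C, G-U}; G·U wobble counts as a
bond by default (switchable off) because hemi-CBCs of the G-C → G-U type
are the canonical example of bond-preserving single-strand changes. A
substitution at a paired site is evaluated once from the pair's
perspective: CBC when both partners change and the new pair still bonds,
hemi-CBC when one changes and the bond holds, non-compensatory when the
new pair falls outside the bond set; unpaired positions class as
`unpaired`. When one site shows several observed states it contributes a
single class — the maximal-severity one, ordered CBC > non-compensatory >
hCBC > unpaired — so per-region counts partition the site list. (Tie
handling at multi-state sites is a package convention; tabulations in the
literature do not state one.)

**Motifs.** The ITS1 angiosperm motif `GGCRY(4–7n)GYGYCAAGGAA` is scanned
over all spacer lengths 4–7, keeping the best window; matching is
IUPAC-aware (pattern `R` accepts A or G; an observed ambiguity passes when
its expansion is contained in the pattern's). The 5.8S blocks M1–M3
default to canonical conserved angiosperm patterns (M3 `TTTGAAYGCA`); the
motif table is configuration, so templates for other groups can be
substituted. A missing region yields a failed check rather than an error.

**Pseudogene screening** compares each clone to the direct-sequencing (or
majority) consensus. A clone is *putative_nonfunctional* if it carries any
5.8S substitution, fails a conserved motif, or has a region GC z-score
below −3 against its library; the verdict is monotone in 5.8S
substitutions. A clone whose private (singleton) variants are exclusively
non-compensatory is *putative_artifact* — the typical signature of a
PCR/cloning error, since real variants drawn from the genome's copy pool
recur across clones and tend to preserve structure. C→T/G→A
deamination-type changes are counted separately as supporting evidence.

**Chimera scan.** Recombinant screening is a single defined computation: at
informative sites (parents unambiguous and different) the query is
assigned to one parent; the 2×2 left/right-by-parent chi-square is
maximized over all breakpoints and calibrated by permuting the assignment
vector (default 999 permutations, seed required; p = (b+1)/(N+1)). Fewer
than 4 informative sites yields a warning and no call; identical parents
are an error. Power is inherently limited by the informative-site count: a
perfect split of n sites cannot reach p ≤ 0.05 below n = 8.

## Morphometrics

GPA centers every configuration, scales it to unit centroid size and
iterates rotate-to-consensus / update-consensus until the consensus moves
less than 1e-8; reflection is never allowed (leaves are oriented). Relative
warps are the principal components of the aligned, flattened coordinates
with no bending-energy weighting (α = 0, the TpsRelw default). Group mean
shapes are coordinate-wise means re-standardized to unit size.

**Procrustes distance** defaults to the full form sin ρ = √(1 − β²), with
the partial form √(2 − 2β) available, β being the sum of signed singular
values of the unit pre-shapes' cross-product (the sign guard excludes
reflections). Which of the two a published distance table used is often
unrecoverable; both are offered and the choice is explicit in the API.

**Symmetrization** (object symmetry) averages a configuration with its
reflected, relabeled copy after optimally rotating the mirror onto the
original, then averages once more with the map image. Because the
reflect-and-relabel map T is a linear involution, (X + T(X))/2 is exactly
T-invariant, making the operation idempotent to machine precision. The
6-pairs + 2-midline landmark pairing used by the synthetic leaves is
configuration — real datasets supply their own.

**Permutation test**: statistic = Euclidean distance between group mean
score vectors on the first 12 relative warps (configurable), p estimated
as (b+1)/(N+1), which is valid for any permutation count. Group order is
canonicalized internally so a label swap returns the identical seeded
p-value. The tangent-space check regresses pairwise tangent (Euclidean)
distances on Procrustes distances; correlations ≈ 1 certify the linear
approximation for the observed shape variation.

## Synthetic data: what it emulates, and what not

The generators are pure functions of (config, seed) and byte-reproducible.
Defaults encode the study conditions the pipeline is designed for:

| parameter | default | rationale |
| --- | --- | --- |
| L (ITS1/5.8S/ITS2) | 241/164/212 | spacer lengths of the motivating system; 164 is a typical angiosperm 5.8S |
| divergence | 0.02 | target whole-alignment p-distance between parents (≈ the 0.97–0.98 interspecific identities typical of closely related species) |
| dosage | (2, 1) | a tetraploid maternal gamete contributes two genome copies to a triploid hybrid, the diploid paternal gamete one |
| n_clones | 20 | standard clone-library depth |
| pseudogene_rate | 0.2 | fraction of clones drawn as pseudogenized copies (≈ the 16–20% of clones carrying 5.8S variants such surveys report) |
| clone_error_rate | 2e-5 /base | accumulated proofreading-polymerase PCR + cloning error |
| intragenomic_poly_rate | 0.004 | low-level intra-pool copy variation in 3 of 10 copies |
| landmark groups | 28/26/41, σ = 0.02 | the morphometric study design: three leaf groups, 14 landmarks, isotropic shape noise |

Divergence hits only the spacers: the 5.8S and the conserved motifs are
held invariant between parents (they are conserved at this taxonomic
depth), which is exactly the property the pseudogene screen exploits.
Mutations use a uniform-site model with transition bias κ = 2 so that K2P
estimation is exercised. Pseudogenized clones receive 5.8S substitutions
plus GC-lowering spacer changes; chimeras are spliced between the two
parental consensus copies so the clone-QC use case is mirrored. The
structure template is a hairpin-stem pairing map (six ITS1 and four ITS2
hairpins, two 5.8S stems) over the generated sequence.

Deliberately **not** emulated: indel evolution (alignment is fixed-length
by construction, so gap handling is exercised only by hand-built cases),
coalescent population structure, chromatogram-level noise, rate
heterogeneity along the sequence, and non-isotropic or allometric shape
variation. Passing the recovery tests therefore certifies the analysis
chain under the stated generative model, not robustness to alignment
error or to structured real-world noise.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full synthetic study
(3 × 20 clones, 617 columns, 95 leaf configurations), NeighborNet
recovery on random 4–8-taxon trees, permutation-null calibration over 500
seeded replicates at 99 permutations each, and 999-permutation chimera
calibrations — sizes chosen so every stage's statistical behaviour is
visible while a complete run stays in the tens of seconds. Reproduction of
the archived GenBank accession survey (147 sequences) requires a one-time
network fetch (`itshybrid fetch --accessions KF671968-KF672114`) or a local
cache under `data/genbank/`; the corresponding test fails when neither is
available, and the original landmark data were never deposited, so the
published morphometric distance values are validated by parameter recovery
under the same study design rather than re-computation.

Ties in agglomerations break deterministically toward the earlier index;
NNLS uses scipy's solver with a 1e-6 weight floor; GPA converges at 1e-8;
identity values round half-up at 3 decimals; all stochastic procedures
take explicit seeds and are deterministic under them.
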