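# Methods

This note records the statistical models, algorithmic choices and known
limitations behind each stage of the pipeline, in the order the pipeline
runs them.

## Input model and transforms

Abundance tables are samples × taxa, counts or proportions. Relative
abundance divides each sample row by its total; an all-zero sample is an
error. Genus collapse sums ASV columns sharing a genus; ASVs without a
genus assignment are pooled per their most resolved parent rank under a
`unclassified_<rank name>` label, so named families/orders survive as
network nodes rather than vanishing into one "unassigned" bucket. The
node-inclusion filter keeps taxa whose mean relative abundance over **all**
samples is strictly greater than the threshold (default 0.5%); the mean is
taken over all samples because one overall network is built before
per-treatment subnetworks are extracted.

BIOM 2.1 (HDF5) input is read directly with h5py (observation-major CSR);
TSV follows the amplicon convention of taxa rows × sample columns with
`#` comments.

## Co-occurrence network

Spearman ρ for every unordered taxon pair (average ranks for ties), with
p-values from the t approximation on n−2 degrees of freedom — at the
default screen (|ρ| > 0.70) the difference from exact small-n permutation
null tables is negligible, and the approximation is deterministic.
Benjamini–Hochberg adjustment runs across the upper-triangle family of a
single community's matrix only; bacterial and fungal networks are built
and screened independently. An edge requires |ρ| > 0.70 (strict) and
adjusted p < 0.01 (strict); isolated taxa are dropped.

Treatment subnetworks are induced subgraphs on the taxa with nonzero mean
relative abundance within the treatment's samples (presence rule; an
abundance cutoff within treatment would be an alternative, but presence is
the weakest assumption and keeps edge attributes untouched).

Topology panel: node/edge counts, average degree 2E/N, density, share of
positive-ρ edges, average shortest-path length over connected pairs within
components (finite on disconnected graphs, monotone under edge addition),
mean betweenness centrality normalised by (n−1)(n−2)/2, modularity of the
detected partition, and mean clustering coefficient. Graphs with < 3 nodes
report 0 for the path-based metrics with a warning.

**Network complexity** is axis 1 of a principal-coordinate analysis of the
Euclidean distances between z-scored topology rows (equivalent to PCA
here). Constant metric columns are dropped with a warning; identical
summaries yield all-zero scores. The axis sign is fixed so that average
degree loads positively — "more connected" always scores higher — because
an eigenvector's sign is otherwise arbitrary.

## Modules

Community detection is agglomerative (fast-greedy/CNM) modularity
maximisation on |ρ|-weighted edges: modularity for negative weights is not
well defined, so correlation signs are dropped for partitioning (they stay
on the edges). Starting from singletons, the merge with the largest ΔQ is
applied repeatedly — only connected pairs are candidates, so modules never
span components — and the partition with maximum Q along the merge path is
returned. Ties in ΔQ break to the lexicographically smallest pair of
community representatives, making the partition deterministic. On small
planted-structure graphs the greedy optimum matches exhaustive search;
on sparse unstructured graphs greedy agglomeration can land visibly below
the true optimum — a known property of the algorithm family, shared by
other library implementations.

Minimum-size enforcement (default 20): iteratively, the smallest
undersized module is merged into the neighbouring module with the greatest
total |ρ| edge weight; ties go to the larger module, then the
lexicographically smallest member. Undersized modules with no neighbours
(isolated components) are kept but flagged unassigned. Q is recomputed and
can only decrease or stay.

Module abundance is the sum of member relative abundances per sample.
Module–nutrient association is univariate OLS of nutrient on module
abundance with a two-sided t-test on the slope and stars at
0.05/0.01/0.001; regressions are reported uncorrected (matching the usual
panel presentation) with an additional BH-adjusted column for rigour.
Abundances are not standardised first — slopes are in nutrient units per
unit relative abundance.

## Core taxa

For each module × nutrient, a regression forest (500 trees by default,
mtry = ⌈p/3⌉, minimum leaf 5) predicts the nutrient from member
abundances. The forest is a bagged ensemble of CART trees with explicit
bootstrap bookkeeping, so out-of-bag sets are exactly reproducible from
the seed. Importance is %IncMSE: out-of-bag predictions are aggregated
forest-level, each predictor column is permuted within the out-of-bag rows
per tree, and the percent increase in OOB MSE is reported.

Significance is a response-permutation null: the nutrient vector is
permuted n_perm times, the whole importance computation repeated, and
p = (1 + #{null ≥ observed}) / (1 + n_perm) per taxon. A taxon is core if
p < α for at least one nutrient of its module. Permuting the response
keeps the predictor correlation structure, so the null is calibrated even
for strongly co-varying module members; n_perm < 20 is rejected as too
coarse. An importance-threshold or top-k rule would be the main
alternative; the permutation rule was chosen because it is null-calibrated
and testable.

Highly correlated members share importance, so at large module sizes
(25+ taxa at n = 18) individual p-values lose power even when the module
signal is strong — the validation regime uses modules of ~5 taxa where
per-taxon attribution is statistically meaningful.

## Pathway screening

Bipartite Spearman screens (microbe columns × gene columns; gene columns
× nutrient columns) at |ρ| > 0.60 and raw p < 0.05 — deliberately looser
than the network screen and uncorrected, because the aim is to retain
biologically meaningful weak links for the join step rather than control
the family-wise rate at this stage. A complete pathway (m, g, n) is the
relational join: the (m,g) and (g,n) edges must both be retained. The sign
product labels direction: two like signs → "promotes", mixed → "inhibits".
Exports: SIF plus node-class attributes (microbe, C-/N-/P-gene, nutrient)
and GraphML.

Enzyme-gene panels are editable JSON configuration
(`rhizonet/data/gene_panels_synthetic.json`); the shipped file is a
synthetic placeholder panel with the typical panel sizes for a soil C/N/P
functional study (19/13/9 bacterial and 12/6/8 fungal genes) and common
enzyme display names — users substitute their own KO/EC lists.

## Multivariate statistics

Shannon uses natural log on proportions; Chao1 = S_obs + F1(F1−1)/(2(F2+1))
needs counts (NaN on relative tables). Bray–Curtis via scipy; PCoA is
classical scaling of the Gower-centred squared-distance matrix with
negative eigenvalues reported and coordinate axes restricted to positive
ones.

PERMANOVA follows McArdle–Anderson: sequential (Type-I) sums of squares
from nested projection matrices on the Gower-centred matrix, pseudo-F per
term, p-values by free row/column permutation with the add-one formula
(minimum attainable p is 1/(n_perm+1); default 999 permutations). Both
factor orders are worth inspecting under Type-I SS; the pipeline emits
(tillage, straw, interaction) and the reverse. Free permutation ignores
the split-plot structure of a real tillage trial (whole-plot tillage);
restricted permutation would be the conservative alternative and is a
known limitation here.

Mantel is the Pearson correlation of upper-triangle distances with
simultaneous row/column permutation of the second matrix (two-sided on
|r|).

Variation partitioning uses redundancy-analysis R² (trace of fitted over
total variance of the centred response) per explanatory subset union,
each adjusted by Ezekiel's formula, combined by inclusion–exclusion into
unique/shared fractions for 2–3 sets. Negative adjusted fractions are
reported as computed and flagged, never clipped. Collinear columns within
a set are dropped via rank-revealing QR with a warning.

## PLS path modeling

Lohmöller's alternating algorithm with Mode A (reflective) outer
estimation and the path weighting scheme for inner estimation — the common
default for ecological PLS-PM, stated explicitly for reproducibility.
Manifests are standardised (ddof 1); outer weights start equal; latent
scores are standardised each round with a deterministic orientation (the
first manifest of each block loads positively); convergence is max
absolute outer-weight change < 1e-6 within 300 iterations. Path
coefficients are OLS of each endogenous latent on its predecessors; block
communality is the squared loading; GoF = √(mean communality × mean R²).
The design encodes tillage NT=0/MT=1 and straw NS=0/HS=0.5/TS=1; the
community blocks use Shannon plus the first two ordination axes (the
pipeline uses PCoA of Bray–Curtis; PCA of abundances would be the
alternative reading).

Bootstrap: resample rows with replacement (default 1000), refit, report
mean, SE, 2.5/97.5 percentile CI and sign-stability per path;
non-converging refits are dropped, more than 10% dropped is an error.

## Synthetic generator

Per sample, each module draws a latent factor = treatment shift +
N(0, module_factor_sd); member log-abundance = baseline + loading × factor
+ N(0, taxon_noise_sd); background taxa are independent; the matrix is
exponentiated and row-normalised (log-normal multiplicative model —
realistic skew, rank-stable correlations). Nutrients are linear in the
module factors plus noise. Genes are linear in driver relative abundances
plus noise, shifted by a positive offset and clipped at zero; the default
offset is 3×noise_sd plus the total magnitude of negative coefficients,
which keeps anti-driven genes non-negative without clipping away their
planted monotone signal (relative abundances never exceed 1).

Defaults mirror the study scale: 2×3 factorial × 3 replicates
(18 samples), 4 modules × 25 taxa + 20 background taxa, module factor sd
1.0, taxon noise sd 0.3 (noise ratio 0.3), treatment shifts of magnitude
1.5 cycling through tillage-responsive, straw-dose-responsive,
interaction-responsive and unresponsive module archetypes.

`planted_chain_config` defines the pathway-validation regime: genes driven
by **whole modules** (a single driver is statistically indistinguishable
from its module-mates under correlation screening, so chain identifiability
requires module-level drivers); one nutrient per module; module factors
independent of the treatments; 60 background taxa so compositional closure
stays mild; 9 replicates per cell (54 samples) so that the loose
|ρ| > 0.60 screen has a very small null pass rate. At the study's own
n = 18 the loose screen passes ~1% of null pairs, which across hundreds of
candidate pairs caps attainable precision around 0.8 — a real property of
the screening method at that sample size, not of the implementation.

What the generator does **not** emulate: sequencing depth and zero
inflation (abundances are strictly positive), phylogenetic correlation,
overdispersed counts, and the split-plot randomisation of a real field
trial. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to every
property of real amplicon data.

## Validation problem sizes

The test suite validates: FDR control on 500 independent-taxa tables
(18 × 30); module recovery over 20 replicate datasets at the 18-sample
study scale; greedy-vs-exhaustive modularity on 20 planted-partition
graphs of ≤ 8 nodes; the pathway join against a brute-force triple loop on
100 random instances and chain recovery over 5 generator seeds; PERMANOVA
type-I calibration on 500 null datasets (99 permutations each) plus the
exact 0.001 floor at 999 permutations under strong separation; classical
ANOVA/Procrustes equivalences at 1e-9/1e-6; PLS-PM path recovery over 100
replicates (n = 50, measurement noise 0.2); VPA on exactly orthogonalised
halves (n = 200); core-taxon recall over 3 replicates (n_perm = 100) and a
60-replicate null selection rate; complexity ordering over 100 paired
high/low-connectivity datasets. These sizes were chosen to make each
statistical bound sharp at desk scale.
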