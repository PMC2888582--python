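# Methods

`gvprotcomm` re-implements, as a tested library and CLI, the computational
chain used in comparative label-free shotgun proteomics of bovine
germinal-vesicle (GV) oocytes and their surrounding cumulus cells: filtering
SEQUEST-style peptide-spectrum matches (PSMs), estimating identification
confidence against a reversed-sequence decoy database, quantifying proteins
by XCorr-weighted spectral counting, profiling the result with GO slims and
annotation-quality (GAQ) scores, and scoring process-level balances and
gene-set enrichment. Every stage is exercised end-to-end on synthetic data
with known ground truth; nothing here re-analyses the original raw spectra.

## Identification filtering and confidence

A PSM passes the primary filter iff all four gates hold, checked in order:
peptide length ≥ 6 residues; ΔCn ≥ 0.1; Xcorr ≥ the charge-state threshold
(1.9, 2.2, 3.7 for +1, +2, +3); Rsp < 5. Length, ΔCn and Xcorr comparisons
are inclusive, the Rsp bound strict — a literal reading of the usual wording
of these criteria. Rejections are tallied by the first failing gate, so the
tally plus the passing count always reproduces the input count. Charges
outside {+1,+2,+3} get their own tally bucket. Whether the Rsp gate belongs
to the primary filter or a later stage is ambiguous in the source protocol;
it is applied here as part of the primary filter.

Confidence comes from a target-decoy strategy. Decoy databases are built by
whole-sequence reversal (not shuffling): deterministic, and it preserves each
entry's amino-acid composition and length. Because match quality depends on
precursor charge, one empirical null is fitted per charge state from decoy
Xcorr values, and a target PSM's p-value is the add-one smoothed exceedance
probability

    p = (#{decoy Xcorr_z ≥ x} + 1) / (N_z + 1),

with ties counting as exceedances. Add-one smoothing avoids p = 0 from a
finite decoy set; the attainable floor is 1/(N_z+1). The null is fitted from
all decoy records at their raw scores — pushing decoys through the Xcorr
gate first would amputate the null's lower tail and destroy calibration.

Evidence is collapsed to the best Xcorr per (peptide, charge) so repeated
spectra of one peptide do not multiply confidence; repeats still count in
quantification. A protein is retained when at least one distinct peptide has
p < 0.05. Fisher's method (χ² = −2Σln p on 2k df) over a protein's
distinct-peptide p-values is reported as an auxiliary ranking statistic only:
the exact protein-probability formula used historically lives in secondary
references, so retention deliberately rests on the simple per-peptide rule.
Shared peptides confer retention on every parent accession and are flagged.

## Quantification and differential expression

The abundance proxy is ΣXcorr: per protein and (cell type, replicate), the
sum of Xcorr over that protein's passing PSMs. Unobserved cells are 0, not
missing — under data-dependent acquisition, absence of sampled spectra is
evidence of low abundance, and spectral-count matrices are conventionally
complete. No cross-replicate normalisation is applied by default (a
total-sum scaling switch exists); no multiple-testing correction by default
(a Benjamini–Hochberg switch exists), both to stay faithful to the emulated
protocol's raw α ≤ 0.05.

Differential expression is one-way two-group ANOVA per protein on the
per-replicate ΣXcorr values. The sums of squares are computed explicitly so
degenerate inputs have defined semantics: all observations identical → F = 0,
p = 1, not differential; zero within-group variance with distinct means →
F = ∞, p = 0; all-zero rows are untestable and tallied separately. With two
groups this ANOVA is identical to the pooled-variance t-test (F = t²), which
the tests verify wholesale. Direction ("higher"/"lower" in the comparison
cell type, cumulus by convention) comes from the group means and is defined
only for differential rows. Membership partitioning (oocyte-only /
cumulus-only / common) uses presence of ≥ 1 passing PSM per cell type.

## GO-slim profiling, GAQ, and process balances

A protein maps to a slim category iff one of its annotated terms equals the
slim term or has it among its is_a/part_of ancestors; only those two
relationship types are traversed, and obsolete terms never participate in
ancestry. NOT-qualified GAF annotations are excluded at parse time
(colocalizes_with / contributes_to are retained); GAF terms missing from the
ontology are reported, never silently dropped.

Category percentages are computed per replicate — proteins of the category
present in the replicate over slim-annotated proteins present in the
replicate — so the between-cell-type comparison (two-sided pooled-variance
Student's t) has genuine replication; the emulated study does not state its
unit of replication, so this is the package's choice.

The GAQ score is GAQ(protein) = Σ over annotations of depth(term) ×
weight(evidence code). Depth is the shortest is_a/part_of path (in edges) to
the namespace root — deterministic and cheap; the original GAQ convention
lives in its own citation, so the depth definition and the weight table are
both configurable. Default weights ship as data
(`src/gvprotcomm/data/ec_weights.tsv`): experimental codes
(EXP/IDA/IPI/IMP/IGI/IEP) 4, curated homology (ISS/ISO/ISA) and TAS/IC 3,
NAS 2, IEA 1, ND 0. GAQ is additive, order-invariant, and never decreases
when annotations are added or upgraded to stronger evidence.

Net-effect tables count, per biological process, differential proteins
higher minus lower (expression balance) or curated agonists minus
antagonists (regulation balance). Multi-category proteins count in every
category; the process list is input data, not code, because the curation
behind such lists is data. Contradictory regulation assertions (one
protein/process pair asserted in both directions) are an error; assertions
about proteins outside the declared universe are excluded with a warning.

## Gene-set enrichment

For a focus set of n proteins from a universe of N and a gene set of size K
overlapping in k, the right-tail Fisher exact p-value is the hypergeometric
tail Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), evaluated in log space via the
hypergeometric survival function; k = 0 returns exactly 1. The score is
−log10(p). Two conventions are applied: pathway significance at p ≤ 0.05 and
network significance at score strictly > 2. Published descriptions disagree
between "≥ 2" and "> 2" for the network rule; the stricter comparator is the
default and it is configurable. Enrichment is one-sided (depletion out of
scope), the universe is the gene-set collection's declared accession universe
(overridable), and the proprietary network-growing heuristics of commercial
pathway tools are deliberately not emulated — enrichment over declared sets
is the reproducible core.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the analysis assumes: two
cell types × 3 replicates × 4 fractions of target and decoy PSMs; charge
states +1/+2/+3 (probabilities 0.2/0.5/0.3); per-charge correct-match Xcorr
from truncated normals centred above the filter thresholds (means 2.8, 3.3,
4.6) and random/decoy Xcorr well below them (means 1.0, 1.2, 1.5); ΔCn and
Rsp drawn so most correct PSMs pass the primary filter; a configurable
fraction of shared proteins (default 0.2) of which a configurable fraction
(default 0.3) carries a true fold effect (default 3, 80% higher in cumulus,
matching the strong upward skew such comparisons show); and a matching toy
annotation bundle — a fixed ≥4-level DAG with both is_a and part_of edges,
GAF annotations with an IEA-heavy evidence mix, ten mid-level slim terms,
gene sets partially overlapping the truly up-regulated proteins, and an
agonist/antagonist regulation table over oocyte-expressed proteins.

PSM counts per protein per replicate are negative binomial with mean
proportional to true abundance (mean 20 PSMs at baseline). The dispersion
default is size = 50, i.e. ~14% extra-Poisson CV: replicates in the emulated
design are pooled samples of hundreds of cells — technical-level
reproducibility, not animal-to-animal biological variation. This was chosen
once, before any threshold tuning, and is a free parameter of the stated
world, not an inference about any real dataset. Decoy record counts are
Poisson with mean decoy_ratio × target count (default ratio 1). Peptides are
deterministic pseudo-tryptic strings keyed by protein index; no amino-acid
chemistry, retention time, raw spectra or isotope patterns are simulated.
Fixing the seed makes every emitted file byte-identical.

A green test on this world therefore establishes: the arithmetic of every
stage, the calibration of the empirical p-values, type-I control and power
of the ANOVA under negative-binomial counts, and the exactness of the
set/graph operations. It does not establish anything about real
chromatographic variation, ionisation competition, peptide-level missingness
structure, shared-peptide inference ambiguity at real database scale, or the
content of any curated knowledgebase.

## Numerical and design choices

- ΣXcorr sums over spectra, not distinct peptides: keeps the count
  information spectral counting relies on; flagged for sensitivity analysis.
- Empirical p-values use searchsorted on a sorted decoy array; exact ties are
  exceedances by construction.
- The Fisher-combination p uses the χ² survival function; tests check it
  against the closed form for even degrees of freedom.
- t- and F-statistics with zero pooled variance: p = 1 when means are equal,
  p = 0 otherwise.
- Percentage denominators with no annotated proteins in a replicate give 0%,
  not NaN.
- Membership counts report both the distinct-protein total and per-cell-type
  totals, because published "total protein" figures often count shared
  proteins once per cell type.

## Known limitations

- Protein inference is accession-level with full credit to every parent of a
  shared peptide; no parsimony/razor grouping or ProteinProphet-style
  mixture modelling.
- The OBO reader covers the OBO 1.2 subset the pipeline needs (id, name,
  namespace, is_a, part_of, is_obsolete), not the format's every feature.
- Probabilistic rescoring of PSMs (mixture models) and MS1/intensity-based
  quantification are out of scope.
- Enrichment reproduces the Fisher-exact/score conventions, not any
  proprietary knowledgebase or network-growing algorithm.
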