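# Methods

`probiotarget` packages the computational core of a drug–probiotic
interaction analysis: starting from a bacterial proteome, it shortlists
essential, cytoplasmic, human-non-homologous proteins; scores their
druggability; summarizes their interaction network; and quantifies the
downstream effects of drug exposure with dose–response, qPCR and
MD-trajectory analytics. This note documents the models, the defaults and
why, the synthetic data the tests stand on, and the known limitations.

## Subtractive filter cascade

Four chained stages, each producing an auditable trace (input ids,
retained ids, per-protein reason codes):

1. **Redundancy removal.** Greedy longest-first clustering in the CD-HIT
   style: sequences are visited longest first and join the first cluster
   whose *founder* they match at ≥ the identity threshold (default 0.70).
   Identity is exact matches over the alignment length of a global
   Needleman–Wunsch alignment (match 1, mismatch 0, linear gap −1).
   The exact alignment replaces the word-filter heuristic of production
   clustering tools: at the scale this package targets (thousands of
   proteins, not millions) exactness is affordable and makes the brute-force
   oracle test meaningful. Representatives are the cluster founders
   (longest members).
2. **Essentiality.** Retain proteins whose externally predicted
   essentiality score is ≥ 0.24. The boundary is inclusive; all threshold
   comparisons in the cascade follow the inequality direction as published,
   with strictness configurable where the source is silent.
3. **Localization consensus.** Three predictors vote; a vote counts only
   above its tool's confidence rule (PSORTb score ≥ 7.5, DeepLocPro
   probability ≥ 0.5, CELLO2GO's top-reliability label). The default
   decision rule is a majority of the tools that reported, because the
   combination rule used upstream is not published; `min_votes` overrides
   it.
4. **Human non-homology.** A BLAST hit is *significant* iff E-value
   ≤ 1e-3 AND identity > 30% AND coverage > 30%; proteins with no
   significant hit are retained. The published criteria are phrased as
   search parameters, so whether significance required all three
   conditions or any one is ambiguous; AND is the default and
   `combine="any"` gives the stricter reading.

The external predictors themselves (essentiality, localization, BLAST,
TM-helix, signal-peptide, solubility, surface/disorder predictions) are
consumed as annotation-table columns, never re-implemented.

## Physicochemical calculators

Native ProtParam-convention implementations: average isotopic masses
(+ one water), Kyte–Doolittle GRAVY, the Guruprasad instability index
(dipeptide weights from the published DIWV table as distributed with
Biopython; the formula II = 10/L · Σ DIWV over consecutive pairs is
implemented here), Ikai's aliphatic index (X_A + 2.9 X_V + 3.9 (X_I+X_L),
mole percent), and the theoretical pI by bisection of the
Henderson–Hasselbalch net charge with the Bjellqvist pKa set (termini 7.5 /
3.55; K 10.0, R 12.0, H 5.98; D 4.05, E 4.45, C 9.0, Y 10.0). The charge is
strictly monotone in pH, so bisection converges to the unique root
(tolerance 1e-4 in charge or pH). Non-canonical residues raise by default;
`ignore_unknown=True` drops them.

## Druggability scoring and tiers

A binary, equal-weight multi-criteria score. The default preset has eight
criteria: MW < 90 kDa, GRAVY < 0, instability < 40, aliphatic index > 70,
solubility score > 0.45, zero TM helices, signal-peptide criterion, and a
structural-favourability flag (≥ 30% solvent-accessible residues, longest
disordered run < 20 (strict), helix+sheet fraction ≥ 0.30 — the last bound
is this package's quantification of "stable secondary structure", which the
source pipeline leaves unquantified; it is configurable). Comparator
strictness follows the printed inequality symbols (MW strictly below
90 kDa; totals ≥ 8 at the top tier).

Two genuinely open design points, resolved as follows and configurable:

* **Signal peptide direction.** The upstream pipeline selects cytoplasmic
  proteins yet lists "presence of signal peptide features" among scored
  parameters. The default here scores *absence* of a Sec/SPI signal
  (probability < 0.5 → 1), consistent with cytoplasmic selection;
  `default_criteria(signal_peptide_scored_when="present")` flips it.
* **Tier cutpoints.** Totals ≥ 8 → very_high, 7 → high, 5–6 → moderate,
  else low. Only the ≥ 8 boundary is anchored in the published rule; the
  lower boundaries are this package's defaults and mandatory config.

Tier and KEGG-category summaries report counts and percentages to two
decimals; percentages are over the scored set (tiers) or the annotated
subset (KEGG).

## Interaction-network metrics

Graphs are undirected with edge confidences in [0, 1]. Confidence
filtering (default ≥ 0.70, boundary inclusive) never drops nodes —
singletons are biologically meaningful candidates. Average degree is 2E/N;
the clustering coefficient is the *mean of local coefficients* with
degree < 2 nodes contributing 0 (the Cytoscape/STRING summary convention;
chosen over global transitivity, which cannot be distinguished without the
original edge list). Hubs are nodes at or above the (1 − 0.2) degree
quantile, ranked by descending degree with ties broken by id.

## Dose–response analytics

Percent inhibition is (1 − OD_treated/OD_control) × 100 against the mean
drug-free growth control; negative values (stimulation) are reported
unclamped. The MIC is the lowest tested concentration whose mean
inhibition reaches 90%.

IC50 comes from a four-parameter log-logistic,
f(x) = c + (d − c)/(1 + exp(b (ln x − ln e))), fitted by least squares to
replicate-level percent inhibition by default (`response="od"` fits raw
OD; fitting replicates rather than means keeps the residual information).
All four parameters are free; the inflection is fitted as log e because
the sampling distribution of a concentration parameter is right-skewed —
intervals built on log(IC50) have close-to-nominal coverage in the
package's own simulations, whereas natural-scale Wald intervals undercover
when the upper asymptote lies beyond the tested range. The natural-scale
IC50 ± SE is reported via the delta method. A fit whose curve does not
describe an actual inhibitory effect (response moving the wrong way with
dose) is returned flagged, not raised.

Treated-vs-control comparisons are two-sided Welch t-tests per
concentration, Benjamini–Hochberg-adjusted across a drug's concentrations.

## 2^-ΔΔCt expression analysis

Per replicate, ΔCt = Ct_target − Ct_reference paired by
condition/replicate (reference wells sharing a replicate are averaged;
unpaired target replicates are dropped with a warning). ΔΔCt is computed
per treated replicate against the gene's *mean* control ΔCt, so treated
replicates carry variance while the control's own mean ΔΔCt is 0 by
construction. Fold change = 2^−ΔΔCt and log2FC = −ΔΔCt are defining
identities (amplification efficiency fixed at 2; no efficiency
correction). Welch t-tests compare treated vs control ΔCt per
gene/condition; BH correction spans the whole gene × condition family by
default (`family="per_gene"` narrows it).

## Trajectory summary statistics

Trajectories are frames × atoms × 3 in nm with per-atom masses and
1-based residue indices; uniform frame spacing is enforced. I/O is plain
multi-frame XYZ plus a sidecar atom→residue/mass table — binary simulation
formats are out of scope, as is any simulation, PBC handling or energetics.

* **RMSD**: mass-weighted, after optional mass-weighted Kabsch
  superposition onto the reference frame; degenerate selections
  (< 3 atoms or collinear) fall back to translation-only with a warning.
* **RMSF**: per-atom fluctuation about the time-average position, averaged
  within residues. Flexible residues are those above mean + 1 SD of the
  per-residue RMSF (sample SD), reported with contiguous runs. For a
  profile with mean 0.12 nm and SD 0.073 nm this threshold is 0.19 nm at
  two decimals. Superposition is off by default (the generator produces no
  rotation); enable it for trajectories with rigid-body motion.
* **Radius of gyration**: mass-weighted, per frame.
* **Hydrogen bonds**: geometric criteria — donor–acceptor distance
  ≤ 0.35 nm for the pair count, plus H–D–A angle ≤ 30° for the H-bond
  count. The distance cutoff is the published value; 30° is the
  simulation tool's documented default (not published for this analysis);
  both are configurable. The H-bond count can never exceed the pair count.
* **Series statistics**: mean, sample SD, SE = SD/√n, and cumulant ratios
  cum3 = m₃/m₂^1.5 (standardized skewness) and cum4 = m₄/m₂² − 3 (excess
  kurtosis, Gaussian → 0), using population central moments; undefined
  (None) for constant series.
* **Equilibration time**: the published analyses report equilibration
  times without a method, so the rule here is invented and documented: the
  band is mean ± tolerance·SD of the last 50% of frames (tolerance 1.0);
  t* is the earliest time from which every value stays inside the band,
  provided at least `min_plateau` (5 ns) remains; otherwise none.

## Synthetic data generator

One integer seed drives all generators through splittable streams
(`SeedSequence(seed, spawn_key=(k,))` with a frozen k per generator), so
identical seeds give byte-identical outputs and adding a generator never
perturbs the others.

* **Proteomes**: redundancy groups are substitution-only mutants of a
  founder (exactly ⌊(1−identity)·L⌋ substituted positions), so pairwise
  identity is countable without alignment; the rest are i.i.d. random
  singletons. No substitution-matrix realism is attempted.
* **Annotations**: pass/fail per filter drawn from configurable rates,
  scores then placed on the corresponding side of each published
  threshold. Default rates (essential 0.18, cytoplasmic 0.85,
  non-homologous 0.40) echo the published cascade's stage ratios
  (279/1532, 233/279, 93/233).
* **Plates**: OD = LL4(concentration) + Gaussian noise truncated at zero
  (instrument floor; truncation, not resampling). Defaults are the assay
  conditions: asymptotes 0/0.893 OD, IC50 91.28 µg/mL, slope 1, noise SD
  0.02 OD, triplicate, two-fold dilutions up to 200 µg/mL.
* **Ct tables**: reference-gene Ct condition-independent in expectation;
  target genes carry their true ΔΔCt as an additive Ct shift in treated
  conditions; replicate noise 0.15 cycles by default (a typical qPCR
  technical-replicate SD; the source reports n = 3 but no Ct SD). Default
  effects are the six assayed genes' published dose-dependent ΔΔCt values.
* **Trajectories**: frame = reference + i.i.d. Gaussian displacement with
  per-residue SD from an amplitude profile (+ optional rigid drift), so
  the expected per-atom RMSF is amplitude·√3 in closed form. This
  reproduces the *statistical* structure of an equilibrated trajectory —
  it has no autocorrelation, no physics, and equilibration-time estimates
  on it are trivial. Rank-order recovery checks use a geometric profile
  (8% steps) because orderings closer than the ~1/√(2N) relative
  Monte-Carlo error of an RMSF estimate are not identifiable from N
  frames.

Because the generators match the fitted models exactly, passing recovery
tests demonstrate correctness of the estimators, not robustness to the
model violations real data carry (autocorrelated trajectories, non-Gaussian
OD noise, efficiency ≠ 2 amplification, indels).

## Problem sizes in the test and acceptance runs

Tests run on proteomes of 20–40 proteins (lengths 40–400), plates of 5
positive doses × 3–30 replicates, Ct tables of 6 genes × 3 conditions × 3
replicates, and trajectories of up to 5001 frames × ≤ 60 Cα atoms; the
IC50 coverage suite fits 200 seeded plates. These sizes exercise every
code path while keeping the whole suite in seconds.

## Known limitations

* Clustering is O(n²) exact alignment — appropriate up to a few thousand
  sequences, not for metagenome-scale inputs.
* IC50 standard errors are asymptotic (delta method on the log scale);
  with 3 replicates and an IC50 near the top tested dose they remain
  approximate, and estimates beyond the tested range should be treated as
  unstable (the analysis that motivated this package hit exactly that with
  one of its two drugs).
* The equilibration-time rule is a pragmatic band heuristic, not a
  statistical changepoint method.
* Hydrogen-bond counting is all-pairs per frame — fine for ligand-site
  selections, quadratic for whole proteins.
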