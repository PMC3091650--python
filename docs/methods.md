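# Methods

## Scope and model

`aluedit` re-implements, as a tested pipeline over synthetic data, a
large-scale analysis of the structural, sequence and thermodynamic
determinants of A-to-I RNA editing in human Alu repeats. A-to-I editing by
ADAR enzymes requires double-stranded RNA; in human transcripts that dsRNA
is overwhelmingly formed by nearby, oppositely oriented Alu copies
base-pairing within one pre-mRNA. Because inosine is read as guanosine,
editing appears as A>G mismatches in RNA-to-genome alignments.

The pipeline has five computational stages:

1. **Site calling.** Alignment mismatches are cleaned of known SNPs,
   intersected with Alu annotations (mismatch types re-expressed on the
   Alu's strand), and filtered to clusters: within one RNA alignment, a
   maximal run of identical mismatches uninterrupted by a different mismatch
   type; all members of runs of ≥ 3 become the putative editing set E1.
   "Consecutive" is RNA-local (adjacency in the RNA's ordered mismatch list,
   no genomic-distance cap). The control set E0 is every other Alu-strand
   adenosine of the analysed Alus. Cluster purity (fraction A>G) is reported
   as QC, not enforced as a filter.
2. **Neighborhoods.** For each Alu carrying E1 sites (and each partner), the
   nearest antisense Alu is found by edge-to-edge gap (ties broken
   downstream), the window [min start − 200, max end + 200) is built, and
   windows overlapping by strictly more than 400 bp on the same strand are
   merged transitively. The window's strand is the edited Alu's strand and
   all fold coordinates live on that strand.
3. **Structure micro-classification.** Each predicted secondary structure
   (CT or dot-bracket input; pseudoknots rejected; G·U wobble counts as a
   pair; U normalised to T) is partitioned into six substructure kinds —
   helix, interior loop, bulge, hairpin, multibranch junction, exterior
   strand — where loop elements own only their unpaired constituent
   nucleotides. Per site we derive: cePos (distance to the closest edge of
   the site's own strand, or stacked-pair steps from the nearest helix
   terminus for helix sites — base-pair steps are the natural helix metric
   and reproduce "cePos = 5 in a 17-bp helix" style statements); strand and
   opposite-strand lengths and their difference (asymmetry, interior loops
   only); the opposite nucleotide opNuc (pairing partner in a helix; for
   cePos = 0 interior-loop sites the most-5' nucleotide of one strand faces
   the most-3' of the other, undefined when a length-1 strand faces a longer
   one; n/a otherwise); flanking-helix direction for loop-edge sites; and
   the 30 sequence neighbours on each side (element-agnostic, record-edge
   neighbours excluded from statistics).
4. **Context statistics.** Stratified editing frequencies with Wilson 95%
   CIs; enrichment factor of a context = frequency in the context ÷ mean
   frequency over all eligible sites of the stratum (so site-share-weighted
   enrichments average to 1, and freq/enrichment is one shared baseline
   across a table — the property the packaged reference joint-context table
   is checked against); per-offset 2×4 Pearson chi-square scans (df 3, no
   continuity correction, empty nucleotide columns dropped, expected < 5
   flagged); two-proportion pooled z-tests (equivalent to the 2×2 Pearson
   chi-square) and Bonferroni correction min(1, p·m). Integer-valued
   covariates (lengths, cePos) are pooled above configurable caps.
5. **Ensemble thermodynamics.** A neighborhood's fold ensemble is the
   discrete list of supplied structures; fold n gets Boltzmann weight
   P_n ∝ exp(−G_n/RT) with R = 1.98717×10⁻³ kcal·mol⁻¹·K⁻¹ and
   T = 310.15 K (the usual folding temperature), computed with a max-shift
   so weights are invariant to energy offsets. Per site, p^s is the total
   weight of folds placing it in kind s, and the structural entropy
   H = −Σ p^s ln p^s (nats; 0 ≤ H ≤ ln 6) measures micro-structural
   volatility. Frequency-vs-entropy profiles are binned equal-count per
   ground-state stratum (minimum-energy fold, ties to the first listed);
   because H = 0 is a point mass, it forms its own bin and the quantile bins
   cover the fluctuating sites.

No folding is performed: ensembles are consumed exactly as given (MFOLD-style
CT with `dG =` headers, or dot-bracket plus energies).

## Synthetic data

The generator emits every input the pipeline consumes, from one seed:

* **Genome.** `n_alu_pairs` sense/antisense pairs of a fixed 280-nt Alu-like
  consensus (~60% GC), each copy independently diverged by substitutions
  (default 0.15/site, typical of Alu–Alu divergence) and short indels
  (0.02/site, ≤ 3 nt), planted in random background. Inter-Alu gaps are
  drawn from bins <1000 / 1000–2000 / 2000–3000 / 3000–6800 nt with weights
  0.61/0.22/0.09/0.08; the inter-pair spacer (8 kb) exceeds the maximum gap
  so the nearest antisense Alu is always the within-pair partner. SNP
  positions are sampled at 10⁻³/bp.
* **Fold ensembles.** The ground state of each neighborhood is the duplex of
  its two Alu arms, built by global base-level alignment (edlib) of arm 1
  against the reverse complement of arm 2: complementary aligned columns
  (Watson–Crick or G·U) become pairs, mismatched columns become interior
  loops, indels become bulges and asymmetric loops; monotonicity of the
  alignment guarantees a non-crossing structure. Suboptimal folds are the
  ground state with 5 random windows of 8–25 nt unpaired; free-energy gaps
  between successive folds are exponential (scale 0.5 kcal/mol), or energies
  are inverted from explicit target weights. Defaults (8 folds, small gaps,
  several windows) are chosen so that structural entropy has usable dynamic
  range, emulating "all folds relevant at body temperature"; sparser
  ensembles leave most sites at exactly H = 0.
* **Editing model.** Every Alu-strand adenosine is edited independently with
  probability baseline(kind) × f(up1) × f(dn1) × f(opNuc) × f(cePos) ×
  f(symmetry) × exp(−λH), clipped to [0, 1]. Default baselines are the
  observed per-kind frequencies of the large human survey (helix 0.044,
  interior 0.091, bulge 0.031, hairpin 0.032, junction 0.024, strand 0.020)
  — detection-scale rates, not biochemical ones. Default neighbour effects
  follow the reported preferences (upstream T 2.2×, upstream G 0.32×,
  downstream G preferred, opposite C 3.5×), symmetric interior loops get a
  2× boost, interior sites off the loop edge 0.2×, helices gain 3% per
  base-pair step into the stack (capped at 10), and λ = 1. Because the
  multipliers do not average to exactly 1 over the synthetic context
  distribution, the realised overall editing fraction at defaults (~0.10)
  sits above the per-kind baselines; all validation targets are effects, not
  the overall rate.
* **Record emission.** One simulated RNA spans 10 consecutive same-strand
  neighborhoods (long pre-mRNAs contain several Alu pairs), so true edits
  form long same-type runs and survive cluster calling; an RNA whose edit
  count falls below the cluster threshold is demoted to unedited in the
  truth labels (with one RNA per neighborhood this demotion acted as a
  strong ascertainment filter and biased per-site frequencies by 5–10%).
  Noise: decoy mismatches (never A>G in either strand frame, so they split
  but cannot join clusters), mismatch records on known SNP positions, and a
  per-site detection sensitivity. Editing is simulated only at Alu-strand
  adenosines of each transcript's own-strand Alu; the antisense partner's
  adenosines are edited on the opposite-strand transcript of the same locus.

**What the generator does not emulate:** real Alu subfamily structure and
insertion-age spectra, transcript expression levels and coverage variation,
physically realistic fold energies (energies are assigned, not computed),
tissue biology beyond a binary tag, and editing-level (per-site percentage)
variation — labels are binary, as in the emulated analysis. Passing tests
therefore demonstrate that the pipeline's inference machinery is correct and
unbiased under a known multiplicative model, not that the biological effect
sizes are as planted.

## Validation designs

* **Oracle equivalence.** The classifier is compared against an independent
  O(n²) per-position loop-decomposition oracle on the exhaustive set of 538
  valid dot-bracket strings of length ≤ 12 (minimum hairpin 3).
* **Round trip.** With noise off and sensitivity 1, the called E1 set must
  equal the simulated truth exactly, and the per-kind counts must partition
  all Alu-strand adenosines of the analysed Alus.
* **Parameter recovery.** An isolated-effects world (~50,000 adenosines,
  520 pairs; only upstream-T 2.2×, opposite-C 3.5×, per-kind baselines and
  λ = 1 act) is analysed blind. Contexts of consensus-derived sites are
  mutually correlated (up1, opNuc and kind couple through consensus
  position — as in real Alus), so raw conditional frequencies are biased
  estimators of the planted multipliers. Each effect is instead estimated
  as a rate ratio inside strata where the other effects are constant
  (helix for up1; interior split by opNuc class; interior non-T-up1 for
  opNuc), with the known exp(−H) factor divided out
  (Σ edited / Σ exp(−H) estimates the stratum rate) and strata pooled by
  inverse variance. Recovered values must fall within 10% of truth.
  The frequency-vs-entropy profile of ground-state-helix sites, at 4
  equal-count bins, must be strictly decreasing; 4 bins (rather than the
  reporting default of 10) keep adjacent-bin frequency gaps at ≥ 2 standard
  errors at this sample size. The interior ground-state stratum contains
  only ~700 fluctuating sites at this scale (interior sites usually keep
  their kind across folds), so its profile is reported but not asserted.

## Numerical and degenerate-input choices

* Natural logarithms throughout the entropy machinery; probability vectors
  must sum to 1 within 10⁻⁶; 0·ln 0 ≡ 0; float jitter in Boltzmann sums is
  rounded so H = 0 is exact (H = 0 sites must share one profile bin).
* CT energies are read/written at 0.01 kcal/mol; re-derived weights and
  entropies agree with exact values to ~10⁻³.
* Coordinates are 0-based half-open internally and in BED; 1-based only
  inside CT records and structure-local positions.
* Pseudoknots are rejected, not silently broken. Empty loops (stacked
  helices, junctions with no unpaired nucleotide) own no positions.
* Wilson intervals are clamped to [0, 1] with exact endpoints at k = 0 and
  k = n. Empty groups carry n = 0 and undefined frequency.
* Tie-breaks: equidistant antisense partners go downstream; equal-energy
  ground states go to the first structure listed (MFOLD emits best-first).
* A mismatch inside overlapping Alus is assigned to the Alu with the
  smaller start; an E1 call whose Alu-strand reference base is not A is
  dropped with a warning.

## Limitations

Real RNA/EST alignments, UCSC annotations and MFOLD ensembles are out of
scope; the headline tables of the emulated survey summarise ~620,000 real
sites and are not reproducible at this scale. The brain vs non-brain
comparison and the joint-context enrichment table are validated against
their published summary counts (packaged as a small reference table), not
recomputed from raw data. Editing levels (fractions of transcripts edited
per site) are not modelled.
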