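# aluedit

Structural, sequence and thermodynamic analysis of A-to-I RNA editing in
Alu inverted repeats.

## The problem

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; inosine
reads as guanosine, so editing shows up as A>G mismatches when RNAs are
aligned back to the genome. In human transcripts virtually all of this
editing happens inside Alu repeats: two nearby, oppositely oriented Alu
copies in one pre-mRNA base-pair into a long imperfect duplex, the ADAR
substrate. Editing across these duplexes is strongly site-selective, and the
selectivity is only partly explained by the flanking-sequence motifs
(upstream T preferred, upstream G avoided, downstream G preferred).

`aluedit` is a pipeline for asking *what the local secondary structure and
its thermodynamic stability add* to those sequence preferences. It is aimed
at computational RNA biologists who have (or can simulate) alignment
mismatch tables, repeat annotations and secondary-structure ensembles, and
who want stratified editing statistics per micro-structure.

## What it computes

* **Editing-site calling** — mismatches are SNP-filtered, intersected with
  Alu intervals (re-expressed on the Alu strand), and called in clusters:
  all members of runs of ≥ 3 identical consecutive mismatches within one RNA
  become the edited set E¹; every other Alu-strand adenosine is the control
  set E⁰.
* **dsRNA neighborhoods** — containing Alu + nearest antisense Alu +
  intervening sequence + 200-nt flanks, merged when overlapping > 400 bp on
  the same strand.
* **Per-nucleotide micro-structure** — every position of every fold is
  classified into helix, interior loop, bulge, hairpin, junction or exterior
  strand; per site the pipeline derives cePos (distance to the closest edge
  of the site's own element), the opposite nucleotide opNuc (pairing partner
  in a helix, cross-strand edge partner at interior-loop edges), loop
  asymmetry, and 30 sequence neighbours each side.
* **Context statistics** — editing frequency f(context) with Wilson 95% CIs,
  enrichment factors f(context)/f̄ against a shared stratum baseline,
  per-offset χ² scans of E¹ vs E⁰ neighbour composition (df = 3),
  two-proportion z-tests and Bonferroni correction.
* **Boltzmann-ensemble thermodynamics** — over the supplied fold list,
  P_n = e^(−G_n/RT)/Z per fold, per-site substructure probabilities
  p_i^s = Σ_n P_n·χ_i^s(n), and the structural entropy
  H_i = −Σ_s p_i^s ln p_i^s (0 for a structurally rigid site, ln 6 at most),
  with editing-frequency-vs-entropy profiles per ground-state stratum.
* **Synthetic data** — a seeded generator for the whole input bundle
  (genome with planted Alu pairs, SNPs, CT fold ensembles, mismatch
  records) driven by a known multiplicative editing model
  p = baseline(kind)·f(up1)·f(dn1)·f(opNuc)·f(cePos)·f(symmetry)·e^(−λH),
  so every stage is testable against ground truth without downloads.

Formats: BED6, FASTA, mismatch TSV, MFOLD-style multi-record CT (or
dot-bracket + energies). See `docs/methods.md` for the full model account.

## Worked example

```bash
python analysis/01_simulate.py            # seeded synthetic dataset
python analysis/02_run_pipeline.py        # full analysis -> results/report/
```

The default run (60 Alu pairs, seed 7) simulates 5,718 Alu-strand
adenosines, 640 of them edited, and the pipeline prints:

```
{
  "n_e1": 636,
  "n_e0": 5082,
  "called_ag_fraction": 1.0,
  "n_neighborhoods": 120,
  ...
}

editing frequency by substructure kind:
    kind  n_sites  n_edited     freq   ci_low  ci_high
   bulge      353        11 0.031161 0.017488 0.054930
 hairpin        9         2 0.222222 0.063225 0.547411
   helix     3825       165 0.043137 0.037144 0.050047
interior     1525       458 0.300328 0.277846 0.323813
  strand        6         0 0.000000 0.000000 0.390334
```

636 of the 640 truly edited sites survive cluster calling with no false
positives (`called_ag_fraction` 1.0 means every called mismatch is A>G on
its Alu strand). Helix sites come out at their planted baseline frequency
0.044; interior-loop sites are far above their 0.091 baseline because the
favourable contexts (opposite C, symmetric loops, upstream T) multiply it.
The report directory also contains frequency-vs-length, cePos and asymmetry
tables, enrichment-factor tables, the ±30-offset χ² scan and the
entropy profiles.

The recovery study runs the pipeline blind against planted effects:

```bash
python analysis/03_parameter_recovery.py
```

```
sites analysed: 50025
  up1_t_multiplier       truth 2.2    recovered 2.2069 (+0.3%)
  opnuc_c_multiplier     truth 3.5    recovered 3.5094 (+0.3%)
  helix_baseline         truth 0.044  recovered 0.0458 (+4.0%)
  interior_baseline      truth 0.091  recovered 0.0869 (-4.6%)

editing frequency vs entropy, ground-state helix:
 bin  entropy_mean  n_sites     freq
   0      0.006351     8374 0.053380
   1      0.117717     8375 0.049075
   2      0.374306     8372 0.039417
   3      0.622946     8372 0.027353
```

i.e. the planted sequence/structure effects are re-estimated within a few
percent, and editing frequency falls monotonically with structural entropy —
structurally rigid sites are the better substrates.

A CLI wraps the same stages (`aluedit simulate|call-sites|run-all|validate`),
and `analysis/04_reference_checks.py` reruns the closed-form checks against
the published survey numbers.

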