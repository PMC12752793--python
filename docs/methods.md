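# Methods

## Problem setting

`affiselect` analyzes deep-sequenced pools from iterative display selections
(ribosome display, phage display) of a randomized protein scaffold against a
target antigen. Two observations drive the design:

1. Read counts after several rounds of capture and PCR reflect amplification
   efficiency and local sequence context as much as affinity, so a few
   sequences dominate the reads while genuinely selected families hide in
   the tail. The pipeline therefore clusters the set of *unique* protein
   sequences and uses read counts only as metadata.
2. Selected binders are accompanied by a mutational halo of near-neighbour
   variants that survive selection because they barely change affinity.
   Clustering by a physicochemical amino-acid distance groups each binder
   with its halo, and a per-cluster consensus recovers the underlying
   binder sequence.

## Read funnel

Paired amplicon reads are merged on their overlap (greedy maximal overlap of
at least 12 nt with mismatch fraction <= 0.1; at overlap mismatches the
higher-quality base wins, ties to read 1). The constant primer-tail flanks
are located by substitution-only scanning (<= 2 mismatches per flank,
reverse complement tried if the forward search fails); the insert strictly
between them is translated with the standard genetic code. Reads are
rejected — and counted, so that the funnel conserves every read exactly
once — for failed merging, missing flanks, out-of-frame insert length,
ambiguous codons, internal stops, or off-design protein length. Surviving
proteins are deduplicated into one pool per round.

Greedy maximal overlap can, on pathologically repetitive inserts, prefer a
longer overlap with a few mismatches over a shorter perfect one; randomized
NNS inserts are effectively never repetitive at that scale. Indel-tolerant
flank matching is deliberately omitted: an indel in a constant primer
region breaks the reading frame regardless.

Cysteine-containing sequences are kept by default (an optional
`drop_cysteine` flag removes them; in practice such clones often bind
non-specifically, but removal is a curation decision, not an algorithmic
one).

## Grantham distance and clustering

The residue distance is computed from the composition/polarity/volume
formula `D = rho * sqrt(1.833 dc^2 + 0.1018 dp^2 + 0.000399 dv^2)` with the
scale `rho` fixed so the 190 distinct pairwise distances average exactly
100, then rounded to integers. This reproduces the familiar table values
(Leu-Ile 5; Cys-Trp 215, the maximum). A handful of entries of the
historically printed table differ by one unit from the formula (the printed
table is known to be internally inconsistent); the computed-and-rounded
matrix is used throughout for self-consistency.

Sequence distance is the **sum** of per-position residue distances (not the
mean), so the whole-sequence distance decomposes exactly into the
per-position heatmap rows; the mean is a rescale and available as an
option. Comparison can be restricted to the design's randomized positions.

Clustering is agglomerative (average linkage by default; complete/single
available) on the all-pairs distance matrix of the unique sequences,
flattened at a distance cutoff, or to a requested number of clusters when
one is given. Sequences are sorted lexicographically before the matrix is
built, and all tie-breaks (consensus residues, representative picking) fall
back to frequency/size then alphabetical order, making every output
deterministic under input reordering.

The per-cluster consensus takes, at each position, the residue among those
observed there that minimizes the summed Grantham distance to the members'
residues (ties: higher frequency, then alphabet). This Grantham-coherent
consensus is self-consistent with the distance used for the heatmap; a
plain-majority mode exists. For two-member clusters the summed distance is
symmetric in the two observed residues, so the alphabetical tie-break
decides — a documented consequence of the rule, not an accident.

Representatives are picked by deterministic greedy max-min: seed with the
largest cluster's consensus, then repeatedly add the consensus whose
minimum distance to the chosen set is largest. This covers the diversity of
the dendrogram with a fixed budget of clones to synthesize.

The logo matrix is the per-position residue frequency over unique sequences
(columns sum to 1); the heatmap matrix stacks each sequence's per-position
distance profile to its cluster consensus.

## Selection-campaign simulator

Real selection pools from the kind of campaign this package targets are
generally not deposited, so the generator plants known truth and emulates
the processes that make count-based analysis misleading:

- **Library**: fixed scaffold codons plus NNS codons (stop-free sense
  subset) at the randomized positions; planted binder families are spiked
  at configurable initial frequencies as a parent plus per-position halo
  substitutions (`halo_rate`; optionally bounded in Grantham distance).
- **Capture**: binomial survival per molecule at the family fitness, or a
  background rate for non-binders. Under *competition* elution, only
  families of the competable epitope class keep their fitness; others drop
  to background — modeling elution with a competitor binder as class
  gating, since only the selective consequence matters downstream.
- **Mutation**: substitution-only RT/PCR errors per base per round
  (indels are excluded by design; frameshift handling is exercised through
  the funnel's rejection path instead).
- **Amplification**: per-sequence i.i.d. log-normal factors
  (`pcr_bias_sd`) followed by multinomial resampling to a fixed carrying
  capacity. This reproduces count-ranking distortion without modeling PCR
  cycles; at zero mutation it leaves the unique-sequence set unchanged as
  long as the capacity is large relative to the number of unique members.
- **Sequencing**: reads drawn multinomially, flanks attached, substitution
  errors per base, fixed Q40 qualities, paired FASTQ plus a truth ledger
  naming each read's source and family.

In the infinite-population limit one round enriches a binder family from
frequency `f` to `f' = f w / (f w + (1-f) b)`; the stochastic simulation
matches this in expectation (tested at n = 1e5), has no drift under neutral
capture (martingale test over 200 replicate rounds), and is byte-identical
under a fixed seed.

Defaults (background capture 5e-3, mutation 1e-4 /base/round, bias sigma
0.5, sequencing error 1e-3 /base, 2e4 reads and 1e5 molecules per round)
are chosen to make enrichment well-conditioned at desk scale; they are
deliberately modest problem sizes, and all are exposed in `CampaignConfig`.
What the simulator does **not** emulate: indels, chimeric PCR products,
quality-score structure, affinity-dependent competition kinetics, and the
actual scaffold sequence of any published library (the default design's
scaffold is a synthetic Sul7d-like stand-in). Passing recovery tests
therefore show correctness of the analysis under the modeled noise
processes, not performance on any particular real campaign.

## Binding and cytotoxicity quantitation

**Single-cycle kinetics.** Increasing analyte concentrations are injected
back-to-back (default 12.5/25/50/100/200 nM, 120 s each) with one final
600 s dissociation, no regeneration between steps. The 1:1 Langmuir model
is `dR/dt = ka C(t) (Rmax - R) - kd R`, `KD = kd/ka`. The bivalent-analyte
model adds a crosslinking step `AL + L <-> AL2` with `ka2` in 1/(RU s)
(the response-unit convention of SPR evaluation software), free-ligand
conservation `L = Rmax - AL - 2 AL2`, response `AL + AL2`, and apparent
`KD = kd1/ka1`; at `ka2 = 0` it reduces exactly to the 1:1 model.

Forward traces use a fixed-step classical Runge-Kutta integrator
(dt = 0.1 s default) for cross-platform reproducibility; the 1:1 trace
agrees with the piecewise-exponential closed form to ~1e-12 of Rmax.
Fits are bounded least squares in log10-parameter space with 5 seeded
log-uniform multi-starts (ka in [1e3, 1e7] 1/(M s), kd in [1e-5, 1e-1]
1/s); the best residual sum of squares wins. The 1:1 fit evaluates the
closed form; the bivalent fit integrates at 1 s steps inside the optimizer
(accurate to well below the fitted noise for these rate scales).
Degenerate input (no signal span, or residuals comparable to the signal)
raises a non-convergence error carrying diagnostics.

Noiseless round trips recover generating parameters to <0.1% (1:1) and
<0.5% (bivalent, apparent KD). With 1% Gaussian noise the 1:1 KD stays
within 5% on every one of 50 seeded replicates. The bivalent model is
weakly identified — ka1/kd1 trade against the crosslinking step — so on
some noise draws even the global optimum deviates by >5% in apparent KD;
its accuracy is therefore characterized in the mean (<10% over seeded
replicates) rather than per replicate. Mass-transport limitation, global
multi-curve fitting, and drift correction are out of scope; sensorgrams
are assumed reference-subtracted upstream.

**Dose-response.** The one-site model `Y = top X / (h + X)` is fit with
`h` in log space, which makes the fit exactly equivariant under rescaling
of the dose axis; `Y(h) = top/2` by construction. A warning is issued when
the largest dose is below 3x the fitted half-dose (plateau unreached).

**Cytotoxicity and screening.** Specific lysis is
`(experimental - spontaneous) / (maximal - spontaneous) * 100` with
plate-mean controls, reported unclipped. ELISA positivity requires a
specific/aspecific signal ratio strictly above 10. RMFI is the sample
median fluorescence over the control median. Fold changes are plain
ratios, used by the report generator for affinity-improvement tables.

## Problem sizes in the test suite

Tests run at desk scale: pools of tens to hundreds of sequences, campaigns
of 2-5 thousand to 1e5 molecules, 12-family recovery with 15 members per
family, 50-replicate noise studies for the fast fitters and 5 for the
ODE-based bivalent fitter. The brute-force clustering oracle is applied to
pools of at most 12 sequences, where first-principles agglomeration is
exhaustive; draws whose merge order is not uniquely defined (exact distance
ties) are excluded, since no flat partition is well-defined there.

## Known limitations

- Unequal-length sequences are rejected rather than aligned; pools are
  design-length by construction.
- The integer-rounded Grantham matrix reproduces the published table for
  the anchor entries but differs by one unit on a few pairs where the
  historically printed table disagrees with its own formula.
- The bivalent fit reports the apparent affinity of the first binding
  step; avidity is summarized, not decomposed.
- Cluster count depends on the cutoff (or is user-fixed); no criterion for
  choosing it automatically is provided.
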