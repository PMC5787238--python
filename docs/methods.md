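# Methods

## Problem and model

The package estimates the composition of a bacterial community from
short-read amplicon sequencing of several independently PCR-amplified
regions of the 16S rRNA gene. The statistical unit is the full-length
reference sequence ("bacterium" *j*, *J* in total); the data are the
retained unique reads *i* with multiplicities, pooled over regions.

**Reference representation.** Reference sequences with IUPAC ambiguity
codes are expanded into every concrete variant (alphabetical order at each
position); records with more than three ambiguous positions are discarded,
so a record yields at most 4³ = 64 variants. Expanded variants are distinct
taxa for reconstruction but keep their source id for reporting. A taxon is
*amplified* in a region when both primers place with at most two
substitution mismatches (IUPAC-aware, no indels) and the inter-primer
amplicon is non-empty. Primer sites are found by scanning the whole forward
strand for the fewest-mismatch window (leftmost on ties), the reverse site
only downstream of the forward one; on sequences ≤ 2 kb this scan is tested
against an independent brute-force oracle. Amplicon coordinates are 0-based
half-open and exclude primer bases, because reads are primer-trimmed before
matching. An amplicon shorter than the read length k is treated as not
amplified: real amplicons (~200–250 bp) always exceed Illumina-length
reads, so the short case is a degenerate corner we resolve conservatively.

**Mixture matrix.** For paired-end data each (taxon, amplified region)
contributes one k-mer — the first k bases of the amplicon concatenated with
the first k bases of its reverse complement — with weight
M.. = 1/R(j), where R(j) is the taxon's number of amplified regions; for
single-end data the two k-length ends are separate rows with weight
0.5/R(j). Columns of amplified taxa sum to one. A k-mer occurring in two
regions occupies two rows; identical k-mers within one region share a row
(weights accumulate).

**Read model and likelihood.** A read matches a same-region k-mer with
probability (p_e/3)^n_e (1−p_e)^(L−n_e) under a constant per-base error
rate p_e (default 0.005) and independence across the L compared bases;
pairs with more than two mismatches are treated as probability zero and not
stored. The community likelihood is ∏_i ∑_j Q_ij π_j with Q = E·M, concave
in π over the simplex, maximized by the multiplicative EM fixed point with
each unique read's term weighted by its count (identical to per-read
iteration). Final frequencies normalize π by R to undo the fact that a
taxon amplified in more regions emits proportionally more reads.

## Filters

* **Quality** (per read, defaults configurable): discard iff strictly more
  than 25% of bases are below Phred 30, or strictly more than 3 bases are
  below Phred 10, or any base call is ambiguous.
* **Demultiplexing**: reads are assigned to the unique primer matching with
  ≤ 2 mismatches after removing the barcode; ties and non-matches go to an
  unassigned bin. Sample-level barcode demultiplexing is out of scope
  (barcode length defaults to 0).
* **Low-frequency reads**: after exact-sequence collapsing, a unique read
  is discarded iff its count is strictly below 1e-4 × the region's
  pre-filter total, setting a 0.01% detection floor.
* **Candidate bacteria**: a taxon is excluded when some region amplifies it
  with a perfect primer match yet none of its k-mers there received any
  read. The rule is vacuous for taxa amplified only through mismatched
  primer sites; those are retained regardless of support. Taxa with no
  matched k-mer anywhere are additionally pruned before EM purely for
  efficiency — the update zeroes them after one iteration, so the fit is
  unchanged.

## Numerical choices

* EM starts uniform on the candidates; convergence is max-absolute change
  in π below 1e-8 (cap 10,000 iterations). The update works on ratios —
  stable because stored E entries are bounded below by
  (p_e/3)² (1−p_e)^L — while the log-likelihood trace is accumulated in log
  space and asserted non-decreasing.
* π entries below 1e-12 are zeroed before normalization (numeric cleanup
  far below any reportable frequency).
* Correctness of the optimizer is checked against an independent dense
  simplex grid search on ≤ 3-taxon instances. A step-1e-3 coarse scan alone
  cannot certify a 1e-6 log-likelihood agreement (the quadratic loss over a
  half-step offset exceeds it), so the oracle refines locally around the
  best coarse point at step 1e-5; the coarse grid remains the independent
  global scan, justified by concavity.

## Groups, ambiguity, post-processing

Supported sequences sharing identical k-mers over *all* amplified regions
(footprints include not-amplified markers) form a group; group frequency is
the summed x of members. Per profiled organism, ambiguity is the exponent
of the natural-log Shannon entropy of the per-sequence weight vector built
by splitting each matched group's frequency equally among its members and
normalizing. Equal within-group splitting is the unique convention
consistent with the single-group case, where ambiguity must equal group
size; natural log makes the effective number base-independent. Group-to-
organism matching uses species-level labels from the reference taxonomy (a
deterministic, offline stand-in for an online classification service); the
rank is configurable.

Post-processing merges groups sharing the species label (frequencies
added), discards merged entries below 0.1%, and renormalizes.

## Simulation conditions

The simulator reproduces the benchmark conditions of the method: communities
of 100 members drawn uniformly from the reference with 1/rank frequencies
(the bottom half of such a community carries ~13% of the mass), a total
budget of 200,000 reads split equally across regions (remainder to the
lowest-numbered regions), multinomial read draws within a region from the
members amplified there (frequencies renormalized — non-amplified members
drop out of that region's PCR), and i.i.d. uniform substitution errors at a
configurable rate (default 0.005). The published error model for the read
simulator it emulates is not specified at the level of parameters, so the
uniform-substitution model stands in; the only property the pipeline
exercises is mismatch-tolerant matching. An `exact_proportions` mode
apportions counts deterministically (largest remainder) for known-answer
fixtures. Reconstructions are scored by weighted recall Σ f_m·I_m and
weighted precision Σ x_r·I_r with indicators set by *exact* full-length
sequence identity — a single mismatch counts as an error. The incremental
region experiment orders regions greedily to maximize the number of
distinct footprint groups at each step (ties to the lowest id) and keeps
the total read budget constant as regions are added.

**Synthetic references.** Toy references embed exact primer sites around
random amplicons (default 60 nt, k = 20), optionally drawing a region's
amplicons from a small pool to engineer shared footprints. They emulate the
combinatorial structure of real 16S databases — shared regions, partial
amplification, primer mismatches — but not their phylogenetic correlation,
length variation, chimeras, or copy-number variation; passing tests
demonstrate the estimator's correctness under the model, not robustness to
real-data artifacts such as PCR bias, which the multi-region design only
averages. Test and demonstration problem sizes (200-taxon references,
5,000-read simulations, 20 seeds) were chosen as the smallest scales at
which the resolution effects are unambiguous.

## Known limitations

* The error model in the likelihood is position-independent and
  substitution-only; quality scores inform filtering but not E.
* 16S copy-number differences between organisms are not corrected.
* Reads matching no k-mer are excluded from N rather than modeled by an
  outlier class, so heavily contaminated samples inflate nothing but are
  silently under-counted in the likelihood.
* Frequencies for known-answer fixtures are exact only when the read budget
  divides evenly across regions and members; otherwise deterministic
  apportionment leaves O(1/N) deviations.
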