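# Methods

## Model

A mutational catalog is a vector **v** ∈ ℕ₀^ξ of mutation counts over a
fixed alphabet of ξ mutation channels (for single-base substitutions,
the 96 pyrimidine-strand trinucleotide channels). A mutational signature is
a probability mass function over the same alphabet; n signatures form the
columns of S ∈ ℝ₊^(ξ×n). Assignment assumes the catalog is a superposition
of signatures,

    v ≈ S a,  a ≥ 0,

and estimates the activity vector a (mutations attributed to each
signature) by nonnegative least squares,

    min_{a ≥ 0} ‖v − S a‖₂²,

scored by the relative error ε = ‖v − S a‖₂² / ‖v‖₂². The NNLS subproblem
is solved with the Lawson–Hanson active-set method (`scipy.optimize.nnls`),
which is exact up to numerical tolerance.

## Sparse selection

Fitting all reference signatures at once overfits: with 79 candidate
columns, noise is absorbed by spurious low-activity signatures. Sparsity is
obtained by alternating greedy passes around NNLS:

1. **Full fit.** ε_min is computed on the complete reference set (the
   activities of this fit are discarded; only the error floor is kept).
2. **Backward removal.** Among the selected signatures, repeatedly remove
   the one whose removal raises ε least, as long as that increase is at
   most the removal threshold (default **0.01**) and at least one signature
   remains. ε_min is updated after every accepted removal, so the budget is
   per removal, not per pass.
3. **Forward addition.** Among excluded signatures, repeatedly add back the
   one whose inclusion lowers ε most, as long as that decrease is at least
   the addition threshold (default **0.05**). Candidates are always drawn
   from the full original reference, including signatures dropped in
   earlier passes.
4. Repeat 2–3 until a full pass changes nothing (a hard cap of 100 passes
   guards against cycling, with a warning; in practice convergence takes a
   handful of passes).

Both threshold comparisons are inclusive (≤ for removal, ≥ for addition).
Ties between candidate moves (ε within 1e-12) go to the earliest column in
the reference's order, making runs exactly reproducible. The final NNLS
activities on the selected set are rounded to nonnegative integers (half
away from zero); signatures rounding to zero are dropped. No redistribution
forces Σa to equal Σv: rounding slack is at most 0.5 per selected
signature, and the stored relative error is recomputed from the integer
activities so results are self-consistent.

A mathematically exact shortcut is used during removal scans: a candidate
whose coefficient in the current NNLS solution is exactly zero cannot
change the minimizer when removed, so its ε equals ε_min without a solve.
This prunes most of the work when starting from a large reference, where
the initial fit already zeroes most coefficients.

### Detectability floor

The removal threshold implies a resolution limit that users should know:
removing a signature whose activity-weighted column satisfies
‖a_t s_t‖₂² ≲ 0.01 · ‖v‖₂² costs less than the threshold and is therefore
pruned — by design. Concretely, a signature contributing less than roughly
10% of the catalog's L2 mass (for near-orthogonal signatures, activity
below ~10% of the dominant signature's) cannot be detected, regardless of
noise. This is the sparsity mechanism, not a defect: it trades sensitivity
to faint processes for near-perfect precision.

## Per-mutation probabilities

Given the selected signatures and activities, the probability that a
mutation of channel k was caused by signature t is its share of the
reconstructed count,

    p_kt = s_kt · a_t / (S a)_k,

computed from the reconstruction (S a)_k, not the observed count, even
where the two differ. Rows with positive reconstruction sum to 1 (checked
to 1e-9); channels with zero reconstructed count are uninformative and
flagged. Per-mutation annotation requires a list of individual mutations
(VCF/MAF); a matrix input only yields the per-channel table, since a
spectrum carries no information about individual variants.

## Reconstruction metrics

For each fitted sample the package reports cosine similarity, Kullback–
Leibler divergence, Pearson correlation, and L1/L2 relative errors between
observed and reconstructed spectra. KL is computed between the two spectra
normalized to probability distributions with cells floored at 1e-12 before
the logarithm (the floor is a numerical choice; no smoothing rule is
canonical). Pearson is computed on raw counts. An all-zero observed
spectrum is an error; zero-count samples are skipped upstream and flagged.

## Benchmark scoring

Estimated activities are compared with ground truth per sample at the level
of signature presence/absence: TP = assigned (≥1 mutation) and truly
active, FP = assigned but truly absent, FN = truly active but unassigned.
Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 = their harmonic mean.
Degenerate denominators: a sample with no assignments gets precision 1.0
(it made no false claims) and a sample with no truly active signatures gets
sensitivity 1.0; F1 is 0 when both are 0. Per-sample scores are averaged
per noise level. These conventions are documented choices, not canon.

## Synthetic cohorts

The simulator emulates refitting benchmarks built from cancer cohorts:

- **Structure.** 9 groups ("cancer types") × 30 samples by default; a pool
  of 21 ground-truth signatures drawn from the reference; each group uses 4
  of them; every sample of a group is active for all of its group's
  signatures.
- **Activities.** Per-signature mutation counts are log-uniform between 10
  and 5,000 by default — a scale-free spread covering the dynamic range of
  mutational burdens.
- **Counts.** Each signature's mutations are drawn multinomially over
  channels, so catalogs are integer counts and the per-sample total equals
  the total ground-truth activity exactly at 0% noise.
- **Noise.** Non-systematic noise multiplies each channel count by a factor
  uniform in [1 − η, 1 + η] (η ∈ {0, 0.05, 0.10} in the standard protocol),
  then rounds to nonnegative integers. Separate RNG streams for structure
  and noise make the pre-noise cohort identical across noise levels at a
  fixed seed.
- **Synthetic signatures.** Columns are sparse symmetric-Dirichlet draws
  (concentration 0.1), concentrating mass on a few channels as real
  signatures do; an optional rejection step enforces a maximum pairwise
  cosine for well-separated references.

What the simulator does **not** emulate: the correlation structure of real
reference signatures (flat, overlapping signatures make selection harder
than separated synthetic ones), realistic per-cancer-type activity
distributions (real benchmark ground truths derive from sparse fits of
real tumors and therefore concentrate above the detectability floor,
whereas log-uniform activities place a large fraction below it), and
systematic (non-random) noise. Passing synthetic benchmarks therefore
demonstrates correctness of the engine and scoring, not field performance
on real genomes. In particular, under the default log-uniform activities
roughly 40% of ground-truth activities fall below the detectability floor,
capping mean sensitivity near 0.6 while precision stays ≥ 0.99 — the
measured benchmark numbers reflect the activity distribution as much as
the engine. An exact-reproduction mode accepts externally produced
catalog + ground-truth tables directly (`sigassign benchmark --catalog
... --truth ...`), for scoring on published benchmark datasets.

## Problem sizes and numerics

The standard in-repo protocol uses 270 samples per noise level with a
79-signature reference (~1 minute per level on one core thanks to the
zero-coefficient shortcut). Solver agreement is verified against exhaustive
active-set enumeration (all 2^q supports) at q ≤ 6, and the greedy path is
verified step-by-step against a literal candidate-scan transcription at
n ≤ 8, ξ = 96. Signature columns are renormalized on load (zero columns
are errors); catalogs are reordered to the signature file's channel order,
and any unmatched label is an error rather than a silent misalignment.

## Input conventions

Coordinates are 1-based (VCF convention); the context window is
[pos−1, pos+1]. Multi-allelic VCF records are split per alt allele; only
single-base substitutions are classified; variants with non-ACGT alleles or
contexts (e.g. N-containing), reference mismatches, or flanks beyond contig
ends are skipped and tallied by reason. MAF input uses only the minimal
column set (Chromosome, Start_Position, Reference_Allele, Tumor_Seq_Allele2,
Tumor_Sample_Barcode). The reference genome is user-supplied FASTA; no
genome is bundled.
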