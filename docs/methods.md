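# Methods

This note documents the models, defaults, and numerical choices behind
`thermorca`, and what the synthetic study conditions do and do not show
about real screening data.

## The engineering loop

The pipeline models an iterative design-build-test campaign for a
heat-labile enzyme. One pass of the loop is:

1. **Curate** a candidate ortholog set against the reference (wildtype)
   sequence: keep candidates with pairwise identity > 0.20 and length
   ≥ 140 residues, strip predicted chloroplast transit peptides, align,
   and trim gap-heavy columns/rows.
2. **Screen** for ATPase activity at room temperature and after 1 h heat
   shocks at 38/42/46/50 °C; summarize each sequence by its activity flag
   and its maximum tolerated shock temperature (tmax).
3. **Train** a variational autoencoder on the one-hot MSA, with a
   semi-supervised head predicting the measured labels.
4. **Design** the next round by Gaussian sampling of the latent space
   around the wildtype embedding, decoding, rejecting anything more than
   20 substitutions from the wildtype, and ranking by predicted tmax.
5. Screen the designs, append labels, retrain, repeat.

In software the wet-lab stage is an `AssayOracle`; the trace simulator,
a results-table lookup, and real plate data are interchangeable behind it.

## Sequence VAE

**Model.** Input is the flattened one-hot alignment (L columns × 21
symbols; the gap is a first-class symbol). The encoder is an MLP
(default widths 256, 64) producing a diagonal-Gaussian posterior
q(z|x) = N(μ(x), diag σ²(x)) over a 4-dimensional latent; the decoder
mirrors it (64, 256) and emits per-column categorical distributions via a
position-wise softmax. Training maximizes the ELBO: the reconstruction
term is the categorical log-likelihood under a single reparameterized
sample, the KL term is closed-form,
KL = ½ Σ_d (μ_d² + σ_d² − 1 − log σ_d²) ≥ 0, weighted by `kl_weight`
(default 1) with a linear warm-up over the first 10% of epochs to avoid
early posterior collapse.

**Semi-supervision.** A one-hidden-layer head (16 units) on the posterior
mean μ predicts standardized tmax (squared error) and the activity flag
(logistic cross-entropy), summed over labeled rows only and weighted by
`property_weight` (λ, default 1). Missing labels are masked, never
imputed. With λ = 0 the encoder/decoder trajectory is identical to the
unsupervised run under the same seed (the head draws its initial weights
from an independent stream), which the tests exploit as a reduction check.

**Optimization.** Hand-written backpropagation in numpy, verified against
central finite differences to ~1e-6 relative error, with Adam
(lr 1e-3), decoupled weight decay 1e-4 on weight matrices, and
column-level input dropout 0.3 in a denoising configuration (the encoder
sees a corrupted input; the decoder reconstructs the clean one-hot).
The default batch size is 32: at the few-hundred-sequence scales this
package targets, full-batch training gives the optimizer only `epochs`
parameter updates, which measurably underfits the supervised head
(held-out rank correlation ~0.55 vs ~0.85 with minibatching on the
planted fixture); full batch remains available (`batch_size=0`) and is
used where permutation-invariance of the objective matters. One global
seed drives initialization and all reparameterization draws, so training
is bit-reproducible. Log-variances are clipped to ±10; a non-finite loss
raises a divergence error carrying the epoch and history.

## Latent-space design

Candidates are drawn from a diagonal Gaussian centered at the wildtype's
posterior mean. The sampling standard deviation is `sigma_scale` × 1 per
dimension — **prior units** — by default. Posterior units
(`sigma_scale · σ(x_wt)`) are also available, but a well-fit posterior is
much tighter than the prior (σ ≈ 0.25–0.4 here), and sampling at that
scale explores so small a neighborhood that per-position argmax decoding
returns only a handful of distinct sequences; in prior units the sampler
comfortably yields tens of thousands of distinct candidates. Decoding is
deterministic argmax (one sequence per latent point; ties break to the
fixed alphabet order). The rejection stage enforces, on every emitted
variant: Hamming distance to the wildtype ≤ `max_hamming` (default 20,
with the gap counted as a symbol), no duplicates, not the wildtype, and
not previously tested. Sampling proceeds in chunks until the request is
filled or an attempt cap of 100 × n_candidates is reached, at which point
a "sampler starved" error reports the acceptance rate. Design rounds
oversample 4×, rank by predicted tmax (ties: fewer mutations, then
lexical id), and return the top n.

## Screen analytics

The coupled assay converts ATP hydrolysis into NADH oxidation, read as an
A340 decrease, so activity appears as a negative initial slope and — in
the permissive long-endpoint screen — as near-complete substrate
depletion. Two call modes are provided:

- **endpoint** (default, matching a ~16 h permissive read): active iff
  the total A340 drop exceeds 50% of the unshocked positive control's
  drop;
- **kinetic**: active iff the initial least-squares slope (default window:
  first 25% of readings) is below the no-enzyme control slope by more
  than 3 control standard deviations. A small absolute tolerance (1e-9
  ΔA340/min) absorbs float-level jitter on perfectly flat traces, so a
  rate exactly equal to control is always inactive.

tmax assignment: inactive at RT → "inactive"; active at RT only →
"RT-only"; otherwise the maximum shock temperature with an active call
(non-monotone patterns resolve to the maximum and are logged). Tallies
count a sequence with tmax = T at every ladder temperature ≤ T, so ladder
counts are non-increasing by construction, and active + inactive = tested
exactly. "Active above T" defaults to tmax ≥ T (configurable to strict).
Concentration normalization targets 5 µM; under-concentrated wells run
neat and carry an "undiluted" flag.

## Synthetic study conditions

The generator exists so that every downstream stage has a ground truth.

**MSA.** Sequences are sampled around a random wildtype with per-column
conservation (default 0.9 — the marginal probability of the wildtype
residue; 3 alternate residues per column). Variation is correlated across
columns through a latent-factor model: each row draws u ~ N(0, I₂) and
column j deviates when u·a_j crosses a threshold calibrated to the
column's conservation (a_j a fixed random unit loading), plus 2% iid flip
noise. This is the minimal structure that makes an MSA informative for a
latent-variable model — with fully independent columns the ELBO optimum
ignores z, the decoder collapses to the consensus, and latent sampling
cannot produce variants at all. It is *not* a phylogeny: there is no
tree, no evolutionary time, and rows are exchangeable. Consequences for
interpretation: passing tests show the pipeline recovers planted,
factor-correlated signal; they do not show robustness to phylogenetic
confounding (shared ancestry mimicking functional covariation), alignment
error, or insertion/deletion structure (generated MSAs are gap-free by
default, though the model and distances fully support gaps).

**Phenotype.** tmax is a pure function of genotype:
`base_tmax` 38 °C + `delta_tmax` 8 °C per key position carrying its
stabilizing residue (default: one proline→glycine position, echoing the
single-mutation stabilized variant such a screen can find). The
stability–activity trade-off multiplies the catalytic rate by
`activity_scale` = 0.3 per stabilizing substitution. Sequences deviating
from the wildtype at any "fragile" column (10 by default, conservation
0.97 — columns where any substitution kills activity are under strong
purifying selection) are inactive outright, which produces the large
inactive fraction a natural screen shows. Heat shock is a step function:
full activity at or below tmax, none above; graded thermal damage is out
of scope.

**Traces.** A340(t) = max(A0 − r·t, floor) + N(0, sd²), with A0 = 1
(arbitrary units; the source screen reports no absolute amplitudes),
floor 0.05, base rate 0.02 ΔA340/min, observation noise sd 0.005. The
simulated screen's default endpoint is 960 min (~16 h): long enough that
a stabilized variant at 30% wildtype rate still exhausts the substrate,
which is precisely why the permissive screen is run long — at short
endpoints the endpoint call systematically misses slow-but-stable
enzymes (the screen's most interesting class).

## Feasibility of the recovery check

The parameter-recovery test plants the signal at one key column and asks
the semi-supervised head to rank held-out variants (Spearman ≥ 0.7). With
a single binary determinant the held-out truth takes two values, and the
tie-corrected Spearman of even a *perfect* predictor is bounded:
≈ 0.69 at 20% minor-allele frequency, ≈ 0.87 at 50%. The recovery fixture
therefore plants the key column at 50/50 — the information-maximizing
design for a planted-signal experiment — while the campaign generator
keeps the rare-allele default (20%), which is the realistic
natural-screen condition. The trained head reaches ρ ≈ 0.85 on this
fixture, essentially the attainable ceiling.

## Problem sizes

Tests and the acceptance script run deliberately scaled studies chosen as
the package's CPU-scale defaults: 200-sequence × 120-column MSAs for
training checks (a full campaign would use ~2,000 × ~300), campaigns of
100 naturals + 2 × 50 designs (vs ~2,000 + 2 × ~700 at full scale),
10,000-variant constrained-sampling runs, and 60–150 training epochs.
The loop's qualitative behavior (constraint fidelity, recovery,
round-over-round progression, exact tallies) is scale-free; absolute
loss values and acceptance rates are not.

## Known limitations

- The curation identity denominator (global alignment length, BLOSUM62,
  gap open −11 / extend −1) is a documented convention, not a claim about
  how any published set was filtered; a shorter-sequence denominator is
  available.
- The transit-peptide predictor shipped here is a deterministic anchor
  heuristic behind the `CtpPredictor` interface; a real predictor should
  be wrapped for production curation.
- The VAE claims the loss *structure* (ELBO + optional supervised head),
  not any published architecture or weights; hyperparameters are this
  package's CPU-scale choices.
- Replay of a deposited results table is exercised against synthetic
  stand-in tables with known planted counts; column synonyms for external
  dialects are configurable in `screening.TABLE_SYNONYMS`.
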