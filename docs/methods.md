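# Methods

## Problem setting

T-cell receptors recognise short peptides (epitopes) presented on MHC
molecules; the third complementarity-determining region of the β chain
(CDR3β) is the most variable loop and the dominant determinant of
specificity. `tcrdiff` addresses two coupled tasks: (i) generating CDR3β
sequences specific to a given epitope with a denoising diffusion
probabilistic model (DDPM) operating on nucleotide one-hot encodings, and
(ii) predicting TCR–epitope binding with a classifier built on the
denoiser's encoder.

## Data representation

CDR3β amino-acid sequences of length 7–24 are back-translated to
nucleotides using one fixed codon per residue — the most frequently used
human codon, shipped as a 20-row TSV resource and user-overridable. The
nucleotide string is one-hot encoded over channels (A, T, G, C) as
A=[1,0,0,0], T=[0,1,0,0], G=[0,0,1,0], C=[0,0,0,1] into a fixed 72×4 matrix
(24 residues × 3 nt), zero-padded beyond the true length. There is no fifth
"pad" channel; padding is the all-zero row.

Decoding a real-valued matrix back to a sequence scans positions left to
right, emits the arg-max channel, and terminates at the first row whose
maximum falls below `pad_threshold` (default 0.5); the result is trimmed to
a whole number of codons. Ties break by channel order A>T>G>C. This is the
minimal decoder consistent with the encoding; the threshold is the natural
midpoint of the {0,1} channel values.

By default the diffusion operates on recentred encodings x ∈ {−1,+1}
(`rescale=True`), mapped back to [0,1] before decoding. Raw {0,1} channels
sit far from the unit-variance Gaussian noise scale, which degrades the
signal-to-noise ratio of the reverse process; recentring is the standard
image-diffusion convention and is exposed as a flag.

## Diffusion model

The forward process is the fixed Markov chain
q(X_t|X_{t−1}) = N(√(1−β_t)·X_{t−1}, β_t·I) with a linear schedule
β_1 = 10⁻⁴ … β_T = 0.1 over T = 10 steps. With α_t = 1−β_t and
ᾱ_t = Π_{s≤t} α_s the closed form is X_t = √ᾱ_t·X_0 + √(1−ᾱ_t)·ε. The
denoiser ε_θ(X_t, t, e) is trained by the MSE noise-prediction objective
L(θ) = E‖ε − ε_θ(X_t, t, e)‖², with Adam (lr 10⁻⁴ at full scale; the
desk-scale runs below use 3·10⁻³). Training stops early when the epoch loss
fails to improve by ≥0.001 for three consecutive epochs, or at `max_epochs`.

The denoiser is a mirrored 1-D convolutional U-Net along the 72-position
axis: channel ladder 64→128→256→512 by default (the last entry is the
encoder bottleneck width, 512), kernel 3, residual blocks of two
convolutions with group normalisation and SiLU, stride-2 down-sampling
(72→36→18→9) and nearest-neighbour up-sampling with skip connections fused
by a 1×1 convolution. The timestep enters as a 128-dim sinusoidal embedding
through a two-layer MLP; the epitope enters as a fixed 1024-dim embedding.
Both conditioning signals are projected per block to the block's channel
width and broadcast-added after the first convolution ("project and
inject"). Exact depth, widths and injection mechanics are configuration,
not claims; only the bottleneck width, the mirrored structure with skips,
and the per-layer conditioning are part of the model contract.

Because no deep-learning framework is assumed, the network, its layers, and
Adam are implemented on a small reverse-mode automatic-differentiation
engine over numpy arrays (`tcrdiff._autograd`, `tcrdiff.nn`), with gradient
correctness verified against central finite differences in the test suite's
development and training determinism guaranteed by routing all randomness
through one `numpy.random.Generator`.

### Sampling, and the short-schedule caveat

Ancestral sampling runs X_{t−1} = (X_t − β_t/√(1−ᾱ_t)·ε_θ)/√α_t + σ_t·z
from t = T down to 1, with z = 0 at the final step. The default reverse
variance is the forward-posterior value σ_t² = β_t·(1−ᾱ_{t−1})/(1−ᾱ_t);
σ_t² = β_t is available by configuration. With only 10 steps and β ≤ 0.1
the posterior variance is the measurably better choice: the β variant
over-injects noise near t = T and blurs reconstruction tails.

A structural property of this schedule is that ᾱ_T ≈ 0.595: the forward
process never converges to the N(0, I) prior, so a reverse chain started
from pure noise is evaluated far outside the marginals the denoiser was
trained on, and prior-started samples are weakly structured. The package
therefore exposes two generation modes:

* `ancestral_sample` — the textbook prior-started chain (kept as the
  documented sampler contract, and useful with longer schedules);
* `reconstruct_sequences` — forward-corrupt a reference TCR to X_T and run
  the learned reverse chain. This is the regime the model is trained in and
  produces paired original/generated sequences; all evaluation-grade
  generation uses it.

## Epitope conditioning

Every epitope maps to a 1024-dimensional vector. The default encoder is a
deterministic, weight-free featurization: hashed k-mer counts (k = 1..3)
plus sinusoidal positional features folded into 1024 bins by a stable
(seed-independent) hash, unit-normalised. It is injective in practice,
position-sensitive, needs no network access, and makes every pipeline run
reproducible. A pre-trained protein language-model adapter (ProtT5-XL,
mean-pooled per-residue states truncated to 1024) sits behind the same
interface for environments with the optional `transformers` dependency; the
pooling choice is this package's, since only the (1, 1024) shape is part of
the contract. Any deterministic callable returning a 1024-vector is
accepted.

## Binding predictors

Two variants share the form: encoder (down-sampling stage of the U-Net) →
global-average-pooled bottleneck features → concatenation with the epitope
embedding → a stack of linear layers with SiLU and dropout 0.6 on the input
of every layer except the final one → sigmoid.

* **epiBP**: seven linear layers, no HLA information.
* **epiStarBP**: five linear layers; a locus-level HLA one-hot
  (HLA-A=[1,0,0], HLA-B=[0,1,0], HLA-C=[0,0,1]) is concatenated to the
  input of every head layer.

Head widths taper geometrically from the concatenated input width to 1;
head weights use a He-style (√6-gain) uniform initialization, without which
the deep SiLU stack attenuates input variation to near-constant logits.
The encoder is fine-tuned jointly with the head by default; a freeze flag
supports ablation. Training minimises binary cross-entropy with Adam, holds
out one fifth of the pairs (disjoint by (CDR3β, epitope) key), and records
per-epoch held-out accuracy and F1.

## Evaluation statistics

* **Position-wise Pearson**: for each nucleotide position, the Pearson
  correlation between the two sets' 4-entry frequency columns (their
  position-frequency-matrix columns). Positions where either column has
  zero variance, or that one set never reaches, are flagged undefined
  rather than given a number. Operationalising "correlation at each
  position" as PFM-column correlation is this package's reading.
* **Cosine similarity**: over flattened zero-padded one-hot encodings;
  padding contributes zeros to both vectors, so the statistic is bounded in
  [0, 1] for one-hot inputs. Nucleotide encodings are used, matching the
  model's native representation.
* **Latents**: encoder bottleneck features of clean inputs (t = 0, zero
  conditioning vector, so the latent reflects the TCR sequence alone),
  pooled over positions to one vector of the bottleneck width. The default
  pooling is the per-channel root-mean-square: it keeps a channel's
  response to a sequence feature visible regardless of where along the loop
  it fires, which matters because CDR3β lengths vary; mean and max pooling
  are exposed alternatives.
* **Map**: PCA to 10 components, then UMAP (n_neighbors=15, min_dist=0.3,
  n_components=2, metric=hamming, spread=0.5), seeded.
* **k-NN purity** (k = 5): mean fraction of a point's k nearest Euclidean
  neighbours in the PCA-10 space sharing its label, self excluded.
* **Classification metrics**: accuracy, F1 and confusion counts at a 0.5
  probability threshold.
* **PFM export**: column-stochastic per-position frequencies over the
  nucleotide or amino-acid alphabet, normalised by per-position coverage so
  variable-length sets are handled; written as TSV for logo-rendering
  tools.

## Synthetic data

The generator emulates the statistical structure of curated
epitope-specific repertoires without claiming biology: each epitope class
is a random 9-mer with a class core motif; its TCRs are
`prefix + mutated core + random filler + suffix` with the conserved
germline-like termini (default prefix "CASS", suffix "F"), per-position
core mutation at `mutation_rate`, and lengths uniform within the 7–24
filter. Class motifs are sampled to differ pairwise in at least half their
positions, guaranteeing separability; HLA loci are assigned uniformly per
class. A healthy pool shares the termini but draws cores independent of
every class motif (cores equal to a motif are rejected). All output is
deterministic given the spec seed.

What the synthetic corpus does **not** emulate: V(D)J recombination
statistics, codon usage beyond the fixed back-translation table, epitope
biochemistry, or any real binding energetics. Passing tests on it
demonstrates that the machinery recovers planted structure under the
model's assumptions — not that the model reproduces real repertoires.

## Desk-scale study conditions

The self-contained study that the tests and `scripts/acceptance.py` run
uses: a two-class corpus (50 TCRs per class, mutation-free cores, seed
fixed), a 300-TCR healthy pool, and a reduced U-Net (channel ladder
16→32→64, i.e. a 64-wide bottleneck, 72→36→18) trained for 2400 epochs of
batch-8 Adam at lr 3·10⁻³ with early stopping disabled — about five minutes
on one CPU. The binding predictors train on 200 balanced pairs (100
cognate, 100 healthy-pool negatives) for 120 epochs at lr 3·10⁻⁴. These sizes are the
package's chosen demonstration conditions; the full-scale defaults
(512-wide bottleneck, lr 10⁻⁴, early stopping on) remain the package
defaults for real corpora.

## Numerical choices and degenerate inputs

* All schedule algebra is float64; ᾱ is an exact cumulative product, and
  the invariant ᾱ_t/ᾱ_{t−1} = α_t holds to machine precision.
* Non-finite denoiser outputs or reverse-chain intermediates raise
  immediately, naming the offending timestep.
* The decoder is total on finite inputs; empty decodes (every row below
  threshold) yield the empty string, which downstream IO flags rather than
  silently drops.
* Negative sampling rejects collisions with the positive set and with
  already-emitted pairs, and raises after a bounded number of attempts if
  the pool cannot supply enough distinct pairs.
* Duplicate (CDR3β, epitope) rows are deduplicated before splitting to
  prevent leakage across the generation/prediction halves.
* The 50/50 split is an unstratified uniform partition over pairs; sizes
  differ by at most one.

## Known limitations

* The short 10-step schedule makes prior-started ancestral sampling
  mismatched by construction (see above); faithful generation requires a
  reference set to corrupt, which limits de-novo use of this exact
  schedule. Longer schedules fix this but depart from the printed setup.
* The default epitope encoder is a featurizer, not a learned language
  model; it preserves identity and composition, not biophysics. Conclusions
  about epitope-similarity structure in the latent space require the
  language-model adapter.
* The numpy training stack is single-threaded and CPU-bound; it is sized
  for the desk-scale study, not for repertoire-scale corpora.
* Binding-predictor metrics on synthetic data reflect planted separability
  and say nothing about accuracy on curated databases.
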