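# tcrdiff

Epitope-conditioned generation of T-cell receptor CDR3β sequences with a
denoising diffusion probabilistic model, plus TCR–epitope binding prediction
built on the model's encoder.

## Who this is for

Computational immunologists who want to (a) propose candidate CDR3β
sequences for a target epitope, (b) score TCR–epitope pairs for binding,
or (c) study how a diffusion model represents repertoire structure — all
from sequence data alone, with a fully self-contained synthetic benchmark
so nothing needs to be downloaded.

## The model

CDR3β amino-acid sequences (length 7–24) are back-translated to nucleotides
with the most frequent human codon per residue and one-hot encoded over
(A, T, G, C) into 72×4 matrices. A forward diffusion process corrupts an
encoding X₀ over T = 10 steps with Gaussian noise under a linear schedule
β₁ = 10⁻⁴ … β₁₀ = 0.1:

    q(X_t | X_{t−1}) = N(√(1−β_t)·X_{t−1}, β_t·I)
    X_t = √ᾱ_t·X₀ + √(1−ᾱ_t)·ε,   α_t = 1−β_t,  ᾱ_t = Π_{s≤t} α_s

A conditional 1-D U-Net ε_θ(X_t, t, e) — mirrored encoder/decoder with skip
connections, a 512-dim bottleneck by default, sinusoidal timestep
embeddings, and a 1024-dim epitope embedding e injected at every level — is
trained to predict the noise by minimising L(θ) = E‖ε − ε_θ(X_t, t, e)‖².
Sampling runs the learned reverse chain; decoded matrices are read back to
nucleotides (arg-max with a padding threshold) and translated to peptides.

Two binding predictors extend the trained encoder with linear heads:
**TCR-epiBP** (7 layers, no HLA) and **TCR-epi\*BP** (5 layers, with a
locus-level HLA one-hot concatenated into every head layer); dropout 0.6 on
all but the final layer.

The neural network stack (layers, autodiff, Adam) is implemented in numpy
inside the package, so the only dependencies are the standard scientific
Python stack. See `docs/methods.md` for the full model description, design
choices, and limitations.

## Worked example

Train a small denoiser on one synthetic epitope class and inspect what it
learned (about five minutes on one CPU):

```python
from tcrdiff.pipeline import demo_corpus, train_demo_generator, consensus_recovery
from tcrdiff.diffusion import reconstruct_sequences
from tcrdiff.evaluation import mean_cosine, knn_purity, extract_latents
from tcrdiff.seq_codec import translate

by_class, epitopes, healthy, spec = demo_corpus(seed=7, healthy_n=300)
net, schedule, trace = train_demo_generator(by_class[0], seed=1)

seqs, _ = reconstruct_sequences(net, schedule, by_class[0], epitopes[0], seed=5)
aas = [translate(s)[0] if s else "" for s in seqs]
print("recovery:", consensus_recovery(aas, spec.prefix, spec.suffix))
print("example: ", aas[0])

gen = [s for s in seqs if s]
cos_a, _ = mean_cosine(gen, [p.tcr.nt for p in by_class[0]], l_max=72)
cos_h, _ = mean_cosine(gen, [h.nt for h in healthy], l_max=72)
print(f"cosine vs cognate {cos_a:.3f} vs healthy {cos_h:.3f}")

pairs = [p for cls in by_class for p in cls]
latents = extract_latents(net, [p.tcr for p in pairs])
print("k-NN purity:", knn_purity(latents, [p.epitope for p in pairs], k=5))
```

Typical output:

```
recovery: 0.96
example:  CASSDLTHLMNNMYTF
cosine vs cognate 0.635 vs healthy 0.474
k-NN purity: 0.952
```

Reading the numbers: 96% of generated sequences carry the conserved
germline-like "CASS…F" termini of the training class; generated sequences
are far closer (cosine over one-hot encodings) to the cognate
epitope-specific TCRs than to unrelated healthy-donor TCRs; and the
encoder's latent space separates the two epitope classes almost perfectly
(k = 5 neighbour purity 0.95 in PCA-10 space).

The same workflow is available from the shell:

```bash
tcrdiff simulate --out-dir data --seed 7
tcrdiff train-gen --pairs data/pairs.tsv --out-dir run --channels 16,32,64 --seed 1
tcrdiff generate --checkpoint run/generator.ckpt --epitope GILGFVFTL -n 8 --out gen.fasta
# train-bp needs both labels: concatenate data/pairs.tsv and data/negatives.tsv first
tcrdiff train-bp --pairs data/all_pairs.tsv --checkpoint run/generator.ckpt --out-dir bp
tcrdiff evaluate --generated gen.fasta --reference data/pairs.tsv --out-dir report
```

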