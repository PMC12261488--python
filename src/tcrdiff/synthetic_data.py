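"""Synthetic CDR3β repertoires with the statistical structure the model assumes.

Real CDR3β loops carry conserved terminal residues (a cysteine-anchored
"CASS…" prefix from the germline V segment and a phenylalanine-containing
J-segment suffix) around a hypervariable middle. The generator emulates this:
each synthetic epitope class shares a core motif (with per-position mutation
noise), flanked by the conserved prefix/suffix and random filler residues,
at lengths inside the 7–24 filter. A "healthy pool" provides TCRs with the
same termini but cores independent of every class motif, for negative
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import BindingPair, TcrRecord
from .seq_codec import STANDARD_AA, back_translate

__all__ = ["SyntheticSpec", "generate_repertoire", "generate_healthy_pool"]

HLA_LOCI = ("A", "B", "C")


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic repertoire.

    Defaults mirror the structure of curated epitope-specific repertoires:
    45–60 cognate TCRs per epitope, lengths inside the 7–24 filter, a
    "CASS" prefix and "F" suffix, and 9-mer epitopes.
    """

    n_epitopes: int = 2
    tcrs_per_epitope: tuple[int, int] = (45, 60)
    length_range: tuple[int, int] = (7, 24)
    prefix: str = "CASS"
    suffix: str = "F"
    motif_len: int = 4
    mutation_rate: float = 0.1
    epitope_len: int = 9
    seed: int = 0
    motifs: list[str] = field(default_factory=list)  # filled at generation time

    def validate(self) -> None:
        fixed = len(self.prefix) + self.motif_len + len(self.suffix)
        if fixed > 24:
            raise SpecError(f"prefix+motif+suffix length {fixed} exceeds 24")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise SpecError("mutation_rate must be in [0, 1]")
        lo, hi = self.length_range
        if not (7 <= lo <= hi <= 24):
            raise SpecError("length_range must lie within [7, 24]")
        if hi < fixed:
            raise SpecError(
                f"length_range upper bound {hi} cannot fit prefix+motif+suffix ({fixed})"
            )

    @property
    def min_length(self) -> int:
        return max(self.length_range[0], len(self.prefix) + self.motif_len + len(self.suffix))


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def _sample_motifs(rng: np.random.Generator, n: int, length: int, max_tries: int = 10000) -> list[str]:
    """Class motifs differing pairwise in at least half their positions."""
    motifs: list[str] = []
    tries = 0
    while len(motifs) < n:
        if tries >= max_tries:
            raise SpecError("could not sample sufficiently distinct class motifs")
        tries += 1
        cand = _random_peptide(rng, length)
        if all(sum(a != b for a, b in zip(cand, m)) >= length / 2 for m in motifs):
            motifs.append(cand)
    return motifs


def _mutate(rng: np.random.Generator, core: str, rate: float) -> str:
    if rate == 0.0:
        return core
    chars = list(core)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = STANDARD_AA[int(rng.integers(len(STANDARD_AA)))]
    return "".join(chars)


def _build_cdr3b(rng: np.random.Generator, spec: SyntheticSpec, core: str) -> str:
    length = int(rng.integers(spec.min_length, spec.length_range[1] + 1))
    n_filler = length - len(spec.prefix) - len(core) - len(spec.suffix)
    filler = _random_peptide(rng, n_filler) if n_filler > 0 else ""
    return spec.prefix + core + filler + spec.suffix


def generate_repertoire(spec: SyntheticSpec) -> tuple[list[BindingPair], list[str]]:
    """Generate cognate (TCR, epitope) pairs for ``spec.n_epitopes`` classes.

    Each class gets a random 9-mer epitope and a class motif; its TCRs are
    prefix + mutated motif + random filler + suffix, all labelled binders.
    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    epitopes = [_random_peptide(rng, spec.epitope_len) for _ in range(spec.n_epitopes)]
    spec.motifs = _sample_motifs(rng, spec.n_epitopes, spec.motif_len)
    lo, hi = spec.tcrs_per_epitope
    pairs: list[BindingPair] = []
    for epi, motif in zip(epitopes, spec.motifs):
        n_tcrs = int(rng.integers(lo, hi + 1))
        hla = HLA_LOCI[int(rng.integers(3))]  # one locus per epitope class
        for _ in range(n_tcrs):
            core = _mutate(rng, motif, spec.mutation_rate)
            cdr3b = _build_cdr3b(rng, spec, core)
            rec = TcrRecord(
                cdr3b=cdr3b, nt=back_translate(cdr3b), epitope=epi,
                hla_locus=hla, label=1, source="synthetic",
            )
            pairs.append(BindingPair(tcr=rec, epitope=epi, label=1))
    return pairs, epitopes


def generate_healthy_pool(n: int, spec: SyntheticSpec) -> list[TcrRecord]:
    """TCRs with the conserved termini but cores unrelated to any class motif.

    Requires ``generate_repertoire`` to have filled ``spec.motifs`` (or an
    empty motif list, in which case any core is acceptable). Cores equal to a
    class motif are rejected and resampled.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from the repertoire stream
    forbidden = set(spec.motifs)
    out: list[TcrRecord] = []
    while len(out) < n:
        core = _random_peptide(rng, spec.motif_len)
        if core in forbidden:
            continue
        cdr3b = _build_cdr3b(rng, spec, core)
        out.append(
            TcrRecord(cdr3b=cdr3b, nt=back_translate(cdr3b),
                      hla_locus=None, label=None, source="synthetic-healthy")
        )
    return out
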