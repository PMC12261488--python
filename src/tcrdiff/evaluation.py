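"""Quantitative evaluations of generated repertoires and predictors.

Position-wise Pearson correlation between the nucleotide-frequency profiles of
two sequence sets, cosine similarity over flattened one-hot encodings, latent
extraction from the denoiser's encoder, PCA→UMAP mapping, k-NN label purity,
classification metrics, and position-frequency-matrix export for logo tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_codec import NT_CHANNELS, STANDARD_AA, one_hot_encode

__all__ = [
    "PositionFrequencyMatrix",
    "LatentEmbedding",
    "positionwise_pearson",
    "mean_cosine",
    "extract_latents",
    "latent_map",
    "knn_purity",
    "classification_metrics",
    "pfm_export",
]


# ---------------------------------------------------------------------------
# Position frequency matrices and position-wise correlation
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Per-position symbol frequencies (column-stochastic over used positions)."""

    matrix: np.ndarray  # L x |alphabet|
    counts_total: np.ndarray  # sequences covering each position
    alphabet: str

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.alphabet))
        df.insert(0, "position", np.arange(len(df)))
        df["n"] = self.counts_total
        df.to_csv(path, sep="\t", index=False)


def pfm_export(sequences: list[str], alphabet: str = "nt") -> PositionFrequencyMatrix:
    """Count symbol frequencies per position across a sequence set.

    Sequences may differ in length; each position's frequencies are normalized
    by the number of sequences that reach it.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if alphabet == "nt":
        symbols = NT_CHANNELS
    elif alphabet == "aa":
        symbols = STANDARD_AA
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    index = {s: i for i, s in enumerate(symbols)}
    bad = set("".join(sequences)) - set(symbols)
    if bad:
        raise ValueError(f"symbols outside the {alphabet} alphabet: {sorted(bad)}")
    l_max = max(len(s) for s in sequences)
    counts = np.zeros((l_max, len(symbols)))
    totals = np.zeros(l_max)
    for s in sequences:
        for i, c in enumerate(s):
            counts[i, index[c]] += 1.0
            totals[i] += 1.0
    freq = np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0)
    return PositionFrequencyMatrix(matrix=freq, counts_total=totals, alphabet=symbols)


def positionwise_pearson(set_a: list[str], set_b: list[str]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between the two sets' nucleotide-frequency columns, per position.

    Returns ``(r, defined)`` where ``defined[i]`` is False at positions where
    either set's 4-entry frequency column has zero variance (r undefined) or
    is not covered by one of the sets; such entries of ``r`` are NaN.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    pfm_a = pfm_export(set_a, "nt")
    pfm_b = pfm_export(set_b, "nt")
    length = max(len(pfm_a.matrix), len(pfm_b.matrix))

    def col(pfm, i):
        return pfm.matrix[i] if i < len(pfm.matrix) and pfm.counts_total[i] > 0 else None

    r = np.full(length, np.nan)
    defined = np.zeros(length, dtype=bool)
    for i in range(length):
        a, b = col(pfm_a, i), col(pfm_b, i)
        if a is None or b is None:
            continue
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        ac, bc = a - a.mean(), b - b.mean()
        r[i] = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        defined[i] = True
    return r, defined


# ---------------------------------------------------------------------------
# Cosine similarity over one-hot encodings
# ---------------------------------------------------------------------------

def _flatten_onehots(seqs: list[str], l_max: int) -> np.ndarray:
    return np.stack([one_hot_encode(s, l_max).matrix.ravel() for s in seqs])


def mean_cosine(set_a: list[str], set_b: list[str], l_max: int | None = None
                ) -> tuple[float, np.ndarray]:
    """Mean and full pairwise cosine-similarity matrix between two sets.

    Sequences are one-hot encoded, zero-padded to a common length, and
    flattened; padding contributes zeros to both vectors.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    if l_max is None:
        l_max = max(len(s) for s in set_a + set_b)
    a = _flatten_onehots(set_a, l_max)
    b = _flatten_onehots(set_b, l_max)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-vector input")
    sim = (a @ b.T) / np.outer(na, nb)
    return float(sim.mean()), sim


# ---------------------------------------------------------------------------
# Latent-space analysis
# ---------------------------------------------------------------------------

@dataclass
class LatentEmbedding:
    vector: np.ndarray
    tcr_id: str
    epitope: str | None = None


def extract_latents(denoiser, tcrs, encoder=None, pooling: str = "rms",
                    ) -> list[LatentEmbedding]:
    """Encoder-bottleneck features for clean (uncorrupted, t=0) inputs.

    The conditioning vector is zeroed so the latent reflects the TCR sequence
    alone. Features are pooled over positions to one vector of the bottleneck
    width per TCR; the default is the per-channel root-mean-square, which
    keeps a channel's response to a sequence feature visible regardless of
    where along the loop it fires ("mean" and "max" are also accepted).
    """
    from .corpus import TcrRecord  # noqa: F401

    cfg = denoiser.config
    xs, ids, epis = [], [], []
    for rec in tcrs:
        rec = rec.with_nt()
        m = one_hot_encode(rec.nt, cfg.l_max).matrix.T
        xs.append(2.0 * m - 1.0 if cfg.rescale else m)
        ids.append(rec.cdr3b)
        epis.append(rec.epitope)
    x = np.stack(xs)
    cond = np.zeros(cfg.cond_dim)
    h = denoiser.encode(x, 0, cond).data
    if pooling == "rms":
        feats = np.sqrt((h ** 2).mean(axis=2))
    elif pooling == "mean":
        feats = h.mean(axis=2)
    elif pooling == "max":
        feats = h.max(axis=2)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return [LatentEmbedding(vector=feats[i], tcr_id=ids[i], epitope=epis[i])
            for i in range(len(tcrs))]


def _latent_matrix(latents) -> np.ndarray:
    return np.stack([l.vector for l in latents])


def pca_reduce(latents, n_components: int = 10, seed: int = 0) -> np.ndarray:
    from sklearn.decomposition import PCA

    x = _latent_matrix(latents)
    n_components = min(n_components, x.shape[0], x.shape[1])
    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def latent_map(latents, seed: int = 0) -> np.ndarray:
    """PCA to 10 components, then UMAP to 2-D.

    UMAP runs with n_neighbors=15, min_dist=0.3, n_components=2,
    metric="hamming", spread=0.5; seeded for reproducibility.
    """
    import umap

    if len(latents) < 16:
        raise ValueError("need at least 16 points for the UMAP neighbourhood")
    reduced = pca_reduce(latents, 10, seed)
    reducer = umap.UMAP(n_neighbors=15, min_dist=0.3, n_components=2,
                        metric="hamming", spread=0.5, random_state=seed)
    return np.asarray(reducer.fit_transform(reduced))


def knn_purity(latents, labels: list | None = None, k: int = 5) -> float:
    """Mean fraction of each point's k nearest neighbours sharing its label.

    Distances are Euclidean in the PCA-10 space; the point itself is excluded
    from its neighbourhood.
    """
    from sklearn.neighbors import NearestNeighbors

    if labels is None:
        labels = [l.epitope for l in latents]
    labels = np.asarray(labels)
    n = len(latents)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    if len(set(labels.tolist())) < 2:
        return 1.0
    x = pca_reduce(latents, 10)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = idx[:, 1:]  # drop self
    same = labels[neigh] == labels[:, None]
    return float(same.mean())


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def classification_metrics(labels, predictions, threshold: float = 0.5) -> dict:
    """Accuracy, F1, and confusion counts at a probability threshold."""
    from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    pred = (predictions >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    return {
        "accuracy": float(accuracy_score(labels, pred)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn),
    }
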