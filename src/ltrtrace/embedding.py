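"""Distances between module sequences and their 3D embedding.

Pairwise Levenshtein (unit-cost edit) distances over the module-id alphabet
are reduced to three dimensions with t-SNE. The embedding rests on a radial
assumption: older elements carry shorter module sequences and small mutual
distances, so they collect near the center, while recent elements from
different evolutionary branches point outward. Angles between centered
coordinates then become the distance for clustering, and the rank
correlation between module-sequence length and distance from the center is
the diagnostic for whether the assumption holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats
from sklearn.manifold import TSNE

from .modseq import ModuleSequence

__all__ = [
    "EmbedParams",
    "Embedding",
    "deduplicate_sequences",
    "levenshtein",
    "levenshtein_matrix",
    "embed_3d",
    "radial_correlation",
    "angular_matrix",
]


@dataclass(frozen=True)
class EmbedParams:
    perplexity: float = 50.0
    early_exaggeration: float = 12.0
    learning_rate: float = 200.0
    seed: int = 42


@dataclass
class Embedding:
    coords: np.ndarray  # (n, 3)
    params: EmbedParams
    radial_corr: float | None = None

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def centered(self) -> np.ndarray:
        return self.coords - self.center

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.centered, axis=1)


def deduplicate_sequences(
    sequences: list[ModuleSequence],
) -> tuple[list[tuple[str, ...]], list[list[int]]]:
    """Collapse identical module sequences to one representative point.

    Returns the unique sequences (as tuples, first-seen order) and, for each,
    the indices of the input sequences it represents. Collapsing keeps the
    t-SNE perplexity meaningful when bursts produce many identical copies.
    """
    uniq: dict[tuple[str, ...], int] = {}
    groups: list[list[int]] = []
    order: list[tuple[str, ...]] = []
    for i, s in enumerate(sequences):
        key = tuple(s.mods)
        if key not in uniq:
            uniq[key] = len(order)
            order.append(key)
            groups.append([])
        groups[uniq[key]].append(i)
    return order, groups


def _levenshtein_dp(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein(a: tuple[str, ...] | list[str], b: tuple[str, ...] | list[str]) -> int:
    """Unit-cost edit distance between two module-id sequences."""
    return _levenshtein_dp(tuple(a), tuple(b))


def levenshtein_matrix(sequences: list[ModuleSequence] | list[tuple[str, ...]]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of edit distances over module symbols.

    Module ids are mapped to single characters so edlib's bit-parallel
    algorithm can be used; datasets with more than 255 distinct module ids
    fall back to the plain dynamic program.
    """
    seqs = [tuple(s.mods) if isinstance(s, ModuleSequence) else tuple(s) for s in sequences]
    alphabet = sorted({m for s in seqs for m in s})
    n = len(seqs)
    mat = np.zeros((n, n), dtype=float)
    if len(alphabet) <= 255:
        # chr(1)..: edlib treats input as a plain character string
        code = {m: chr(i + 1) for i, m in enumerate(alphabet)}
        strs = ["".join(code[m] for m in s) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                d = edlib.align(strs[i], strs[j], mode="NW", task="distance")["editDistance"]
                mat[i, j] = mat[j, i] = d
    else:
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = _levenshtein_dp(seqs[i], seqs[j])
    return mat


def embed_3d(
    distmatrix: np.ndarray,
    params: EmbedParams | None = None,
    seq_lengths: np.ndarray | None = None,
) -> Embedding:
    """Reduce a precomputed distance matrix to 3D with t-SNE.

    The Barnes-Hut solver is used; for a fixed seed it reproduces coordinates
    bit-for-bit. If ``seq_lengths`` is given, the radial-assumption
    diagnostic (Spearman correlation of sequence length vs distance from
    center; expected > 0) is stored on the result.
    """
    params = params or EmbedParams()
    D = np.asarray(distmatrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if params.perplexity >= n:
        raise ValueError(
            f"perplexity ({params.perplexity}) must be below the number of points "
            f"({n}); the usual adjustment range is 50-500 for large datasets, "
            "or reduce it for small ones"
        )
    tsne = TSNE(
        n_components=3,
        metric="precomputed",
        method="barnes_hut",
        init="random",
        perplexity=params.perplexity,
        early_exaggeration=params.early_exaggeration,
        learning_rate=params.learning_rate,
        random_state=params.seed,
    )
    coords = tsne.fit_transform(D)
    emb = Embedding(coords=np.asarray(coords, dtype=float), params=params)
    if seq_lengths is not None:
        emb.radial_corr = radial_correlation(emb, np.asarray(seq_lengths))
    return emb


def radial_correlation(embedding: Embedding, seq_lengths: np.ndarray) -> float:
    """Spearman rank correlation between module-sequence length and distance
    from the embedding center. Positive values support the radial assumption
    (longer, younger sequences farther out)."""
    norms = embedding.norms
    if np.allclose(norms, norms[0]) or np.allclose(seq_lengths, seq_lengths[0]):
        return 0.0
    rho = stats.spearmanr(seq_lengths, norms).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def angular_matrix(embedding: Embedding, atol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise angles in [0, pi] between centered coordinates.

    Returns (angles, valid) where ``valid`` marks points with non-zero
    centered norm; rows/columns of points sitting exactly at the center are
    NaN and such points are excluded from angular clustering (flagged
    low-confidence downstream).
    """
    X = embedding.centered
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for angular distances")
    norms = np.linalg.norm(X, axis=1)
    valid = norms > atol
    angles = np.full((n, n), np.nan)
    idx = np.flatnonzero(valid)
    U = X[idx] / norms[idx, None]
    cosine = np.clip(U @ U.T, -1.0, 1.0)
    sub = np.arccos(cosine)
    np.fill_diagonal(sub, 0.0)
    angles[np.ix_(idx, idx)] = sub
    return angles, valid
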