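"""Word embeddings and antonym-pair semantic axes.

A semantic axis is a unit vector built from antonym pairs: average the
difference vectors v(plus pole) - v(minus pole) over the pairs of a packaged
vocabulary (severity, gender, toxicity, expense) and normalize. A term's
meaning along the axis is the cosine of its vector with the axis vector, and
those projections are correlated against external ground-truth attributes
(disease burden, gender prevalence, LD50, price) by Pearson's r with a
t-based two-sided p value.

Embeddings are trained in-package by a compact word2vec implementation
(CBOW or skip-gram with negative sampling, mini-batched numpy SGD) that is
deterministic given a seed, or loaded from the standard word2vec text
format. Multiword terms are underscore-joined tokens; a lookup for an
out-of-vocabulary multiword term falls back to the mean of its in-vocabulary
constituent words, and the fallback is recorded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "EmbeddingSpace",
    "Word2Vec",
    "AntonymPairSet",
    "SemanticAxis",
    "ProjectionReport",
    "PACKAGED_AXES",
    "load_axis_pairs",
    "build_axis",
    "project",
    "project_many",
    "correlate_with_groundtruth",
    "dimensional_robustness",
    "load_word2vec_text",
    "save_word2vec_text",
    "read_attribute_table",
]

PACKAGED_AXES = ("severity", "gender", "toxicity", "expense")


# ---------------------------------------------------------------------------
# containers


class EmbeddingSpace:
    """Token -> vector mapping with a fixed dimension."""

    def __init__(
        self,
        vectors: dict[str, np.ndarray],
        metadata: dict | None = None,
    ):
        if not vectors:
            raise ValueError("empty embedding space")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector lengths: {sorted(dims)}")
        self.d = dims.pop()
        self.vectors = {t: np.asarray(v, dtype=np.float64) for t, v in vectors.items()}
        for t, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite components in vector for {t!r}")
        self.metadata = metadata or {}

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def lookup(self, term: str) -> tuple[np.ndarray, bool]:
        """Vector for ``term``; returns (vector, used_constituent_fallback).

        An out-of-vocabulary underscore-joined multiword term falls back to
        the mean of its in-vocabulary constituent words.
        """
        if term in self.vectors:
            return self.vectors[term], False
        if "_" in term:
            parts = [p for p in term.split("_") if p in self.vectors]
            if parts:
                return np.mean([self.vectors[p] for p in parts], axis=0), True
        raise KeyError(f"term not in vocabulary: {term!r}")


@dataclass(frozen=True)
class AntonymPairSet:
    """Named, ordered antonym vocabulary: (plus pole, minus pole) pairs."""

    name: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("need >= 1 antonym pair")
        for plus, minus in self.pairs:
            if plus == minus:
                raise ValueError(f"degenerate pair ({plus!r}, {minus!r})")


@dataclass
class SemanticAxis:
    name: str
    vector: np.ndarray  # unit norm
    pairs_used: int
    pairs_dropped: list[tuple[str, str]] = field(default_factory=list)
    fallbacks: list[str] = field(default_factory=list)


@dataclass
class ProjectionReport:
    """Axis projections matched against a ground-truth attribute."""

    scores: dict[str, float]
    groundtruth: dict[str, float]
    r: float
    p: float
    n: int
    method: str = "pearson"
    unmatched: list[str] = field(default_factory=list)


def load_axis_pairs(axis: str | Path) -> AntonymPairSet:
    """A packaged axis by name (severity/gender/toxicity/expense) or a
    two-column TSV file of (plus, minus) poles, one pair per line."""
    if isinstance(axis, str) and axis in PACKAGED_AXES:
        text = (resources.files("nero.data") / "axes" / f"{axis}.tsv").read_text(
            encoding="utf-8"
        )
        name = axis
    else:
        text = Path(axis).read_text(encoding="utf-8")
        name = Path(axis).stem
    pairs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        plus, minus = line.rstrip("\n").split("\t")
        pairs.append((plus.strip(), minus.strip()))
    return AntonymPairSet(name, tuple(pairs))


# ---------------------------------------------------------------------------
# word2vec trainer


class Word2Vec(BaseEstimator):
    """Compact word2vec with negative sampling, deterministic given a seed.

    Parameters mirror the usual word2vec knobs: ``d`` embedding dimension,
    ``window`` sentence context window, ``epochs`` training passes,
    ``architecture`` "cbow" (default) or "skipgram", ``negative`` negative
    samples per example, ``min_count`` vocabulary floor, ``alpha`` initial
    learning rate (linearly decayed).

    Attributes after ``fit``: ``space_`` (:class:`EmbeddingSpace`),
    ``vocab_`` (token -> row index).
    """

    def __init__(
        self,
        d: int = 300,
        window: int = 10,
        epochs: int = 20,
        architecture: str = "cbow",
        min_count: int = 1,
        negative: int = 5,
        alpha: float = 0.025,
        batch_size: int = 256,
        seed: int = 0,
    ):
        self.d = d
        self.window = window
        self.epochs = epochs
        self.architecture = architecture
        self.min_count = min_count
        self.negative = negative
        self.alpha = alpha
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, sentences: Iterable[Sequence[str]], y=None):
        if self.architecture not in {"cbow", "skipgram"}:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        sents = [list(s) for s in sentences]
        if not sents or all(not s for s in sents):
            raise ValueError("empty sentence stream")
        counts = Counter(tok for s in sents for tok in s)
        vocab_tokens = sorted(
            (t for t, c in counts.items() if c >= self.min_count),
            key=lambda t: (-counts[t], t),
        )
        if not vocab_tokens:
            raise ValueError("no token meets min_count")
        vocab = {t: i for i, t in enumerate(vocab_tokens)}
        V = len(vocab)
        rng = np.random.default_rng(self.seed)

        # flatten corpus; per-position context indices with a padding row V
        encoded = [
            np.array([vocab[t] for t in s if t in vocab], dtype=np.int64)
            for s in sents
        ]
        encoded = [e for e in encoded if len(e) > 0]
        flat = np.concatenate(encoded)
        lengths = np.array([len(e) for e in encoded])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        n_pos = len(flat)
        pos = np.arange(n_pos)
        sent_idx = np.searchsorted(offsets, pos, side="right") - 1
        lo = offsets[sent_idx]
        hi = offsets[sent_idx + 1]
        w = self.window
        ctx = np.full((n_pos, 2 * w), V, dtype=np.int64)
        col = 0
        for off in range(-w, w + 1):
            if off == 0:
                continue
            j = pos + off
            ok = (j >= lo) & (j < hi)
            ctx[ok, col] = flat[j[ok]]
            col += 1
        has_ctx = (ctx != V).any(axis=1)
        positions = pos[has_ctx]

        # unigram^0.75 negative-sampling table
        freqs = np.bincount(flat, minlength=V).astype(np.float64)
        noise = freqs**0.75
        noise_cdf = np.cumsum(noise / noise.sum())

        W_in = (rng.random((V + 1, self.d), dtype=np.float64) - 0.5) / self.d
        W_in[V] = 0.0
        W_out = np.zeros((V, self.d), dtype=np.float64)

        K = self.negative
        n_batches_total = self.epochs * max(1, int(np.ceil(len(positions) / self.batch_size)))
        batch_no = 0
        labels = None

        def scatter_update(W: np.ndarray, idx: np.ndarray, grad: np.ndarray) -> None:
            np.add.at(W, idx.reshape(-1), -grad.reshape(-1, grad.shape[-1]))
        for _ in range(self.epochs):
            order = rng.permutation(len(positions))
            for start in range(0, len(order), self.batch_size):
                batch = positions[order[start : start + self.batch_size]]
                lr = self.alpha * max(
                    1e-4, 1.0 - batch_no / max(1, n_batches_total)
                )
                batch_no += 1
                c_idx = ctx[batch]  # (B, 2w)
                mask = (c_idx != V).astype(np.float64)
                centers = flat[batch]
                negs = np.searchsorted(
                    noise_cdf, rng.random((len(batch), K))
                ).astype(np.int64)
                out_idx = np.concatenate([centers[:, None], negs], axis=1)
                if labels is None or labels.shape[0] != len(batch):
                    labels = np.zeros((len(batch), K + 1))
                    labels[:, 0] = 1.0
                if self.architecture == "cbow":
                    weights = mask / np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
                    h = np.einsum("bcd,bc->bd", W_in[c_idx], weights)
                    U = W_out[out_idx]
                    logits = np.clip(np.einsum("bd,bkd->bk", h, U), -6.0, 6.0)
                    g = (expit(logits) - labels) * lr
                    grad_h = np.einsum("bk,bkd->bd", g, U)
                    scatter_update(W_out, out_idx, g[:, :, None] * h[:, None, :])
                    scatter_update(
                        W_in, c_idx, grad_h[:, None, :] * weights[:, :, None]
                    )
                    W_in[V] = 0.0  # padding row stays inert
                else:  # skipgram: predict each context word from the center
                    for c in range(2 * w):
                        tgt = c_idx[:, c]
                        live = tgt != V
                        if not live.any():
                            continue
                        ctr = centers[live]
                        h = W_in[ctr]
                        oi = np.concatenate(
                            [tgt[live][:, None], negs[live]], axis=1
                        )
                        U = W_out[oi]
                        lab = np.zeros((len(ctr), K + 1))
                        lab[:, 0] = 1.0
                        logits = np.clip(np.einsum("bd,bkd->bk", h, U), -6.0, 6.0)
                        g = (expit(logits) - lab) * lr
                        scatter_update(W_out, oi, g[:, :, None] * h[:, None, :])
                        scatter_update(
                            W_in, ctr[:, None], np.einsum("bk,bkd->bd", g, U)[:, None, :]
                        )
        vectors = {t: W_in[i].copy() for t, i in vocab.items()}
        self.vocab_ = vocab
        self.space_ = EmbeddingSpace(
            vectors,
            metadata={
                "source": "nero.Word2Vec",
                "config": {
                    "d": self.d,
                    "window": self.window,
                    "epochs": self.epochs,
                    "architecture": self.architecture,
                    "min_count": self.min_count,
                    "negative": self.negative,
                    "alpha": self.alpha,
                    "seed": self.seed,
                },
            },
        )
        return self


def train_embedding(sentences, **kwargs) -> EmbeddingSpace:
    """Functional wrapper over :class:`Word2Vec`."""
    return Word2Vec(**kwargs).fit(sentences).space_


# ---------------------------------------------------------------------------
# axes, projections, correlations


def build_axis(
    space: EmbeddingSpace, pairs: AntonymPairSet | str
) -> SemanticAxis:
    """Mean of (plus - minus) difference vectors over usable pairs, unit-normed.

    Pairs with an unresolvable pole are dropped and recorded; multiword poles
    may resolve through the constituent-mean fallback (recorded too). Raises
    if no pair is usable.
    """
    if isinstance(pairs, str):
        pairs = load_axis_pairs(pairs)
    diffs = []
    dropped: list[tuple[str, str]] = []
    fallbacks: list[str] = []
    for plus, minus in pairs.pairs:
        try:
            v_plus, fb_p = space.lookup(plus)
            v_minus, fb_m = space.lookup(minus)
        except KeyError:
            dropped.append((plus, minus))
            continue
        if fb_p:
            fallbacks.append(plus)
        if fb_m:
            fallbacks.append(minus)
        diffs.append(v_plus - v_minus)
    if not diffs:
        missing = sorted({t for pair in dropped for t in pair if t not in space})
        raise ValueError(
            f"axis {pairs.name!r}: no antonym pair resolvable in vocabulary; "
            f"missing terms: {missing}"
        )
    mean = np.mean(diffs, axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0:
        raise ValueError(f"axis {pairs.name!r}: degenerate (zero) direction")
    return SemanticAxis(
        name=pairs.name,
        vector=mean / norm,
        pairs_used=len(diffs),
        pairs_dropped=dropped,
        fallbacks=fallbacks,
    )


def project(
    space: EmbeddingSpace, axis: SemanticAxis, term: str, mode: str = "cosine"
) -> float:
    """Scalar meaning of ``term`` along ``axis``: cosine (default) or dot."""
    v, _ = space.lookup(term)
    if mode == "dot":
        return float(v @ axis.vector)
    if mode != "cosine":
        raise ValueError(f"unknown projection mode {mode!r}")
    norm = float(np.linalg.norm(v))
    if norm == 0:
        raise ValueError(f"zero vector for term {term!r}")
    return float(v @ axis.vector / norm)


def project_many(
    space: EmbeddingSpace,
    axis: SemanticAxis,
    terms: Iterable[str],
    mode: str = "cosine",
) -> dict[str, float]:
    return {t: project(space, axis, t, mode) for t in terms}


def correlate_with_groundtruth(
    scores: dict[str, float],
    groundtruth: dict[str, float],
    method: str = "pearson",
) -> ProjectionReport:
    """Correlate axis projections with an external attribute table.

    Pearson r with the two-sided t-transform p value by default
    (``method="spearman"`` for rank correlation); requires >= 3 matched terms
    and nonzero variance on both sides.
    """
    matched = sorted(set(scores) & set(groundtruth))
    unmatched = sorted(set(scores) ^ set(groundtruth))
    if len(matched) < 3:
        raise ValueError(f"need >= 3 matched terms, got {len(matched)}")
    x = np.array([scores[t] for t in matched])
    y = np.array([groundtruth[t] for t in matched])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or ground truth")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProjectionReport(
        scores={t: float(scores[t]) for t in matched},
        groundtruth={t: float(groundtruth[t]) for t in matched},
        r=float(r),
        p=float(p),
        n=len(matched),
        method=method,
        unmatched=unmatched,
    )


def dimensional_robustness(
    space_a: EmbeddingSpace,
    space_b: EmbeddingSpace,
    terms: Sequence[str] | None = None,
    method: str = "spearman",
) -> dict:
    """Stability of entity geometry across embedding dimensionalities.

    Correlates the two spaces' pairwise cosine-distance vectors over all
    pairs of shared terms (Spearman rho by default, matching the usual
    reporting of this check). Returns ``{"rho": ..., "n_terms": ...,
    "n_pairs": ...}``.
    """
    if terms is None:
        terms = sorted(set(space_a.vectors) & set(space_b.vectors))
    else:
        terms = list(terms)
        missing = [t for t in terms if t not in space_a or t not in space_b]
        if missing:
            raise KeyError(f"terms missing from a space: {missing}")
    if len(terms) < 3:
        raise ValueError(f"need >= 3 shared terms, got {len(terms)}")
    Xa = np.stack([space_a[t] for t in terms])
    Xb = np.stack([space_b[t] for t in terms])
    da = pdist(Xa, metric="cosine")
    db = pdist(Xb, metric="cosine")
    if np.array_equal(da, db):
        rho = 1.0
    elif method == "spearman":
        rho = float(sps.spearmanr(da, db).statistic)
    elif method == "pearson":
        rho = float(sps.pearsonr(da, db).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"rho": rho, "n_terms": len(terms), "n_pairs": len(da)}


# ---------------------------------------------------------------------------
# I/O


def save_word2vec_text(space: EmbeddingSpace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.d}\n")
        for token in sorted(space.vectors):
            vals = " ".join(repr(float(x)) for x in space.vectors[token])
            fh.write(f"{token} {vals}\n")


def load_word2vec_text(path: str | Path) -> EmbeddingSpace:
    """Standard word2vec text format: header ``vocab_size d`` then one
    ``token v1 .. vd`` line per token."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed header, expected 'vocab_size d'")
        n, d = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            token = parts[0]
            comps = parts[1:]
            if len(comps) != d:
                raise ValueError(
                    f"line {lineno}: expected {d} components, got {len(comps)}"
                )
            if token in vectors:
                raise ValueError(f"line {lineno}: duplicate token {token!r}")
            vectors[token] = np.array([float(x) for x in comps])
    if len(vectors) != n:
        raise ValueError(f"header declared {n} tokens, file has {len(vectors)}")
    return EmbeddingSpace(vectors, metadata={"source": str(path)})


def read_attribute_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (term, value) -> dict; header row optional."""
    out: dict[str, float] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        term, value = line.rstrip("\n").split("\t")[:2]
        if i == 0:
            try:
                float(value)
            except ValueError:
                continue  # header
        out[term.strip()] = float(value)
    return out
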