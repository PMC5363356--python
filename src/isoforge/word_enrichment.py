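"""Signed hypergeometric word-enrichment landscapes over ranked gene lists.

For a gene list ranked (typically by increasing fold change after a miRNA
perturbation) and a word — typically the reverse complement of a seed
hexamer — the landscape at each prefix size n is the hypergeometric tail
probability of the word count observed in the first n genes' 3'UTRs, drawing
the prefix's total word tokens from the pooled totals.  Scores are signed
-log10 p: positive for enrichment in the prefix, negative for depletion.
The default statistic counts occurrences (overlap-counted); a
presence/absence mode over genes is available as an option.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RankedGeneList:
    genes: tuple[str, ...]
    ordering_key: str = "increasing log2 fold change"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked gene list contains duplicate ids")

    @classmethod
    def from_scores(
        cls, scores: Mapping[str, float], ordering_key: str = "increasing log2 fold change"
    ) -> "RankedGeneList":
        # stable sort: fold-change ties keep input order (determinism)
        ranked = sorted(scores, key=lambda g: scores[g])
        return cls(genes=tuple(ranked), ordering_key=ordering_key)

    def __len__(self) -> int:
        return len(self.genes)


def count_words(utr: str, k: int) -> dict[str, int]:
    """Overlap-counted sliding-window word occurrences; empty beyond length."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: Counter[str] = Counter()
    for i in range(len(utr) - k + 1):
        counts[utr[i : i + k]] += 1
    return dict(counts)


@dataclass
class WordCountTable:
    k: int
    per_gene: dict[str, dict[str, int]]
    total_words_per_gene: dict[str, int]

    @classmethod
    def from_utrs(cls, utrs: Mapping[str, str], k: int) -> "WordCountTable":
        per_gene = {g: count_words(seq, k) for g, seq in utrs.items()}
        totals = {g: max(len(seq) - k + 1, 0) for g, seq in utrs.items()}
        return cls(k=k, per_gene=per_gene, total_words_per_gene=totals)

    def total_count(self, word: str) -> int:
        return sum(c.get(word, 0) for c in self.per_gene.values())


@dataclass(frozen=True)
class LandscapePoint:
    word: str
    bin_end: int
    signed_score: float


def _signed_score(x: int, n: int, K: int, T: int) -> float:
    """Signed -log10 hypergeometric tail for x successes in a draw of n from
    a population of T tokens containing K successes."""
    if K == 0 or T == 0 or n == 0:
        return 0.0
    tail_enrich = float(hypergeom.sf(x - 1, T, K, n))
    tail_deplete = float(hypergeom.cdf(x, T, K, n))
    expected = n * K / T
    sign = 1.0 if x > expected else -1.0
    p = min(tail_enrich, tail_deplete)
    p = max(p, np.finfo(float).tiny)
    score = -np.log10(p)
    return 0.0 if score == 0.0 else float(sign * score)


def landscape(
    ranked: RankedGeneList,
    words: Iterable[str],
    counts: WordCountTable,
    bin_step: int = 100,
    mode: str = "counts",
) -> list[LandscapePoint]:
    """Enrichment landscape of each word over growing prefixes of the ranking.

    ``mode="counts"`` draws word tokens (the Sylamer-style statistic);
    ``mode="presence"`` draws genes and scores the number of prefix genes
    containing the word at least once.
    """
    if bin_step < 1:
        raise ValueError(f"bin_step must be >= 1, got {bin_step}")
    if mode not in ("counts", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    words = list(words)
    for w in words:
        if len(w) != counts.k:
            raise ValueError(
                f"word {w!r} has length {len(w)}, table was built with k={counts.k}"
            )
    missing = [g for g in ranked.genes if g not in counts.per_gene]
    if missing:
        raise ValueError(f"genes without UTR counts: {missing[:5]}")
    N = len(ranked)
    bins = list(range(bin_step, N + 1, bin_step))
    if not bins or bins[-1] != N:
        bins.append(N)
    points: list[LandscapePoint] = []
    for word in words:
        if mode == "counts":
            per_gene = np.array(
                [counts.per_gene[g].get(word, 0) for g in ranked.genes]
            )
            draw_sizes = np.array(
                [counts.total_words_per_gene[g] for g in ranked.genes]
            )
        else:
            per_gene = np.array(
                [int(counts.per_gene[g].get(word, 0) > 0) for g in ranked.genes]
            )
            draw_sizes = np.ones(N, dtype=int)
        K = int(per_gene.sum())
        T = int(draw_sizes.sum())
        cum_x = np.cumsum(per_gene)
        cum_n = np.cumsum(draw_sizes)
        for b in bins:
            points.append(
                LandscapePoint(
                    word=word,
                    bin_end=b,
                    signed_score=_signed_score(
                        int(cum_x[b - 1]), int(cum_n[b - 1]), K, T
                    ),
                )
            )
    return points


def landscape_table(points: Sequence[LandscapePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.word, p.bin_end, p.signed_score) for p in points],
        columns=["word", "bin_end", "signed_score"],
    )


def control_words(
    alphabet: str = "ACGU",
    k: int = 6,
    n_words: int = 50,
    rng_seed: int = 0,
    exclude: Iterable[str] = (),
) -> set[str]:
    """Reproducible sample of distinct control words, excluding focal seeds."""
    exclude = set(exclude)
    vocab_size = len(alphabet) ** k
    available = vocab_size - len(exclude)
    if n_words > available:
        raise ValueError(
            f"requested {n_words} words but only {available} are available"
        )
    rng = np.random.default_rng(rng_seed)
    if n_words > available // 2 or vocab_size <= 4**8:
        # small vocabularies: enumerate and sample without replacement
        vocab = [
            "".join(p)
            for p in itertools.product(alphabet, repeat=k)
            if "".join(p) not in exclude
        ]
        idx = rng.choice(len(vocab), size=n_words, replace=False)
        return {vocab[i] for i in idx}
    chosen: set[str] = set()
    while len(chosen) < n_words:
        w = "".join(rng.choice(list(alphabet), size=k))
        if w not in exclude:
            chosen.add(w)
    return chosen


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])
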