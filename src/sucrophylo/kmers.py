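"""k-mer spectra and saturation-based choice of word length.

Words are packed two bits per base into ``uint64`` (A=00, C=01, G=10, T=11,
most significant bits first), which keeps counting and set algebra on spectra
vectorised; the dict view required by the TSV dump is materialised on demand.
Windows containing any non-ACGT symbol are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .genome import Genome

_BASES = "ACGT"

MAX_K = 31  # 2 bits/base in uint64


def encode_word(word: str) -> int:
    code = 0
    for ch in word:
        code = (code << 2) | _BASES.index(ch)
    return code


def decode_word(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_words(words: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed words."""
    rc = np.zeros_like(words)
    tmp = words.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
        tmp >>= np.uint64(2)
    return rc


def word_compositions(words: np.ndarray, k: int) -> np.ndarray:
    """Per-word letter counts, shape (n, 4) ordered A,C,G,T."""
    comp = np.zeros((words.size, 4), dtype=np.int16)
    tmp = words.copy()
    for _ in range(k):
        letters = (tmp & np.uint64(3)).astype(np.intp)
        comp[np.arange(words.size), letters] += 1
        tmp >>= np.uint64(2)
    return comp


@dataclass
class KmerSpectrum:
    """Counts of k-length words in one genome.

    ``words`` is sorted and unique; ``word_counts`` aligns with it and sums to
    ``n_windows`` (the number of ACGT-only windows counted).
    """

    genome_id: str
    k: int
    words: np.ndarray
    word_counts: np.ndarray
    n_windows: int
    canonical: bool = False

    @property
    def n_distinct(self) -> int:
        return int(self.words.size)

    @property
    def counts(self) -> dict[str, int]:
        """Dict view word → count (materialised on demand)."""
        return {
            decode_word(int(w), self.k): int(c)
            for w, c in zip(self.words, self.word_counts)
        }

    def dump_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for w, c in zip(self.words, self.word_counts):
                fh.write(f"{decode_word(int(w), self.k)}\t{int(c)}\n")

    @classmethod
    def load_tsv(
        cls, path: Union[str, Path], genome_id: str, canonical: bool = False
    ) -> "KmerSpectrum":
        words, counts = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                w, c = line.split("\t")
                words.append(encode_word(w))
                counts.append(int(c))
        if not words:
            raise ValueError(f"empty spectrum file {path}")
        k = len(w)
        order = np.argsort(np.asarray(words, dtype=np.uint64))
        return cls(
            genome_id=genome_id,
            k=k,
            words=np.asarray(words, dtype=np.uint64)[order],
            word_counts=np.asarray(counts, dtype=np.int64)[order],
            n_windows=int(sum(counts)),
            canonical=canonical,
        )


def _contig_words(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed words of every valid (N-free) window of one contig."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    is_n = (codes == 4).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(is_n)))
    bad = (csum[k:] - csum[:-k]) > 0  # any N within window
    safe = np.where(codes == 4, 0, codes).astype(np.uint64)
    words = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        words = (words << np.uint64(2)) | safe[j : j + m]
    return words[~bad]


def count_kmers(genome: Genome, k: int, canonical: bool = False) -> KmerSpectrum:
    """Count k-mers over all contigs of ``genome``.

    Windows overlapping an ``N`` are skipped.  With ``canonical=True`` each
    word is replaced by the lexicographic minimum of itself and its reverse
    complement before counting.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    if not genome.contigs:
        raise ValueError(f"genome {genome.id!r} has no contigs")
    chunks = [_contig_words(codes, k) for _, codes in genome.contig_codes()]
    allwords = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    if allwords.size == 0:
        raise ValueError(
            f"no countable windows in genome {genome.id!r} at k={k}"
        )
    if canonical:
        allwords = np.minimum(allwords, revcomp_words(allwords, k))
    words, counts = np.unique(allwords, return_counts=True)
    return KmerSpectrum(
        genome_id=genome.id,
        k=k,
        words=words,
        word_counts=counts.astype(np.int64),
        n_windows=int(allwords.size),
        canonical=canonical,
    )


def unique_fraction(spectrum: KmerSpectrum) -> float:
    """Fraction of distinct words occurring exactly once."""
    if spectrum.n_distinct == 0:
        raise ValueError("empty spectrum")
    return float((spectrum.word_counts == 1).sum()) / spectrum.n_distinct


@dataclass
class KCurve:
    """Unique-k-mer fraction as a function of k for one genome."""

    genome_id: str
    fractions: dict[int, float] = field(default_factory=dict)


def select_optimal_k(
    genomes: Sequence[Genome],
    k_min: int,
    k_max: int,
    epsilon: float = 0.005,
    canonical: bool = False,
) -> tuple[int, dict[str, KCurve], bool]:
    """Smallest k at which every genome's unique-k-mer curve plateaus.

    The curve is the fraction of distinct words seen exactly once.  The chosen
    k is the smallest with increase f(k+1) − f(k) < ``epsilon`` for *every*
    genome; if no k ≤ k_max−1 qualifies, returns (k_max, curves, True) with
    the warning flag set.
    """
    if k_min >= k_max:
        raise ValueError("k_min must be < k_max")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    curves = {
        g.id: KCurve(
            g.id,
            {
                k: unique_fraction(count_kmers(g, k, canonical))
                for k in range(k_min, k_max + 1)
            },
        )
        for g in genomes
    }
    for k in range(k_min, k_max):
        if all(
            c.fractions[k + 1] - c.fractions[k] < epsilon for c in curves.values()
        ):
            return k, curves, False
    return k_max, curves, True
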