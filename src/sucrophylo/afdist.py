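"""Alignment-free D2S similarities and pairwise distance matrices.

The D2S statistic compares two k-mer spectra after centering each observed
count by its expectation under an order-0 (independent-letters) background
model of the source genome: for word w with observed counts X_w, Y_w and
n_X, n_Y counted windows,

    X̃_w = X_w − n_X · p_X(w),   p_X(w) = ∏ f_X(letter)  over letters of w,

and the similarity is Σ_w X̃_w Ỹ_w / sqrt(X̃_w² + Ỹ_w²) over the union of
words observed in either spectrum (terms with zero denominator contribute 0).
The distance is −ln of the geometric-mean-normalised similarity ratio.

When spectra were counted canonically, p(w) sums the probabilities of w and
its reverse complement (unless w is its own reverse complement), matching the
merged strand counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .genome import Genome
from .kmers import KmerSpectrum, count_kmers, revcomp_words

R_FLOOR = 1e-12  # similarity-ratio floor keeping −ln finite for NJ


@dataclass
class BackgroundModel:
    """Order-0 nucleotide frequencies f(A), f(C), f(G), f(T)."""

    freqs: np.ndarray  # shape (4,), order A,C,G,T

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("freqs must have shape (4,)")
        if np.any(self.freqs < 0) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be nonnegative and sum to 1")


def background_model(genome: Genome) -> BackgroundModel:
    """Empirical letter frequencies over A,C,G,T (N excluded)."""
    counts = np.zeros(4, dtype=np.int64)
    for _, codes in genome.contig_codes():
        counts += np.bincount(codes, minlength=5)[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"genome {genome.id!r} has no valid (ACGT) bases")
    return BackgroundModel(counts / total)


def _word_probs(
    words: np.ndarray,
    k: int,
    palindrome: np.ndarray | None,
    bg: BackgroundModel,
) -> np.ndarray:
    """P(w) under the order-0 model; strand-summed when counting was canonical.

    Accumulates log-probabilities by 2-bit letter lookups; zero frequencies
    map to log 0 = −inf and exponentiate cleanly to probability 0.
    """
    with np.errstate(divide="ignore"):
        logf = np.log(bg.freqs)
    lp = np.zeros(words.size)
    lp_rc = np.zeros(words.size) if palindrome is not None else None
    logf_comp = logf[::-1]  # complement: A<->T, C<->G under 2-bit codes
    tmp = words.copy()
    for _ in range(k):
        letters = (tmp & np.uint64(3)).astype(np.intp)
        lp += logf[letters]
        if lp_rc is not None:
            lp_rc += logf_comp[letters]
        tmp >>= np.uint64(2)
    with np.errstate(invalid="ignore"):
        p = np.exp(lp)
        if lp_rc is not None:
            p = np.where(palindrome, p, p + np.exp(lp_rc))
    return p


def _sorted_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Union of two sorted unique arrays (merge, no hashing)."""
    m = np.concatenate([a, b])
    m.sort(kind="mergesort")
    if m.size == 0:
        return m
    keep = np.empty(m.size, dtype=bool)
    keep[0] = True
    np.not_equal(m[1:], m[:-1], out=keep[1:])
    return m[keep]


def _aligned_counts(spectrum: KmerSpectrum, union: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(spectrum.words, union)
    idx_clipped = np.minimum(idx, spectrum.words.size - 1)
    hit = spectrum.words[idx_clipped] == union
    out = np.zeros(union.size, dtype=np.int64)
    out[hit] = spectrum.word_counts[idx_clipped[hit]]
    return out


def d2s_similarity(
    sx: KmerSpectrum,
    sy: KmerSpectrum,
    bx: BackgroundModel,
    by: BackgroundModel,
) -> float:
    """Background-centered D2S similarity over the union of observed words."""
    if sx.k != sy.k:
        raise ValueError(f"mismatched k: {sx.k} vs {sy.k}")
    if sx.canonical != sy.canonical:
        raise ValueError("spectra mix canonical and non-canonical counting")
    if sx.n_distinct == 0 or sy.n_distinct == 0:
        raise ValueError("empty spectrum")
    union = _sorted_union(sx.words, sy.words)
    palindrome = union == revcomp_words(union, sx.k) if sx.canonical else None
    px = _word_probs(union, sx.k, palindrome, bx)
    py = _word_probs(union, sx.k, palindrome, by)
    xt = _aligned_counts(sx, union) - sx.n_windows * px
    yt = _aligned_counts(sy, union) - sy.n_windows * py
    denom = np.sqrt(xt * xt + yt * yt)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, xt * yt / denom, 0.0)
    return float(terms.sum())


def d2s_distance(
    sx: KmerSpectrum,
    sy: KmerSpectrum,
    bx: BackgroundModel,
    by: BackgroundModel,
    r_floor: float = R_FLOOR,
) -> float:
    """−ln of the self-normalised similarity ratio, clamped into (0, 1]."""
    sxx = d2s_similarity(sx, sx, bx, bx)
    syy = d2s_similarity(sy, sy, by, by)
    return _distance_from_sims(
        d2s_similarity(sx, sy, bx, by), sxx, syy, sx.genome_id, sy.genome_id, r_floor
    )


def _distance_from_sims(
    sxy: float, sxx: float, syy: float, lx: str, ly: str, r_floor: float = R_FLOOR
) -> float:
    if sxx <= 0 or syy <= 0:
        raise ValueError(
            f"non-positive self-similarity for {lx if sxx <= 0 else ly!r}; "
            "input degenerate (e.g. genome shorter than k)"
        )
    r = sxy / math.sqrt(sxx * syy)
    if r >= 1.0:
        return 0.0
    if r <= r_floor:
        return -math.log(r_floor)
    return -math.log(r)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(np.abs(np.diag(self.values)) > 1e-9):
            raise ValueError("nonzero diagonal")
        if np.any(np.abs(self.values - self.values.T) > 1e-9):
            raise ValueError("matrix not symmetric within 1e-9")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self, path: Union[str, Path], relaxed: bool = False) -> None:
        """Square PHYLIP format; classic mode pads labels to width 10."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                if not relaxed and len(label) > 10:
                    raise ValueError(
                        f"label {label!r} exceeds 10 characters; use relaxed=True"
                    )
                name = f"{label}  " if relaxed else f"{label:<10}"
                fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: Union[str, Path]) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, values=np.asarray(rows))


def distance_matrix(
    genomes: Sequence[Genome], k: int, canonical: bool = False
) -> DistanceMatrix:
    """All-pairs D2S distances among ``genomes`` at word length ``k``."""
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    labels = [g.id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels")
    spectra = [count_kmers(g, k, canonical) for g in genomes]
    bgs = [background_model(g) for g in genomes]
    return distance_matrix_from_spectra(spectra, bgs)


def distance_matrix_from_spectra(
    spectra: Sequence[KmerSpectrum], bgs: Sequence[BackgroundModel]
) -> DistanceMatrix:
    """All-pairs distances from precomputed spectra and background models."""
    n = len(spectra)
    labels = [s.genome_id for s in spectra]
    selfsims = [
        d2s_similarity(spectra[i], spectra[i], bgs[i], bgs[i]) for i in range(n)
    ]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sxy = d2s_similarity(spectra[i], spectra[j], bgs[i], bgs[j])
            values[i, j] = values[j, i] = _distance_from_sims(
                sxy, selfsims[i], selfsims[j], labels[i], labels[j]
            )
    return DistanceMatrix(labels=labels, values=values)
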