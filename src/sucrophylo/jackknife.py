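"""Genome-deletion jackknife and node-support annotation.

Each pseudo-replicate deletes a fixed fraction of every genome, one
fragment (default 100 bp) at a time, at non-overlapping uniformly sampled
positions, then recomputes the D2S distance matrix and neighbor-joining
tree.  The support of an internal node of the reference tree is the
percentage of replicate trees containing its bipartition, rounded to the
nearest integer (half up).

Deletion is applied per contig (⌊fraction·contig_length/fragment⌋ fragments
each), so the deleted fraction is exact up to one fragment per contig and no
chimeric splices join material across contigs.  Each (seed, replicate,
contig) triple seeds an independent random stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .afdist import background_model, distance_matrix_from_spectra
from .genome import Genome
from .kmers import count_kmers
from .trees import PhyloTree, neighbor_joining

_PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class JackknifeConfig:
    replicates: int = 100
    delete_fraction: float = 0.40
    fragment_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delete_fraction < 1.0:
            raise ValueError("delete_fraction must be in [0, 1)")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _delete_fragments(
    seq: str, n_fragments: int, fragment: int, rng: np.random.Generator
) -> str:
    """Splice out n non-overlapping fragments at uniform positions."""
    if n_fragments == 0:
        return seq
    length = len(seq)
    starts: list[int] = []
    occupied = np.zeros(length, dtype=bool)
    for _ in range(n_fragments):
        for _attempt in range(_PLACEMENT_RETRIES):
            s = int(rng.integers(0, length - fragment + 1))
            if not occupied[s : s + fragment].any():
                occupied[s : s + fragment] = True
                starts.append(s)
                break
        else:
            raise RuntimeError(
                "could not place a non-overlapping deletion fragment after "
                f"{_PLACEMENT_RETRIES} retries; reduce delete_fraction"
            )
    return _splice(seq, starts, fragment)


def _splice(seq: str, starts: list[int], fragment: int) -> str:
    pieces = []
    prev = 0
    for s in sorted(starts):
        pieces.append(seq[prev:s])
        prev = s + fragment
    pieces.append(seq[prev:])
    return "".join(pieces)


def jackknife_genome(
    genome: Genome, cfg: JackknifeConfig, replicate_index: int
) -> Genome:
    """One pseudo-replicate of ``genome`` under ``cfg``.

    Per contig, ⌊delete_fraction·contig_length/fragment_length⌋ fragments are
    removed, so the output contig length is exactly contig_length −
    fragments·fragment_length.
    """
    contigs = []
    for name, seq in genome.contigs:
        n_frag = int(cfg.delete_fraction * len(seq) / cfg.fragment_length)
        if n_frag > 0 and len(seq) <= cfg.fragment_length:
            raise ValueError(
                f"contig {name!r} shorter than one deletion fragment"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, replicate_index, zlib.crc32(name.encode())]
            )
        )
        contigs.append((name, _delete_fragments(seq, n_frag, cfg.fragment_length, rng)))
    return Genome(id=genome.id, contigs=contigs)


def jackknife_support(
    genomes: Sequence[Genome],
    reference_tree: PhyloTree,
    k: int,
    cfg: JackknifeConfig,
    canonical: bool = False,
    progress: bool = False,
) -> PhyloTree:
    """Annotate a copy of ``reference_tree`` with jackknife node supports.

    support(node) = round(100 · replicates containing the node's bipartition
    / replicates), half up.
    """
    labels = {g.id for g in genomes}
    if labels != reference_tree.tip_labels:
        raise ValueError("reference tree tips do not match genome labels")
    counts: dict[frozenset[str], int] = {}
    for rep in range(cfg.replicates):
        try:
            jk = [jackknife_genome(g, cfg, rep) for g in genomes]
            spectra = [count_kmers(g, k, canonical) for g in jk]
            bgs = [background_model(g) for g in jk]
            dm = distance_matrix_from_spectra(spectra, bgs)
            tree = neighbor_joining(dm)
        except Exception as exc:
            raise RuntimeError(f"jackknife replicate {rep} failed: {exc}") from exc
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
        if progress:
            print(f"jackknife replicate {rep + 1}/{cfg.replicates} done")
    annotated = reference_tree.copy()
    tips = annotated.tip_labels
    anchor = min(tips)
    for node, ls in annotated._leafsets():
        if node.parent_node is None or not (2 <= len(ls) <= len(tips) - 2):
            continue
        key = ls if anchor not in ls else frozenset(tips - ls)
        frac = counts.get(key, 0) / cfg.replicates
        node.support = int(np.floor(100.0 * frac + 0.5))  # round half up
    return annotated


def render_supports(tree: PhyloTree, display_floor: int = 70) -> str:
    """Newick text with supports below ``display_floor`` suppressed in
    display only; the tree data keep all values."""
    return tree.write_newick(show_supports=True, support_floor=display_floor)
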