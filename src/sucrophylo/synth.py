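"""Synthetic genomes, coverage tracks and presence/absence matrices.

The generator emulates the statistical structure the downstream analyses
assume — clade-structured divergence of whole genomes along a known tree
(Jukes–Cantor substitutions), per-base read depth with known regional copy
numbers (Poisson), and Bernoulli presence/absence with a group-specific
enrichment differential — and always emits the generating truth alongside the
data so parameter recovery can be tested end to end.

Randomness is driven exclusively by ``numpy.random.Generator`` streams spawned
from explicit integer seeds; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .cnv import CoverageTrack, FeatureDef
from .enrich import PresenceMatrix
from .genome import Genome, codes_to_seq
from .trees import PhyloTree


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a full synthetic study."""

    seed: int
    root_length: int = 50_000
    gc_content: float = 0.38  # S. cerevisiae genome-wide GC
    tree: PhyloTree | None = None
    depth_mean: float = 50.0
    group_sizes: tuple[int, int] = (8, 8)
    presence_probs: tuple[float, float] = (0.95, 0.10)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for p in self.presence_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must be in [0, 1]")


@dataclass
class TruthRecord:
    """Generating truth emitted beside every simulated dataset."""

    tree: PhyloTree | None = None
    copy_numbers: dict[str, float] = field(default_factory=dict)
    presence: pd.DataFrame | None = None

    def write_copy_numbers(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\ttrue_copies\n")
            for fid, c in self.copy_numbers.items():
                fh.write(f"{fid}\t{c:g}\n")

    def write_presence(self, path: Union[str, Path]) -> None:
        if self.presence is None:
            raise ValueError("no presence truth recorded")
        self.presence.astype(int).to_csv(path, sep="\t", index_label="strain")

    def write_tree(self, path: Union[str, Path]) -> None:
        if self.tree is None:
            raise ValueError("no tree truth recorded")
        Path(path).write_text(self.tree.write_newick() + "\n")


def simulate_root_genome(length: int, gc: float, seed: int) -> Genome:
    """Single-contig i.i.d. genome with P(G)+P(C)=gc split equally."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x726F6F74]))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return Genome(id="root", contigs=[("chr1", codes_to_seq(codes))])


def jc_substitution_probability(d: float) -> float:
    """P(site differs) after a Jukes–Cantor branch of length d subs/site."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _mutate(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    p = jc_substitution_probability(d)
    out = codes.copy()
    valid = codes < 4
    hit = valid & (rng.random(codes.size) < p)
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the three alternative bases
        out[hit] = (codes[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def evolve_along_tree(
    root: Genome, tree: PhyloTree, seed: int
) -> tuple[dict[str, Genome], TruthRecord]:
    """Evolve ``root`` down ``tree`` under Jukes–Cantor.

    Branch lengths are expected substitutions per site; each branch applies
    independent per-site substitutions with probability
    p_sub = (3/4)(1 − exp(−4d/3)).  Returns tip genomes keyed by label and
    the generating tree as truth.
    """
    root_codes = [(name, codes.copy()) for name, codes in root.contig_codes()]
    tips: dict[str, Genome] = {}
    dtree = tree._tree
    node_index = {id(n): i for i, n in enumerate(dtree.preorder_node_iter())}
    seqs: dict[int, list[tuple[str, np.ndarray]]] = {
        id(dtree.seed_node): root_codes
    }
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            parent_seqs = root_codes
        else:
            parent_seqs = seqs[id(node.parent_node)]
            d = node.edge.length if node.edge.length is not None else 0.0
            if d < 0:
                raise ValueError("negative branch length")
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, node_index[id(node)]])
            )
            parent_seqs = [(name, _mutate(c, d, rng)) for name, c in parent_seqs]
            seqs[id(node)] = parent_seqs
        if node.is_leaf():
            label = node.taxon.label
            tips[label] = Genome(
                id=label,
                contigs=[(name, codes_to_seq(c)) for name, c in parent_seqs],
            )
    # free internal sequences eagerly on big trees is unnecessary at these sizes
    return tips, TruthRecord(tree=tree)


def two_clade_tree(
    focal_labels: Sequence[str],
    background_labels: Sequence[str],
    d_within: float = 0.01,
    d_between: float = 0.2,
) -> PhyloTree:
    """Two clades whose within-pair divergence is ``d_within`` and whose
    cross-clade divergence is ``d_within`` + ``d_between``."""
    w = d_within / 2.0
    b = d_between / 2.0
    focal = ",".join(f"{t}:{w:g}" for t in focal_labels)
    bg = ",".join(f"{t}:{w:g}" for t in background_labels)
    return PhyloTree.read_newick(f"(({focal}):{b:g},({bg}):{b:g});")


def shuffle_fragments(
    genome: Genome, fragment_length: int, seed: int
) -> Genome:
    """Randomly reorder fixed-length fragments of each contig.

    A stress knob for alignment-free analyses: shuffling preserves k-mer
    content away from fragment joins, so D2S distances should be nearly
    unchanged while any position-dependent method would break.  Off by
    default everywhere; call explicitly.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x73687566]))
    contigs = []
    for name, seq in genome.contigs:
        pieces = [
            seq[i : i + fragment_length]
            for i in range(0, len(seq), fragment_length)
        ]
        order = rng.permutation(len(pieces))
        contigs.append((name, "".join(pieces[i] for i in order)))
    return Genome(id=genome.id, contigs=contigs)


def simulate_coverage(
    features: Sequence[FeatureDef],
    genome_length: int,
    depth_mean: float,
    seed: int,
    sequence_name: str = "chr1",
) -> tuple[CoverageTrack, TruthRecord]:
    """Per-base depth ~ Poisson(λ·c); c is the regional true copy number.

    Each feature carries its true copy number in ``reference_copies``; bases
    outside every feature have c = 1.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    spans = sorted((f.start, f.end, f) for f in features)
    prev_end = 0
    for start, end, f in spans:
        if start < 0 or end > genome_length:
            raise ValueError(f"feature {f.feature_id!r} outside genome bounds")
        if start < prev_end:
            raise ValueError(f"feature {f.feature_id!r} overlaps a previous feature")
        prev_end = end
    lam = np.full(genome_length, depth_mean, dtype=float)
    truth: dict[str, float] = {}
    for start, end, f in spans:
        lam[start:end] = depth_mean * f.reference_copies
        truth[f.feature_id] = f.reference_copies
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x636F76]))
    depth = rng.poisson(lam).astype(np.int64)
    track = CoverageTrack(depths={sequence_name: depth})
    return track, TruthRecord(copy_numbers=truth)


def simulate_presence_matrix(
    n_focal: int,
    n_background: int,
    p_focal: float,
    p_background: float,
    n_features: int,
    seed: int,
) -> tuple[PresenceMatrix, TruthRecord]:
    """Independent Bernoulli presence with group-specific probabilities."""
    for p in (p_focal, p_background):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70726573]))
    strains = [f"focal_{i+1:03d}" for i in range(n_focal)] + [
        f"bg_{i+1:03d}" for i in range(n_background)
    ]
    features = [f"feat_{j+1:04d}" for j in range(n_features)]
    mat = np.empty((len(strains), n_features), dtype=bool)
    mat[:n_focal] = rng.random((n_focal, n_features)) < p_focal
    mat[n_focal:] = rng.random((n_background, n_features)) < p_background
    df = pd.DataFrame(mat, index=strains, columns=features)
    groups = {s: ("focal" if i < n_focal else "background") for i, s in enumerate(strains)}
    pm = PresenceMatrix(presence=df, groups=groups)
    return pm, TruthRecord(presence=df)


# ---------------------------------------------------------------------------
# writers (the matching readers live in cnv / enrich)


def write_depth_tsv(track: CoverageTrack, path: Union[str, Path]) -> None:
    """3-column depth table: sequence, 1-based position, depth."""
    with open(path, "w") as fh:
        for name, depth in track.depths.items():
            for pos, d in enumerate(depth, start=1):
                fh.write(f"{name}\t{pos}\t{int(d)}\n")


def write_features_bed(
    features: Sequence[FeatureDef], path: Union[str, Path]
) -> None:
    """BED-like file: seq, start, end (0-based half-open), id, true copies."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.sequence}\t{f.start}\t{f.end}\t{f.feature_id}\t{f.reference_copies:g}\n"
            )


def write_presence_tsv(matrix: PresenceMatrix, path: Union[str, Path]) -> None:
    matrix.presence.astype(int).to_csv(path, sep="\t", index_label="strain")
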