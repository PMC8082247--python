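"""Read-depth copy-number estimation and group statistics.

Copy number of a probed feature is estimated as its mean per-base depth
(flanks excluded — flanks exist to let reads align fully at the gene ends,
not to be quantified) divided by the genome-wide mean depth.  Differential
copy numbers subtract the reference-annotation copies, giving the signed
extra-copy matrix rendered as a heatmap in the study design this package
supports.  Group differences are tested per feature with a two-sided
Mann-Whitney U (exact enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome

MIN_FLANK = 250  # bp; minimum probe flank unless explicitly overridden
EXACT_MW_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined n
HEATMAP_CLIP = 4.0  # display clip: > +4 extra copies shown as one class


@dataclass(frozen=True)
class FeatureDef:
    """A probed gene/region with its reference-annotation copy count."""

    feature_id: str
    sequence: str
    start: int  # 0-based, half-open
    end: int
    reference_copies: float = 1.0
    flank_up: int = 0
    flank_down: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: start must be < end"
            )
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError(f"feature {self.feature_id!r}: flanks must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-sequence arrays of per-base read depth."""

    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.depths = {
            name: np.asarray(d, dtype=np.int64) for name, d in self.depths.items()
        }

    @property
    def genome_mean_depth(self) -> float:
        total = sum(int(d.sum()) for d in self.depths.values())
        n = sum(d.size for d in self.depths.values())
        if n == 0:
            raise ValueError("empty coverage track")
        return total / n

    @property
    def genome_median_depth(self) -> float:
        return float(np.median(np.concatenate(list(self.depths.values()))))


def read_depth_tsv(path: Union[str, Path]) -> CoverageTrack:
    """3-column TSV (sequence, 1-based position, depth) → CoverageTrack.

    Positions absent from the table are depth 0; array length per sequence is
    the maximum listed position.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["seq", "pos", "depth"],
        dtype={"seq": str, "pos": np.int64, "depth": np.int64},
    )
    depths: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("seq", sort=False):
        arr = np.zeros(int(sub["pos"].max()), dtype=np.int64)
        arr[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
        depths[name] = arr
    return CoverageTrack(depths=depths)


def read_bedgraph(path: Union[str, Path]) -> CoverageTrack:
    """BedGraph (seq, start, end, value; 0-based half-open) → CoverageTrack."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["seq", "start", "end", "depth"],
        comment="t", dtype={"seq": str},
    )
    df = df[pd.to_numeric(df["start"], errors="coerce").notna()]
    depths: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("seq", sort=False):
        arr = np.zeros(int(sub["end"].max()), dtype=np.int64)
        for s, e, v in zip(
            sub["start"].astype(int), sub["end"].astype(int), sub["depth"]
        ):
            arr[s:e] = int(v)
        depths[name] = arr
    return CoverageTrack(depths=depths)


def read_features_bed(path: Union[str, Path]) -> list[FeatureDef]:
    """BED-like reader: seq, start, end, feature_id, reference_copies
    [, flank_up, flank_down]."""
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            seq, start, end, fid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            copies = float(parts[4]) if len(parts) > 4 else 1.0
            fu = int(parts[5]) if len(parts) > 5 else 0
            fd = int(parts[6]) if len(parts) > 6 else 0
            features.append(
                FeatureDef(fid, seq, start, end, copies, fu, fd)
            )
    return features


# ---------------------------------------------------------------------------
# probe construction


def build_probe_reference(
    features: Sequence[FeatureDef],
    source: Genome,
    allow_short_flanks: bool = False,
) -> tuple[Genome, dict[str, list[tuple[str, int]]]]:
    """Concatenate flank+feature+flank per feature into a probe genome.

    Flanks shorter than 250 bp are rejected unless ``allow_short_flanks``;
    returns the probe genome plus a map probe name → per-base (sequence,
    source position) so every probe base round-trips to a unique source base.
    """
    contigs = dict(source.contigs)
    probe_contigs: list[tuple[str, str]] = []
    coord_map: dict[str, list[tuple[str, int]]] = {}
    for f in features:
        if not allow_short_flanks and (f.flank_up < MIN_FLANK or f.flank_down < MIN_FLANK):
            raise ValueError(
                f"feature {f.feature_id!r} has a flank shorter than {MIN_FLANK} bp; "
                "pass allow_short_flanks=True to override"
            )
        if f.sequence not in contigs:
            raise ValueError(
                f"feature {f.feature_id!r} references unknown sequence {f.sequence!r}"
            )
        seq = contigs[f.sequence]
        lo = f.start - f.flank_up
        hi = f.end + f.flank_down
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"feature {f.feature_id!r} plus flanks exceeds source bounds"
            )
        probe_contigs.append((f.feature_id, seq[lo:hi]))
        coord_map[f.feature_id] = [(f.sequence, p) for p in range(lo, hi)]
    return Genome(id=f"{source.id}_probes", contigs=probe_contigs), coord_map


# ---------------------------------------------------------------------------
# copy-number estimation


def normalized_copy_number(
    track: CoverageTrack, feature: FeatureDef, background: str = "mean"
) -> float:
    """Mean feature depth (flanks excluded) over the genome background depth.

    ``background`` selects the genome-wide mean (default, the "average
    genome coverage" convention) or median (robust to focal amplifications).
    """
    if feature.length == 0:
        raise ValueError(f"feature {feature.feature_id!r} has zero length")
    if feature.sequence not in track.depths:
        raise ValueError(
            f"feature {feature.feature_id!r}: sequence {feature.sequence!r} "
            "not covered by track"
        )
    depth = track.depths[feature.sequence]
    if feature.end > depth.size:
        raise ValueError(
            f"feature {feature.feature_id!r} extends past coverage track end"
        )
    if background == "mean":
        baseline = track.genome_mean_depth
    elif background == "median":
        baseline = track.genome_median_depth
    else:
        raise ValueError("background must be 'mean' or 'median'")
    if baseline <= 0:
        raise ValueError("genome background depth must be > 0")
    return float(depth[feature.start : feature.end].mean()) / baseline


@dataclass
class CNVMatrix:
    """Strains × features differential copy numbers (estimate − reference)."""

    values: pd.DataFrame  # may contain NaN for missing strain estimates
    groups: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t", index_label="strain")

    def heatmap_classes(self, clip: float = HEATMAP_CLIP) -> pd.DataFrame:
        """Display export: values clipped at +clip, with entries beyond the
        clip marked as the extreme class; raw values stay in ``values``."""
        return self.values.clip(upper=clip)

    def over_clip_mask(self, clip: float = HEATMAP_CLIP) -> pd.DataFrame:
        return self.values > clip


def differential_cnv(
    copy_estimates: pd.DataFrame,
    features: Sequence[FeatureDef],
    groups: Mapping[str, str] | None = None,
) -> CNVMatrix:
    """Estimate − reference_copies per strain × feature."""
    ref = pd.Series(
        {f.feature_id: f.reference_copies for f in features}, dtype=float
    )
    missing = [c for c in copy_estimates.columns if c not in ref.index]
    if missing:
        raise ValueError(f"features without reference copies: {missing}")
    diff = copy_estimates - ref[copy_estimates.columns]
    return CNVMatrix(values=diff, groups=dict(groups or {}))


# ---------------------------------------------------------------------------
# statistics


@dataclass
class GroupTestResult:
    feature_id: str
    u_statistic: float
    p_value: float
    significant: bool
    n_focal: int
    n_background: int


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for tie-free samples with
    n1+n2 ≤ 12, otherwise normal approximation with tie/continuity correction.

    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size + y.size <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_cnv_test(
    matrix: CNVMatrix,
    groups: Mapping[str, str] | None = None,
    focal: str = "focal",
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Per-feature two-sided Mann-Whitney U, focal vs background strains.

    Strains with a missing (NaN) estimate are excluded per feature; features
    where either group empties out are skipped with a warning entry omitted.
    """
    groups = dict(groups) if groups is not None else matrix.groups
    if not groups:
        raise ValueError("no group labels provided")
    focal_strains = [s for s, g in groups.items() if g == focal]
    bg_strains = [s for s, g in groups.items() if g != focal]
    results = []
    for fid in matrix.values.columns:
        col = matrix.values[fid]
        xs = col.reindex(focal_strains).dropna()
        ys = col.reindex(bg_strains).dropna()
        if xs.empty or ys.empty:
            continue
        u, p = mann_whitney_u(xs.to_numpy(), ys.to_numpy())
        results.append(
            GroupTestResult(
                feature_id=fid,
                u_statistic=u,
                p_value=p,
                significant=p < alpha,
                n_focal=int(xs.size),
                n_background=int(ys.size),
            )
        )
    return results


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a 95% CI from the Fisher z transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(x.size - 3)
    zcrit = 1.959964
    return r, (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))
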