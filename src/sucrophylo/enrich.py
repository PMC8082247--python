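"""Presence/absence calling and Fisher-exact group enrichment.

Presence of a genetic feature in a strain is called from similarity-search
hit tables (BLAST outfmt-6 style): a feature is present when at least one hit
passes the identity (strictly greater than the cut-off, 70% by default) and
query-coverage thresholds.  A feature counts as present "even in
heterozygosis": hits to either of its alternative alleles suffice.

Enrichment of each feature in a focal strain group versus a background group
is assessed with Fisher's exact test on the 2×2 presence table; the
two-sided p sums the probabilities of all tables no more probable than the
observed one under the hypergeometric null with fixed margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_IDENTITY = 70.0  # percent, strict >
DEFAULT_MIN_COVERAGE = 0.5  # fraction of query length


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit of a feature query against a strain genome."""

    query_id: str
    strain_id: str
    percent_identity: float
    alignment_length: int
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")
        if self.alignment_length <= 0:
            raise ValueError("alignment length must be positive")


#: default outfmt-6 column order
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast6(
    path: Union[str, Path],
    query_lengths: Mapping[str, int] | None = None,
    columns: Sequence[str] | None = None,
    strain_from_subject=None,
) -> list[HitRecord]:
    """Read a 12-column BLAST tabular file into hit records.

    ``query_coverage`` is alignment length over the query length when
    ``query_lengths`` is given, else aligned query span / max query position
    seen (a conservative stand-in).  ``strain_from_subject`` maps subject ids
    to strain ids (default: identity).
    """
    cols = list(columns or BLAST6_COLUMNS)
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    strain_of = strain_from_subject or (lambda s: s)
    hits = []
    for row in df.itertuples(index=False):
        q = str(row.qseqid)
        alen = int(row.length)
        if query_lengths and q in query_lengths:
            cov = min(1.0, alen / query_lengths[q])
        else:
            cov = min(1.0, alen / max(abs(int(row.qend) - int(row.qstart)) + 1, alen))
        hits.append(
            HitRecord(
                query_id=q,
                strain_id=str(strain_of(str(row.sseqid))),
                percent_identity=float(row.pident),
                alignment_length=alen,
                query_coverage=cov,
            )
        )
    return hits


def kmer_containment_hits(
    feature_seqs: Mapping[str, str],
    genomes: Iterable,
    k: int = 21,
) -> list[HitRecord]:
    """Naive exact matcher: the fraction of a feature's k-mers found in a
    strain genome becomes the hit's query coverage.

    Exact matches only (identity reported as 100), so this is a stand-in for
    a real similarity search usable on synthetic data where markers are
    implanted verbatim; it has no tolerance for sequence divergence.
    """
    from .genome import Genome
    from .kmers import count_kmers

    import numpy as np

    feature_spectra = {}
    for fid, seq in feature_seqs.items():
        if len(seq) < k:
            raise ValueError(f"feature {fid!r} shorter than k={k}")
        feature_spectra[fid] = count_kmers(
            Genome(fid, [("q", seq)]), k
        ).words
    hits = []
    for genome in genomes:
        gwords = count_kmers(genome, k).words
        for fid, fwords in feature_spectra.items():
            contained = np.isin(fwords, gwords, assume_unique=True).sum()
            containment = float(contained) / fwords.size
            if containment > 0:
                hits.append(
                    HitRecord(
                        query_id=fid,
                        strain_id=genome.id,
                        percent_identity=100.0,
                        alignment_length=len(feature_seqs[fid]),
                        query_coverage=containment,
                    )
                )
    return hits


@dataclass
class PresenceMatrix:
    """Complete strains × features boolean table plus group labels."""

    presence: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate strain ids")
        self.presence = self.presence.astype(bool)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.presence.astype(int).to_csv(path, sep="\t", index_label="strain")


def read_groups_tsv(path: Union[str, Path]) -> dict[str, str]:
    """Two-column strain→group TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            strain, group = line.split()[:2]
            out[strain] = group
    return out


def call_presence(
    hits: Iterable[HitRecord],
    strains: Sequence[str],
    features: Sequence[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    allele_map: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> PresenceMatrix:
    """Present iff ≥1 hit passes identity (> min_identity) and coverage
    (≥ min_coverage) thresholds.

    ``allele_map`` maps alternative-allele query ids onto their feature id;
    a hit to either allele marks the feature present (heterozygosity rule).
    Strains with no hits at all are absent everywhere.
    """
    allele_map = dict(allele_map or {})
    known_features = set(features)
    known_strains = set(strains)
    mat = pd.DataFrame(False, index=list(strains), columns=list(features))
    bad_strains, bad_features = set(), set()
    for hit in hits:
        fid = allele_map.get(hit.query_id, hit.query_id)
        if fid not in known_features:
            bad_features.add(hit.query_id)
            continue
        if hit.strain_id not in known_strains:
            bad_strains.add(hit.strain_id)
            continue
        if hit.percent_identity > min_identity and hit.query_coverage >= min_coverage:
            mat.loc[hit.strain_id, fid] = True
    if bad_strains or bad_features:
        raise ValueError(
            f"hits reference unknown strains {sorted(bad_strains)} "
            f"or features {sorted(bad_features)}"
        )
    return PresenceMatrix(presence=mat, groups=dict(groups or {}))


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 presence table: (focal present/absent, background present/absent)."""

    a: int  # focal, present
    b: int  # focal, absent
    c: int  # background, present
    d: int  # background, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def focal_size(self) -> int:
        return self.a + self.b

    @property
    def background_size(self) -> int:
        return self.c + self.d


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio.

    p is the sum of probabilities of all tables with the observed margins
    whose point probability does not exceed the observed one; the odds ratio
    is a·d/(b·c), infinite when b·c = 0 (and a·d > 0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return float(p), odds


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (matching hand-reported percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentResult:
    feature_id: str
    table: ContingencyTable
    focal_percent: float
    background_percent: float
    odds_ratio: float
    p_value: float
    significant: bool


def enrichment_report(
    matrix: PresenceMatrix,
    focal: str = "focal",
    alpha: float = 0.05,
    percent_decimals: int = 2,
    correct: bool = False,
) -> list[EnrichmentResult]:
    """Per-feature Fisher enrichment of the focal group vs the background.

    By default each feature is reported at its raw p (the per-feature
    reporting convention); ``correct=True`` applies Benjamini-Hochberg
    FDR control across features before flagging significance, as an
    extension for larger feature panels.
    """
    groups = matrix.groups
    focal_strains = [s for s in matrix.presence.index if groups.get(s) == focal]
    bg_strains = [s for s in matrix.presence.index if groups.get(s) not in (None, focal)]
    if not focal_strains or not bg_strains:
        raise ValueError("both groups must be nonempty")
    results = []
    for fid in matrix.presence.columns:
        col = matrix.presence[fid]
        a = int(col.loc[focal_strains].sum())
        c = int(col.loc[bg_strains].sum())
        table = ContingencyTable(
            a=a, b=len(focal_strains) - a, c=c, d=len(bg_strains) - c
        )
        p, odds = fisher_exact(table)
        results.append(
            EnrichmentResult(
                feature_id=fid,
                table=table,
                focal_percent=round_half_away(
                    100.0 * a / len(focal_strains), percent_decimals
                ),
                background_percent=round_half_away(
                    100.0 * c / len(bg_strains), percent_decimals
                ),
                odds_ratio=odds,
                p_value=p,
                significant=p < alpha,
            )
        )
    if correct and results:
        rejected = _benjamini_hochberg([r.p_value for r in results], alpha)
        for r, rej in zip(results, rejected):
            r.significant = rej
    return results


def _benjamini_hochberg(pvalues: Sequence[float], alpha: float) -> list[bool]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    threshold_rank = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * alpha / m:
            threshold_rank = rank
    rejected = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= threshold_rank:
            rejected[idx] = True
    return rejected


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature\ta\tb\tc\td\tfocal_percent\tbackground_percent\t"
            "odds_ratio\tp_value\tsignificant\n"
        )
        for r in results:
            t = r.table
            fh.write(
                f"{r.feature_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{r.focal_percent}\t{r.background_percent}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{int(r.significant)}\n"
            )
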