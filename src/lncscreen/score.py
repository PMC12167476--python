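"""Normalization, fold changes, and gene scoring against the NTC null.

The scoring model follows the dropout-screen lineage: per-sample counts
are normalized to the median of the plasmid reference, each guide gets a
log2 fold change (endpoint vs plasmid, pseudocount 1), and each gene is
summarized by the mean of its three most extreme guides in its dominant
direction.  That top-k statistic is standardized against an empirical
null of same-size pseudo-genes resampled from the non-targeting
controls, giving a z-score; |z| > 3 calls a hit (negative z = guides
dropped out = positive regulator of growth).  A Mann-Whitney U test of
the gene's guide fold changes against all NTC fold changes accompanies
each call, exact by enumeration for small groups and normal-approximated
(tie- and continuity-corrected) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lncscreen.library_model import LibraryDesign
from lncscreen.quantify import CountTable


class NormalizationError(ValueError):
    """A sample's median raw count is zero; normalization undefined."""


class NullModelError(ValueError):
    """The NTC null is degenerate (zero spread)."""


@dataclass
class NormalizedTable:
    """Raw counts plus median-normalized values (reference column unchanged)."""

    raw: CountTable
    normalized: np.ndarray  # float, same shape as raw.counts

    @property
    def guide_ids(self) -> list[str]:
        return self.raw.guide_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.raw.sample_ids

    @property
    def reference_sample(self) -> str:
        return self.raw.reference_sample

    def normalized_column(self, sample_id: str) -> np.ndarray:
        return self.normalized[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.normalized, index=pd.Index(self.guide_ids, name="guide_id"),
            columns=self.sample_ids,
        )


@dataclass(frozen=True)
class GuidePhenotype:
    """Per-guide phenotype: normalized counts, log2 fold change, filter flag."""

    guide_id: str
    normalized_reference: float
    normalized_endpoint: float
    lfc: float
    passed_filter: bool


@dataclass(frozen=True)
class NtcNull:
    """Empirical null of top-k pseudo-gene scores resampled from NTC lfcs."""

    pseudo_gene_scores: np.ndarray
    mu: float
    sigma: float
    k: int
    pseudo_gene_size: int
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class GeneScore:
    """Gene-level screen score and hit call."""

    gene_id: str
    n_guides_used: int
    direction: int  # -1 dropout, +1 enrichment
    topk_mean_lfc: float
    z: float
    u_stat: float
    p_value: float
    hit_class: str  # positive_regulator | negative_regulator | none
    topk_guide_lfcs: tuple[float, ...] = ()
    bh_q: float = float("nan")


def median_normalize(table: CountTable) -> NormalizedTable:
    """Normalize each sample to the median of the reference column.

    normalized(g, s) = raw(g, s) / median(column s) * median(reference);
    the reference column is returned unchanged.  Computed as a per-column
    division before the common rescale so that multiplying a column's raw
    counts by a constant leaves its normalized values bit-identical.
    """
    counts = table.counts.astype(float)
    medians = np.median(counts, axis=0)
    for sid, m in zip(table.sample_ids, medians):
        if m <= 0:
            raise NormalizationError(f"sample {sid!r} has zero median raw count")
    ref_j = table.sample_ids.index(table.reference_sample)
    normalized = (counts / medians) * medians[ref_j]
    normalized[:, ref_j] = counts[:, ref_j]
    return NormalizedTable(raw=table, normalized=normalized)


def guide_lfc(
    table: NormalizedTable,
    endpoint: str,
    pseudocount: float = 1.0,
    min_reference_count: int = 10,
) -> list[GuidePhenotype]:
    """Per-guide log2 fold change of one endpoint vs the plasmid reference.

    lfc = log2((norm_endpoint + pseudocount) / (norm_reference + pseudocount)).
    Guides with fewer than ``min_reference_count`` raw reads in the
    reference are flagged ``passed_filter=False`` and excluded downstream
    (their plasmid representation is too thin for a stable ratio).
    """
    if endpoint not in table.sample_ids:
        raise ValueError(f"unknown endpoint sample {endpoint!r}")
    if endpoint == table.reference_sample:
        raise ValueError("endpoint must differ from the reference sample")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if min_reference_count < 0:
        raise ValueError("min_reference_count must be >= 0")
    norm_end = table.normalized_column(endpoint)
    norm_ref = table.normalized_column(table.reference_sample)
    raw_ref = table.raw.sample_column(table.reference_sample)
    lfc = np.log2((norm_end + pseudocount) / (norm_ref + pseudocount))
    passed = raw_ref >= min_reference_count
    return [
        GuidePhenotype(gid, float(nr), float(ne), float(l), bool(p))
        for gid, nr, ne, l, p in zip(table.guide_ids, norm_ref, norm_end, lfc, passed)
    ]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_gene(
    gene_lfcs: Sequence[float],
    ntc_lfcs: Sequence[float],
    max_exact_comb: int = 100_000,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of a gene's guide lfcs vs the NTCs.

    Returns (U for the gene group, two-sided p).  When the number of
    group assignments C(n+m, n) is at most ``max_exact_comb`` the p-value
    is exact — computed by enumerating every assignment of the pooled
    midranks, which handles ties — otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(gene_lfcs, dtype=float)
    y = np.asarray(ntc_lfcs, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations in each group")
    n, m = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_stat = float(ranks[:n].sum() - n * (n + 1) / 2)
    if math.comb(n + m, n) <= max_exact_comb:
        p = _exact_mw_p(ranks, n, u_stat)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u_stat, min(p, 1.0)


def _exact_mw_p(pooled_ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every choice of n pooled midranks.

    The permutation distribution of U is symmetric about n*m/2 (ranks
    reverse under value negation), so two-sided p = P(|U - nm/2| >=
    |u_obs - nm/2|).
    """
    m = pooled_ranks.size - n
    center = n * m / 2
    offset = n * (n + 1) / 2
    d_obs = abs(u_obs - center) - 1e-9  # tolerate float fuzz in midranks
    hits = 0
    total = 0
    for idx in combinations(range(pooled_ranks.size), n):
        u = pooled_ranks[list(idx)].sum() - offset
        if abs(u - center) >= d_obs:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# NTC pseudo-gene null and gene scoring
# ---------------------------------------------------------------------------


def _topk_directional_scores(lfc_matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise top-k statistic: mean of the k most extreme values in the
    direction of each row's median (median tie -> dropout, -1)."""
    med = np.median(lfc_matrix, axis=1)
    direction = np.where(med > 0, 1, -1)
    srt = np.sort(lfc_matrix, axis=1)
    low = srt[:, :k].mean(axis=1)
    high = srt[:, -k:].mean(axis=1)
    return np.where(direction < 0, low, high), direction


def build_ntc_null(
    ntc_lfcs: Sequence[float],
    pseudo_gene_size: int = 10,
    k: int = 3,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> NtcNull:
    """Build the empirical null of gene scores from non-targeting controls.

    Each resample draws ``pseudo_gene_size`` NTC lfcs without replacement
    and scores the pseudo-gene exactly as a real gene is scored: mean of
    the k most extreme values in the direction of the pseudo-gene's
    median.  mu and sigma of those scores standardize real gene scores.
    """
    ntc = np.asarray(ntc_lfcs, dtype=float)
    if pseudo_gene_size > ntc.size:
        raise ValueError(f"pseudo_gene_size {pseudo_gene_size} exceeds {ntc.size} NTC lfcs")
    if k > pseudo_gene_size:
        raise ValueError("k must be <= pseudo_gene_size")
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    # row-wise draws without replacement: first pseudo_gene_size of a random order
    keys = rng.random((n_resamples, ntc.size))
    idx = np.argpartition(keys, pseudo_gene_size - 1, axis=1)[:, :pseudo_gene_size]
    draws = ntc[idx]
    scores, _ = _topk_directional_scores(draws, k)
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    if sigma <= 0 or not np.isfinite(sigma):
        raise NullModelError(
            "degenerate NTC null (sigma = 0): NTC fold changes have no spread; "
            "check the NTC lfcs or increase resamples"
        )
    return NtcNull(
        pseudo_gene_scores=scores, mu=mu, sigma=sigma, k=k,
        pseudo_gene_size=pseudo_gene_size, n_resamples=n_resamples, seed=seed,
    )


def score_gene(
    gene_lfcs: Sequence[float],
    null: NtcNull,
    ntc_lfcs: Sequence[float],
    tau: float = 3.0,
    gene_id: str = "",
) -> GeneScore:
    """Score one gene against the NTC null.

    direction = sign of the median guide lfc (exact zero counts as
    dropout); topk_mean_lfc = mean of the k guides most extreme in that
    direction; z = (topk_mean_lfc - mu) / sigma; z < -tau calls a
    positive regulator of growth (guides dropped out), z > +tau a
    negative regulator.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.asarray(gene_lfcs, dtype=float)
    if x.size < null.k:
        raise ValueError(f"gene {gene_id or '?'}: needs >= {null.k} usable guides, got {x.size}")
    scores, direction = _topk_directional_scores(x[None, :], null.k)
    topk = float(scores[0])
    d = int(direction[0])
    z = (topk - null.mu) / null.sigma
    if z < -tau:
        hit = "positive_regulator"
    elif z > tau:
        hit = "negative_regulator"
    else:
        hit = "none"
    u, p = mann_whitney_gene(x, ntc_lfcs)
    topk_lfcs = tuple(float(v) for v in (np.sort(x)[: null.k] if d < 0 else np.sort(x)[-null.k:][::-1]))
    return GeneScore(
        gene_id=gene_id, n_guides_used=int(x.size), direction=d, topk_mean_lfc=topk,
        z=float(z), u_stat=u, p_value=p, hit_class=hit, topk_guide_lfcs=topk_lfcs,
    )


def rank_hits(scores: Sequence[GeneScore], direction: str = "dropout") -> list[GeneScore]:
    """Ranked hit list for one direction, with each hit's top guide lfcs.

    Dropout keeps positive regulators sorted by ascending z; enrichment
    keeps negative regulators sorted by descending z.  Ties break by
    smaller p, then gene id.
    """
    if direction == "dropout":
        hits = [s for s in scores if s.hit_class == "positive_regulator"]
        hits.sort(key=lambda s: (s.z, s.p_value, s.gene_id))
    elif direction == "enrichment":
        hits = [s for s in scores if s.hit_class == "negative_regulator"]
        hits.sort(key=lambda s: (-s.z, s.p_value, s.gene_id))
    else:
        raise ValueError("direction must be 'dropout' or 'enrichment'")
    return hits


# ---------------------------------------------------------------------------
# full-screen driver
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Everything the scoring stage produces for one endpoint column."""

    phenotypes: list[GuidePhenotype]
    null: NtcNull
    gene_scores: list[GeneScore]
    unscored_genes: list[str]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [s.gene_id for s in self.gene_scores],
                "n_guides_used": [s.n_guides_used for s in self.gene_scores],
                "direction": [s.direction for s in self.gene_scores],
                "topk_mean_lfc": [s.topk_mean_lfc for s in self.gene_scores],
                "z": [s.z for s in self.gene_scores],
                "u_stat": [s.u_stat for s in self.gene_scores],
                "p_value": [s.p_value for s in self.gene_scores],
                "bh_q": [s.bh_q for s in self.gene_scores],
                "hit_class": [s.hit_class for s in self.gene_scores],
            }
        )

    def phenotypes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [p.guide_id for p in self.phenotypes],
                "normalized_reference": [p.normalized_reference for p in self.phenotypes],
                "normalized_endpoint": [p.normalized_endpoint for p in self.phenotypes],
                "lfc": [p.lfc for p in self.phenotypes],
                "passed_filter": [p.passed_filter for p in self.phenotypes],
            }
        )


def score_screen(
    table: CountTable,
    library: LibraryDesign,
    endpoint: str,
    tau: float = 3.0,
    k: int = 3,
    pseudocount: float = 1.0,
    min_reference_count: int = 10,
    n_resamples: int = 10_000,
    seed: int = 0,
    pseudo_gene_size: int | None = None,
    center_on_ntc: bool = True,
) -> ScreenResult:
    """Run normalization → lfc → NTC null → per-gene scores for one endpoint.

    Gene-level statistics are computed on fold changes centered on the
    NTC median (``center_on_ntc``), so a global shift — e.g. read-depth
    reallocation when strong dropouts free up sequencing reads — cannot
    push every gene's dominant direction to one side of the null.  The
    per-guide phenotype table keeps the uncentered lfcs.

    Genes with fewer than ``k`` filter-passing guides are reported in
    ``unscored_genes`` rather than scored.  A Benjamini-Hochberg q-value
    column is attached for information; hit calls use the z threshold
    only.
    """
    if set(table.guide_ids) != set(library.guide_ids):
        raise ValueError("count table guides do not match the library")
    norm = median_normalize(table)
    phenotypes = guide_lfc(norm, endpoint, pseudocount, min_reference_count)
    lfc_by_guide = {p.guide_id: p.lfc for p in phenotypes if p.passed_filter}

    ntc_ids = [g.guide_id for g in library.guides_by_class("non_targeting")]
    ntc_lfcs = np.array([lfc_by_guide[g] for g in ntc_ids if g in lfc_by_guide])
    if ntc_lfcs.size < 2:
        raise ValueError("fewer than 2 usable non-targeting control guides")
    if center_on_ntc:
        shift = float(np.median(ntc_lfcs))
        ntc_lfcs = ntc_lfcs - shift
        lfc_by_guide = {g: v - shift for g, v in lfc_by_guide.items()}

    size = pseudo_gene_size if pseudo_gene_size is not None else library.guides_per_gene
    size = min(size, ntc_lfcs.size)
    null = build_ntc_null(ntc_lfcs, pseudo_gene_size=size, k=k, n_resamples=n_resamples, seed=seed)

    gene_scores: list[GeneScore] = []
    unscored: list[str] = []
    for gene, guide_ids in library.gene_to_guides().items():
        lfcs = [lfc_by_guide[g] for g in guide_ids if g in lfc_by_guide]
        if len(lfcs) < max(k, 2):
            unscored.append(gene)
            continue
        gene_scores.append(score_gene(lfcs, null, ntc_lfcs, tau=tau, gene_id=gene))

    if gene_scores:
        q = stats.false_discovery_control([s.p_value for s in gene_scores], method="bh")
        gene_scores = [replace(s, bh_q=float(qv)) for s, qv in zip(gene_scores, q)]
    return ScreenResult(
        phenotypes=phenotypes, null=null, gene_scores=gene_scores, unscored_genes=unscored
    )
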