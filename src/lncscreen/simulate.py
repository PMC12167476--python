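"""Generative model of a pooled CRISPRi dropout screen with known truth.

The simulator reproduces the stages of the screen that shape the count
data: unequal plasmid representation (log-normal), infection at low MOI
with Poisson founding at a chosen coverage, deterministic exponential
outgrowth where a guide's growth rate is reduced by its gene's fitness
effect scaled by that guide's efficacy, and multinomial (optionally
Dirichlet-multinomial overdispersed) sequencing of both the plasmid pool
and the endpoint.  Clone growth itself is deterministic: at >1000x
coverage the founding and sequencing sampling dominate the noise.

Ground truth (per-gene effects, per-guide efficacies) is carried in
:class:`SimTruth` so recovery tests can compare calls against what was
planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lncscreen.library_model import LibraryDesign
from lncscreen.quantify import CountTable


@dataclass(frozen=True)
class SimConfig:
    """Screen-simulation parameters.

    Defaults mirror the screen's stated conditions: infection at MOI 0.3,
    >1000 cells per guide, 21 days of growth at roughly one doubling per
    day, and sequencing depth of 500 reads per guide per sample.
    """

    seed: int = 0
    moi: float = 0.3
    coverage: float = 1000.0
    days: float = 21.0
    doubling_time_days: float = 1.0
    depth: int | None = None  # None -> 500 * library size
    dispersion: float = 0.0
    plasmid_lognormal_sigma: float = 0.5
    guide_active_fraction: float = 0.7
    knockdown_given_active: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.moi <= 1:
            raise ValueError("moi must be in (0, 1]")
        if self.coverage <= 0 or self.days < 0 or self.doubling_time_days <= 0:
            raise ValueError("coverage and doubling_time must be positive, days >= 0")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0 or self.plasmid_lognormal_sigma < 0:
            raise ValueError("dispersion and plasmid_lognormal_sigma must be >= 0")
        if not 0 <= self.guide_active_fraction <= 1:
            raise ValueError("guide_active_fraction must be in [0, 1]")
        if not 0 < self.knockdown_given_active <= 1:
            raise ValueError("knockdown_given_active must be in (0, 1]")

    def resolve_depth(self, library_size: int) -> int:
        return self.depth if self.depth is not None else 500 * library_size


@dataclass
class SimTruth:
    """Planted per-gene fitness effects and per-guide efficacies.

    ``gene_effect`` is the fractional growth-rate deficit when a gene is
    fully perturbed (0 neutral, 1 growth arrested); ``guide_efficacy``
    scales that deficit per guide.  NTC guides have efficacy 0.
    """

    gene_effect: dict[str, float]
    guide_efficacy: dict[str, float]

    def __post_init__(self) -> None:
        for g, e in self.gene_effect.items():
            if not 0 <= e <= 1:
                raise ValueError(f"gene_effect[{g!r}] = {e} outside [0, 1]")
        for g, e in self.guide_efficacy.items():
            if not 0 <= e <= 1:
                raise ValueError(f"guide_efficacy[{g!r}] = {e} outside [0, 1]")

    def to_frame(self, library: LibraryDesign) -> pd.DataFrame:
        rows = []
        for g in library:
            rows.append(
                {
                    "guide_id": g.guide_id,
                    "target_gene_id": g.target_gene_id,
                    "gene_effect": self.gene_effect.get(g.target_gene_id, 0.0)
                    if g.target_gene_id
                    else 0.0,
                    "guide_efficacy": self.guide_efficacy.get(g.guide_id, 0.0),
                }
            )
        return pd.DataFrame(rows)


def make_truth(
    library: LibraryDesign,
    gene_effects: Mapping[str, float] | None,
    config: SimConfig,
    seed: int | None = None,
) -> SimTruth:
    """Assign ground truth under the default guide-efficacy model.

    Each targeting guide is active with probability
    ``guide_active_fraction``; active guides get efficacy
    ``knockdown_given_active``, inactive guides 0.  NTC guides always 0.
    Genes not named in ``gene_effects`` are neutral (effect 0).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    effects = dict(gene_effects or {})
    known_genes = set(library.gene_to_guides())
    unknown = sorted(set(effects) - known_genes)
    if unknown:
        raise ValueError(f"gene_effects name genes absent from the library: {unknown[:10]}")
    efficacy: dict[str, float] = {}
    for g in library:
        if g.guide_class == "non_targeting":
            efficacy[g.guide_id] = 0.0
        else:
            active = rng.random() < config.guide_active_fraction
            efficacy[g.guide_id] = config.knockdown_given_active if active else 0.0
    for gene in known_genes:
        effects.setdefault(gene, 0.0)
    return SimTruth(gene_effect=effects, guide_efficacy=efficacy)


def _single_integration_fraction(moi: float) -> float:
    """Probability an infected cell carries exactly one integration
    (zero-truncated Poisson)."""
    return moi * math.exp(-moi) / (1.0 - math.exp(-moi))


def _sample_counts(
    rng: np.random.Generator, weights: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        return np.zeros_like(weights, dtype=np.int64)
    p = weights / total
    if dispersion > 0:
        # Dirichlet-multinomial: concentration p/dispersion, smaller
        # dispersion -> closer to plain multinomial
        alpha = np.where(p > 0, p / dispersion, 0.0)
        live = alpha > 0
        pd_ = np.zeros_like(p)
        pd_[live] = rng.dirichlet(alpha[live])
        p = pd_
    return rng.multinomial(depth, p).astype(np.int64)


def simulate_screen(
    library: LibraryDesign,
    truth: SimTruth,
    config: SimConfig,
    n_endpoints: int = 1,
    reference_sample: str = "plasmid",
    endpoint_prefix: str = "day21",
) -> tuple[CountTable, SimTruth]:
    """Simulate plasmid + endpoint counts for a library under planted truth.

    Stages: plasmid abundance a_g ~ LogNormal(0, sigma); founders ~
    Poisson(coverage * a_g / mean(a) * P(single integration | MOI));
    growth rate r_g = ln2/Td * (1 - effect * efficacy); endpoint clone
    size founders * exp(r_g * days); each sample sequenced to ``depth``
    reads by multinomial (Dirichlet-multinomial when dispersion > 0).
    Returns the count table and the truth echoed back.
    """
    guide_ids = library.guide_ids
    missing = [g.guide_id for g in library if g.guide_id not in truth.guide_efficacy]
    missing += [
        g.target_gene_id
        for g in library
        if g.target_gene_id and g.target_gene_id not in truth.gene_effect
    ]
    if missing:
        raise ValueError(f"truth missing ids: {sorted(set(missing))[:10]}")
    if n_endpoints < 1:
        raise ValueError("n_endpoints must be >= 1")

    rng = np.random.default_rng(config.seed)
    n = len(guide_ids)
    depth = config.resolve_depth(n)

    abundance = rng.lognormal(mean=0.0, sigma=config.plasmid_lognormal_sigma, size=n)
    lam = config.coverage * abundance / abundance.mean() * _single_integration_fraction(config.moi)
    founders = rng.poisson(lam)

    effect = np.array(
        [truth.gene_effect.get(g.target_gene_id, 0.0) if g.target_gene_id else 0.0 for g in library]
    )
    efficacy = np.array([truth.guide_efficacy[g.guide_id] for g in library])
    growth_rate = math.log(2.0) / config.doubling_time_days * (1.0 - effect * efficacy)
    clone_size = founders * np.exp(growth_rate * config.days)

    cols = [_sample_counts(rng, abundance, depth, config.dispersion)]
    sample_ids = [reference_sample]
    for i in range(n_endpoints):
        cols.append(_sample_counts(rng, clone_size, depth, config.dispersion))
        sample_ids.append(endpoint_prefix if n_endpoints == 1 else f"{endpoint_prefix}_r{i + 1}")
    table = CountTable(
        guide_ids=list(guide_ids),
        sample_ids=sample_ids,
        counts=np.column_stack(cols),
        reference_sample=reference_sample,
    )
    return table, truth


def write_fastq(
    table: CountTable,
    library: LibraryDesign,
    out_dir: str | Path,
    context5: str = "",
    read_len: int | None = None,
    pad_base: str = "A",
) -> dict[str, Path]:
    """Write one FASTQ per sample with exactly count(g, s) reads per guide.

    Each read is ``context5 + spacer`` (padded to ``read_len`` if given),
    so counting with trim5 = len(context5) recovers the table exactly.
    Returns sample -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacer = {g.guide_id: g.spacer for g in library}
    paths: dict[str, Path] = {}
    for j, sid in enumerate(table.sample_ids):
        path = out_dir / f"{sid}.fastq"
        with open(path, "w") as fh:
            r = 0
            for gid, c in zip(table.guide_ids, table.counts[:, j]):
                seq = context5 + spacer[gid]
                if read_len is not None and len(seq) < read_len:
                    seq = seq + pad_base * (read_len - len(seq))
                qual = "I" * len(seq)
                for _ in range(int(c)):
                    fh.write(f"@{sid}_read{r}_{gid}\n{seq}\n+\n{qual}\n")
                    r += 1
        paths[sid] = path
    return paths


def power_grid(
    library: LibraryDesign,
    effect_sizes: Sequence[float],
    n_planted: int,
    replicates: int,
    seed: int,
    config: SimConfig | None = None,
    tau: float = 3.0,
    k: int = 3,
    n_resamples: int = 2000,
) -> pd.DataFrame:
    """Detection power and false-positive rate across planted effect sizes.

    For each effect size and replicate, plants ``n_planted`` lncRNA genes
    at that growth-rate deficit, simulates a screen, runs the scoring
    pipeline, and tallies the fraction of planted genes called positive
    regulators (power) and of neutral genes called either hit class
    (FPR), with Monte-Carlo standard errors.
    """
    from lncscreen.score import score_screen

    if replicates < 10:
        raise ValueError("replicates must be >= 10")
    base = config or SimConfig()
    genes = sorted(
        {g.target_gene_id for g in library if g.guide_class == "tss_targeting"}
    )
    if n_planted > len(genes):
        raise ValueError("n_planted exceeds the number of lncRNA genes")
    ss = np.random.SeedSequence(seed)
    rows = []
    for effect in effect_sizes:
        powers, fprs = [], []
        for child in ss.spawn(replicates):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(rep_seed)
            planted = list(rng.choice(genes, size=n_planted, replace=False))
            cfg = SimConfig(**{**asdict(base), "seed": rep_seed})
            truth = make_truth(library, {g: float(effect) for g in planted}, cfg, seed=rep_seed + 1)
            table, _ = simulate_screen(library, truth, cfg)
            res = score_screen(
                table, library, endpoint="day21", tau=tau, k=k,
                n_resamples=n_resamples, seed=rep_seed + 2,
            )
            planted_set = set(planted)
            hit_by_gene = {s.gene_id: s.hit_class for s in res.gene_scores}
            planted_scored = [g for g in planted_set if g in hit_by_gene]
            neutral = [g for g in hit_by_gene if g not in planted_set]
            if planted_scored and effect > 0:
                powers.append(
                    np.mean([hit_by_gene[g] == "positive_regulator" for g in planted_scored])
                )
            if neutral:
                fprs.append(np.mean([hit_by_gene[g] != "none" for g in neutral]))
        row = {"effect": float(effect), "replicates": replicates}
        if powers:
            row["power"] = float(np.mean(powers))
            row["power_se"] = float(np.std(powers, ddof=1) / math.sqrt(len(powers))) if len(powers) > 1 else 0.0
        else:
            row["power"] = float("nan")
            row["power_se"] = float("nan")
        row["fpr"] = float(np.mean(fprs)) if fprs else float("nan")
        row["fpr_se"] = (
            float(np.std(fprs, ddof=1) / math.sqrt(len(fprs))) if len(fprs) > 1 else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows)

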