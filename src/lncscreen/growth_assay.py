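"""Mixed-cell competition (mCherry) growth assay analysis.

Knockdown cells carrying an mCherry-marked sgRNA are mixed 1:1 with
unmarked cells and the marker-positive fraction is followed by flow
cytometry.  Under constant relative growth rates the *odds* of being
marker-positive, f/(1-f), evolve exponentially, so enrichment is defined
on the odds scale normalized to day 0:

    E(t) = [f(t)/(1-f(t))] / [f(0)/(1-f(0))]

E = 1 means the two populations grow equally; E < 1 means the
guide-bearing cells are outgrown.  Percent growth change of a knockdown
line is measured against the median enrichment of control-sgRNA lines:
100 * (1 - E_target/median(E_controls)), positive = decreased growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AssaySeries:
    """Marker-positive fraction over time for one cell line."""

    line_id: str
    sgrna_id: str
    is_control: bool
    timepoints: tuple[float, ...]
    cherry_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.timepoints
        f = self.cherry_fraction
        if len(t) != len(f) or len(t) == 0:
            raise ValueError("timepoints and fractions must be equal-length and non-empty")
        if t[0] != 0:
            raise ValueError("timepoints must start at day 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(not 0 < x < 1 for x in f):
            raise ValueError("cherry fractions must be strictly inside (0, 1)")

    def fraction_at(self, t: float) -> float:
        try:
            return self.cherry_fraction[self.timepoints.index(t)]
        except ValueError:
            raise KeyError(f"line {self.line_id!r}: no measurement at day {t}") from None


def _odds(f: float) -> float:
    if not 0 < f < 1:
        raise ValueError(f"fraction {f} has undefined odds")
    return f / (1.0 - f)


def enrichment(series: AssaySeries, t: float) -> float:
    """Odds of being marker-positive at day t, normalized to day 0."""
    return _odds(series.fraction_at(t)) / _odds(series.fraction_at(0))


def percent_growth_change(
    target: AssaySeries, controls: Sequence[AssaySeries], t: float
) -> float:
    """Percent decreased growth of target vs the median of control lines.

    100 * (1 - E_target(t) / median(E_controls(t))); positive values mean
    the knockdown line grew less than controls (75 = 75% decreased
    growth), negative values mean it outgrew them.
    """
    if not controls:
        raise ValueError("need at least one control series")
    e_t = enrichment(target, t)
    e_c = float(np.median([enrichment(c, t) for c in controls]))
    return 100.0 * (1.0 - e_t / e_c)


def simulate_assay(
    relative_growth_deficit: float,
    days: Sequence[float] = tuple(range(0, 22, 2)),
    doubling_time_days: float = 1.0,
    measurement_cv: float = 0.0,
    seed: int = 0,
    start_fraction: float = 0.5,
    line_id: str = "sim",
    sgrna_id: str = "sim_sg1",
    is_control: bool = False,
) -> AssaySeries:
    """Simulate a competition series under a constant growth deficit.

    The marked population doubles every ``doubling_time_days /
    (1 - deficit)`` days while the unmarked reference doubles every
    ``doubling_time_days``, so the odds decay as
    ``odds(t) = odds(0) * 2^(-t * deficit / Td)``.  Measured fractions
    get multiplicative noise with the given CV, clipped inside (0, 1).
    """
    if not 0 <= relative_growth_deficit <= 1:
        raise ValueError("relative_growth_deficit must be in [0, 1]")
    if not 0 < start_fraction < 1:
        raise ValueError("start_fraction must be in (0, 1)")
    if measurement_cv < 0:
        raise ValueError("measurement_cv must be >= 0")
    days = tuple(float(d) for d in days)
    rng = np.random.default_rng(seed)
    odds0 = _odds(start_fraction)
    fractions = []
    for t in days:
        odds = odds0 * 2.0 ** (-t * relative_growth_deficit / doubling_time_days)
        f = odds / (1.0 + odds)
        if measurement_cv > 0:
            f = f * (1.0 + measurement_cv * rng.standard_normal())
        fractions.append(float(min(max(f, 1e-6), 1 - 1e-6)))
    return AssaySeries(
        line_id=line_id, sgrna_id=sgrna_id, is_control=is_control,
        timepoints=days, cherry_fraction=tuple(fractions),
    )


def fit_growth_deficit(series: AssaySeries, doubling_time_days: float = 1.0) -> float:
    """Recover the relative growth deficit from a competition series.

    Least-squares slope of log2 odds vs time: deficit = -slope * Td.
    Exact inversion of :func:`simulate_assay` for noiseless data.
    """
    t = np.asarray(series.timepoints)
    log2_odds = np.log2([_odds(f) for f in series.cherry_fraction])
    slope = np.polyfit(t, log2_odds, 1)[0]
    return float(-slope * doubling_time_days)


# ---------------------------------------------------------------------------
# CSV I/O: long format, one row per (line, day)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["line_id", "sgrna_id", "is_control", "day", "cherry_fraction"]


def read_assay_csv(path: str | Path) -> list[AssaySeries]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    out = []
    for (line, sg, ctl), grp in df.groupby(["line_id", "sgrna_id", "is_control"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            AssaySeries(
                line_id=str(line), sgrna_id=str(sg), is_control=bool(ctl),
                timepoints=tuple(float(d) for d in grp["day"]),
                cherry_fraction=tuple(float(f) for f in grp["cherry_fraction"]),
            )
        )
    return out


def write_assay_csv(series: Sequence[AssaySeries], path: str | Path) -> None:
    rows = [
        {
            "line_id": s.line_id, "sgrna_id": s.sgrna_id, "is_control": s.is_control,
            "day": t, "cherry_fraction": f,
        }
        for s in series
        for t, f in zip(s.timepoints, s.cherry_fraction)
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def assay_report(series: Sequence[AssaySeries], t: float) -> pd.DataFrame:
    """Enrichment and percent growth change at day t for every non-control line."""
    controls = [s for s in series if s.is_control]
    targets = [s for s in series if not s.is_control]
    if not controls:
        raise ValueError("no control series in input")
    ctrl_median = float(np.median([enrichment(c, t) for c in controls]))
    rows = []
    for s in targets:
        e = enrichment(s, t)
        rows.append(
            {
                "line_id": s.line_id,
                "sgrna_id": s.sgrna_id,
                "enrichment": e,
                "control_median_enrichment": ctrl_median,
                "percent_decreased_growth": 100.0 * (1.0 - e / ctrl_median),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "AssaySeries",
    "enrichment",
    "percent_growth_change",
    "simulate_assay",
    "fit_growth_deficit",
    "read_assay_csv",
    "write_assay_csv",
    "assay_report",
]
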