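"""Homolog pairing scoring, time-course rates, and collision-trap counts.

A nucleus with two GFP-marked homologous loci shows one fluorescent spot
when the loci lie closer than 0.2 µm ("paired") and two spots otherwise.
The pairing rate of a strain is estimated from the hourly time course as
the change in percent paired between t3 and t5 divided by 2, in percent
paired per hour.  Collision-trap experiments score the fraction of
single-spot nuclei among cells at the earliest prophase stage (Zip1 spots
present, no Zip1 lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "CellSpotObservation",
    "PairingTimecourse",
    "CollisionCounts",
    "score_paired",
    "paired_fraction",
    "pairing_rate",
    "pairing_rate_regression",
    "collision_counts",
    "correlate_rate_vs_rpm",
]

STAGES = ("pre_meiotic", "zip1_spots", "zip1_lines", "later")
PAIRING_THRESHOLD_UM = 0.2


@dataclass
class CellSpotObservation:
    """One scored nucleus: spot count, optional separation, prophase stage."""

    cell_id: str
    n_spots: int
    spot_separation_um: float | None = None
    stage: str = "zip1_spots"
    trap: str = "none"
    genotype: str = ""
    locus_pair: str = ""
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        if self.n_spots not in (1, 2):
            raise ValueError("n_spots must be 1 or 2")
        if self.spot_separation_um is not None and self.spot_separation_um < 0:
            raise ValueError("spot separation must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.trap not in ("dimer", "tetramer", "none"):
            raise ValueError("trap must be 'dimer', 'tetramer' or 'none'")


@dataclass
class PairingTimecourse:
    """Percent paired per hourly timepoint for one genotype × locus."""

    genotype: str
    locus: str
    hours: list[float]
    percent_paired: list[float]
    n_cells: list[int]
    replicate_id: str = ""
    true_rate_pct_per_h: float | None = None  # set by the simulator

    def __post_init__(self) -> None:
        if not (len(self.hours) == len(self.percent_paired) == len(self.n_cells)):
            raise ValueError("hours, percent_paired and n_cells must align")
        if any(b <= a for a, b in zip(self.hours, self.hours[1:])):
            raise ValueError("hours must be strictly increasing")
        if any(not 0.0 <= p <= 100.0 for p in self.percent_paired):
            raise ValueError("percent_paired must lie in [0, 100]")

    def percent_at(self, hour: float) -> float:
        for h, p in zip(self.hours, self.percent_paired):
            if h == hour:
                return p
        raise KeyError(f"timepoint t{hour:g} not present in the time course")


@dataclass
class CollisionCounts:
    """Single- vs two-spot nucleus counts for one condition."""

    condition: str
    n_single: int
    n_double: int

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_double < 0:
            raise ValueError("counts must be non-negative")
        if self.n_single + self.n_double == 0:
            raise ValueError("at least one nucleus must be counted")

    @property
    def n_total(self) -> int:
        return self.n_single + self.n_double

    @property
    def single_fraction_pct(self) -> float:
        return 100.0 * self.n_single / self.n_total


def score_paired(
    observation: CellSpotObservation | None = None,
    *,
    separation_um: float | None = None,
    positions: tuple[Sequence[float], Sequence[float]] | None = None,
    threshold_um: float = PAIRING_THRESHOLD_UM,
) -> bool:
    """Score a nucleus as paired.

    Paired means a single resolvable spot, or two spots strictly closer
    than the threshold (default 0.2 µm; a separation of exactly the
    threshold scores unpaired).  Accepts an observation, a separation, or a
    pair of spot positions.
    """
    if observation is not None:
        if observation.n_spots == 1:
            return True
        if observation.spot_separation_um is None:
            raise ValueError("two-spot observation without a separation")
        return observation.spot_separation_um < threshold_um
    if positions is not None:
        a, b = (np.asarray(p, dtype=float) for p in positions)
        separation_um = float(np.linalg.norm(a - b))
    if separation_um is None:
        raise ValueError("provide an observation, a separation, or two positions")
    return separation_um < threshold_um


def paired_fraction(
    observations: Iterable[CellSpotObservation],
    stage_filter: str | Sequence[str] | None = None,
    threshold_um: float = PAIRING_THRESHOLD_UM,
) -> tuple[float, int]:
    """Percent of cells scoring paired, with the n after stage filtering.

    For collision-trap analysis ``stage_filter="zip1_spots"`` keeps only
    early-prophase nuclei (Zip1 spots present, no lines).
    """
    if stage_filter is None:
        kept = list(observations)
    else:
        stages = (stage_filter,) if isinstance(stage_filter, str) else tuple(stage_filter)
        kept = [o for o in observations if o.stage in stages]
    if not kept:
        raise ValueError("no observations left after stage filtering")
    n_paired = sum(score_paired(o, threshold_um=threshold_um) for o in kept)
    return 100.0 * n_paired / len(kept), len(kept)


def collision_counts(
    observations: Iterable[CellSpotObservation],
    condition: str,
    stage_filter: str | Sequence[str] | None = "zip1_spots",
) -> CollisionCounts:
    """Single-/two-spot counts for one condition after stage filtering."""
    if stage_filter is None:
        kept = list(observations)
    else:
        stages = (stage_filter,) if isinstance(stage_filter, str) else tuple(stage_filter)
        kept = [o for o in observations if o.stage in stages]
    if not kept:
        raise ValueError("no observations left after stage filtering")
    n_single = sum(o.n_spots == 1 for o in kept)
    return CollisionCounts(
        condition=condition, n_single=n_single, n_double=len(kept) - n_single
    )


def pairing_rate(timecourse: PairingTimecourse, t_start: float = 3.0, t_end: float = 5.0) -> float:
    """Pairing rate in percent paired per hour.

    The t3 percent paired is subtracted from the t5 value and the
    difference divided by the elapsed 2 h.  The estimate may be negative.
    """
    p_start = timecourse.percent_at(t_start)
    p_end = timecourse.percent_at(t_end)
    return (p_end - p_start) / (t_end - t_start)


def pairing_rate_regression(timecourse: PairingTimecourse) -> float:
    """Least-squares alternative: slope of percent paired over all hours."""
    slope, _ = np.polyfit(timecourse.hours, timecourse.percent_paired, 1)
    return float(slope)


def correlate_rate_vs_rpm(
    rates_by_genotype: Mapping[str, float],
    rpm_by_genotype: Mapping[str, float],
) -> tuple[float, float, pd.DataFrame]:
    """Spearman rank correlation between pairing rates and an RPM measure.

    Both mappings are keyed by genotype; only genotypes present in both are
    used and at least three matches are required.  Returns (ρ, p, scatter
    table) where the table has one row per genotype for plotting.
    """
    common = sorted(set(rates_by_genotype) & set(rpm_by_genotype))
    if len(common) < 3:
        raise ValueError("need at least 3 matched genotypes")
    rates = [rates_by_genotype[g] for g in common]
    rpms = [rpm_by_genotype[g] for g in common]
    rho, p = _st.spearmanr(rates, rpms)
    table = pd.DataFrame({"genotype": common, "pairing_rate": rates, "rpm": rpms})
    return float(rho), float(p), table
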