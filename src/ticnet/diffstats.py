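"""Cross-state and intra-replicate log2-ratio populations and Znet scores.

For a comparison of state A against state B with two biological replicates
each, every retained protein contributes four log2 differences of TIC:

    Z0 = log2 A1 - log2 B1        cross-state, replicate pair 1
    Z1 = log2 A2 - log2 B2        cross-state, replicate pair 2
    R0 = log2 A1 - log2 A2        intra-replicate, state A
    R1 = log2 B1 - log2 B2        intra-replicate, state B

Three populations — {Z0}, {Z1} and the pooled intra-replicate {R0 u R1} —
are each normalized to mean 0 / sd 1. The two normalized cross-state values
are averaged per protein and the merged population renormalized to unit sd,
giving the Znet score. Fixed cutoffs 1.0 / 1.65 / 1.96 mark the outermost
33% / 10% / 5% of a null population; a positive Znet means higher
expression in the first-named state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Comparison, TicTable
from .errors import (
    DegeneratePopulationError,
    InsufficientDataError,
    UnsupportedDesignError,
    ValidationError,
)

#: Tier thresholds on |Znet|: outermost 33% / 10% / 5% of a null population.
TIER_THRESHOLDS = (1.0, 1.65, 1.96)
TIER_NAMES = ("inner", "outer33", "outer10", "outer5")

#: Default significance threshold (outermost 10%).
SIGNIFICANCE_THRESHOLD = 1.65


@dataclass
class RatioPopulations:
    """Per-protein Z0, Z1, R0, R1 values for one comparison."""

    frame: pd.DataFrame
    comparison: Comparison

    def __post_init__(self) -> None:
        needed = {"Z0", "Z1", "R0", "R1"}
        if not needed.issubset(self.frame.columns):
            raise ValidationError(f"ratio frame must have columns {sorted(needed)}")
        if not np.isfinite(self.frame[list(needed)].to_numpy()).all():
            raise ValidationError(
                "non-finite ratio encountered; detection filter contract violated"
            )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ComparisonResult:
    """Per-protein merged scores and flags for one two-state comparison.

    ``frame`` columns grow as the pipeline proceeds: Z0..R1 and their
    normalized counterparts, ``znet``, then ``tier``/``direction``/
    ``significant`` and finally ``sn``/``sn_reliable``.
    """

    frame: pd.DataFrame
    comparison: Comparison
    system_sn: float | None = None
    nd_proteins: pd.Index = field(default_factory=lambda: pd.Index([]))


def compute_ratio_populations(
    table: TicTable, comparison: Comparison
) -> RatioPopulations:
    """Evaluate the four log2-difference formulas on a filtered table.

    The table must already have passed the detection filter for this
    comparison (no ND among the four samples).
    """
    a1, a2, b1, b2 = (
        np.log2(table.values[c]) for c in table.comparison_samples(comparison)
    )
    frame = pd.DataFrame(
        {"Z0": a1 - b1, "Z1": a2 - b2, "R0": a1 - a2, "R1": b1 - b2},
        index=table.values.index,
    )
    return RatioPopulations(frame, comparison)


def normalize_population(values, name: str = "population") -> np.ndarray:
    """Center to mean 0 and scale to sample (n-1) sd 1; rank-preserving."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"population {name!r} needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegeneratePopulationError(name)
    return (x - x.mean()) / sd


def population_stats(pops: RatioPopulations) -> dict[str, tuple[float, float]]:
    """(mean, sample sd) of the three normalization populations.

    Z0 and Z1 are normalized separately; the intra-replicate population
    pools R0 and R1.
    """
    f = pops.frame
    pooled = np.concatenate([f["R0"].to_numpy(), f["R1"].to_numpy()])
    out = {}
    for name, arr in (("Z0", f["Z0"].to_numpy()), ("Z1", f["Z1"].to_numpy()),
                      ("R", pooled)):
        sd = arr.std(ddof=1)
        if sd == 0:
            raise DegeneratePopulationError(name)
        out[name] = (float(arr.mean()), float(sd))
    return out


def normalized_populations(pops: RatioPopulations) -> pd.DataFrame:
    """Z0n, Z1n, R0n, R1n on the mean-0 / sd-1 scale of their populations."""
    st = population_stats(pops)
    f = pops.frame
    return pd.DataFrame(
        {
            "Z0n": (f["Z0"] - st["Z0"][0]) / st["Z0"][1],
            "Z1n": (f["Z1"] - st["Z1"][0]) / st["Z1"][1],
            "R0n": (f["R0"] - st["R"][0]) / st["R"][1],
            "R1n": (f["R1"] - st["R"][0]) / st["R"][1],
        },
        index=f.index,
    )


def merge_znet(pops: RatioPopulations) -> ComparisonResult:
    """Merge the normalized cross-state values into Znet scores.

    Znet_i = mean(Z0n_i, Z1n_i), with the merged population recentered to
    mean 0 and renormalized to unit sample sd so the fixed tier cutoffs
    keep their null-tail meaning.
    """
    if len(pops) < 2:
        raise InsufficientDataError("need >= 2 proteins to merge Znet scores")
    if {"Z0", "Z1"} - set(pops.frame.columns):
        raise UnsupportedDesignError("exactly two replicates per state required")
    norm = normalized_populations(pops)
    merged = (norm["Z0n"] + norm["Z1n"]) / 2.0
    znet = pd.Series(
        normalize_population(merged.to_numpy(), name="Znet"),
        index=merged.index, name="znet",
    )
    frame = pd.concat([pops.frame, norm], axis=1)
    frame["znet"] = znet
    return ComparisonResult(frame, pops.comparison)


def classify_tiers(
    result: ComparisonResult,
    thresholds: tuple[float, float, float] = TIER_THRESHOLDS,
) -> ComparisonResult:
    """Assign tier, direction and the outer-10% significance flag.

    Tier boundaries use strict inequality: |Znet| > 1.96 -> outer5,
    > 1.65 -> outer10, > 1.0 -> outer33, else inner.
    """
    t33, t10, t5 = thresholds
    z = result.frame["znet"]
    az = z.abs()
    tier = np.select(
        [az > t5, az > t10, az > t33],
        [TIER_NAMES[3], TIER_NAMES[2], TIER_NAMES[1]],
        default=TIER_NAMES[0],
    )
    result.frame["tier"] = tier
    result.frame["direction"] = np.select(
        [z > 0, z < 0], ["up", "down"], default="none"
    )
    result.frame["significant"] = az > t10
    return result
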