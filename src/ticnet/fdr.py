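"""Signal-to-noise statistics and Monte-Carlo FDR calibration.

The system S/N is a dataset-level quality measure: the mean of the two
cross-state population standard deviations divided by the mean of the two
intra-replicate ones. The per-protein S/N compares a protein's cross-state
vector magnitude to its intra-replicate vector magnitude on the normalized
(unit-sd) scale — the unit-sd normalization is what realizes the scaling by
overall system quality. Under the statistic's reference null (independent
standard-normal components) sn^2 follows F(2,2), so P(sn > c) = 1/(1+c^2).

The Monte-Carlo FDR model destroys the cross-state structure per protein by
relabeling the four samples into the two pseudo-state splits that do not
reproduce the true states; intra-replicate noise is preserved, and pseudo
populations are scaled with the observed populations' normalization
constants so null exceedances are counted on the same scale as the observed
statistic. FDR(c) = E[null exceedances at c] / observed exceedances at c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import (
    ComparisonResult,
    RatioPopulations,
    normalized_populations,
    population_stats,
)
from .errors import AlignmentError, DegeneratePopulationError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Per-protein S/N cutoff calibrated to FDR <= 10%.
SN_CUTOFF = 2.8

DEFAULT_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


@dataclass
class SnScores:
    """System S/N plus the per-protein statistic for one comparison."""

    system: float
    values: pd.Series  # per-protein sn; +inf where intra-replicate magnitude 0
    method: str = "normalized"

    @property
    def infinite(self) -> pd.Series:
        return ~np.isfinite(self.values)


@dataclass
class FdrCurve:
    """Monte-Carlo map from S/N cutoff to estimated FDR.

    ``fdr`` is NaN where the observed data has no discoveries at the cutoff
    (the rate is undefined there, not zero). Defined entries are clipped to
    [0, 1] and made nonincreasing by a cumulative minimum from the right.
    """

    cutoffs: np.ndarray
    fdr: np.ndarray
    reps: int
    seed: int

    def fdr_at(self, cutoff: float) -> float:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        if not np.isclose(self.cutoffs[i], cutoff):
            raise ValueError(f"cutoff {cutoff} not on the grid")
        return float(self.fdr[i])


def system_sn(pops: RatioPopulations) -> float:
    """mean(sd(Z0), sd(Z1)) / mean(sd(R0), sd(R1)) on the raw log2 scale."""
    if len(pops) < 2:
        raise InsufficientDataError("system S/N needs >= 2 proteins")
    f = pops.frame
    sd = {c: f[c].std(ddof=1) for c in ("Z0", "Z1", "R0", "R1")}
    denom = (sd["R0"] + sd["R1"]) / 2.0
    if denom == 0:
        raise DegeneratePopulationError("intra-replicate")
    return float((sd["Z0"] + sd["Z1"]) / 2.0 / denom)


def protein_sn(pops: RatioPopulations, method: str = "normalized") -> SnScores:
    """Per-protein S/N: cross-state over intra-replicate vector magnitude.

    ``method="normalized"`` (default) computes
    sqrt(Z0n^2 + Z1n^2) / sqrt(R0n^2 + R1n^2) on the mean-0/sd-1 scale.
    ``method="raw"`` divides the raw magnitude ratio by the system S/N;
    the two coincide when sd(Z0) = sd(Z1) and sd(R0) = sd(R1).

    Proteins whose intra-replicate magnitude is exactly zero get sn = +inf
    (maximal replicate consistency), flagged via :attr:`SnScores.infinite`.
    """
    system = system_sn(pops)
    if method == "normalized":
        n = normalized_populations(pops)
        num = np.hypot(n["Z0n"], n["Z1n"])
        den = np.hypot(n["R0n"], n["R1n"])
    elif method == "raw":
        f = pops.frame
        num = np.hypot(f["Z0"], f["Z1"]) / system
        den = np.hypot(f["R0"], f["R1"])
    else:
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(divide="ignore"):
        sn = num.to_numpy() / den.to_numpy()
    sn = np.where(den.to_numpy() == 0, np.inf, sn)
    values = pd.Series(sn, index=pops.frame.index, name="sn")
    n_inf = int((~np.isfinite(values)).sum())
    if n_inf:
        logger.warning("%d proteins with zero intra-replicate magnitude (sn=inf)",
                       n_inf)
    return SnScores(system=system, values=values, method=method)


def _null_relabelings(pops: RatioPopulations, pick: np.ndarray):
    """Pseudo Z/R under the two signal-destroying sample relabelings.

    With samples (A1, A2, B1, B2), the two 2+2 splits other than the true
    one are {A1,B1 | A2,B2} and {A1,B2 | A2,B1}. Both yield pseudo
    cross-state differences built purely from intra-replicate noise, while
    the true cross-state signal moves into the pseudo intra-replicate slots.
    All quantities are linear in the observed differences:

        split 1: Z* = ( R0,  R1)    R* = (Z0,      Z1     )
        split 2: Z* = ( R0, -R1)    R* = (Z0 + R1, Z1 - R1)
    """
    f = pops.frame
    Z0, Z1 = f["Z0"].to_numpy(), f["Z1"].to_numpy()
    R0, R1 = f["R0"].to_numpy(), f["R1"].to_numpy()
    pZ0 = R0
    pZ1 = np.where(pick, R1, -R1)
    pR0 = np.where(pick, Z0, Z0 + R1)
    pR1 = np.where(pick, Z1, Z1 - R1)
    return pZ0, pZ1, pR0, pR1


def monte_carlo_fdr(
    pops: RatioPopulations,
    grid: np.ndarray = DEFAULT_GRID,
    reps: int = 500,
    seed: int = 0,
    method: str = "normalized",
) -> FdrCurve:
    """Estimate FDR as a function of the per-protein S/N cutoff.

    For each Monte-Carlo replicate every protein independently receives one
    of the two signal-destroying relabelings; pseudo S/N values are computed
    with the observed populations' normalization constants, and exceedance
    counts over the grid are averaged across replicates.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable estimate")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")

    obs = protein_sn(pops, method=method).values.to_numpy()
    n_obs = (obs[:, None] > grid[None, :]).sum(axis=0)

    st = population_stats(pops)
    (mz0, sz0), (mz1, sz1), (mr, sr) = st["Z0"], st["Z1"], st["R"]

    rng = np.random.default_rng(seed)
    n = len(pops)
    null_counts = np.zeros(len(grid))
    for _ in range(reps):
        pick = rng.integers(0, 2, n).astype(bool)
        pZ0, pZ1, pR0, pR1 = _null_relabelings(pops, pick)
        num = np.hypot((pZ0 - mz0) / sz0, (pZ1 - mz1) / sz1)
        den = np.hypot((pR0 - mr) / sr, (pR1 - mr) / sr)
        with np.errstate(divide="ignore", invalid="ignore"):
            psn = np.where(den == 0, np.inf, num / den)
        psn = np.sort(psn)
        null_counts += n - np.searchsorted(psn, grid, side="right")
    null_mean = null_counts / reps

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, null_mean / np.maximum(n_obs, 1), np.nan)
    fdr = np.clip(fdr, 0.0, 1.0)
    # enforce monotonicity (nonincreasing in the cutoff) over defined entries
    defined = ~np.isnan(fdr)
    vals = fdr[defined][::-1]
    fdr[defined] = np.maximum.accumulate(vals)[::-1]
    return FdrCurve(cutoffs=grid, fdr=fdr, reps=reps, seed=seed)


def apply_sn_filter(
    result: ComparisonResult, scores: SnScores, cutoff: float = SN_CUTOFF
) -> ComparisonResult:
    """Attach per-protein S/N and the strict ``sn > cutoff`` reliability flag.

    Infinite sn (zero intra-replicate disagreement) passes the filter with a
    logged warning. The |Znet| significance flag and the S/N reliability
    flag are carried independently.
    """
    if not result.frame.index.equals(scores.values.index):
        raise AlignmentError("result and S/N scores cover different proteins")
    result.frame["sn"] = scores.values
    result.frame["sn_reliable"] = scores.values > cutoff
    result.system_sn = scores.system
    n_inf = int(scores.infinite.sum())
    if n_inf:
        logger.warning("%d proteins pass the S/N filter with infinite sn", n_inf)
    return result
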