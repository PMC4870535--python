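"""Core in-memory containers: the protein x sample TIC matrix and comparisons.

A :class:`TicTable` holds total-ion-count (TIC) protein quantities for a set
of samples, each sample belonging to a (state, replicate) cell of the design.
Not-detected (ND) entries are stored as NaN; a stored TIC is always > 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

_SAMPLE_RE = re.compile(r"^(?P<state>.+)_rep(?P<rep>\d+)$")


def parse_sample_id(sample_id: str) -> tuple[str, int]:
    """Split a ``<state>_rep<k>`` sample id into (state, replicate)."""
    m = _SAMPLE_RE.match(sample_id)
    if not m:
        raise SchemaError(
            f"sample id {sample_id!r} does not follow '<state>_rep<k>' convention"
        )
    return m.group("state"), int(m.group("rep"))


@dataclass(frozen=True)
class Comparison:
    """A two-state contrast; positive scores mean higher in ``state_a``."""

    state_a: str
    state_b: str

    @property
    def label(self) -> str:
        return f"{self.state_a}_vs_{self.state_b}"

    def swapped(self) -> "Comparison":
        return Comparison(self.state_b, self.state_a)


@dataclass
class TicTable:
    """Protein x sample TIC matrix with an explicit sample design.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample id; entries
        are positive TIC values or NaN for not-detected.
    design
        Mapping sample id -> (state, replicate number). Derived from the
        column names when omitted.
    """

    values: pd.DataFrame
    design: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.design:
            self.design = {c: parse_sample_id(c) for c in self.values.columns}
        missing = [c for c in self.values.columns if c not in self.design]
        if missing:
            raise SchemaError(f"samples without design entry: {missing}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(arr <= 0):
                raise ValidationError(
                    "TIC values must be positive or ND (NaN); found entries <= 0"
                )

    # -- design helpers -------------------------------------------------
    @property
    def states(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.design.values():
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for(self, state: str) -> list[str]:
        """Sample ids of ``state`` ordered by replicate number."""
        pairs = [
            (rep, sid) for sid, (st, rep) in self.design.items() if st == state
        ]
        if not pairs:
            raise SchemaError(f"state {state!r} not present in table")
        return [sid for _, sid in sorted(pairs)]

    def comparison_samples(self, comparison: Comparison) -> list[str]:
        """The four sample columns of a comparison: A1, A2, B1, B2."""
        a = self.samples_for(comparison.state_a)
        b = self.samples_for(comparison.state_b)
        if len(a) != 2 or len(b) != 2:
            raise SchemaError(
                f"comparison {comparison.label} needs exactly 2 replicates per "
                f"state, found {len(a)} and {len(b)}"
            )
        return a + b

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def log2(self, columns: list[str] | None = None) -> pd.DataFrame:
        cols = columns if columns is not None else list(self.values.columns)
        return np.log2(self.values[cols])
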