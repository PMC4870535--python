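"""Annotation-level summaries: COG cross-tabs, overlap counts, HOV rollups.

Proteins are grouped by higher-order variables (HOVs): COG single-letter
functional classes, EC numbers, KEGG modules or METACYC pathways. The COG
cross-tab counts significantly up/down proteins per class and comparison; a
protein with several COG letters is counted once per letter. The overlap
summary partitions the significant proteins of three comparisons into the
seven Venn regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .diffstats import SIGNIFICANCE_THRESHOLD, ComparisonResult
from .errors import ConfigError, ValidationError
from .fdr import SN_CUTOFF

#: Sentinel COG class for unannotated proteins ("Not in COG").
COG_UNKNOWN = "X"

VALID_COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

HOV_COLUMNS = {"COG": "cog", "EC": "ec", "KEGG": "kegg", "METACYC": "metacyc"}


@dataclass
class AnnotationMap:
    """Protein id -> COG letters / EC numbers / KEGG modules / METACYC pathways.

    Backed by a DataFrame indexed by protein id with string columns
    ``cog, ec, kegg, metacyc``; multiple memberships are ';'-separated and
    empty strings mean unannotated.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in HOV_COLUMNS.values():
            if col not in self.frame.columns:
                self.frame[col] = ""
        self.frame = self.frame.fillna("")
        bad = []
        for pid, cog in self.frame["cog"].items():
            for letter in self._split(cog):
                if letter not in VALID_COG_LETTERS:
                    bad.append((pid, letter))
        if bad:
            raise ValidationError(f"malformed COG letters: {bad[:10]}")

    @staticmethod
    def _split(value: str) -> list[str]:
        return [v for v in str(value).replace(",", ";").split(";") if v]

    def cogs_for(self, protein_id: str) -> list[str]:
        """COG letters of a protein; [X] when absent or unannotated."""
        if protein_id not in self.frame.index:
            return [COG_UNKNOWN]
        letters = self._split(self.frame.at[protein_id, "cog"])
        return letters or [COG_UNKNOWN]

    def categories_for(self, protein_id: str, hov: str) -> list[str]:
        if hov not in HOV_COLUMNS:
            raise ConfigError(
                f"unknown HOV {hov!r}; expected one of {sorted(HOV_COLUMNS)}"
            )
        if hov == "COG":
            return self.cogs_for(protein_id)
        if protein_id not in self.frame.index:
            return []
        return self._split(self.frame.at[protein_id, HOV_COLUMNS[hov]])


def cog_crosstab(
    results: list[ComparisonResult],
    ann: AnnotationMap,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """Up/down counts of significant proteins per COG class and comparison.

    A protein counts toward a comparison when |Znet| > ``threshold``; its
    direction is the sign of Znet; multi-letter assignments contribute once
    per letter. Unannotated proteins fall into class X. A ``Total`` row sums
    over classes.
    """
    labels = [r.comparison.label for r in results]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicated comparison labels: {labels}")

    counts: dict[tuple[str, str, str], int] = {}
    letters_seen: set[str] = set()
    for r in results:
        z = r.frame["znet"]
        hits = z[z.abs() > threshold]
        for pid, score in hits.items():
            direction = "up" if score > 0 else "down"
            for letter in ann.cogs_for(pid):
                letters_seen.add(letter)
                key = (letter, r.comparison.label, direction)
                counts[key] = counts.get(key, 0) + 1

    rows = sorted(letters_seen - {COG_UNKNOWN}) + (
        [COG_UNKNOWN] if COG_UNKNOWN in letters_seen else []
    )
    columns = pd.MultiIndex.from_tuples(
        [(lab, d) for lab in labels for d in ("up", "down")],
        names=["comparison", "direction"],
    )
    table = pd.DataFrame(0, index=pd.Index(rows, name="cog"), columns=columns)
    for (letter, lab, d), n in counts.items():
        table.loc[letter, (lab, d)] = n
    table.loc["Total"] = table.sum(axis=0)
    return table


def _significant_sets(
    results: list[ComparisonResult], use: str, threshold: float, sn_cutoff: float
) -> list[pd.Index]:
    sets = []
    for r in results:
        if use == "znet":
            mask = r.frame["znet"].abs() > threshold
        elif use == "sn":
            if "sn" not in r.frame.columns:
                raise ConfigError(
                    f"comparison {r.comparison.label} has no S/N scores"
                )
            mask = r.frame["sn"] > sn_cutoff
        else:
            raise ConfigError(f"unknown significance rule {use!r}")
        sets.append(r.frame.index[mask])
    return sets


def overlap_counts(
    results: list[ComparisonResult],
    use: str = "znet",
    threshold: float = SIGNIFICANCE_THRESHOLD,
    sn_cutoff: float = SN_CUTOFF,
) -> pd.DataFrame:
    """Venn-style partition of significant proteins across three comparisons.

    Each protein in the union of the three significant sets lands in exactly
    one of the 7 membership regions. Per region and member comparison the
    up/down split is recorded; non-member comparisons show 0.
    """
    if len(results) != 3:
        raise ConfigError(f"need exactly 3 comparisons, got {len(results)}")
    labels = [r.comparison.label for r in results]
    if len(set(labels)) != 3:
        raise ConfigError(f"duplicated comparison labels: {labels}")

    sets = _significant_sets(results, use, threshold, sn_cutoff)
    union = sets[0].union(sets[1]).union(sets[2])
    directions = [r.frame["direction"] for r in results]

    rows = []
    for membership in product((True, False), repeat=3):
        if not any(membership):
            continue
        region = [
            pid
            for pid in union
            if all((pid in sets[k]) == membership[k] for k in range(3))
        ]
        row: dict[str, object] = {
            "region": "&".join(
                lab for lab, m in zip(labels, membership) if m
            ),
            "n": len(region),
        }
        for k, lab in enumerate(labels):
            ups = downs = 0
            if membership[k]:
                for pid in region:
                    if directions[k].loc[pid] == "up":
                        ups += 1
                    else:
                        downs += 1
            row[f"{lab}_up"] = ups
            row[f"{lab}_down"] = downs
        rows.append(row)
    out = pd.DataFrame(rows).set_index("region")
    assert out["n"].sum() == len(union)
    return out


def hov_rollup(
    result: ComparisonResult,
    ann: AnnotationMap,
    hov: str = "COG",
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-category member count, significant up/down counts and mean Znet.

    A protein belonging to several categories of the chosen HOV appears in
    each of their rows.
    """
    if hov not in HOV_COLUMNS:
        raise ConfigError(
            f"unknown HOV {hov!r}; expected one of {sorted(HOV_COLUMNS)}"
        )
    records: dict[str, list] = {}
    for pid, row in result.frame.iterrows():
        for cat in ann.categories_for(pid, hov):
            records.setdefault(cat, []).append(row)
    out_rows = []
    for cat in sorted(records):
        members = pd.DataFrame(records[cat])
        sig = members["znet"].abs() > threshold
        out_rows.append(
            {
                "category": cat,
                "n_members": len(members),
                "n_up": int((sig & (members["znet"] > 0)).sum()),
                "n_down": int((sig & (members["znet"] < 0)).sum()),
                "mean_znet": float(members["znet"].mean()),
            }
        )
    return pd.DataFrame(
        out_rows, columns=["category", "n_members", "n_up", "n_down", "mean_znet"]
    ).set_index("category")
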