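"""TSV dialects, run configuration and result serialization.

All tables are plain tab-separated text. In TIC tables an empty field (or
the literal ``ND``) is a not-detected entry; zero intensities are normalized
to ND on ingest with a logged warning, because log2 is undefined at 0 and
the analysis reports ND, never 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import TicTable
from .containers import Comparison
from .errors import ConfigError, ParseError, SchemaError
from .diffstats import TIER_THRESHOLDS
from .fdr import SN_CUTOFF

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TIC tables
# ---------------------------------------------------------------------------

def read_tic_table(path: str | Path, design: dict | None = None) -> TicTable:
    """Read a protein x sample TIC table from TSV.

    First column is ``protein_id``; remaining headers are sample ids
    (``<state>_rep<k>`` unless an explicit design is given). Raises
    :class:`ParseError` with a line number for ragged rows, non-numeric or
    negative intensities, and duplicate protein ids.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "protein_id":
        raise SchemaError(
            f"{path}: header must start with 'protein_id' followed by sample ids"
        )
    samples = header[1:]
    ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    n_zero = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(fields)}", lineno
            )
        pid = fields[0]
        if pid in seen:
            raise ParseError(f"duplicate protein id {pid!r}", lineno)
        seen.add(pid)
        row: list[float] = []
        for value in fields[1:]:
            v = value.strip()
            if v in ("", "ND", "NA", "nan"):
                row.append(float("nan"))
                continue
            try:
                x = float(v)
            except ValueError:
                raise ParseError(f"non-numeric intensity {value!r}", lineno) from None
            if x < 0:
                raise ParseError(f"negative intensity {value!r}", lineno)
            if x == 0:
                n_zero += 1
                row.append(float("nan"))
            else:
                row.append(x)
        ids.append(pid)
        data.append(row)
    if n_zero:
        logger.warning("%s: %d zero intensities ingested as ND", path, n_zero)
    values = pd.DataFrame(
        data, index=pd.Index(ids, name="protein_id"), columns=samples
    )
    return TicTable(values, design=design or {})


def write_tic_table(table: TicTable, path: str | Path) -> Path:
    """Write a TIC table as TSV with empty fields for ND entries."""
    path = Path(path)
    out = table.values.copy()
    # keep integral counts readable; general floats round-trip via repr
    out = out.map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    out.to_csv(path, sep="\t", index=True, index_label="protein_id")
    return path


# ---------------------------------------------------------------------------
# Peptides, truth, annotations
# ---------------------------------------------------------------------------

def read_peptides(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_id": str,
                                            "sample_id": str})
    missing = {"peptide_id", "protein_id", "sample_id", "intensity"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: peptide table missing columns {sorted(missing)}")
    return df


def write_peptides(peptides: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    peptides.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=True, index_label="protein_id")
    return path


def read_annotation(path: str | Path):
    from .summarize import AnnotationMap

    df = pd.read_csv(path, sep="\t", index_col="protein_id", dtype=str).fillna("")
    return AnnotationMap(df)


def write_annotation(ann_frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ann_frame.to_csv(path, sep="\t", index=True, index_label="protein_id")
    return path


# ---------------------------------------------------------------------------
# Comparison results and FDR curves
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "Z0", "Z1", "R0", "R1", "znet", "sn", "tier", "direction",
    "significant", "sn_reliable",
]


def write_result(result, path: str | Path) -> Path:
    """Per-comparison result TSV (machine-readable analogue of a score table).

    The header comment states the sign convention: positive Znet = higher in
    the first-named state.
    """
    path = Path(path)
    cols = [c for c in RESULT_COLUMNS if c in result.frame.columns]
    frame = result.frame[cols].copy()
    nd = pd.DataFrame(
        {c: float("nan") if c not in ("tier", "direction") else "" for c in cols},
        index=result.nd_proteins,
    )
    if len(nd):
        nd["tier"] = "ND"
        nd["direction"] = "ND"
        frame = pd.concat([frame, nd])
    with open(path, "w") as fh:
        fh.write(
            f"# comparison: {result.comparison.label}; direction: "
            f"{result.comparison.state_a} minus {result.comparison.state_b}\n"
        )
        if result.system_sn is not None:
            fh.write(f"# system_sn: {result.system_sn:.6g}\n")
        frame.to_csv(fh, sep="\t", index=True, index_label="protein_id",
                     float_format="%.6g")
    return path


def write_fdr_curve(curve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"cutoff": curve.cutoffs, "fdr": curve.fdr}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    meta = Path(str(path) + ".meta.json")
    meta.write_text(
        json.dumps({"reps": curve.reps, "seed": curve.seed}, sort_keys=True) + "\n"
    )
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Thresholds default to the published values (tiers 1.0/1.65/1.96 on
    |Znet|, S/N cutoff 2.8); a seed is mandatory whenever the Monte-Carlo
    FDR stage is enabled.
    """

    tic_path: str | None = None
    peptide_path: str | None = None
    annotation_path: str | None = None
    comparisons: list[Comparison] = field(default_factory=list)
    tier_thresholds: tuple[float, float, float] = TIER_THRESHOLDS
    sn_cutoff: float = SN_CUTOFF
    mc_enabled: bool = True
    mc_reps: int = 500
    mc_grid_max: float = 10.0
    mc_grid_step: float = 0.1
    seed: int | None = None
    output_dir: str = "ticnet_out"

    def __post_init__(self) -> None:
        if (self.tic_path is None) == (self.peptide_path is None):
            raise ConfigError("exactly one of tic_path / peptide_path is required")
        if not self.comparisons:
            raise ConfigError("comparisons: at least one comparison is required")
        labels = [c.label for c in self.comparisons]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"comparisons: duplicated labels {labels}")
        if self.mc_enabled and self.seed is None:
            raise ConfigError("seed is required when the Monte-Carlo stage is enabled")
        if len(self.tier_thresholds) != 3:
            raise ConfigError("tier_thresholds must have exactly 3 values")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            comparisons = [
                Comparison(c["state_a"], c["state_b"])
                for c in raw.get("comparisons", [])
            ]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"comparisons: each entry needs state_a/state_b ({exc})")
        inp = raw.get("input", {})
        thr = raw.get("thresholds", {})
        mc = raw.get("monte_carlo", {})
        return cls(
            tic_path=inp.get("tic"),
            peptide_path=inp.get("peptides"),
            annotation_path=raw.get("annotation"),
            comparisons=comparisons,
            tier_thresholds=tuple(thr.get("tiers", TIER_THRESHOLDS)),
            sn_cutoff=float(thr.get("sn_cutoff", SN_CUTOFF)),
            mc_enabled=bool(mc.get("enabled", True)),
            mc_reps=int(mc.get("reps", 500)),
            mc_grid_max=float(mc.get("grid_max", 10.0)),
            mc_grid_step=float(mc.get("grid_step", 0.1)),
            seed=mc.get("seed", raw.get("seed")),
            output_dir=raw.get("output_dir", "ticnet_out"),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "tic": self.tic_path,
                "peptides": self.peptide_path,
                "annotation": self.annotation_path,
                "comparisons": [c.label for c in self.comparisons],
                "tiers": list(self.tier_thresholds),
                "sn_cutoff": self.sn_cutoff,
                "mc": [self.mc_enabled, self.mc_reps, self.mc_grid_max,
                       self.mc_grid_step],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()
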