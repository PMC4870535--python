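"""Synthetic two-condition x two-replicate proteomics data with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-protein baseline abundance is lognormal (normal on the log2
scale), replicate noise is additive on the log2 scale, a fraction of
proteins carries a true differential effect (symmetric up/down), and each
(protein, sample) cell can drop out completely at random (ND).

Intensities are emitted as integer ion counts (rounded lognormal draws,
minimum 1). This keeps the peptide-level split exact: a protein's TIC is
distributed over its peptides with a multinomial draw, so summing peptide
rows reproduces the protein table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import TicTable
from .errors import ConfigError

__all__ = [
    "SyntheticConfig",
    "paperlike_config",
    "generate_dataset",
    "generate_peptide_table",
    "generate_multistate_dataset",
    "generate_annotation",
]

#: COG letters used by the synthetic annotation generator, weighted roughly
#: like a bacterial genome annotation (metabolism-heavy).
_COG_LETTERS = "CEGHIJKLMNOPQRSTUV"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset.

    Attributes
    ----------
    n_proteins
        Number of proteins in the simulated proteome.
    de_fraction
        Fraction of proteins with a true differential effect, in [0, 1].
    effect_log2
        Per-state shift magnitude on the log2 scale: a differential protein's
        mean is ``base + effect_log2`` in one state and ``base - effect_log2``
        in the other (up/down assigned with equal probability), so the
        realized log2 fold change between states is ``2 * effect_log2``.
    base_log2_mean, base_log2_sd
        Mean and between-protein spread of the log2 baseline TIC.
    rep_noise_sd
        Within-condition replicate noise sd on the log2 scale.
    dropout_prob
        Per-(protein, sample) probability of a missing (ND) measurement,
        independent of intensity.
    peptides_per_protein
        Mean peptide count per protein for the peptide-level output
        (exactly 1 peptide when set to 1).
    seed
        Random seed; identical config => bit-identical output.
    states
        Names of the two conditions.
    """

    n_proteins: int = 1200
    de_fraction: float = 0.2
    effect_log2: float = 2.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    rep_noise_sd: float = 0.2
    dropout_prob: float = 0.06
    peptides_per_protein: float = 8.0
    seed: int = 0
    states: tuple[str, str] = ("condA", "condB")

    def __post_init__(self) -> None:
        if int(self.n_proteins) < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        for name in ("effect_log2", "base_log2_sd", "rep_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if self.peptides_per_protein < 1:
            raise ConfigError("peptides_per_protein must be >= 1")
        if len(self.states) != 2 or self.states[0] == self.states[1]:
            raise ConfigError("states must be two distinct names")


def paperlike_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default preset emulating the study conditions.

    1200 proteins, 20% differential at +/-2 log2 units per state, replicate
    noise 0.2 log2 units (cross-state sd >5x the intra-replicate sd, the
    published data-quality regime), 6% dropout so that ~1060 proteins are
    detected in both replicates of a condition — inside the printed
    1042–1233 range.
    """
    return replace(SyntheticConfig(seed=seed), **overrides)


def _sample_ids(config: SyntheticConfig) -> list[str]:
    a, b = config.states
    return [f"{a}_rep1", f"{a}_rep2", f"{b}_rep1", f"{b}_rep2"]


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"SYN_{i:05d}" for i in range(1, n + 1)], name="protein_id")


def generate_dataset(config: SyntheticConfig) -> tuple[TicTable, pd.DataFrame]:
    """Generate a TIC table and its ground-truth labels.

    Returns
    -------
    table
        :class:`TicTable` with four samples (two states x two replicates);
        ND entries are NaN.
    truth
        DataFrame indexed by protein id with columns ``label`` (one of
        ``up``/``down``/``null``, sign relative to the first state) and
        ``true_log2fc`` (state-A mean minus state-B mean on the log2 scale).
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_proteins)
    ids = _protein_ids(n)

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, n)
    is_de = rng.random(n) < config.de_fraction
    sign = rng.choice([-1.0, 1.0], n)
    shift = np.where(is_de, sign * config.effect_log2, 0.0)

    # log2 sample values: state A at base+shift, state B at base-shift,
    # plus iid replicate noise per sample.
    means = np.column_stack([base + shift, base + shift, base - shift, base - shift])
    log2_tic = means + rng.normal(0.0, config.rep_noise_sd, size=(n, 4))
    tic = np.maximum(np.rint(np.exp2(log2_tic)), 1.0)

    if config.dropout_prob > 0:
        nd = rng.random(size=(n, 4)) < config.dropout_prob
        tic = np.where(nd, np.nan, tic)

    values = pd.DataFrame(tic, index=ids, columns=_sample_ids(config))
    table = TicTable(values)

    label = np.where(~is_de, "null", np.where(sign > 0, "up", "down"))
    truth = pd.DataFrame(
        {"label": label, "true_log2fc": 2.0 * shift}, index=ids
    )
    return table, truth


def generate_peptide_table(config: SyntheticConfig) -> pd.DataFrame:
    """Peptide-level observations whose per-protein sums equal the TIC table.

    Each protein gets a fixed peptide roster (size 1 + Poisson(mean-1), at
    least one) with protein-level ionization weights; in each sample where
    the protein is detected, its integer TIC is split over the roster with a
    multinomial draw. Peptides receiving zero counts in a sample are simply
    not observed there. ND (protein, sample) cells emit no rows.
    """
    table, _ = generate_dataset(config)
    rng = np.random.default_rng([config.seed, 0x5EED])

    ppp = config.peptides_per_protein
    n = len(table)
    if ppp == 1:
        k_per_protein = np.ones(n, dtype=int)
    else:
        k_per_protein = 1 + rng.poisson(ppp - 1.0, n)

    rows: list[tuple[str, str, str, float]] = []
    sample_ids = list(table.values.columns)
    for (protein, tics), k in zip(table.values.iterrows(), k_per_protein):
        weights = rng.dirichlet(np.ones(k))
        for sample in sample_ids:
            tic = tics[sample]
            if np.isnan(tic):
                continue
            counts = rng.multinomial(int(tic), weights)
            for j, c in enumerate(counts):
                if c > 0:
                    rows.append((f"{protein}_pep{j + 1}", protein, sample, float(c)))
    return pd.DataFrame(
        rows, columns=["peptide_id", "protein_id", "sample_id", "intensity"]
    )


def generate_multistate_dataset(
    config: SyntheticConfig, states: tuple[str, ...] = ("GB", "R80", "FFA")
) -> tuple[TicTable, pd.DataFrame]:
    """Shared-universe generator for more than two conditions.

    Extension of :func:`generate_dataset` used to exercise multi-comparison
    summaries (three pairwise contrasts over one protein universe). Each
    differential protein draws an independent level from
    {-effect_log2, 0, +effect_log2} per state; the truth table reports the
    realized log2 fold change for every state pair.
    """
    if len(states) < 2 or len(set(states)) != len(states):
        raise ConfigError("states must be distinct names")
    rng = np.random.default_rng(config.seed)
    n = int(config.n_proteins)
    ids = _protein_ids(n)
    n_states = len(states)

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, n)
    is_de = rng.random(n) < config.de_fraction
    levels = rng.choice([-1.0, 0.0, 1.0], size=(n, n_states))
    levels[~is_de] = 0.0
    offsets = levels * config.effect_log2

    columns, blocks = [], []
    for j, state in enumerate(states):
        mean = base + offsets[:, j]
        noise = rng.normal(0.0, config.rep_noise_sd, size=(n, 2))
        blocks.append(np.exp2(mean[:, None] + noise))
        columns += [f"{state}_rep1", f"{state}_rep2"]
    tic = np.maximum(np.rint(np.concatenate(blocks, axis=1)), 1.0)
    if config.dropout_prob > 0:
        nd = rng.random(size=tic.shape) < config.dropout_prob
        tic = np.where(nd, np.nan, tic)

    table = TicTable(pd.DataFrame(tic, index=ids, columns=columns))
    truth = pd.DataFrame({"label": np.where(is_de, "de", "null")}, index=ids)
    for i in range(n_states):
        for j in range(i + 1, n_states):
            truth[f"log2fc_{states[i]}_vs_{states[j]}"] = (
                offsets[:, i] - offsets[:, j]
            )
    return table, truth


def generate_annotation(protein_ids, seed: int = 0) -> pd.DataFrame:
    """Synthetic annotation map: COG letters, EC, KEGG module, METACYC.

    Roughly 15% of proteins are unannotated (empty COG -> sentinel class X
    downstream); ~10% of annotated proteins carry two COG letters, the IMG
    convention for multi-domain assignments.
    """
    rng = np.random.default_rng([seed, 0xC06])
    ids = list(protein_ids)
    letters = np.array(list(_COG_LETTERS))
    rows = []
    for pid in ids:
        if rng.random() < 0.15:
            cog = ""
        else:
            k = 2 if rng.random() < 0.10 else 1
            cog = ";".join(rng.choice(letters, size=k, replace=False))
        ec = (
            f"{rng.integers(1, 7)}.{rng.integers(1, 20)}."
            f"{rng.integers(1, 20)}.{rng.integers(1, 99)}"
            if rng.random() < 0.5
            else ""
        )
        kegg = f"M{rng.integers(1, 400):05d}" if rng.random() < 0.6 else ""
        metacyc = f"PWY-{rng.integers(1000, 9999)}" if rng.random() < 0.4 else ""
        rows.append((pid, cog, ec, kegg, metacyc))
    return pd.DataFrame(
        rows, columns=["protein_id", "cog", "ec", "kegg", "metacyc"]
    ).set_index("protein_id")
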