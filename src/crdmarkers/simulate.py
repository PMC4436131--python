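"""Synthetic two-channel circadian expression data and serum time series.

Emulates a chronic jet-lag mouse study: animals entrained to a 12:12
light-dark cycle are exposed to repeated 8-h phase shifts on a clockwise
(CW, phase delay) or counterclockwise (CCW, phase advance) rotation, and
sampled around the clock at 4-h Zeitgeber-time intervals at five stages:
baseline, after 1 shift, after 6 shifts, 5 days recovery and 14 days
recovery. Liver expression is measured on two-color arrays in which every
sample is co-hybridized against a pooled common reference, with three
replicate spots per probe.

Three gene archetypes are simulated on the natural-log scale:

* ``circadian`` — mesor + amplitude * cos(2*pi*(ZT - acrophase)/24), with an
  optional per-(stage, protocol) acrophase offset modelling re-entrainment;
* ``crd_responsive`` — a monotone log-fold effect proportional to the number
  of accumulated shifts, attenuated by a persistence fraction during the
  recovery stages (persistence 1.0 = fully non-reversible deregulation);
* ``null`` — mesor only.

All stochasticity flows from a single :class:`numpy.random.Generator`, so an
identical config + seed yields a bit-identical dataset. The ground-truth
table is the authoritative record of what was planted; recovery tests read
it rather than re-deriving truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

STAGES = ("baseline", "shift1", "shift6", "rec5", "rec14")
PROTOCOLS = ("CW", "CCW")
NO_PROTOCOL = "none"
DEFAULT_ZTS = (0, 4, 8, 12, 16, 20)

#: shifts accumulated by the time each stage is sampled
ACCUMULATED_SHIFTS = {"baseline": 0, "shift1": 1, "shift6": 6, "rec5": 6, "rec14": 6}
RECOVERY_STAGES = frozenset({"rec5", "rec14"})

#: per-time-point replication of the array experiment
DEFAULT_REPLICATES = {"baseline": 4, "shift1": 2, "shift6": 2, "rec5": 2, "rec14": 2}

SAMPLE_CHANNEL = "sample"
REFERENCE_CHANNEL = "reference"


def generate_design(
    stages: Sequence[str] = STAGES,
    protocols: Sequence[str] = PROTOCOLS,
    zts: Sequence[int] = DEFAULT_ZTS,
    replicates: int | Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Full-factorial sampling design over (stage, protocol, ZT, replicate).

    Baseline samples carry protocol ``none`` (animals not yet shifted); every
    other stage is crossed with the requested rotation protocols. Replicates
    are per (stage, protocol, ZT) cell, given as one integer for all stages
    or a mapping stage -> count. Row order is deterministic: stage, protocol,
    ZT, replicate, in the order given.
    """
    if not stages:
        raise ConfigError("stage list must not be empty")
    if not zts:
        raise ConfigError("ZT list must not be empty")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    if len(set(zts)) != len(zts):
        raise ConfigError("duplicate ZT values")
    if replicates is None:
        replicates = DEFAULT_REPLICATES
    if isinstance(replicates, int):
        replicates = {stage: replicates for stage in stages}
    rows = []
    for stage in stages:
        n_rep = replicates.get(stage, 1)
        if n_rep < 1:
            raise ConfigError(f"replicates for stage '{stage}' must be >= 1")
        stage_protocols = [NO_PROTOCOL] if stage == "baseline" else list(protocols)
        if not stage_protocols:
            raise ConfigError("protocol list must not be empty for shifted stages")
        for protocol in stage_protocols:
            for zt in zts:
                for rep in range(1, n_rep + 1):
                    rows.append(
                        {
                            "sample_id": f"{stage}_{protocol}_zt{int(zt):02d}_r{rep}",
                            "stage": stage,
                            "protocol": protocol,
                            "zt": int(zt),
                            "replicate": rep,
                        }
                    )
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise ConfigError("duplicate sample ids in design")
    return design


def make_gene_table(
    n_null: int,
    n_circadian: int,
    n_crd: int,
    *,
    mesor: float = 8.0,
    amplitude: float = 1.0,
    rec14_fold_change: float = 1.5,
    full_shift_count: int = 6,
    persistence: float = 1.0,
    n_crd_secreted: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a per-gene parameter table for :class:`GeneConfig`.

    CRD-responsive genes alternate sign (up/down regulation) and accumulate
    ``+/- ln(rec14_fold_change)/full_shift_count`` per shift, so that after
    the full schedule with persistence 1.0 the expected recovery-stage fold
    change equals ``rec14_fold_change`` (or its reciprocal). The first
    ``n_crd_secreted`` CRD genes are marked secreted, i.e. planted blood
    candidates; circadian acrophases are drawn uniformly on [0, 24).
    """
    if n_crd_secreted is None:
        n_crd_secreted = n_crd
    if n_crd_secreted > n_crd:
        raise ConfigError("n_crd_secreted cannot exceed n_crd")
    rng = np.random.default_rng(seed)
    records = []
    log_fc = math.log(rec14_fold_change) / full_shift_count
    for i in range(n_crd):
        sign = 1.0 if i % 2 == 0 else -1.0
        records.append(
            {
                "gene": f"crd{i:04d}",
                "archetype": "crd_responsive",
                "mesor": mesor,
                "amplitude": 0.0,
                "acrophase": np.nan,
                "crd_log_fc": sign * log_fc,
                "persistence": persistence,
                "secreted": i < n_crd_secreted,
            }
        )
    for i in range(n_circadian):
        records.append(
            {
                "gene": f"circ{i:04d}",
                "archetype": "circadian",
                "mesor": mesor,
                "amplitude": amplitude,
                "acrophase": float(rng.uniform(0.0, 24.0)),
                "crd_log_fc": 0.0,
                "persistence": 0.0,
                "secreted": False,
            }
        )
    for i in range(n_null):
        records.append(
            {
                "gene": f"null{i:05d}",
                "archetype": "null",
                "mesor": mesor,
                "amplitude": 0.0,
                "acrophase": np.nan,
                "crd_log_fc": 0.0,
                "persistence": 0.0,
                "secreted": False,
            }
        )
    return pd.DataFrame.from_records(records)


#: default re-entrainment lag: one 8-h shift has not been absorbed yet, so
#: circadian peaks sit 8 h later (CW delay) or earlier (CCW advance); by the
#: sixth shift (48 h total, i.e. 0 mod 24) and during recovery the phase is back.
DEFAULT_ACROPHASE_OFFSETS: Mapping[tuple[str, str], float] = {
    ("shift1", "CW"): 8.0,
    ("shift1", "CCW"): -8.0,
}


@dataclass(frozen=True)
class GeneConfig:
    """Gene-level generative model plus array-technical parameters.

    ``noise_sd`` is the biological between-animal standard deviation of the
    ln-level; ``spot_noise_sd`` is the technical per-spot standard deviation;
    ``probe_offset_sd`` spreads fixed per-probe affinity offsets (drawn once,
    shared by every sample, so replicate-spot averaging is meaningful).
    """

    genes: pd.DataFrame
    noise_sd: float = 0.1
    spot_noise_sd: float = 0.1
    probe_offset_sd: float = 0.3
    probes_per_gene: int = 1
    spots_per_probe: int = 3
    acrophase_offsets: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ACROPHASE_OFFSETS)
    )
    crd_protocol_scale: Mapping[str, float] = field(
        default_factory=lambda: {"CW": 1.0, "CCW": 1.0}
    )
    seed: int = 0

    def __post_init__(self):
        required = {"gene", "archetype", "mesor", "amplitude", "acrophase",
                    "crd_log_fc", "persistence", "secreted"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ConfigError(f"gene table missing columns: {sorted(missing)}")
        if self.genes["gene"].duplicated().any():
            raise ConfigError("duplicate gene ids in gene table")
        if (self.genes["amplitude"] < 0).any():
            raise ConfigError("amplitude must be >= 0")
        pers = self.genes["persistence"]
        if ((pers < 0) | (pers > 1)).any():
            raise ConfigError("persistence fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.spot_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.probes_per_gene < 1 or self.spots_per_probe < 1:
            raise ConfigError("probes_per_gene and spots_per_probe must be >= 1")

    @property
    def probe_ids(self) -> list[str]:
        return [
            f"{gene}_p{j}"
            for gene in self.genes["gene"]
            for j in range(1, self.probes_per_gene + 1)
        ]


def expected_ln_levels(design: pd.DataFrame, config: GeneConfig) -> pd.DataFrame:
    """Noise-free expected ln-expression, genes x samples.

    This is the generative model's mean structure: the cosinor term for
    circadian genes (with any per-condition acrophase offset) plus the
    accumulated-shift effect for CRD-responsive genes, attenuated by the
    persistence fraction during recovery.
    """
    unknown = set(design["stage"]) - set(STAGES)
    if unknown:
        raise DataError(f"design contains unknown stage(s): {sorted(unknown)}")
    genes = config.genes
    n_genes, n_samples = len(genes), len(design)
    mu = np.tile(genes["mesor"].to_numpy(float)[:, None], (1, n_samples))

    amp = genes["amplitude"].to_numpy(float)
    acro = genes["acrophase"].to_numpy(float)
    has_rhythm = amp > 0
    zt = design["zt"].to_numpy(float)
    offsets = np.array(
        [
            config.acrophase_offsets.get((stage, protocol), 0.0)
            for stage, protocol in zip(design["stage"], design["protocol"])
        ]
    )
    if has_rhythm.any():
        phase = 2.0 * np.pi * (zt[None, :] - (acro[has_rhythm, None] + offsets[None, :])) / 24.0
        mu[has_rhythm, :] += amp[has_rhythm, None] * np.cos(phase)

    log_fc = genes["crd_log_fc"].to_numpy(float)
    pers = genes["persistence"].to_numpy(float)
    shifts = design["stage"].map(ACCUMULATED_SHIFTS).to_numpy(float)
    recovery = design["stage"].isin(RECOVERY_STAGES).to_numpy()
    scale = np.array(
        [config.crd_protocol_scale.get(p, 1.0) for p in design["protocol"]]
    )
    dose = shifts * scale * np.where(recovery, pers[:, None], 1.0)
    mu += log_fc[:, None] * dose

    return pd.DataFrame(mu, index=genes["gene"].to_numpy(), columns=design["sample_id"].to_numpy())


def generate_expression(design: pd.DataFrame, config: GeneConfig) -> pd.DataFrame:
    """Simulate spot-level two-channel raw intensities.

    Returns a "probe matrix": rows indexed by (probe_id, spot), columns by
    (sample_id, channel) with channels ``sample`` and ``reference``. The
    sample channel is ``exp(gene ln-level + probe offset + spot noise)``; the
    reference channel mimics an equimolar pool of all experimental samples,
    ``exp(mean ln-level across samples + probe offset + spot noise)``.
    """
    rng = np.random.default_rng(config.seed)
    mu = expected_ln_levels(design, config).to_numpy()
    n_genes, n_samples = mu.shape
    n_probes, n_spots = config.probes_per_gene, config.spots_per_probe

    bio = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples)) if config.noise_sd > 0 else 0.0
    ln_level = mu + bio  # (G, S)
    probe_offset = (
        rng.normal(0.0, config.probe_offset_sd, size=(n_genes, n_probes))
        if config.probe_offset_sd > 0
        else np.zeros((n_genes, n_probes))
    )

    # (G, P, S, K) spot-level ln intensities for both channels
    base = ln_level[:, None, :, None] + probe_offset[:, :, None, None]
    ref_base = ln_level.mean(axis=1)[:, None, None, None] + probe_offset[:, :, None, None]
    shape = (n_genes, n_probes, n_samples, n_spots)
    if config.spot_noise_sd > 0:
        sample_ln = base + rng.normal(0.0, config.spot_noise_sd, size=shape)
        ref_ln = ref_base + rng.normal(0.0, config.spot_noise_sd, size=shape)
    else:
        sample_ln = np.broadcast_to(base, shape)
        ref_ln = np.broadcast_to(ref_base, shape)

    # rows: (probe, spot); columns: (sample, channel)
    sample_vals = np.exp(sample_ln).transpose(0, 1, 3, 2).reshape(-1, n_samples)
    ref_vals = np.exp(ref_ln).transpose(0, 1, 3, 2).reshape(-1, n_samples)
    values = np.empty((sample_vals.shape[0], 2 * n_samples))
    values[:, 0::2] = sample_vals
    values[:, 1::2] = ref_vals

    row_index = pd.MultiIndex.from_product(
        [config.probe_ids, range(1, n_spots + 1)], names=["probe_id", "spot"]
    )
    col_index = pd.MultiIndex.from_product(
        [design["sample_id"].to_numpy(), (SAMPLE_CHANNEL, REFERENCE_CHANNEL)],
        names=["sample_id", "channel"],
    )
    return pd.DataFrame(values, index=row_index, columns=col_index)


def probe_matrix_to_long(probe_matrix: pd.DataFrame) -> pd.DataFrame:
    """Flatten a probe matrix to tidy rows: probe_id, spot, sample_id, channel, intensity."""
    long = probe_matrix.stack(["sample_id", "channel"], future_stack=True).rename("intensity")
    return long.reset_index()


def probe_matrix_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`probe_matrix_to_long`."""
    required = {"probe_id", "spot", "sample_id", "channel", "intensity"}
    missing = required - set(long.columns)
    if missing:
        raise DataError(f"spot table missing columns: {sorted(missing)}")
    wide = long.pivot_table(
        index=["probe_id", "spot"],
        columns=["sample_id", "channel"],
        values="intensity",
        sort=False,
    )
    return wide


def probe_annotation(config: GeneConfig) -> dict[str, str]:
    """Probe -> gene mapping implied by the generator's probe layout."""
    return {
        f"{gene}_p{j}": gene
        for gene in config.genes["gene"]
        for j in range(1, config.probes_per_gene + 1)
    }


def ground_truth_table(config: GeneConfig) -> pd.DataFrame:
    """Planted truth, one row per gene, with expected recovery-stage fold change."""
    truth = config.genes.copy()
    shifts = ACCUMULATED_SHIFTS["rec14"]
    truth["expected_rec14_fc"] = np.exp(
        truth["crd_log_fc"] * shifts * truth["persistence"]
    )
    return truth


@dataclass(frozen=True)
class SerumConfig:
    """Generative model for one serum analyte.

    ``stage_shift`` maps a stage or (stage, protocol) pair to a fractional
    level change relative to the baseline mesor (+0.18 = +18%). Outliers are
    injected additively at ``outlier_magnitude`` times ``noise_sd`` into
    randomly chosen rows and recorded in the returned ground-truth sidecar.
    """

    name: str
    rhythmic: bool = True
    mesor: float = 100.0
    amplitude: float = 30.0
    acrophase: float = 12.0
    tau: float = 24.0
    stage_shift: Mapping[object, float] = field(default_factory=dict)
    noise_sd: float = 15.0
    n_per_cell: int | Mapping[str, int] = 5
    outlier_count: int = 0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigError("period tau must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.outlier_count < 0:
            raise ConfigError("outlier_count must be >= 0")

    def cell_n(self, stage: str) -> int:
        if isinstance(self.n_per_cell, Mapping):
            return int(self.n_per_cell.get(stage, 2))
        return int(self.n_per_cell)

    def shift_for(self, stage: str, protocol: str) -> float:
        if (stage, protocol) in self.stage_shift:
            return float(self.stage_shift[(stage, protocol)])
        return float(self.stage_shift.get(stage, 0.0))


def generate_serum(
    design: pd.DataFrame, config: SerumConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a serum analyte over the design's (stage, protocol, ZT) grid.

    Returns ``(series, outlier_sidecar)``; the sidecar lists the injected
    outlier rows (by sample_id) with the additive perturbation applied.
    """
    rng = np.random.default_rng(config.seed)
    cells = design[["stage", "protocol", "zt"]].drop_duplicates().reset_index(drop=True)
    rows = []
    for _, cell in cells.iterrows():
        n = config.cell_n(cell["stage"])
        level = config.mesor * (1.0 + config.shift_for(cell["stage"], cell["protocol"]))
        if config.rhythmic:
            level += config.amplitude * math.cos(
                2.0 * math.pi * (cell["zt"] - config.acrophase) / config.tau
            )
        for rep in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"{config.name}_{cell['stage']}_{cell['protocol']}"
                    f"_zt{int(cell['zt']):02d}_r{rep}",
                    "analyte": config.name,
                    "stage": cell["stage"],
                    "protocol": cell["protocol"],
                    "zt": int(cell["zt"]),
                    "replicate": rep,
                    "value": level,
                }
            )
    series = pd.DataFrame(rows)
    if config.noise_sd > 0:
        series["value"] += rng.normal(0.0, config.noise_sd, size=len(series))
    if config.outlier_count > len(series):
        raise ConfigError("more outliers requested than rows generated")
    sidecar_rows = []
    if config.outlier_count:
        idx = rng.choice(len(series), size=config.outlier_count, replace=False)
        delta = config.outlier_magnitude * config.noise_sd
        for i in np.sort(idx):
            series.loc[i, "value"] += delta
            sidecar_rows.append(
                {"sample_id": series.loc[i, "sample_id"], "injected_delta": delta}
            )
    sidecar = pd.DataFrame(sidecar_rows, columns=["sample_id", "injected_delta"])
    return series, sidecar


def with_seed(config, seed: int):
    """Return a copy of a (frozen) config dataclass with a different seed."""
    return replace(config, seed=seed)
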