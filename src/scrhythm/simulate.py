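"""Synthetic single-cell time courses, binding series, and promoters.

The count generator plants cosine rhythms on the log2-mean scale so that a
gene with amplitude ``A`` has an expected log2 fold change of ``2A`` between
its peak and trough timepoints. Counts are negative binomial per cell, scaled
by a log-normal size factor, with an independent logistic detection step that
ties dropout to expression level (a genuine hurdle structure).

All generators are deterministic functions of (config, seed). Each sample
draws from its own ``numpy`` SeedSequence-spawned stream keyed by
``(seed, sample_index)`` so samples regenerate identically regardless of
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from scrhythm.io import CellCountMatrix, TimeSeries, logger

HOURS_PER_DAY = 24.0


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell time-course generator.

    The default design mirrors a 4-timepoint (every 6 h), 3-replicate
    study with several cell types of unequal abundance.
    """

    n_genes: int = 200
    n_cell_types: int = 3
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    n_replicates_per_timepoint: int = 3
    cells_per_sample_per_type: tuple[int, int] = (80, 120)
    rhythmic_fraction: float = 0.1
    amplitude_log2: float = 0.5
    baseline_log_mean: float = 0.7   # natural-log mean of per-cell baseline
    baseline_log_sd: float = 0.8
    nb_dispersion: float = 0.3
    dropout_midpoint: float = 0.0    # log2-mean at which detection prob = 0.5
    dropout_slope: float = 1.0
    size_factor_log_sd: float = 0.3
    clock_panel_size: int = 8
    rhythmic_cell_types: tuple[str, ...] | None = None  # None -> all types
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) == 0 or any(not 0 <= t < HOURS_PER_DAY for t in tps):
            raise ValueError("timepoints must lie in [0, 24)")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints = tps
        if self.n_genes <= 0 or self.n_cell_types <= 0:
            raise ValueError("n_genes and n_cell_types must be positive")
        if self.n_replicates_per_timepoint <= 0:
            raise ValueError("need at least one replicate per timepoint")
        lo, hi = self.cells_per_sample_per_type
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_sample_per_type must be a positive range")
        if not 0.0 <= self.rhythmic_fraction <= 1.0:
            raise ValueError("rhythmic_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.amplitude_log2 < 0:
            raise ValueError("amplitude_log2 must be nonnegative")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"type{chr(ord('A') + i)}" for i in range(self.n_cell_types)]

    @property
    def n_rhythmic(self) -> int:
        return int(round(self.rhythmic_fraction * self.n_genes))


@dataclass
class GroundTruth:
    """Planted simulation parameters for recovery scoring.

    ``genes`` carries gene_id, is_rhythmic, amplitude_log2, phase_hours
    (NaN for non-rhythmic genes), baseline_mean, and clock_arm
    ('positive' / 'repressor' / '' for non-panel genes). ``cells`` carries
    barcode, sample, timepoint_hours, cell_type, size_factor.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def _gene_params(config: SimConfig) -> pd.DataFrame:
    """Draw per-gene baselines, rhythmic flags, amplitudes, and phases."""
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    n = config.n_genes
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    is_rhythmic = np.zeros(n, dtype=bool)
    phase = np.full(n, np.nan)
    amplitude = np.zeros(n)
    clock_arm = np.array([""] * n, dtype=object)

    n_rhythmic = config.n_rhythmic
    # clock panel first: antiphase arms, always rhythmic when the rhythmic
    # budget allows (a zero rhythmic_fraction disables the panel too, so the
    # GroundTruth count invariant holds exactly)
    panel = min(config.clock_panel_size, n_rhythmic, n)
    for i in range(panel):
        is_rhythmic[i] = True
        amplitude[i] = max(config.amplitude_log2, 0.5)
        phase[i] = 0.0 if i % 2 == 0 else 12.0
        clock_arm[i] = "positive" if i % 2 == 0 else "repressor"
        baseline[i] = max(baseline[i], 2.0)  # clock genes are well expressed
    extra = n_rhythmic - panel
    if extra > 0:
        pool = np.arange(panel, n)
        chosen = rng.choice(pool, size=extra, replace=False)
        is_rhythmic[chosen] = True
        amplitude[chosen] = config.amplitude_log2
        phase[chosen] = rng.uniform(0.0, HOURS_PER_DAY, size=extra)

    gene_ids = np.array(
        [f"clk{'P' if clock_arm[i] == 'positive' else 'R'}{i:02d}" if clock_arm[i]
         else f"gene{i:04d}" for i in range(n)],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_rhythmic": is_rhythmic,
            "amplitude_log2": amplitude,
            "phase_hours": phase,
            "baseline_mean": baseline,
            "clock_arm": clock_arm,
        }
    )


def expected_log2_mean(genes: pd.DataFrame, t: float,
                       rhythmic_active: bool = True) -> np.ndarray:
    """Planted log2 mean of every gene at hour ``t`` (before size factors)."""
    log2mu = np.log2(genes["baseline_mean"].to_numpy())
    if rhythmic_active:
        rhy = genes["is_rhythmic"].to_numpy()
        amp = genes["amplitude_log2"].to_numpy()[rhy]
        phi = genes["phase_hours"].to_numpy()[rhy]
        log2mu[rhy] += amp * np.cos(2 * np.pi * (t - phi) / HOURS_PER_DAY)
    return log2mu


def simulate_cell_counts(config: SimConfig) -> tuple[CellCountMatrix, GroundTruth]:
    """Generate a sparse count matrix plus the planted ground truth.

    For rhythmic gene g at hour t the log2 mean is
    ``log2(baseline_g) + A_g * cos(2*pi*(t - phi_g)/24)``; cell-level counts
    are negative binomial with that mean scaled by a per-cell size factor,
    then independently zeroed with probability
    ``1 - logistic(slope * (log2 mean - midpoint))``.
    """
    genes = _gene_params(config)
    disp = config.nb_dispersion
    r = 1.0 / disp  # NB size parameter

    sample_index = 0
    blocks: list[sp.csr_matrix] = []
    cell_rows: list[pd.DataFrame] = []
    for t in config.timepoints:
        for rep in range(1, config.n_replicates_per_timepoint + 1):
            sample = f"ZT{t:g}_rep{rep}"
            rng = np.random.default_rng([config.seed, sample_index])
            lo, hi = config.cells_per_sample_per_type
            block_cols = []
            meta_parts = []
            for ct in config.cell_type_names:
                n_cells = int(rng.integers(lo, hi + 1))
                sf = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_cells))
                active = (
                    config.rhythmic_cell_types is None
                    or ct in config.rhythmic_cell_types
                )
                log2mu = expected_log2_mean(genes, t, rhythmic_active=active)
                mu = np.power(2.0, log2mu)[:, None] * sf[None, :]
                p = r / (r + mu)
                counts = rng.negative_binomial(r, p)
                p_det = expit(
                    config.dropout_slope * (log2mu - config.dropout_midpoint)
                )
                detected = rng.random(counts.shape) < p_det[:, None]
                counts = counts * detected
                block_cols.append(sp.csr_matrix(counts))
                meta_parts.append(
                    pd.DataFrame(
                        {
                            "barcode": [
                                f"{sample}_{ct}_c{j:04d}" for j in range(n_cells)
                            ],
                            "sample": sample,
                            "timepoint_hours": t,
                            "cell_type": ct,
                            "size_factor": sf,
                        }
                    )
                )
            blocks.append(sp.hstack(block_cols, format="csr"))
            cell_rows.append(pd.concat(meta_parts, ignore_index=True))
            sample_index += 1

    counts = sp.hstack(blocks, format="csr")
    cells = pd.concat(cell_rows, ignore_index=True)
    if counts.shape[1] == 0:
        raise ValueError("configuration produced zero cells")
    ccm = CellCountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        cells=cells[["barcode", "sample", "timepoint_hours", "cell_type"]].copy(),
    )
    truth = GroundTruth(genes=genes, cells=cells, config=config)
    logger.debug(
        "simulated %d genes x %d cells (%d rhythmic)",
        ccm.n_genes, ccm.n_cells, int(genes["is_rhythmic"].sum()),
    )
    return ccm, truth


def simulate_binding_series(
    mesor: float,
    amplitude: float,
    phase_hours: float,
    period_hours: float,
    noise_sd: float,
    times: np.ndarray,
    seed: int = 0,
) -> TimeSeries:
    """Cosine signal ``mesor + A*cos(2*pi*(t - phase)/period)`` plus noise."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if period_hours <= 0:
        raise ValueError("period_hours must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    values = mesor + amplitude * np.cos(
        2 * np.pi * (times - phase_hours) / period_hours
    )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return TimeSeries(times=times, values=values)


def simulate_promoter(
    length: int,
    planted_motifs: list[tuple[int, str]] | None = None,
    seed: int = 0,
) -> tuple[str, list[tuple[int, str]]]:
    """Uniform-random ACGT background with motifs overwritten at given starts.

    Returns the sequence and the planted (position, motif) list. Planted
    motifs must fit inside the sequence and must not overlap each other.
    """
    planted = sorted(planted_motifs or [], key=lambda pm: pm[0])
    if length <= 0:
        raise ValueError("length must be positive")
    prev_end = -1
    for pos, motif in planted:
        if not motif or set(motif) - set("ACGT"):
            raise ValueError(f"motif {motif!r} is not over ACGT")
        if pos < 0 or pos + len(motif) > length:
            raise ValueError(f"motif {motif!r} at {pos} exceeds sequence bounds")
        if pos < prev_end:
            raise ValueError("planted motifs overlap")
        prev_end = pos + len(motif)
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.array(list("ACGT")), size=length)
    for pos, motif in planted:
        seq[pos:pos + len(motif)] = list(motif)
    return "".join(seq), planted
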