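"""Parameter-sweep campaign over the topology parameters (m, m_tc, m_cc).

For every triplet of the grid a batch of random networks is generated
and each enumerated retinal-input schedule is simulated and classified.
Two stimulation modes exist:

* ``single``   — every combination of one stimulated first-row site per
  hemisphere is run (N x N schedules per network);
* ``full_row`` — the whole first row of both nuclei is stimulated (one
  schedule per network).

Counts of the synchronization categories are accumulated per triplet
and marginalized over each parameter (summing the other two), which is
the layout of the campaign's headline table.

Seeding: a master seed spawns one child generator per
(triplet index, replicate) via
``np.random.SeedSequence(master_seed, spawn_key=(triplet_index, replicate))``,
so any sub-sweep can be re-run in isolation and the whole sweep is
byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .analysis import SyncCategory, classify, detect_periods_batch
from .dynamics import DynamicsParams, StimulusSchedule, simulate_batch
from .topology import PathwayNetwork, TopologySpec, assemble_network

__all__ = [
    "SweepConfig",
    "SweepResult",
    "enumerate_inputs",
    "planned_simulation_count",
    "run_sweep",
    "table1_layout",
    "CATEGORY_COLUMNS",
]

DEFAULT_GRID = (3, 9, 27, 81)
CATEGORY_COLUMNS = ("eta1", "eta2", "other_sync", "no_sync")
_CAT_TO_COL = {
    SyncCategory.ETA1: "eta1",
    SyncCategory.ETA2: "eta2",
    SyncCategory.OTHER_SYNC: "other_sync",
    SyncCategory.NO_SYNC: "no_sync",
}

KMode = Literal["single", "full_row"]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one sweep campaign.

    The defaults are the campaign's study conditions: N = 10, T = 1,
    P = 10, d = 2, grid {3, 9, 27, 81} for each topology parameter,
    horizon 200 with a trailing 100-step analysis window.  ``n_networks``
    is the scale knob: 100 replicates per triplet in single-site mode
    (10 000 in full-row mode) is the full campaign; small values give
    proportionally scaled-down sweeps.
    """

    m_values: tuple[int, ...] = DEFAULT_GRID
    m_tc_values: tuple[int, ...] = DEFAULT_GRID
    m_cc_values: tuple[int, ...] = DEFAULT_GRID
    k_mode: KMode = "single"
    n_networks: int = 100
    N: int = 10
    T: float = 1.0
    P: int = 10
    d: int = 2
    amplitude: float = 1.0
    horizon: int = 200
    window: int = 100
    phase: int = 0
    tc_directed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_mode not in ("single", "full_row"):
            raise ValueError(f"k_mode must be 'single' or 'full_row', got {self.k_mode!r}")
        if self.n_networks < 1:
            raise ValueError(f"n_networks must be >= 1, got {self.n_networks}")
        # validate every triplet is feasible and dynamics params are sound
        for m, m_tc, m_cc in self.triplets():
            TopologySpec(N=self.N, m=m, m_tc=m_tc, m_cc=m_cc, tc_directed=self.tc_directed)
        self.dynamics_params()

    def triplets(self) -> list[tuple[int, int, int]]:
        """Grid triplets (m, m_tc, m_cc) in row-major order."""
        return list(itertools.product(self.m_values, self.m_tc_values, self.m_cc_values))

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(
            T=self.T,
            P=self.P,
            k=1 if self.k_mode == "single" else self.N,
            amplitude=self.amplitude,
            d=self.d,
            horizon=self.horizon,
            window=self.window,
            phase=self.phase,
        )

    def schedules_per_network(self) -> int:
        return self.N * self.N if self.k_mode == "single" else 1

    def replicate_rng(self, triplet_index: int, replicate: int) -> np.random.Generator:
        """The documented child-seed derivation."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(triplet_index, replicate))
        return np.random.default_rng(ss)


def enumerate_inputs(network: PathwayNetwork, k_mode: KMode) -> list[StimulusSchedule]:
    """All retinal-input schedules of a stimulation mode.

    ``single``: the Cartesian product (left first-row site) x (right
    first-row site), N^2 schedules.  ``full_row``: one schedule with all
    N first-row nodes stimulated per hemisphere.
    """
    N = network.spec.N
    if k_mode == "single":
        return [
            StimulusSchedule.single_site(network, a, b)
            for a in range(N)
            for b in range(N)
        ]
    if k_mode == "full_row":
        return [StimulusSchedule.full_row(network)]
    raise ValueError(f"unknown k_mode {k_mode!r}")


def planned_simulation_count(config: SweepConfig) -> int:
    """Dry-run arithmetic: triplets x replicates x schedules, without
    executing any dynamics."""
    return len(config.triplets()) * config.n_networks * config.schedules_per_network()


@dataclass(frozen=True)
class SweepResult:
    """Per-triplet category counts of a sweep, plus marginal views."""

    config: SweepConfig
    table: pd.DataFrame  # columns m, m_tc, m_cc, eta1, eta2, other_sync, no_sync, total

    def marginal(self, param: str) -> pd.DataFrame:
        """Category counts summed over the other two grid parameters."""
        if param not in ("m", "m_tc", "m_cc"):
            raise ValueError(f"param must be one of m, m_tc, m_cc, got {param!r}")
        cols = list(CATEGORY_COLUMNS) + ["total"]
        return self.table.groupby(param, sort=True)[cols].sum().reset_index()

    def totals(self) -> pd.Series:
        return self.table[list(CATEGORY_COLUMNS) + ["total"]].sum()

    def fraction(self, category: str, param: str | None = None) -> pd.Series | float:
        """Category fraction overall, or per value of a marginal parameter."""
        if param is None:
            tot = self.totals()
            return float(tot[category] / tot["total"])
        marg = self.marginal(param).set_index(param)
        return marg[category] / marg["total"]


def _single_site_stimuli(
    network: PathwayNetwork, amplitude: float
) -> np.ndarray:
    """Stimulus matrix for all N^2 single-site schedules, one row each,
    ordered as (left site, right site) in row-major order."""
    N = network.spec.N
    rows = network.input_rows
    stim = np.zeros((N * N, network.n_total), dtype=np.float32)
    for idx, (a, b) in enumerate(itertools.product(range(N), range(N))):
        stim[idx, rows[0][a]] = amplitude
        stim[idx, rows[1][b]] = amplitude
    return stim


def _classify_counts(
    counts: np.ndarray, window: int, P: int
) -> list[SyncCategory]:
    """Classify a batch of runs from their (batch, steps, 4) count arrays."""
    tails = counts[:, -window:, :]
    periods = detect_periods_batch(tails)
    out = []
    for row in periods:
        ps = [int(p) if p > 0 else None for p in row]
        out.append(classify(ps, P).category)
    return out


def _run_triplet_single(
    config: SweepConfig, spec: TopologySpec, triplet_index: int
) -> dict[str, int]:
    params = config.dynamics_params()
    tally = dict.fromkeys(CATEGORY_COLUMNS, 0)
    for rep in range(config.n_networks):
        rng = config.replicate_rng(triplet_index, rep)
        net = assemble_network(spec, rng)
        stim = _single_site_stimuli(net, config.amplitude)
        counts, _ = simulate_batch(net.adjacency(), stim, params, net.n_per_component)
        for cat in _classify_counts(counts, config.window, config.P):
            tally[_CAT_TO_COL[cat]] += 1
    return tally


def _run_triplet_full_row(
    config: SweepConfig,
    spec: TopologySpec,
    triplet_index: int,
    chunk_size: int = 128,
) -> dict[str, int]:
    # one schedule per network; block-diagonal batches of networks share
    # a single vectorized stepping loop
    params = config.dynamics_params()
    n2 = spec.nodes_per_component
    tally = dict.fromkeys(CATEGORY_COLUMNS, 0)
    for start in range(0, config.n_networks, chunk_size):
        reps = range(start, min(start + chunk_size, config.n_networks))
        nets = [
            assemble_network(spec, config.replicate_rng(triplet_index, rep))
            for rep in reps
        ]
        a_big = sp.block_diag([net.adjacency() for net in nets], format="csr")
        stim = np.concatenate(
            [
                StimulusSchedule.full_row(net).vector(net.n_total, config.amplitude)
                for net in nets
            ]
        )[None, :]
        counts, _ = simulate_batch(a_big, stim, params, n2)
        # (1, steps, 4 * R) -> per-network (R, steps, 4)
        per_net = counts[0].reshape(params.horizon + 1, len(nets), 4).transpose(1, 0, 2)
        for cat in _classify_counts(per_net, config.window, config.P):
            tally[_CAT_TO_COL[cat]] += 1
    return tally


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Execute the full sweep: for every grid triplet, generate
    ``n_networks`` seeded networks, simulate every enumerated schedule,
    classify each run, and accumulate category counts.

    Deterministic: the same config (including seed) always yields the
    same counts.
    """
    records = []
    triplets = config.triplets()
    for t_idx, (m, m_tc, m_cc) in enumerate(triplets):
        spec = TopologySpec(
            N=config.N, m=m, m_tc=m_tc, m_cc=m_cc, tc_directed=config.tc_directed
        )
        if config.k_mode == "single":
            tally = _run_triplet_single(config, spec, t_idx)
        else:
            tally = _run_triplet_full_row(config, spec, t_idx)
        total = config.n_networks * config.schedules_per_network()
        assert sum(tally.values()) == total, "category counts must sum to total"
        records.append({"m": m, "m_tc": m_tc, "m_cc": m_cc, **tally, "total": total})
        if progress:
            print(
                f"[{t_idx + 1}/{len(triplets)}] m={m} m_tc={m_tc} m_cc={m_cc}: "
                + " ".join(f"{k}={v}" for k, v in tally.items())
            )
    return SweepResult(config=config, table=pd.DataFrame.from_records(records))


def table1_layout(
    single: SweepResult | None = None, full_row: SweepResult | None = None
) -> pd.DataFrame:
    """Headline-table layout: one block of rows per marginal parameter
    (m, m_tc, m_cc), columns eta1/eta2 per stimulation mode."""
    frames = []
    for param in ("m", "m_tc", "m_cc"):
        block = None
        for mode_name, result in (("k1", single), ("k10", full_row)):
            if result is None:
                continue
            marg = result.marginal(param).set_index(param)
            cols = marg[["eta1", "eta2"]].rename(
                columns={"eta1": f"eta1_{mode_name}", "eta2": f"eta2_{mode_name}"}
            )
            cols[f"total_{mode_name}"] = marg["total"]
            block = cols if block is None else block.join(cols)
        if block is None:
            raise ValueError("at least one of single/full_row results is required")
        block = block.reset_index().rename(columns={param: "value"})
        block.insert(0, "parameter", param)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
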