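"""Deterministic discrete-time excitable dynamics on the pathway network.

Every node follows a refractory-excitable chain: susceptible ``S``,
active stages ``A1 ... Ad`` (for the default ``d = 2`` these are the
classic "active-1"/"active-2" pair), and one inhibited/refractory step
``R``.  At each time step the input of node ``i`` is
``sum_j w_ij o_j(t) + I_i(t)``, where ``o_j(t) = 1`` iff node ``j`` is
in an active stage and ``I_i(t)`` is the periodic retinal drive, nonzero
only for first-row LGN nodes.  Transitions (synchronous update):

* ``S -> A1``      if input >= T, else stays ``S``;
* ``Aj -> Aj+1``   (j < d) if input >= T, else back to ``S``;
* ``Ad -> R``      unconditionally (forced inhibition);
* ``R -> S``       unconditionally.

States are coded as small ints: ``S = 0``, active stages ``1 .. d``,
``R = d + 1``.  The rules are deterministic, so a run is a pure function
of network + stimulus schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .topology import PathwayNetwork

__all__ = [
    "S_STATE",
    "DynamicsParams",
    "StimulusSchedule",
    "ActivityTrace",
    "state_names",
    "node_input",
    "step",
    "run",
    "simulate_batch",
]

S_STATE = 0  # susceptible; active stages are 1..d, refractory is d+1


def state_names(d: int = 2) -> tuple[str, ...]:
    """Human-readable state labels for a given active-chain length.

    For the default ``d = 2`` this is ``('S', 'Y', 'Z', 'R')``.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if d == 2:
        return ("S", "Y", "Z", "R")
    return ("S", *[f"A{j}" for j in range(1, d + 1)], "R")


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the driven dynamics.

    T
        Firing threshold (input units).
    P
        Stimulus period in time steps (one step is read as 1 ms, so
        ``P = 10`` is a 100 Hz drive).
    k
        Number of stimulated first-row LGN nodes per hemisphere (1 or N).
    amplitude
        Stimulus magnitude ``I_i`` delivered on pulse steps.
    d
        Maximum number of consecutive active steps before forced
        inhibition (default 2).
    horizon
        Total number of simulated steps; the trace has ``horizon + 1``
        samples including ``t = 0``.
    window
        Trailing analysis-window length for period detection
        (default 100 steps of the permanent regime).
    phase
        Stimulus onset offset: pulses arrive at ``t = phase (mod P)``.
    """

    T: float = 1.0
    P: int = 10
    k: int = 1
    amplitude: float = 1.0
    d: int = 2
    horizon: int = 200
    window: int = 100
    phase: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"threshold T must be > 0, got {self.T}")
        if self.P < 1:
            raise ValueError(f"period P must be >= 1, got {self.P}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.window < 2 * self.P:
            raise ValueError(
                f"window={self.window} too short to confirm a period up to "
                f"{self.P}: need window >= 2 P = {2 * self.P}"
            )
        if self.horizon < self.window:
            raise ValueError(
                f"horizon={self.horizon} must cover the analysis window "
                f"({self.window}) plus a transient"
            )

    @property
    def transient(self) -> int:
        """Steps discarded before the analysis window."""
        return self.horizon - self.window

    @property
    def refractory_state(self) -> int:
        return self.d + 1


@dataclass(frozen=True)
class StimulusSchedule:
    """Which first-row LGN nodes receive the periodic retinal pulse.

    ``targets`` holds, per hemisphere, the tuple of stimulated global
    node ids (a subset of the network's input rows).
    """

    targets: tuple[tuple[int, ...], tuple[int, ...]]

    @classmethod
    def single_site(
        cls, network: PathwayNetwork, left_site: int, right_site: int
    ) -> "StimulusSchedule":
        """One stimulated node per hemisphere, chosen by first-row column
        index (0-based)."""
        rows = network.input_rows
        N = network.spec.N
        if not (0 <= left_site < N and 0 <= right_site < N):
            raise ValueError(f"site indices must be in [0, {N})")
        return cls(targets=((rows[0][left_site],), (rows[1][right_site],)))

    @classmethod
    def full_row(cls, network: PathwayNetwork) -> "StimulusSchedule":
        """All N first-row nodes stimulated in both hemispheres (k = N)."""
        rows = network.input_rows
        return cls(targets=(tuple(rows[0]), tuple(rows[1])))

    def validate(self, network: PathwayNetwork) -> None:
        rows = network.input_rows
        for hemi, targets in enumerate(self.targets):
            if not set(targets) <= set(rows[hemi]):
                raise ValueError(
                    f"hemisphere {hemi} targets {targets} not all in the "
                    f"input row {rows[hemi]}"
                )

    def vector(self, n_total: int, amplitude: float) -> np.ndarray:
        """Dense per-node stimulus amplitudes on a pulse step."""
        stim = np.zeros(n_total, dtype=np.float32)
        for targets in self.targets:
            stim[list(targets)] = amplitude
        return stim


@dataclass(frozen=True)
class ActivityTrace:
    """Per-component activity time series of one run.

    ``counts[t, c]`` is the number of active nodes of component ``c``
    (0 = left-LGN, 1 = left-VC, 2 = right-LGN, 3 = right-VC) at time
    ``t``; exact integers so that period detection can use exact
    equality.  ``x`` converts to the percent-active series.
    """

    counts: np.ndarray  # (horizon + 1, 4) int
    comp_size: int
    states: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError(f"counts must have shape (steps, 4), got {c.shape}")
        if c.size and (c.min() < 0 or c.max() > self.comp_size):
            raise ValueError("active counts outside [0, nodes per component]")

    @property
    def x(self) -> np.ndarray:
        """Percent-active series, shape (horizon + 1, 4), values in [0, 100]."""
        return self.counts * (100.0 / self.comp_size)

    @property
    def horizon(self) -> int:
        return len(self.counts) - 1


def _output_vector(states: np.ndarray, d: int) -> np.ndarray:
    """o_j = 1 iff node j is in an active stage (1..d)."""
    return (states >= 1) & (states <= d)


def node_input(
    network: PathwayNetwork,
    states: np.ndarray,
    stimulus: np.ndarray | Sequence[float],
    i: int,
    d: int = 2,
) -> float:
    """Input of node ``i``: weighted sum of active in-neighbors' outputs
    plus its retinal stimulus.  Undirected edges feed both endpoints;
    directed thalamocortical edges feed only the cortical endpoint."""
    if not 0 <= i < network.n_total:
        raise KeyError(f"unknown node id {i}")
    o = _output_vector(np.asarray(states), d).astype(np.float32)
    a_row = network.adjacency().getrow(i)
    return float((a_row @ o).item() + float(np.asarray(stimulus, dtype=np.float32)[i]))


def _step_states(
    states: np.ndarray, inputs: np.ndarray, T: float, d: int
) -> np.ndarray:
    """Apply the transition rules to every node, synchronously."""
    fire = inputs >= T
    advanced = np.where(fire, states + 1, S_STATE)  # S/A_j (j<d) branch
    nxt = np.where(
        states < d,
        advanced,
        np.where(states == d, d + 1, S_STATE),  # A_d -> R, R -> S
    )
    return nxt.astype(np.int8)


def step(
    network: PathwayNetwork,
    states: np.ndarray,
    stimulus: np.ndarray | Sequence[float],
    params: DynamicsParams,
) -> np.ndarray:
    """One synchronous update of all nodes from the CURRENT states.

    ``stimulus`` is the per-node retinal input ``I_i`` at this step
    (zeros off pulse steps)."""
    states = np.asarray(states, dtype=np.int8)
    o = _output_vector(states, params.d).astype(np.float32)
    inputs = network.adjacency() @ o + np.asarray(stimulus, dtype=np.float32)
    return _step_states(states, inputs, params.T, params.d)


def simulate_batch(
    a_in: sp.spmatrix,
    stim: np.ndarray,
    params: DynamicsParams,
    comp_size: int,
    record_states: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Run a batch of independent stimulus schedules on one in-adjacency.

    Parameters
    ----------
    a_in:
        (n, n) in-adjacency, ``a_in[i, j] = w_ij`` (may be the
        block-diagonal of several networks).
    stim:
        (batch, n) pulse-step stimulus amplitudes, one row per schedule.
    comp_size:
        Nodes per component; ``n`` must be a multiple of it.

    Returns
    -------
    counts:
        (batch, horizon + 1, n // comp_size) int32 active-node counts.
    states_history:
        (horizon + 1, batch, n) int8 array if ``record_states``, else None.
    """
    a = sp.csr_matrix(a_in, dtype=np.float32)
    stim = np.atleast_2d(np.asarray(stim, dtype=np.float32))
    batch, n = stim.shape
    if a.shape != (n, n):
        raise ValueError(f"adjacency {a.shape} does not match stimulus width {n}")
    if n % comp_size:
        raise ValueError(f"{n} nodes not a multiple of comp_size={comp_size}")
    n_comp = n // comp_size
    d, T = params.d, params.T
    states = np.zeros((batch, n), dtype=np.int8)  # all susceptible at t = 0
    counts = np.empty((batch, params.horizon + 1, n_comp), dtype=np.int32)
    history = (
        np.empty((params.horizon + 1, batch, n), dtype=np.int8)
        if record_states
        else None
    )
    for t in range(params.horizon + 1):
        o = _output_vector(states, d)
        counts[:, t, :] = o.reshape(batch, n_comp, comp_size).sum(axis=2)
        if history is not None:
            history[t] = states
        if t == params.horizon:
            break
        inputs = (a @ o.T.astype(np.float32)).T
        if (t - params.phase) % params.P == 0:
            inputs = inputs + stim
        states = _step_states(states, inputs, T, d)
    return counts, history


def run(
    network: PathwayNetwork,
    params: DynamicsParams,
    schedule: StimulusSchedule,
    record_states: bool = False,
) -> ActivityTrace:
    """Simulate the network from the all-susceptible state at ``t = 0``
    under the periodic schedule, for ``params.horizon`` steps.

    Fully deterministic given network + schedule."""
    schedule.validate(network)
    stim = schedule.vector(network.n_total, params.amplitude)[None, :]
    counts, history = simulate_batch(
        network.adjacency(), stim, params, network.n_per_component, record_states
    )
    return ActivityTrace(
        counts=counts[0],
        comp_size=network.n_per_component,
        states=None if history is None else history[:, 0, :],
    )
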