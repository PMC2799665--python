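"""Two-state Markov (telegraph) generators for open/closed and on/off signals.

Dwell times are sampled *exactly* from their exponential laws and only then
discretised onto the uniform dt grid; per-step Bernoulli flipping would bias
short-dwell statistics whenever a dwell constant approaches dt (the
picosecond regime), so it is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..correlation import HBondExistenceMatrix
from ..errors import ParameterError
from ..state_signal import StateSeries

__all__ = ["TelegraphParams", "gen_telegraph", "HBondSeriesParams", "gen_hbond_series"]


@dataclass
class TelegraphParams:
    """Parameters of the open/closed telegraph process.

    ``k_close`` is the rate (1/ns) of leaving the open state (open->closed),
    i.e. 1/tau_c; ``k_open`` the closed->open rate, 1/tau_o.  A zero rate
    makes the corresponding state absorbing.
    """

    k_close: float  # 1/ns
    k_open: float  # 1/ns
    dt: float  # ns
    n_steps: int
    seed: int
    initial_state: str = "stationary-random"  # "open" | "closed" | "stationary-random"

    def validate(self) -> None:
        if self.k_close < 0 or self.k_open < 0 or (self.k_close == 0 and self.k_open == 0):
            raise ParameterError("need k_close > 0 or k_open > 0, both non-negative")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.n_steps < 2:
            raise ParameterError("n_steps must be >= 2")
        if self.initial_state not in ("open", "closed", "stationary-random"):
            raise ParameterError(f"unknown initial_state {self.initial_state!r}")

    @property
    def p_open_stationary(self) -> float:
        return self.k_open / (self.k_open + self.k_close)


def _telegraph_states(rate_leave: tuple[float, float], first_state: int,
                      dt: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Discretise exact exponential dwells onto the grid t_i = i*dt.

    ``rate_leave[s]`` is the rate of leaving state s; a zero rate is an
    absorbing state (infinite dwell).
    """
    total_time = n_steps * dt
    switch_times: list[np.ndarray] = []
    t = 0.0
    state = first_state
    # draw dwells in alternating-state chunks until the record is covered
    mean_cycle = sum(1.0 / r for r in rate_leave if r > 0)
    chunk = max(int(2 * total_time / mean_cycle) + 16, 64)
    states_of_dwell: list[int] = []
    while t < total_time:
        r = rate_leave[state]
        if r == 0:  # absorbing
            states_of_dwell.append(state)
            switch_times.append(np.array([np.inf]))
            t = np.inf
            break
        n_half = (chunk + 1) // 2
        d = rng.exponential(1.0 / r, size=n_half)
        other = 1 - state
        r2 = rate_leave[other]
        if r2 == 0:
            # next state absorbs: only one more dwell matters
            d = d[:1]
            d2 = np.array([np.inf])
        else:
            d2 = rng.exponential(1.0 / r2, size=d.size)
        inter = np.empty(2 * d.size)
        inter[0::2] = d
        inter[1::2] = d2
        for dur in inter:
            states_of_dwell.append(state)
            switch_times.append(np.array([t + dur]))
            state = 1 - state
            t += dur
            if t >= total_time:
                break
    cum = np.concatenate(switch_times)
    # grid point i (time i*dt) sits in the dwell whose end time exceeds i*dt
    ends = np.minimum(cum, total_time)
    counts = np.diff(np.concatenate(([0], np.ceil(ends / dt - 1e-12)))).astype(np.int64)
    counts = np.clip(counts, 0, None)
    k = int(np.searchsorted(np.cumsum(counts), n_steps, side="left")) + 1
    states = np.repeat(np.asarray(states_of_dwell[:k], dtype=np.int8), counts[:k])
    return states[:n_steps]


def gen_telegraph(params: TelegraphParams) -> StateSeries:
    """Binary open(1)/closed(0) telegraph series, reproducible under the seed."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    if params.initial_state == "open":
        first = 1
    elif params.initial_state == "closed":
        first = 0
    else:
        first = int(rng.random() < params.p_open_stationary)
    states = _telegraph_states((params.k_open, params.k_close), first,
                               params.dt, params.n_steps, rng)
    return StateSeries(dt=params.dt, states=states,
                       group_spec=f"telegraph(kc={params.k_close},ko={params.k_open})")


@dataclass
class HBondSeriesParams:
    """Independent on/off hydrogen-bond processes.

    ``k_break`` is the intact->broken rate (1/ns), ``k_reform`` the reverse;
    the stationary intact fraction is k_reform/(k_break+k_reform).
    """

    k_break: float  # 1/ns
    k_reform: float  # 1/ns
    n_bonds: int
    dt: float  # ns
    n_steps: int
    seed: int
    initial_state: str = "stationary-random"  # "intact" | "broken" | "stationary-random"

    def validate(self) -> None:
        if self.k_break < 0 or self.k_reform < 0 or (self.k_break == 0 and self.k_reform == 0):
            raise ParameterError("rates must be >= 0 and not both zero")
        if self.n_bonds < 1:
            raise ParameterError("n_bonds must be >= 1")
        if self.dt <= 0 or self.n_steps < 2:
            raise ParameterError("dt > 0 and n_steps >= 2 required")

    @property
    def p_intact_stationary(self) -> float:
        return self.k_reform / (self.k_break + self.k_reform)


def gen_hbond_series(params: HBondSeriesParams) -> HBondExistenceMatrix:
    """n_bonds independent Markov on/off series (1 = intact).

    Each bond gets its own child stream of the master seed, so bonds are
    independent and individually reproducible.
    """
    params.validate()
    children = np.random.SeedSequence(params.seed).spawn(params.n_bonds)
    H = np.empty((params.n_steps, params.n_bonds), dtype=np.int8)
    for j, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        if params.initial_state == "intact":
            first = 1
        elif params.initial_state == "broken":
            first = 0
        else:
            first = int(rng.random() < params.p_intact_stationary)
        H[:, j] = _telegraph_states((params.k_reform, params.k_break), first,
                                    params.dt, params.n_steps, rng)
    return HBondExistenceMatrix(dt=params.dt, existence=H)
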