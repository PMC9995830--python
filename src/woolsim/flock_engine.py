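"""Discrete-time, seeded simulation of a virtual sheep flock.

Each sheep alternates between grazing, standing and walking according to a
semi-Markov process: it dwells in a behaviour state for an exponentially
distributed bout, then samples a fresh state (self-transitions allowed, in
which case a new bout of the same behaviour simply begins).  The next-state
distribution is chosen so that the long-run fraction of time spent in each
state equals the configured activity budget exactly: a state is entered with
probability proportional to ``budget / mean_bout`` and occupied for
``mean_bout`` on average, so by renewal-reward the stationary occupancy is
proportional to ``budget``.

Lameness is assigned independently per sheep at session start (a coin-flip
mechanism at probability ``p_lame``) and is immutable thereafter; lame sheep
carry a gait-cue profile (shortened stride on one leg, quickened opposite
stride, head nod) that virtual observers read while the sheep walks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "GRAZE",
    "STAND",
    "WALK",
    "STATES",
    "LEGS",
    "ConfigError",
    "SessionOverError",
    "BehaviorConfig",
    "CueProfile",
    "SheepAgent",
    "FlockState",
    "SessionEventLog",
    "init_flock",
    "step",
    "stationary_budget",
    "run_session",
    "empirical_occupancy",
]

GRAZE, STAND, WALK = "graze", "stand", "walk"
STATES: tuple[str, str, str] = (GRAZE, STAND, WALK)
LEGS: tuple[str, ...] = ("front-left", "front-right", "hind-left", "hind-right")


class ConfigError(ValueError):
    """A configuration field violates its contract; the message names the field."""


class SessionOverError(RuntimeError):
    """Raised when stepping a flock past the configured session length."""


@dataclass(frozen=True)
class BehaviorConfig:
    """Flock behaviour parameters.

    Budgets are long-run fractions of time per state and must sum to 1;
    bout means are in seconds.  Defaults follow the game description:
    grazing ~73% of the time, standing ~23.5%, walking ~3.5%, a flock of
    24 sheep, a 10-minute session, and lameness assigned per sheep with
    probability 0.5.
    """

    budget_graze: float = 0.73
    budget_stand: float = 0.235
    budget_walk: float = 0.035
    mean_bout_graze: float = 60.0
    mean_bout_stand: float = 30.0
    mean_bout_walk: float = 10.0
    tick: float = 1.0
    session_length: float = 600.0
    flock_size: int = 24
    p_lame: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        budgets = (self.budget_graze, self.budget_stand, self.budget_walk)
        for name in ("budget_graze", "budget_stand", "budget_walk"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if abs(sum(budgets) - 1.0) > 1e-9:
            raise ConfigError(
                "budget_graze + budget_stand + budget_walk must equal 1 "
                f"(got {sum(budgets)!r})"
            )
        for name in ("mean_bout_graze", "mean_bout_stand", "mean_bout_walk", "tick"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not self.session_length > 0:
            raise ConfigError("session_length must be > 0")
        if not (isinstance(self.flock_size, (int, np.integer)) and self.flock_size >= 1):
            raise ConfigError("flock_size must be an integer >= 1")
        if not 0.0 <= self.p_lame <= 1.0:
            raise ConfigError("p_lame must lie in [0, 1]")

    @property
    def budgets(self) -> np.ndarray:
        return np.array([self.budget_graze, self.budget_stand, self.budget_walk])

    @property
    def mean_bouts(self) -> np.ndarray:
        return np.array(
            [self.mean_bout_graze, self.mean_bout_stand, self.mean_bout_walk]
        )

    def entry_weights(self) -> np.ndarray:
        """Normalized next-state probabilities (∝ budget / mean bout)."""
        w = self.budgets / self.mean_bouts
        return w / w.sum()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CueProfile:
    """Gait cues of a lame sheep: all three early-lameness cues co-occur."""

    shortened_stride_leg: str
    quickened_opposite_stride: bool = True
    head_nod: float = 1.0

    def __post_init__(self) -> None:
        if self.shortened_stride_leg not in LEGS:
            raise ConfigError(f"shortened_stride_leg must be one of {LEGS}")
        if not 0.0 <= self.head_nod <= 1.0:
            raise ConfigError("head_nod must lie in [0, 1]")


@dataclass
class SheepAgent:
    """One flock member. ``status`` is fixed for the whole session."""

    sheep_id: int
    status: str  # "healthy" | "lame"
    cue: Optional[CueProfile]
    behavior_state: str
    bout_remaining: float

    def __post_init__(self) -> None:
        if (self.cue is None) != (self.status == "healthy"):
            raise ConfigError("cue must be absent iff status is healthy")

    @property
    def is_lame(self) -> bool:
        return self.status == "lame"


@dataclass
class FlockState:
    agents: list[SheepAgent]
    clock: float = 0.0

    def agent(self, sheep_id: int) -> SheepAgent:
        return self.agents[sheep_id - 1]

    @property
    def sheep_ids(self) -> list[int]:
        return [a.sheep_id for a in self.agents]

    @property
    def lame_ids(self) -> set[int]:
        return {a.sheep_id for a in self.agents if a.is_lame}


@dataclass
class SessionEventLog:
    """Ordered record of one game session.

    ``events`` holds ``(time, sheep_id, event)`` tuples where the event is
    either ``state_enter:<state>`` or ``marked_lame``; times never decrease
    and each sheep is marked at most once (marking is irreversible).
    ``roster`` records ground-truth status per sheep for scoring.
    """

    config_echo: BehaviorConfig
    roster: dict[int, str] = field(default_factory=dict)
    events: list[tuple[float, int, str]] = field(default_factory=list)
    end_time: float = 0.0

    def append(self, time: float, sheep_id: int, event: str) -> None:
        if self.events and time < self.events[-1][0] - 1e-12:
            raise ValueError("event times must be non-decreasing")
        if event == "marked_lame" and sheep_id in self.marked_ids():
            return  # idempotent: spray once, never unspray
        self.events.append((time, sheep_id, event))

    def marked_ids(self) -> set[int]:
        return {sid for _, sid, ev in self.events if ev == "marked_lame"}

    def mark_events(self) -> list[tuple[float, int]]:
        return [(t, sid) for t, sid, ev in self.events if ev == "marked_lame"]

    def to_jsonl(self) -> str:
        """Serialize as JSON lines: a header record echoing the config and
        truth roster, then one record per event."""
        header = {
            "record": "header",
            "config": self.config_echo.to_dict(),
            "roster": {str(k): v for k, v in sorted(self.roster.items())},
            "end_time": self.end_time,
        }
        lines = [json.dumps(header)]
        for t, sid, ev in self.events:
            lines.append(
                json.dumps({"record": "event", "time": t, "sheep_id": sid, "event": ev})
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "SessionEventLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty session log")
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed session log at line 1: {exc}") from exc
        if header.get("record") != "header":
            raise ValueError("malformed session log at line 1: missing header record")
        cfg_fields = {f.name for f in dataclasses.fields(BehaviorConfig)}
        cfg = BehaviorConfig(
            **{k: v for k, v in header["config"].items() if k in cfg_fields}
        )
        log = cls(
            config_echo=cfg,
            roster={int(k): v for k, v in header["roster"].items()},
            end_time=float(header["end_time"]),
        )
        for i, ln in enumerate(lines[1:], start=2):
            try:
                rec = json.loads(ln)
                log.append(float(rec["time"]), int(rec["sheep_id"]), str(rec["event"]))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"malformed session log at line {i}: {exc}") from exc
        return log


def stationary_budget(config: BehaviorConfig) -> tuple[float, float, float]:
    """Analytic long-run occupancy of the configured semi-Markov chain.

    Occupancy(state) ∝ entry_probability(state) × mean_bout(state); with entry
    probabilities ∝ budget/mean_bout this reduces to the configured budgets.
    """
    occ = config.entry_weights() * config.mean_bouts
    occ = occ / occ.sum()
    return (float(occ[0]), float(occ[1]), float(occ[2]))


def _sample_state(config: BehaviorConfig, rng: np.random.Generator) -> int:
    return int(rng.choice(3, p=config.entry_weights()))


def init_flock(config: BehaviorConfig, rng: np.random.Generator) -> FlockState:
    """Create a flock at game start.

    Each sheep is independently lame with probability ``p_lame``; lame sheep
    get a uniformly random affected leg and the full cue profile.  The initial
    behaviour state is drawn from the stationary occupancy with a residual
    bout drawn from the stationary residual-life law (exponential, by
    memorylessness), so the process is stationary from the first tick.
    """
    config.validate()
    budgets = config.budgets
    means = config.mean_bouts
    agents: list[SheepAgent] = []
    for sheep_id in range(1, config.flock_size + 1):
        lame = rng.random() < config.p_lame
        cue = CueProfile(shortened_stride_leg=LEGS[rng.integers(4)]) if lame else None
        s = int(rng.choice(3, p=budgets))
        agents.append(
            SheepAgent(
                sheep_id=sheep_id,
                status="lame" if lame else "healthy",
                cue=cue,
                behavior_state=STATES[s],
                bout_remaining=float(rng.exponential(means[s])),
            )
        )
    return FlockState(agents=agents, clock=0.0)


def step(
    flock: FlockState,
    config: BehaviorConfig,
    rng: np.random.Generator,
    log: Optional[SessionEventLog] = None,
) -> list[tuple[int, str, str]]:
    """Advance the flock by one tick, in place.

    Decrements every bout clock by ``tick``; agents whose bout expires sample
    a new state (and bout) per the entry-weight rule — possibly several times
    within one tick for very short bouts.  Returns the list of completed-bout
    transitions ``(sheep_id, ended_state, new_state)`` so callers (observers)
    can classify sheep at the moment a bout ends.
    """
    if flock.clock + config.tick > config.session_length + 1e-9:
        raise SessionOverError(
            f"cannot step past session_length={config.session_length}"
        )
    weights = config.entry_weights()
    means = config.mean_bouts
    transitions: list[tuple[int, str, str]] = []
    flock.clock += config.tick
    for agent in flock.agents:
        agent.bout_remaining -= config.tick
        while agent.bout_remaining <= 0.0:
            s = int(rng.choice(3, p=weights))
            old = agent.behavior_state
            agent.behavior_state = STATES[s]
            agent.bout_remaining += float(rng.exponential(means[s]))
            transitions.append((agent.sheep_id, old, STATES[s]))
            if log is not None:
                log.append(flock.clock, agent.sheep_id, f"state_enter:{STATES[s]}")
    return transitions


def run_session(
    config: BehaviorConfig,
    observer=None,
    seed: Optional[int] = None,
) -> SessionEventLog:
    """Simulate one full game session and return its event log.

    With ``observer`` (an :class:`woolsim.observer.ObserverConfig`) attached,
    a virtual player watches the flock, marks suspects, and may quit early;
    otherwise the session runs unobserved to the timer.  Bitwise reproducible
    given ``(config, observer, seed)``.
    """
    from .observer import VirtualPlayer  # local import to avoid a cycle

    if seed is None:
        seed = config.seed if config.seed is not None else 0
    flock_rng, obs_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    flock = init_flock(config, flock_rng)
    log = SessionEventLog(
        config_echo=config, roster={a.sheep_id: a.status for a in flock.agents}
    )
    for a in flock.agents:
        log.append(0.0, a.sheep_id, f"state_enter:{a.behavior_state}")

    player = VirtualPlayer(observer, config, obs_rng) if observer is not None else None
    end = config.session_length
    if player is not None and player.quit_time is not None:
        end = min(end, player.quit_time)

    n_ticks = int(round(end / config.tick))
    for _ in range(n_ticks):
        transitions = step(flock, config, flock_rng, log=log)
        if player is not None:
            for sid in player.tick(flock, transitions):
                log.append(flock.clock, sid, "marked_lame")
    log.end_time = flock.clock
    return log


def empirical_occupancy(
    config: BehaviorConfig,
    minutes: float,
    n_seeds: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo occupancy of (graze, stand, walk) as fractions of agent-time.

    Simulates the bout process of every sheep in ``n_seeds`` independent
    flocks over ``minutes`` simulated minutes each, using the same stochastic
    law as :func:`step` but sampling whole bouts at once (the next-state draw
    is independent of the current state, so bout state sequences are iid and
    can be generated vectorized).  Time-weighted occupancy is the
    continuous-time limit of the per-tick state census.
    """
    horizon = minutes * 60.0
    weights = config.entry_weights()
    means = config.mean_bouts
    n_agents = n_seeds * config.flock_size
    rng = np.random.default_rng(seed)
    totals = np.zeros(3)
    remaining = np.full(n_agents, horizon)
    # initial stationary state + residual bout
    states = rng.choice(3, size=n_agents, p=config.budgets)
    bouts = rng.exponential(means[states])
    while True:
        take = np.minimum(bouts, remaining)
        np.add.at(totals, states, take)
        remaining -= take
        alive = remaining > 0
        if not alive.any():
            break
        remaining = remaining[alive]
        states = rng.choice(3, size=remaining.size, p=weights)
        bouts = rng.exponential(means[states])
    return totals / totals.sum()
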