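"""Factorial design of the effort-based decision task.

Each session alternates physical- and mental-effort blocks. Every block
crosses valence (reward vs punishment) with the high-effort option's
incentive level and effort level; each factorial cell repeats a fixed
number of times, and the screen side of the high-effort option is
balanced exactly. The alternative option is always the same low
incentive / zero effort anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PHYSICAL = "physical"
MENTAL = "mental"
DOMAINS = (PHYSICAL, MENTAL)
REWARD = "reward"
PUNISHMENT = "punishment"
VALENCES = (REWARD, PUNISHMENT)


class ConfigError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Task structure: 4 alternating blocks of 54 trials by default.

    The default factorial is 3 high-effort incentive levels x 3 effort
    levels x 2 valences x 3 repetitions = 54 trials per block; the fixed
    low option sits at incentive/effort level 0 and is worth +/-0.5
    currency units. Physical efforts are grip squeezes of 0.5-4.5 s at
    55% of maximal voluntary contraction; mental efforts are 2-back
    responses inside a 10 s window (metadata only at this level).
    """

    n_blocks: int = 4
    trials_per_block: int = 54
    he_incentive_levels: int = 3
    he_effort_levels: int = 3
    n_repetitions: int = 3
    low_incentive_level: int = 0
    low_effort_level: int = 0
    low_money_magnitude: float = 0.5
    physical_duration_range_s: tuple[float, float] = (0.5, 4.5)
    physical_force_threshold: float = 0.55
    mental_window_s: float = 10.0

    def __post_init__(self) -> None:
        cells = (
            self.he_incentive_levels * self.he_effort_levels
            * len(VALENCES) * self.n_repetitions
        )
        if cells != self.trials_per_block:
            raise ConfigError(
                f"factorial product {cells} != trials_per_block "
                f"{self.trials_per_block}"
            )
        if self.n_blocks % 2 != 0:
            raise ConfigError("n_blocks must be even to alternate domains")
        if self.trials_per_block % 2 != 0:
            raise ConfigError("trials_per_block must be even for side balance")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Trial:
    block_index: int
    trial_index: int
    domain: str
    valence: str
    he_incentive: int
    he_effort: int
    le_incentive: int
    le_effort: int
    side_of_he: str


@dataclass
class Block:
    domain: str
    seed: int
    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)


def generate_block(domain: str, config: TaskConfig, seed: int,
                   block_index: int = 0) -> Block:
    """Generate one block: exact factorial cell counts, seeded order,
    exactly balanced left/right position of the high-effort option."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    rng = np.random.default_rng(seed)
    cells = [
        (val, inc, eff)
        for val in VALENCES
        for inc in range(1, config.he_incentive_levels + 1)
        for eff in range(1, config.he_effort_levels + 1)
        for _ in range(config.n_repetitions)
    ]
    order = rng.permutation(len(cells))
    half = config.trials_per_block // 2
    sides = np.array(["left"] * half + ["right"] * half)
    rng.shuffle(sides)
    trials = [
        Trial(
            block_index=block_index,
            trial_index=t,
            domain=domain,
            valence=cells[i][0],
            he_incentive=cells[i][1],
            he_effort=cells[i][2],
            le_incentive=config.low_incentive_level,
            le_effort=config.low_effort_level,
            side_of_he=str(sides[t]),
        )
        for t, i in enumerate(order)
    ]
    return Block(domain=domain, seed=seed, trials=trials)


def generate_session(config: TaskConfig, first_domain: str = PHYSICAL,
                     seed: int = 0) -> list[Block]:
    """Generate n_blocks blocks, domains strictly alternating."""
    if first_domain not in DOMAINS:
        raise ValueError(f"unknown domain {first_domain!r}")
    rng = np.random.default_rng(seed)
    other = MENTAL if first_domain == PHYSICAL else PHYSICAL
    blocks = []
    for b in range(config.n_blocks):
        domain = first_domain if b % 2 == 0 else other
        block_seed = int(rng.integers(0, 2**31 - 1))
        blocks.append(generate_block(domain, config, block_seed, block_index=b))
    return blocks


def count_incentive_levels(config: TaskConfig) -> int:
    """Distinct (valence, incentive) levels, counting the low anchor's
    level-0 once per valence: the default design has 8 (4 rewards and
    4 punishments)."""
    return len(VALENCES) * (config.he_incentive_levels + 1)


def session_to_frame(blocks: list[Block]) -> pd.DataFrame:
    """One row per trial, in presentation order."""
    rows = [asdict(t) for block in blocks for t in block.trials]
    return pd.DataFrame(rows)
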