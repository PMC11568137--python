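"""4-2 staircase threshold procedure and simulated observers.

The first stimulus is presented at 17 dB. A seen response makes the next
presentation 4 dB dimmer (higher dB), a miss makes it 4 dB brighter; after
the first response reversal the step drops to 2 dB and the point terminates
at the second reversal. The estimate is the last-seen level. Levels are
clamped to the device range; a point where nothing was ever seen reports
the device's raw floor (-1 on MAIA, adjusted to 0 downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class StaircaseConfig:
    start_db: float = 17.0
    coarse_step_db: float = 4.0
    fine_step_db: float = 2.0
    min_db: float = 0.0
    max_db: float = 34.0
    raw_floor_db: float = 0.0    # reported when nothing is seen (-1 on MAIA)
    max_presentations: int = 50

    def __post_init__(self) -> None:
        if not (self.min_db <= self.start_db <= self.max_db):
            raise ValueError("start level must lie within the device range")
        if not (self.coarse_step_db > self.fine_step_db > 0):
            raise ValueError("need coarse step > fine step > 0")

    @classmethod
    def mp3(cls) -> "StaircaseConfig":
        return cls(max_db=34.0, raw_floor_db=0.0)

    @classmethod
    def maia(cls) -> "StaircaseConfig":
        return cls(max_db=36.0, raw_floor_db=-1.0)


@dataclass(frozen=True)
class ObserverModel:
    """Psychometric response model.

    ``sigma_psy_db == 0`` gives the deterministic step observer (seen iff
    the presented level is at or below threshold). Otherwise the seen
    probability follows a cumulative Gaussian in dB, mixed with lapse
    (false-negative) and guess (false-positive) rates.
    """

    sigma_psy_db: float = 1.0
    false_positive_rate: float = 0.03
    false_negative_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma_psy_db < 0:
            raise ValueError("sigma_psy_db must be >= 0")
        for r in (self.false_positive_rate, self.false_negative_rate):
            if not (0.0 <= r <= 0.2):
                raise ValueError("response-error rates must be in [0, 0.2]")

    @classmethod
    def deterministic(cls) -> "ObserverModel":
        return cls(sigma_psy_db=0.0, false_positive_rate=0.0,
                   false_negative_rate=0.0)

    def p_seen(self, level_db: float, threshold_db: float) -> float:
        if self.sigma_psy_db == 0:
            core = 1.0 if level_db <= threshold_db else 0.0
        else:
            core = float(norm.cdf((threshold_db - level_db) / self.sigma_psy_db))
        return (self.false_positive_rate
                + (1.0 - self.false_positive_rate - self.false_negative_rate) * core)

    def respond(self, level_db: float, threshold_db: float,
                rng: np.random.Generator) -> bool:
        p = self.p_seen(level_db, threshold_db)
        if p >= 1.0:
            return True
        if p <= 0.0:
            return False
        return bool(rng.uniform() < p)


def run_staircase(true_threshold_db: float, observer: ObserverModel,
                  config: StaircaseConfig,
                  rng: np.random.Generator | None = None,
                  return_trace: bool = False):
    """Measure one point with the 4-2 staircase.

    Returns the raw device estimate in dB (``raw_floor_db`` when nothing
    was seen). With ``return_trace`` also returns the list of
    ``(level, seen)`` presentations.
    """
    if not np.isfinite(true_threshold_db):
        raise ValueError("true threshold must be finite")
    if rng is None:
        rng = np.random.default_rng(0)
    level = config.start_db
    step = config.coarse_step_db
    reversals = 0
    last_response: bool | None = None
    last_seen: float | None = None
    trace: list[tuple[float, bool]] = []
    for _ in range(config.max_presentations):
        seen = observer.respond(level, true_threshold_db, rng)
        trace.append((level, seen))
        if seen:
            last_seen = level
        if last_response is not None and seen != last_response:
            reversals += 1
            if reversals == 1:
                step = config.fine_step_db
            if reversals >= 2:
                break
        last_response = seen
        nxt = level + (step if seen else -step)
        nxt = min(max(nxt, config.min_db), config.max_db)
        if nxt == level:
            # pinned at a range limit; further presentations are uninformative
            break
        level = nxt
    estimate = config.raw_floor_db if last_seen is None else last_seen
    if return_trace:
        return estimate, trace
    return estimate
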