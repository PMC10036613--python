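"""Synthetic gaze-trial generator with strategy-conditioned structure.

Each simulated trial is a response time drawn from a per-strategy lognormal,
filled with fixations whose sequence over the 18 payoff AOIs follows a
Markov chain calibrated so that the *category-level* transition frequencies
(own-own, other-other, own<->other within a cell, own<->other across cells,
out-of-AOI) match configured per-strategy proportions.  The defaults encode
the reported behavioural signatures: equilibrium play dwells on the
counterpart's payoffs (other-other 0.29, own-own 0.18), naive play on the
participant's own payoffs (0.36 vs 0.11), coordination play balances the
two (0.26 vs 0.22), with mean response times of 18 050, 13 770 and
15 660 ms respectively and a pooled strategy mixture of 0.48/0.31/0.21.

The category walk is realised as a 3-state role chain (own / other / out)
whose stationary flow frequencies equal the configured category vector
exactly; the chain starts from its stationary distribution, so every
transition's marginal category distribution is unbiased at any sequence
length.  Within-participant consistency is induced by drawing a per-person
strategy propensity from a Dirichlet centred on the pooled mixture.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .games import Game, StrategyLabel, STRATEGIES, label_choice, strategy_predictions, ROW_ACTIONS
from .render import OUT, AOILayout, build_layout

TRANSITION_CATEGORIES = ("own", "other", "intracell", "cross", "out")

#: per-strategy transition-category kernels (sum to 1).  The own-own and
#: other-other masses are the reported per-strategy proportions; the split
#: of the remainder over intracell / cross / out is a modelling choice
#: (coordination gets the largest intracell share: comparing the two
#: players' payoffs within an outcome cell is that strategy's hallmark).
DEFAULT_KERNELS: dict[StrategyLabel, dict[str, float]] = {
    StrategyLabel.EQUILIBRIUM: {"own": 0.18, "other": 0.29, "intracell": 0.12, "cross": 0.35, "out": 0.06},
    StrategyLabel.NAIVE: {"own": 0.36, "other": 0.11, "intracell": 0.10, "cross": 0.37, "out": 0.06},
    StrategyLabel.COORDINATION: {"own": 0.26, "other": 0.22, "intracell": 0.25, "cross": 0.21, "out": 0.06},
}

#: reported mean / SD of response time (ms) per strategy
DEFAULT_RT_MS: dict[StrategyLabel, tuple[float, float]] = {
    StrategyLabel.EQUILIBRIUM: (18050.0, 13200.0),
    StrategyLabel.NAIVE: (13770.0, 16780.0),
    StrategyLabel.COORDINATION: (15660.0, 15400.0),
}

DEFAULT_CLASS_MIXTURE = (0.48, 0.31, 0.21)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class Fixation:
    x: float
    y: float
    start: float  # ms
    end: float  # ms

    def __post_init__(self) -> None:
        for name in ("x", "y", "start", "end"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.end > self.start >= 0):
            raise ValueError(f"fixation times invalid: start={self.start}, end={self.end}")


@dataclass(frozen=True)
class SaccadeEvent:
    start_pos: tuple[float, float]
    end_pos: tuple[float, float]
    start_time: float  # ms
    end_time: float  # ms

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_pos", tuple(float(v) for v in self.start_pos))
        object.__setattr__(self, "end_pos", tuple(float(v) for v in self.end_pos))
        object.__setattr__(self, "start_time", float(self.start_time))
        object.__setattr__(self, "end_time", float(self.end_time))
        if not self.end_time > self.start_time:
            raise ValueError("saccade end_time must exceed start_time")


@dataclass(frozen=True)
class ScanpathRecord:
    """One trial: ordered gaze events plus choice metadata.

    Saccade ``k`` connects fixation ``k`` to fixation ``k+1``; events are
    time-ordered and non-overlapping, and the response time is at least
    the end of the last event.
    """

    participant_id: str
    game_id: str
    fixations: tuple[Fixation, ...]
    saccades: tuple[SaccadeEvent, ...]
    chosen: str
    rt: float  # ms
    label: StrategyLabel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", float(self.rt))
        fx, sc = self.fixations, self.saccades
        if fx and len(sc) not in (len(fx) - 1, 0):
            raise ValueError("saccade count must be len(fixations) - 1 (or 0)")
        t = 0.0
        for i, f in enumerate(fx):
            if f.start < t:
                raise ValueError(f"fixation {i} overlaps the previous event")
            t = f.end
            if i < len(sc):
                s = sc[i]
                if s.start_time < f.end:
                    raise ValueError(f"saccade {i} starts before fixation {i} ends")
                t = s.end_time
        if fx and self.rt < max(fx[-1].end, sc[-1].end_time if sc else 0.0) - 1e-9:
            raise ValueError("response time precedes the last gaze event")

    @property
    def duration(self) -> float:
        """End time of the last event (ms); 0 for an empty record."""
        ends = [f.end for f in self.fixations] + [s.end_time for s in self.saccades]
        return max(ends) if ends else 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic cohort; defaults are the study conditions."""

    class_mixture: tuple[float, float, float] = DEFAULT_CLASS_MIXTURE
    transition_kernel: dict[StrategyLabel, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_KERNELS.items()}
    )
    rt_mean_sd_ms: dict[StrategyLabel, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RT_MS)
    )
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_shape: float = 5.0  # gamma shape; scale = mean / shape
    saccade_duration_ms: float = 30.0
    spatial_noise_sd: float = 8.0  # px jitter of fixations around AOI centres
    out_of_aoi_rate: float = 0.06  # informational: default kernels' "out" mass
    participant_consistency: float = 2.0  # Dirichlet concentration multiplier
    choice_noise: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        for strat, kern in self.transition_kernel.items():
            if set(kern) != set(TRANSITION_CATEGORIES):
                raise ValueError(f"kernel for {strat} must cover {TRANSITION_CATEGORIES}")
            if any(p < 0 for p in kern.values()) or abs(sum(kern.values()) - 1.0) > 1e-9:
                raise ValueError(f"kernel for {strat} is not a probability vector")
        if self.fixation_duration_mean_ms <= 0 or self.saccade_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.choice_noise <= 1:
            raise ValueError("choice_noise must be in [0, 1]")


def _role_chain(kernel: dict[str, float]):
    """Stationary 3-state role chain (own=0, other=1, out=2) realising the
    category kernel as its stationary flow frequencies."""
    p_own, p_other = kernel["own"], kernel["other"]
    q = kernel["intracell"] + kernel["cross"]
    z = kernel["out"]
    denom = p_own + p_other + q
    w = (p_own + q / 2) / denom if denom > 0 else 0.5
    pi = np.array([p_own + q / 2 + z * w / 2, p_other + q / 2 + z * (1 - w) / 2, z / 2])
    M = np.zeros((3, 3))
    if pi[0] > 0:
        M[0] = [p_own / pi[0], (q / 2) / pi[0], (z * w / 2) / pi[0]]
    if pi[1] > 0:
        M[1] = [(q / 2) / pi[1], p_other / pi[1], (z * (1 - w) / 2) / pi[1]]
    M[2] = [w, 1 - w, 0.0]
    intracell_given_mixed = kernel["intracell"] / q if q > 0 else 0.0
    return pi, M, intracell_given_mixed


def _sample_positions(roles, layout: AOILayout, config: GeneratorConfig,
                      p_intracell: float, rng: np.random.Generator):
    """Concrete screen position for each role-state in the walk."""
    own = [a for a in layout.aois if a.role == "own"]
    other = [a for a in layout.aois if a.role == "other"]
    pools = {0: own, 1: other}
    sw, sh = layout.screen

    def jitter(aoi):
        dx, dy = rng.normal(0.0, config.spatial_noise_sd, size=2)
        r = math.hypot(dx, dy)
        lim = 0.9 * aoi.radius
        if r > lim:  # pull rare long draws back inside the disc
            dx, dy = dx * lim / r, dy * lim / r
        return (aoi.center[0] + dx, aoi.center[1] + dy)

    def out_position():
        while True:
            x, y = rng.uniform(0, sw), rng.uniform(0, sh)
            if all(math.hypot(x - a.center[0], y - a.center[1]) > a.radius for a in layout.aois):
                return (x, y)

    positions = []
    current_aoi = None
    for i, role in enumerate(roles):
        if role == 2:
            current_aoi = None
            positions.append(out_position())
            continue
        pool = pools[role]
        if current_aoi is None:
            nxt = pool[rng.integers(len(pool))]
        elif current_aoi.role == ("own" if role == 0 else "other"):
            cand = [a for a in pool if a.aoi_id != current_aoi.aoi_id]
            nxt = cand[rng.integers(len(cand))]
        else:  # mixed-role move: intracell (same cell) vs cross (different cell)
            if rng.uniform() < p_intracell:
                nxt = next(a for a in pool if a.cell == current_aoi.cell)
            else:
                cand = [a for a in pool if a.cell != current_aoi.cell]
                nxt = cand[rng.integers(len(cand))]
        current_aoi = nxt
        positions.append(jitter(nxt))
    return positions


def simulate_trial(
    game: Game,
    strategy: StrategyLabel,
    layout: AOILayout,
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> ScanpathRecord:
    """Simulate one trial played with the given decision strategy.

    Response time is lognormal (matched to the strategy's mean/SD);
    fixations fill the available time; the AOI sequence follows the
    strategy's transition kernel; the chosen action is the strategy's
    predicted action, flipped to a uniform alternative with probability
    ``choice_noise``.
    """
    strategy = StrategyLabel(strategy)
    mu, sigma = lognormal_params(*config.rt_mean_sd_ms[strategy])
    rt = float(rng.lognormal(mu, sigma))

    pi, M, p_intra = _role_chain(config.transition_kernel[strategy])
    scale = config.fixation_duration_mean_ms / config.fixation_duration_shape

    roles = [int(rng.choice(3, p=pi))]
    durations = [float(rng.gamma(config.fixation_duration_shape, scale))]
    t = durations[0] + config.saccade_duration_ms
    while True:
        d = float(rng.gamma(config.fixation_duration_shape, scale))
        if t + d > rt:
            break
        roles.append(int(rng.choice(3, p=M[roles[-1]])))
        durations.append(d)
        t += d + config.saccade_duration_ms
    rt = max(rt, durations[0])

    positions = _sample_positions(roles, layout, config, p_intra, rng)

    fixations, saccades = [], []
    t = 0.0
    for i, (pos, d) in enumerate(zip(positions, durations)):
        fixations.append(Fixation(x=pos[0], y=pos[1], start=t, end=t + d))
        t += d
        if i < len(positions) - 1:
            saccades.append(
                SaccadeEvent(start_pos=pos, end_pos=positions[i + 1],
                             start_time=t, end_time=t + config.saccade_duration_ms)
            )
            t += config.saccade_duration_ms

    preds = strategy_predictions(game)
    chosen = preds[strategy]
    if config.choice_noise > 0 and rng.uniform() < config.choice_noise:
        chosen = str(rng.choice([a for a in ROW_ACTIONS if a != chosen]))

    return ScanpathRecord(
        participant_id=participant_id,
        game_id=game.game_id,
        fixations=tuple(fixations),
        saccades=tuple(saccades),
        chosen=chosen,
        rt=rt,
        label=label_choice(game, chosen),
    )


def simulate_dataset(
    n_participants: int,
    battery: list[Game],
    config: GeneratorConfig,
    rng: np.random.Generator,
    layout: AOILayout | None = None,
) -> list[ScanpathRecord]:
    """Simulate a cohort: every participant plays every game in the battery.

    Each participant's strategy propensity is a Dirichlet draw centred on
    the pooled class mixture with concentration
    ``participant_consistency``; small concentrations yield near-pure
    strategists (high within-person consistency), infinite concentration
    collapses every participant onto the pooled mixture.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    layout = layout or build_layout()
    mixture = np.asarray(config.class_mixture, dtype=float)
    records: list[ScanpathRecord] = []
    for p in range(n_participants):
        pid = f"P{p:03d}"
        if math.isinf(config.participant_consistency):
            propensity = mixture
        else:
            propensity = rng.dirichlet(config.participant_consistency * mixture)
        for game in battery:
            strat = STRATEGIES[int(rng.choice(3, p=propensity))]
            records.append(simulate_trial(game, strat, layout, config, rng, participant_id=pid))
    return records


# ---------------------------------------------------------------------------
# delimited-text round-trip

EVENT_HEADER = ["participant_id", "game_id", "event_type", "x1", "y1", "x2", "y2", "t_start_ms", "t_end_ms"]
TRIAL_HEADER = ["participant_id", "game_id", "chosen_action", "rt_ms", "label"]


class EventParseError(ValueError):
    """Malformed event/metadata file; message names the offending line."""


def write_events(records: list[ScanpathRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``events.csv`` and ``trials.csv`` under ``out_dir``; lossless."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events_path, trials_path = out_dir / "events.csv", out_dir / "trials.csv"
    with events_path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(EVENT_HEADER)
        for rec in records:
            ev: list[tuple[float, list]] = []
            for f in rec.fixations:
                ev.append((f.start, [rec.participant_id, rec.game_id, "fix",
                                     repr(f.x), repr(f.y), "", "", repr(f.start), repr(f.end)]))
            for s in rec.saccades:
                ev.append((s.start_time, [rec.participant_id, rec.game_id, "sacc",
                                          repr(s.start_pos[0]), repr(s.start_pos[1]),
                                          repr(s.end_pos[0]), repr(s.end_pos[1]),
                                          repr(s.start_time), repr(s.end_time)]))
            for _, row in sorted(ev, key=lambda t: t[0]):
                wr.writerow(row)
    with trials_path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(TRIAL_HEADER)
        for rec in records:
            wr.writerow([rec.participant_id, rec.game_id, rec.chosen, repr(rec.rt),
                         rec.label.value if rec.label is not None else ""])
    return events_path, trials_path


def read_events(in_dir: str | Path) -> list[ScanpathRecord]:
    """Read records written by :func:`write_events`, validating invariants.

    Raises :class:`EventParseError` naming the file and 1-based line number
    of the first malformed row, non-monotone time, or trial reference that
    is missing from the metadata file.
    """
    in_dir = Path(in_dir)
    events_path, trials_path = in_dir / "events.csv", in_dir / "trials.csv"
    for p in (events_path, trials_path):
        if not p.exists():
            raise EventParseError(f"missing file: {p}")

    meta: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with trials_path.open(newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd, None)
        if header is None or header[:4] != TRIAL_HEADER[:4]:
            raise EventParseError(f"{trials_path}, line 1: bad header {header}")
        for ln, row in enumerate(rd, start=2):
            if len(row) < 4:
                raise EventParseError(f"{trials_path}, line {ln}: expected >=4 fields")
            pid, gid, chosen, rt = row[0], row[1], row[2], row[3]
            if chosen not in ROW_ACTIONS:
                raise EventParseError(f"{trials_path}, line {ln}: unknown action {chosen!r}")
            try:
                rt_ms = float(rt)
            except ValueError:
                raise EventParseError(f"{trials_path}, line {ln}: bad rt_ms {rt!r}") from None
            label = StrategyLabel(row[4]) if len(row) > 4 and row[4] else None
            meta[(pid, gid)] = {"chosen": chosen, "rt": rt_ms, "label": label}
            order.append((pid, gid))

    fix: dict[tuple[str, str], list[Fixation]] = {k: [] for k in meta}
    sacc: dict[tuple[str, str], list[SaccadeEvent]] = {k: [] for k in meta}
    with events_path.open(newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd, None)
        if header != EVENT_HEADER:
            raise EventParseError(f"{events_path}, line 1: bad header {header}")
        for ln, row in enumerate(rd, start=2):
            if len(row) != len(EVENT_HEADER):
                raise EventParseError(f"{events_path}, line {ln}: expected {len(EVENT_HEADER)} fields")
            pid, gid, etype = row[0], row[1], row[2]
            key = (pid, gid)
            if key not in meta:
                raise EventParseError(
                    f"{events_path}, line {ln}: trial ({pid}, {gid}) not in metadata")
            try:
                t0, t1 = float(row[7]), float(row[8])
                if etype == "fix":
                    fix[key].append(Fixation(x=float(row[3]), y=float(row[4]), start=t0, end=t1))
                elif etype == "sacc":
                    sacc[key].append(SaccadeEvent(
                        start_pos=(float(row[3]), float(row[4])),
                        end_pos=(float(row[5]), float(row[6])),
                        start_time=t0, end_time=t1))
                else:
                    raise ValueError(f"unknown event_type {etype!r}")
            except ValueError as exc:
                raise EventParseError(f"{events_path}, line {ln}: {exc}") from None

    records = []
    for key in order:
        m = meta[key]
        try:
            records.append(ScanpathRecord(
                participant_id=key[0], game_id=key[1],
                fixations=tuple(sorted(fix[key], key=lambda f: f.start)),
                saccades=tuple(sorted(sacc[key], key=lambda s: s.start_time)),
                chosen=m["chosen"], rt=m["rt"], label=m["label"]))
        except ValueError as exc:
            raise EventParseError(f"trial {key}: {exc}") from None
    return records
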