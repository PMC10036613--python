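"""Partial scanpaths: early-prediction subsequences of a trial's events.

A truncated record keeps exactly the fixations and saccades that *finished*
by a cutoff, given either as a fraction of the trial's total duration
(percent mode) or as an absolute time (time mode).  Events straddling the
cutoff are dropped — the partial image must reflect only completed
acquisitions.  Choice metadata is preserved, so the truncated record is the
evaluation unit for "how early is the strategy detectable".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .synth import ScanpathRecord

#: the default evaluation grids: four duration fractions and four absolute
#: cutoffs, eight partial-scanpath sets in total (the full record is a ninth).
PERCENT_GRID = (0.15, 0.30, 0.50, 0.80)
TIME_GRID_MS = (2000.0, 5000.0, 10000.0, 15000.0)


@dataclass(frozen=True)
class TruncationSpec:
    mode: str  # "percent" | "time"
    value: float  # fraction in (0, 1] or cutoff in ms

    def __post_init__(self) -> None:
        if self.mode not in ("percent", "time"):
            raise ValueError(f"mode must be 'percent' or 'time', got {self.mode!r}")
        if self.mode == "percent" and not 0 < self.value <= 1:
            raise ValueError("percent value must lie in (0, 1]")
        if self.mode == "time" and self.value <= 0:
            raise ValueError("time cutoff must be positive")

    @property
    def name(self) -> str:
        if self.mode == "percent":
            return f"p{round(self.value * 100)}"
        return f"t{round(self.value / 1000)}s" if self.value % 1000 == 0 else f"t{self.value}ms"


def default_specs() -> list[TruncationSpec]:
    return [TruncationSpec("percent", v) for v in PERCENT_GRID] + [
        TruncationSpec("time", v) for v in TIME_GRID_MS
    ]


def truncate_record(record: ScanpathRecord, spec: TruncationSpec) -> ScanpathRecord:
    """Retain exactly the events whose end time is <= the cutoff.

    Percent mode measures the cutoff against the trial's response time
    (which truncation preserves, so percent truncation is idempotent); a
    time cutoff at or beyond the trial duration returns the record
    unchanged.  Truncation is monotone: smaller cutoffs keep subsets of
    larger ones.
    """
    cutoff = spec.value * record.rt if spec.mode == "percent" else spec.value
    if cutoff <= 0 and record.fixations:
        raise ValueError(f"non-positive cutoff {cutoff} for {spec}")
    fixations = tuple(f for f in record.fixations if f.end <= cutoff)
    n = len(fixations)
    saccades = tuple(
        s for s in record.saccades[: max(n - 1, 0)] if s.end_time <= cutoff
    )
    return replace(record, fixations=fixations, saccades=saccades)


def build_truncation_sets(
    records: list[ScanpathRecord],
    specs: list[TruncationSpec] | None = None,
) -> dict[TruncationSpec, list[ScanpathRecord]]:
    """One truncated copy of every record per spec (default: the 8 grids)."""
    if not records:
        raise ValueError("no records to truncate")
    specs = default_specs() if specs is None else specs
    return {spec: [truncate_record(r, spec) for r in records] for spec in specs}
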