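"""Core containers for bilayer current recordings and idealized events.

A :class:`CurrentTrace` is a uniformly sampled current record (pA) with a
voltage protocol — an ordered list of constant-voltage epochs — plus free-form
recording metadata (temperature, salt, lipid mixture).  Traces round-trip
through a simple commented-CSV dialect so that simulated and measured data
share one on-disk format.  :class:`EventList` holds the product of
idealization: discrete channel openings with amplitudes, dwell times and a
conductance-level index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Epoch:
    """A constant-voltage stretch of a recording."""

    voltage_mv: float
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CurrentTrace:
    """Uniformly sampled transmembrane current with its voltage protocol.

    Parameters
    ----------
    samples : ndarray
        Current samples, pA.
    sampling_rate : float
        Hz.
    protocol : list of Epoch
        Non-overlapping constant-voltage epochs covering (part of) the record.
    metadata : dict
        Free-form labels (temperature_k, salt, lipid mix, filter cutoff...).
    true_events : EventList or None
        Ground-truth event log embedded by the simulator, for oracle tests.
    """

    samples: np.ndarray
    sampling_rate: float
    protocol: list[Epoch]
    metadata: dict = field(default_factory=dict)
    true_events: "EventList | None" = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        record_end = len(self.samples) / self.sampling_rate
        eps = 1.0 / self.sampling_rate
        prev_end = 0.0
        for ep in self.protocol:
            if ep.end_s <= ep.start_s:
                raise ValueError(f"epoch has nonpositive duration: {ep}")
            if ep.start_s < prev_end - 1e-12 or ep.end_s > record_end + eps:
                raise ValueError(f"epoch outside record or overlapping: {ep}")
            prev_end = ep.end_s

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times, s (left edge of each sampling interval)."""
        return np.arange(len(self.samples)) / self.sampling_rate

    def epoch_slice(self, epoch: Epoch) -> slice:
        i0 = int(round(epoch.start_s * self.sampling_rate))
        i1 = int(round(epoch.end_s * self.sampling_rate))
        return slice(i0, min(i1, len(self.samples)))

    def epoch_samples(self, epoch: Epoch) -> np.ndarray:
        return self.samples[self.epoch_slice(epoch)]

    def copy_with(self, samples: np.ndarray, **meta) -> "CurrentTrace":
        md = dict(self.metadata)
        md.update(meta)
        return CurrentTrace(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            protocol=list(self.protocol),
            metadata=md,
            true_events=self.true_events,
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as commented-header CSV (time_s,current_pA).

        The ground-truth event log, if present, goes to a JSON sidecar
        ``<path>.events.json``.
        """
        path = Path(path)
        lines = [f"# sampling_rate_hz={self.sampling_rate!r}"]
        for ep in self.protocol:
            lines.append(f"# epoch={ep.voltage_mv!r},{ep.start_s!r},{ep.end_s!r}")
        for key, val in sorted(self.metadata.items()):
            lines.append(f"# {key}={val!r}")
        t = self.time
        body = "\n".join(f"{ti:.9g},{si:.9g}" for ti, si in zip(t, self.samples))
        path.write_text("\n".join(lines) + "\ntime_s,current_pA\n" + body + "\n")
        if self.true_events is not None:
            self.true_events.to_json(path.with_suffix(path.suffix + ".events.json"))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrentTrace":
        path = Path(path)
        sampling_rate = None
        protocol: list[Epoch] = []
        metadata: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                key = key.strip()
                if key == "sampling_rate_hz":
                    sampling_rate = float(val)
                elif key == "epoch":
                    v, s, e = (float(x) for x in val.split(","))
                    protocol.append(Epoch(v, s, e))
                else:
                    try:
                        metadata[key] = json.loads(val.replace("'", '"'))
                    except (json.JSONDecodeError, ValueError):
                        metadata[key] = val
        df = pd.read_csv(path, comment="#")
        if sampling_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            sampling_rate = 1.0 / float(np.median(dt))
        events = None
        sidecar = path.with_suffix(path.suffix + ".events.json")
        if sidecar.exists():
            events = EventList.from_json(sidecar)
        return cls(df["current_pA"].to_numpy(), sampling_rate, protocol, metadata, events)


@dataclass(frozen=True)
class ChannelEvent:
    """One idealized channel opening."""

    start_s: float
    dwell_s: float
    amplitude_pa: float
    level: int = 1

    def __post_init__(self) -> None:
        if self.dwell_s <= 0:
            raise ValueError(f"dwell_s must be positive, got {self.dwell_s}")
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")


@dataclass
class EventList:
    """Time-ordered channel openings from one constant-voltage epoch."""

    events: list[ChannelEvent]
    voltage_mv: float
    epoch_duration_s: float

    def __post_init__(self) -> None:
        starts = [ev.start_s for ev in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("events must be time-ordered")
        if self.total_open_time_s > self.epoch_duration_s + 1e-9:
            raise ValueError("total open time exceeds epoch duration")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([ev.amplitude_pa for ev in self.events])

    @property
    def dwells(self) -> np.ndarray:
        return np.array([ev.dwell_s for ev in self.events])

    @property
    def total_open_time_s(self) -> float:
        # level-2 overlaps are separate events but the membrane is "open"
        # once; merge on the time axis.
        if not self.events:
            return 0.0
        total = 0.0
        cur_start = self.events[0].start_s
        cur_end = cur_start + self.events[0].dwell_s
        for ev in self.events[1:]:
            if ev.start_s <= cur_end + 1e-12:
                cur_end = max(cur_end, ev.start_s + ev.dwell_s)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = ev.start_s, ev.start_s + ev.dwell_s
        return total + (cur_end - cur_start)

    @property
    def open_probability(self) -> float:
        """Fraction of epoch time with at least one conducting channel."""
        return self.total_open_time_s / self.epoch_duration_s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [ev.start_s for ev in self.events],
                "dwell_s": [ev.dwell_s for ev in self.events],
                "amplitude_pA": [ev.amplitude_pa for ev in self.events],
                "level": [ev.level for ev in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "voltage_mV": self.voltage_mv,
            "epoch_duration_s": self.epoch_duration_s,
            "events": [
                {
                    "start_s": ev.start_s,
                    "dwell_s": ev.dwell_s,
                    "amplitude_pA": ev.amplitude_pa,
                    "level": ev.level,
                }
                for ev in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EventList":
        payload = json.loads(Path(path).read_text())
        events = [
            ChannelEvent(ev["start_s"], ev["dwell_s"], ev["amplitude_pA"], ev["level"])
            for ev in payload["events"]
        ]
        return cls(events, payload["voltage_mV"], payload["epoch_duration_s"])

    @classmethod
    def from_events(
        cls,
        events: Iterable[ChannelEvent] | Sequence[tuple],
        voltage_mv: float,
        epoch_duration_s: float,
    ) -> "EventList":
        evs = [
            ev if isinstance(ev, ChannelEvent) else ChannelEvent(*ev) for ev in events
        ]
        return cls(evs, voltage_mv, epoch_duration_s)
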