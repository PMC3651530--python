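"""Append-only audit trails at three scopes.

Every engine action emits an event that is fanned out to (1) a console
stream for real-time monitoring, (2) the active sample's ``audit.txt``, and
(3) the series-wide ``series_audit.txt``.  Lines are tab-separated —
ISO-8601 timestamp, scope, level, message, optional JSON payload — so the
files are both greppable and machine-parseable; :func:`error_summary`
round-trips them back into a table of everything at warning level or above.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["AuditEvent", "AuditTrail", "error_summary", "parse_audit_line"]

LEVELS = ("info", "warning", "error", "fatal")


@dataclass(frozen=True)
class AuditEvent:
    timestamp: _dt.datetime
    scope: str  # "series", a sample name, or "sample/expno"
    level: str
    message: str
    payload: dict | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")

    def format_line(self) -> str:
        fields = [
            self.timestamp.isoformat(),
            self.scope,
            self.level,
            self.message.replace("\t", " ").replace("\n", " "),
        ]
        if self.payload is not None:
            fields.append(json.dumps(self.payload, sort_keys=True))
        return "\t".join(fields)


def parse_audit_line(line: str) -> AuditEvent:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 4:
        raise ValueError(f"unparseable audit line: {line!r}")
    timestamp = _dt.datetime.fromisoformat(parts[0])
    payload = json.loads(parts[4]) if len(parts) > 4 and parts[4] else None
    return AuditEvent(
        timestamp=timestamp,
        scope=parts[1],
        level=parts[2],
        message=parts[3],
        payload=payload,
    )


@dataclass
class AuditTrail:
    """Fan-out recorder: console + series file + active sample file.

    An unwritable sink never crashes acquisition: failed writes are buffered
    and flushed on the next successful write to that sink.
    """

    series_path: Path | None = None
    console: io.TextIOBase | None = None
    events: list[AuditEvent] = field(default_factory=list)
    _sample_path: Path | None = None
    _buffers: dict = field(default_factory=dict)
    _last_ts: _dt.datetime | None = None

    def open_sample(self, sample_dir: Path | None) -> None:
        """Direct sample-scope events to ``<sample_dir>/audit.txt``."""
        self._sample_path = Path(sample_dir) / "audit.txt" if sample_dir else None

    def close_sample(self) -> None:
        self._sample_path = None

    def _now(self) -> _dt.datetime:
        now = _dt.datetime.now()
        if self._last_ts is not None and now < self._last_ts:
            now = self._last_ts  # clock went backwards; keep monotone
        self._last_ts = now
        return now

    def record(
        self,
        scope: str,
        level: str,
        message: str,
        payload: dict | None = None,
    ) -> AuditEvent:
        event = AuditEvent(self._now(), scope, level, message, payload)
        self.events.append(event)
        line = event.format_line()
        if self.console is not None:
            try:
                self.console.write(line + "\n")
            except OSError:
                pass
        if self.series_path is not None:
            self._append(self.series_path, line)
        if scope != "series" and self._sample_path is not None:
            self._append(self._sample_path, line)
        return event

    def _append(self, path: Path, line: str) -> None:
        pending = self._buffers.get(path, [])
        pending.append(line)
        try:
            with open(path, "a", encoding="utf-8") as fh:
                fh.write("\n".join(pending) + "\n")
        except OSError:
            self._buffers[path] = pending  # keep for the next attempt
        else:
            self._buffers.pop(path, None)

    # convenience levels
    def info(self, scope, message, payload=None):
        return self.record(scope, "info", message, payload)

    def warning(self, scope, message, payload=None):
        return self.record(scope, "warning", message, payload)

    def error(self, scope, message, payload=None):
        return self.record(scope, "error", message, payload)

    def fatal(self, scope, message, payload=None):
        return self.record(scope, "fatal", message, payload)


def error_summary(series_audit: str | Path) -> tuple[pd.DataFrame, int]:
    """All warning-or-worse events from a series audit file, as a table.

    Returns ``(table, corrupt_lines)``; rows carry timestamp, scope, level
    and message so the time and nature of every acquisition problem can be
    read off directly.  Corrupt lines are counted, not fatal.
    """
    path = Path(series_audit)
    rows = []
    corrupt = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        try:
            event = parse_audit_line(line)
        except (ValueError, json.JSONDecodeError):
            corrupt += 1
            continue
        if LEVELS.index(event.level) >= LEVELS.index("warning"):
            rows.append(
                {
                    "timestamp": event.timestamp,
                    "scope": event.scope,
                    "level": event.level,
                    "message": event.message,
                }
            )
    table = pd.DataFrame(rows, columns=["timestamp", "scope", "level", "message"])
    return table, corrupt
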