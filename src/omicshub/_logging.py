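"""JSON-lines logging for pipeline stages.

Each record becomes one JSON object with timestamp, level, logger, message,
and any structured extras a stage attached (counts, dropped feature ids).
"""

from __future__ import annotations

import json
import logging

_STANDARD = set(logging.LogRecord("", 0, "", 0, "", (), None).__dict__) | {
    "message", "asctime", "taskName"}


class JsonLinesFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        payload = {
            "time": self.formatTime(record, "%Y-%m-%dT%H:%M:%S"),
            "level": record.levelname,
            "logger": record.name,
            "message": record.getMessage(),
        }
        for key, value in record.__dict__.items():
            if key not in _STANDARD:
                payload[key] = value
        return json.dumps(payload, default=str)


def configure_logging(stream=None, level=logging.INFO) -> logging.Handler:
    """Attach a JSON-lines handler to the package logger; returns the handler."""
    handler = logging.StreamHandler(stream)
    handler.setFormatter(JsonLinesFormatter())
    root = logging.getLogger("omicshub")
    root.addHandler(handler)
    root.setLevel(level)
    return handler
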