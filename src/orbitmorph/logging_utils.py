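"""Structured (JSON-lines) logging for auditable pipeline runs."""

from __future__ import annotations

import json
import logging

__all__ = ["configure_jsonl_logging"]


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        payload = {
            "logger": record.name,
            "level": record.levelname,
            "message": record.getMessage(),
        }
        return json.dumps(payload, sort_keys=True)


def configure_jsonl_logging(path=None, level=logging.INFO) -> None:
    """Route orbitmorph log records to stderr (and a file) as JSON lines.

    Records deliberately carry no timestamps so that identical runs
    produce identical logs (the determinism contract extends to the run
    audit trail).
    """
    root = logging.getLogger("orbitmorph")
    root.setLevel(level)
    root.handlers.clear()
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if path is not None:
        handlers.append(logging.FileHandler(path, mode="w"))
    for h in handlers:
        h.setFormatter(_JsonLineFormatter())
        root.addHandler(h)
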