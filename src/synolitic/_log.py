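"""Structured one-line-per-stage logging used across the pipeline."""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager

logger = logging.getLogger("synolitic")


def stage(name: str, **fields) -> None:
    """Emit one structured log line for a pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", name, kv)


@contextmanager
def timed_stage(name: str, **fields):
    """Log a stage line including wall time on exit."""
    t0 = time.perf_counter()
    yield
    stage(name, wall_s=f"{time.perf_counter() - t0:.3f}", **fields)
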