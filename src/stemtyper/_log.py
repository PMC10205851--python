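"""Structured stage logging to stderr: one line per pipeline stage."""

import logging
import sys

_handler = logging.StreamHandler(sys.stderr)
_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s | %(message)s"))

logger = logging.getLogger("stemtyper")
logger.addHandler(_handler)
logger.setLevel(logging.WARNING)


def stage(name: str, **dims) -> None:
    """Log one structured line for a pipeline stage with its dimensions."""
    fields = " ".join(f"{k}={v}" for k, v in dims.items())
    logger.info("stage=%s %s", name, fields)


def set_verbose(verbose: bool = True) -> None:
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
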