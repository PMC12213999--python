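"""CSV/JSON output with reproducibility headers.

Every CSV written by the pipeline carries a ``#``-prefixed header block
recording the tool version, the RNG seed and a hash of the generating
configuration, so identical configurations reproduce bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# stereogaze {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    """Read a CSV, skipping any ``#`` header block."""
    return pd.read_csv(Path(path), comment="#")
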