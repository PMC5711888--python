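"""Report writers: CSV for tabular results, JSON for structured ones.

Every report embeds the run configuration, the model digest and the
package version, so any number in any file traces back to (model, config,
seed).  CSV dialect: comma-separated, UTF-8, ``.`` decimal, 0/1 states.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .netcore import BooleanNetwork

__all__ = ["RunConfig", "write_json_report", "write_csv_report", "provenance"]


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one analysis run (embedded in reports)."""

    command: str
    model_path: str | None = None
    backend: str = "auto"
    n: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def provenance(config: RunConfig, net: BooleanNetwork) -> dict:
    return {
        "angionet_version": __version__,
        "model_digest": net.digest(),
        "node_order": list(net.nodes),
        "input_order": list(net.inputs),
        "config": asdict(config),
    }


def write_json_report(path, payload: dict, config: RunConfig, net: BooleanNetwork) -> None:
    path = Path(path)
    try:
        path.write_text(
            json.dumps({"provenance": provenance(config, net), **payload}, indent=2)
            + "\n"
        )
    except OSError as exc:
        raise OSError(f"cannot write JSON report to {path}: {exc}") from exc


def write_csv_report(path, frame, config: RunConfig, net: BooleanNetwork) -> None:
    """DataFrame to CSV with a ``#``-prefixed provenance header."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# " + json.dumps(provenance(config, net)) + "\n")
            frame.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write CSV report to {path}: {exc}") from exc
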