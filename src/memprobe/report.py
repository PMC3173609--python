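"""Provenance records and human-readable report assembly."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_provenance", "write_atomic", "render_report"]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_atomic(path: str | Path, text: str) -> None:
    """Write text to path atomically (tmp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_provenance(out_path: str | Path, stage: str, parameters: dict,
                     inputs: list[str | Path] | None = None,
                     seed: int | None = None) -> Path:
    """Emit the provenance JSON that accompanies every analysis result.

    Records stage name, all result-affecting parameters, input checksums,
    package version and seed; written atomically next to the result.
    """
    record = {
        "stage": stage,
        "parameters": {k: (v.tolist() if hasattr(v, "tolist") else v)
                       for k, v in parameters.items()},
        "inputs": {str(p): _checksum(p) for p in (inputs or []) if Path(p).exists()},
        "package": {"name": "memprobe", "version": __version__},
        "seed": seed,
    }
    path = Path(str(out_path) + ".provenance.json")
    write_atomic(path, json.dumps(record, indent=2, default=str) + "\n")
    return path


def render_report(table: pd.DataFrame, metric: str, title: str,
                  top_n: int = 10, threshold: float | None = None) -> str:
    """Markdown summary of a per-residue metric table (top residues first)."""
    lines = [f"# {title}", ""]
    if table.empty:
        lines.append("no contacts / no entries")
        return "\n".join(lines) + "\n"
    if threshold is not None:
        lines += [f"threshold: {threshold:.5g}", ""]
    ranked = table.sort_values(metric, ascending=False).head(top_n)
    cols = list(ranked.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "|".join("---" for _ in cols) + "|")
    for _, row in ranked.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
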