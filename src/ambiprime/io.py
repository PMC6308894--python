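"""Flat-file I/O: config files, BED/FASTA export, run manifests.

Coverage tables are tidy CSV (undefined proportions serialize as empty
fields, never 0).  Amplicons are written as BED — 0-based half-open, as
the format dictates — plus a FASTA of the extracted product sequences;
human-readable reports elsewhere print 1-based inclusive coordinates.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd

from .amplicon import Amplicon

__all__ = [
    "read_config",
    "write_coverage_csv",
    "write_amplicons_bed",
    "write_amplicons_fasta",
    "write_manifest",
]


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file.

    Lines starting with ``#`` and blank lines are ignored; values are
    coerced to int, float or bool when they parse as such.
    """
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            for cast in (int, float):
                try:
                    out[key] = cast(val)
                    break
                except ValueError:
                    continue
            else:
                if val.lower() in ("true", "false"):
                    out[key] = val.lower() == "true"
                else:
                    out[key] = val
    return out


def write_coverage_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy coverage table; NaN proportions become empty (null)."""
    table.to_csv(path, index=False, na_rep="")


def write_amplicons_bed(amplicons: list[Amplicon], path: str | Path) -> None:
    """BED6 export (0-based half-open; score = amplicon length)."""
    with open(path, "w") as fh:
        for i, a in enumerate(amplicons):
            fh.write(
                f"{a.seq_id}\t{a.start}\t{a.end}\t"
                f"{a.fwd_site.primer_name}~{a.rev_site.primer_name}.{i + 1}\t"
                f"{a.length}\t+\n"
            )


def write_amplicons_fasta(
    amplicons: list[Amplicon], templates: dict[str, str], path: str | Path
) -> None:
    """FASTA of predicted products, both primer footprints included."""
    with open(path, "w") as fh:
        for i, a in enumerate(amplicons):
            seq = templates[a.seq_id][a.start : a.end]
            fh.write(f">{a.seq_id}|amplicon{i + 1}|{a.start}-{a.end}|len={a.length}\n")
            fh.write(seq + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    params: dict,
    inputs: list[str | Path] = (),
) -> None:
    """Record command, parameters, input checksums and versions as JSON.

    Coverage numbers are meaningless without the match mode, seeds and
    thresholds that produced them, so every CLI run emits one of these.
    """
    from . import __version__

    manifest = {
        "tool": "ambiprime",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    return str(v)
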