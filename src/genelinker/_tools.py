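"""Thin wrappers around the external HMMER and BLAST+ executables.

All subprocess plumbing lives here so the science modules stay testable and
the tool versions can be logged in one place.
"""
from __future__ import annotations

import logging
import shutil
import subprocess

from .errors import ToolError

log = logging.getLogger(__name__)

_version_cache: dict[str, str] = {}


def require_tool(name: str, hint: str) -> str:
    """Return the path of an executable or raise with remediation text."""
    path = shutil.which(name)
    if path is None:
        raise ToolError(
            f"required executable {name!r} not found on PATH; {hint}"
        )
    return path


def tool_version(name: str) -> str:
    """Best-effort version string for a tool, cached per process."""
    if name in _version_cache:
        return _version_cache[name]
    try:
        out = subprocess.run(
            [name, "-h" if name.startswith("hmm") else "-version"],
            capture_output=True, text=True, timeout=30,
        )
        text = (out.stdout or out.stderr).splitlines()
        version = next((ln.strip("# ").strip() for ln in text if ln.strip()), "unknown")
    except Exception:  # pragma: no cover - diagnostics only
        version = "unknown"
    _version_cache[name] = version
    return version


def run_checked(cmd: list[str], what: str) -> subprocess.CompletedProcess:
    """Run a command, raising :class:`ToolError` on non-zero exit."""
    log.debug("running %s: %s", what, " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ToolError(
            f"{what} failed (exit {proc.returncode}): {proc.stderr.strip()[:500]}"
        )
    return proc
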