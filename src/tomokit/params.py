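"""Name-value parameter files.

Each preprocessing task is configured by a plain-text file of
``key = value`` lines (``#`` starts a comment).  Values are coerced in a
fixed order — int, float, bool (``true``/``false``), comma-separated list,
string — and unknown keys for a task are rejected at parse time with the
nearest valid key named, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Any

__all__ = ["ParamFile", "ParamError", "parse_param_file", "coerce_value"]


class ParamError(ValueError):
    pass


def coerce_value(raw: str) -> Any:
    text = raw.strip()
    if "," in text:
        return [coerce_value(tok) for tok in text.split(",") if tok.strip() != ""]
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


@dataclass
class ParamFile:
    task: str
    params: dict[str, Any] = field(default_factory=dict)
    source: str = "<memory>"


def parse_param_file(
    text: str,
    allowed_keys: dict[str, set[str]] | None = None,
    source: str = "<memory>",
) -> ParamFile:
    """Parse a parameter file; the ``task`` key selects the task.

    ``allowed_keys`` maps task name to its valid parameter names; when given,
    both the task name and every key are validated.
    """
    params: dict[str, Any] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ParamError(f"{source}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in stripped.split("=", 1))
        if key in params:
            raise ParamError(f"{source}:{lineno}: duplicate key {key!r}")
        params[key] = coerce_value(raw)
    task = params.pop("task", None)
    if task is None:
        raise ParamError(f"{source}: missing required key 'task'")
    if allowed_keys is not None:
        if task not in allowed_keys:
            raise ParamError(
                f"{source}: unknown task {task!r}; valid: {sorted(allowed_keys)}"
            )
        valid = allowed_keys[task]
        # entries ending in "*" are prefix wildcards (e.g. per-series keys)
        prefixes = tuple(v[:-1] for v in valid if v.endswith("*"))
        for key in params:
            if key in valid or (prefixes and key.startswith(prefixes)):
                continue
            near = difflib.get_close_matches(key, valid, n=1)
            hint = f" (did you mean {near[0]!r}?)" if near else ""
            raise ParamError(
                f"{source}: unknown key {key!r} for task {task!r}{hint}"
            )
    return ParamFile(task=str(task), params=params, source=source)
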