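"""Plain-text key=value configuration files.

All artifact configs (scene, pipeline) serialize to flat ``key = value``
lines so runs are diff-able and language-neutral. Nested mappings are
flattened with dots (``cell_density.follicle = 9.0``); sequences are
comma-separated.
"""

from __future__ import annotations

from pathlib import Path


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (list, tuple)):
        return ", ".join(_format_value(v) for v in value)
    if value is None:
        return "none"
    return repr(value) if isinstance(value, float) else str(value)


def flatten(mapping: dict, prefix: str = "") -> dict:
    out: dict = {}
    for key, value in mapping.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(flatten(value, prefix=f"{full}."))
        else:
            out[full] = value
    return out


def dump_kv(mapping: dict) -> str:
    lines = [f"{k} = {_format_value(v)}" for k, v in flatten(mapping).items()]
    return "\n".join(lines) + "\n"


def _parse_scalar(text: str):
    text = text.strip()
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def parse_kv(text: str) -> dict:
    """Parse ``key = value`` lines into a nested dict (dots nest keys)."""
    flat: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if "," in value:
            flat[key] = [_parse_scalar(v) for v in value.split(",")]
        else:
            flat[key] = _parse_scalar(value)
    nested: dict = {}
    for key, value in flat.items():
        node = nested
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return nested


def write_kv(mapping: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dump_kv(mapping))
    return path


def read_kv(path: str | Path) -> dict:
    return parse_kv(Path(path).read_text())
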