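"""Loading of detection-parameter and run configuration files (JSON/YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from punctaline.detect import PRESETS, DetectionParams

__all__ = ["load_params", "params_from_dict"]


def params_from_dict(spec: dict) -> DetectionParams:
    """Build :class:`DetectionParams` from a config mapping.

    Recognized keys: min_size, sigma, radius, method, connectivity, and a
    nested ``phansalkar: {k, r, p, q}`` block.
    """
    phans = spec.get("phansalkar", {})
    kwargs = {
        key: spec[key]
        for key in ("min_size", "sigma", "radius", "method", "connectivity")
        if key in spec
    }
    for short, long in (("k", "phansalkar_k"), ("r", "phansalkar_r"),
                        ("p", "phansalkar_p"), ("q", "phansalkar_q")):
        if short in phans:
            kwargs[long] = phans[short]
    return DetectionParams(**kwargs)


def load_params(source: str | Path) -> DetectionParams:
    """Resolve a preset name or a JSON/YAML parameter file."""
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise ValueError(f"{source!r} is neither a preset ({sorted(PRESETS)}) nor a file")
    text = path.read_text()
    spec = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(spec, dict):
        raise ValueError(f"{path}: expected a mapping of detection parameters")
    return params_from_dict(spec)
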