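"""Access to the packaged text fixtures (schemas, rulesets, toy SDFs)."""

from __future__ import annotations

from importlib import resources

_FILES = {
    "toxml_mini": "toxml_mini.xsd",
    "default_rules": "default.rules.yaml",
    "default_map": "default_map.yaml",
    "cpdbas_toy": "cpdbas_toy.sdf",
    "isscan_toy": "isscan_toy.sdf",
}


def load_text(name: str) -> str:
    """Return a bundled fixture by short name (see ``_FILES``)."""
    try:
        filename = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}") from None
    return (resources.files("toxlift") / "data" / filename).read_text(encoding="utf-8")
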