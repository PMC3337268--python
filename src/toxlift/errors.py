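"""Exception hierarchy shared across the toolchain."""


class ToxliftError(Exception):
    """Base class for all toolchain errors."""


class SchemaParseError(ToxliftError):
    """Malformed XML schema input; carries the source line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnsupportedConstructError(ToxliftError):
    """Schema uses an XSD construct outside the supported subset."""

    def __init__(self, construct: str, path: tuple[str, ...]):
        self.construct = construct
        self.path = path
        super().__init__(
            f"unsupported construct {construct!r} at /{'/'.join(path) or '(root)'}"
        )


class RuleConflictError(ToxliftError):
    """A rule references a field it cannot legally apply to."""


class LabelCollisionError(ToxliftError):
    """Two distinct fields map onto the same label without a unification rule."""

    def __init__(self, label: str, paths):
        self.label = label
        self.paths = list(paths)
        listing = "; ".join("/".join(p) for p in self.paths)
        super().__init__(f"label {label!r} produced by distinct paths: {listing}")


class DanglingReferenceError(ToxliftError):
    """A rule names a class or path that does not exist."""


class InvalidModelError(ToxliftError):
    """Refusal to serialize a structurally broken ontology or dataset model."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("model failed structural checks: " + "; ".join(self.issues))


class ValueSyntaxError(ToxliftError):
    """Raw indicator string does not match the grammar; carries the string."""

    def __init__(self, text: str, reason: str = "does not match grammar"):
        self.text = text
        super().__init__(f"cannot parse {text!r}: {reason}")


class ValueDomainError(ToxliftError):
    """Syntactically valid indicator string with impossible field values."""

    def __init__(self, text: str, reason: str):
        self.text = text
        super().__init__(f"invalid value {text!r}: {reason}")


class SdfParseError(ToxliftError):
    """Structurally broken SDF record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        self.record_index = record_index
        super().__init__(f"record {record_index}: {message}")


class DatasetError(ToxliftError):
    """Dataset-model level contract violation (duplicate ids, unknown feature...)."""


class UnmappedValueError(ToxliftError):
    """Harmonization map has no entry for a (feature, raw value) pair."""

    def __init__(self, feature: str, raw_value: str):
        self.feature = feature
        self.raw_value = raw_value
        super().__init__(f"no harmonized call for feature {feature!r} value {raw_value!r}")
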