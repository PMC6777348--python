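"""The model descriptor standard.

Every model in a registry directory tree is described by a single
``model.yaml`` file: metadata, a framework kind from a closed set,
input/output array schemas, a data-loader configuration, artifact file
roles, and a self-test block (example inputs plus expected outputs with
a numeric tolerance). Descriptors never carry executable code; the
framework kind selects one of the built-in model implementations, which
keeps loading safe and testable.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

FRAMEWORK_KINDS = ("pwm", "linear", "mlp")
_NAME_RE = re.compile(r"^[A-Za-z0-9_./-]+$")
DEFAULT_TOLERANCE = 1e-5


class DescriptorError(ValueError):
    """Raised for malformed or invalid model descriptors."""


@dataclass
class ArraySchema:
    """Shape contract for one model input or output.

    ``shape`` holds integer extents with ``None`` as the single leading
    wildcard standing for the batch dimension (written ``"*"`` in YAML).
    ``special_type`` of ``DNASeq`` additionally requires batches to be
    one-hot: binary entries whose length-4 rows sum to 0 (N/pad) or 1.
    """

    name: str
    shape: tuple[int | None, ...]
    special_type: str | None = None
    column_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.shape or self.shape[0] is not None:
            raise DescriptorError(
                f"schema {self.name!r}: shape must start with the '*' batch wildcard"
            )
        for ext in self.shape[1:]:
            if ext is None:
                raise DescriptorError(
                    f"schema {self.name!r}: only the leading extent may be '*'"
                )
            if ext < 1:
                raise DescriptorError(f"schema {self.name!r}: extents must be >= 1")
        if self.special_type not in (None, "DNASeq"):
            raise DescriptorError(
                f"schema {self.name!r}: special_type must be DNASeq or absent"
            )
        if self.column_labels is not None and len(self.column_labels) != self.shape[-1]:
            raise DescriptorError(
                f"schema {self.name!r}: {len(self.column_labels)} column_labels "
                f"but last extent is {self.shape[-1]}"
            )


@dataclass
class DataloaderConfig:
    """Keys the data-loader needs: FASTA path key, interval-source key,
    and the fixed sequence length fed to the model."""

    fasta: str | None = None
    intervals: str | None = None
    sequence_length: int | None = None


@dataclass
class TestConfig:
    example_inputs: dict[str, str] = field(default_factory=dict)
    expected_output: str | None = None
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise DescriptorError("test.tolerance must be >= 0")


@dataclass
class ModelDescription:
    name: str
    framework_kind: str
    inputs: list[ArraySchema]
    targets: ArraySchema
    version: str = "0"
    doc: str = ""
    tags: list[str] = field(default_factory=list)
    dataloader: DataloaderConfig = field(default_factory=DataloaderConfig)
    artifacts: dict[str, str] = field(default_factory=dict)
    test: TestConfig = field(default_factory=TestConfig)
    license: str = ""
    authors: str = ""
    extras: dict[str, Any] = field(default_factory=dict)  # unknown keys, preserved

    def __post_init__(self) -> None:
        if not self.name or not _NAME_RE.match(self.name):
            raise DescriptorError(
                f"model name {self.name!r} must be non-empty and match [A-Za-z0-9_./-]+"
            )
        if self.framework_kind not in FRAMEWORK_KINDS:
            raise DescriptorError(
                f"framework_kind {self.framework_kind!r} not allowed; "
                f"allowed kinds: {{{', '.join(FRAMEWORK_KINDS)}}}"
            )


_KNOWN_KEYS = {
    "name", "version", "doc", "tags", "framework_kind", "inputs", "targets",
    "dataloader", "artifacts", "test", "license", "authors",
}


def _parse_shape(raw: list) -> tuple[int | None, ...]:
    out: list[int | None] = []
    for ext in raw:
        if ext == "*" or ext is None:
            out.append(None)
        else:
            out.append(int(ext))
    return tuple(out)


def _parse_schema(raw: dict, where: str) -> ArraySchema:
    if "shape" not in raw:
        raise DescriptorError(f"missing required field: {where}.shape")
    return ArraySchema(
        name=str(raw.get("name", where)),
        shape=_parse_shape(raw["shape"]),
        special_type=raw.get("special_type"),
        column_labels=list(raw["column_labels"]) if raw.get("column_labels") else None,
    )


def parse_model_description(yaml_text: str) -> ModelDescription:
    """Parse a ``model.yaml`` document into a validated description.

    Missing optional fields get defaults (``tags`` [], ``test.tolerance``
    1e-5). Unknown top-level keys are preserved under ``extras`` but have
    no effect.
    """
    raw = yaml.safe_load(yaml_text)
    if not isinstance(raw, dict):
        raise DescriptorError("descriptor must be a YAML mapping")
    for req in ("name", "framework_kind", "inputs", "targets"):
        if req not in raw:
            raise DescriptorError(f"missing required field: {req}")
    inputs = [
        _parse_schema(s, f"inputs[{i}]") for i, s in enumerate(raw["inputs"])
    ]
    targets = _parse_schema(raw["targets"], "targets")
    dl_raw = raw.get("dataloader") or {}
    dataloader = DataloaderConfig(
        fasta=dl_raw.get("fasta"),
        intervals=dl_raw.get("intervals"),
        sequence_length=(
            int(dl_raw["sequence_length"]) if dl_raw.get("sequence_length") else None
        ),
    )
    t_raw = raw.get("test") or {}
    test = TestConfig(
        example_inputs={str(k): str(v) for k, v in (t_raw.get("example_inputs") or {}).items()},
        expected_output=t_raw.get("expected_output"),
        tolerance=float(t_raw.get("tolerance", DEFAULT_TOLERANCE)),
    )
    extras = {k: v for k, v in raw.items() if k not in _KNOWN_KEYS}
    return ModelDescription(
        name=str(raw["name"]),
        framework_kind=str(raw["framework_kind"]),
        inputs=inputs,
        targets=targets,
        version=str(raw.get("version", "0")),
        doc=str(raw.get("doc", "")),
        tags=[str(t) for t in (raw.get("tags") or [])],
        dataloader=dataloader,
        artifacts={str(k): str(v) for k, v in (raw.get("artifacts") or {}).items()},
        test=test,
        license=str(raw.get("license", "")),
        authors=str(raw.get("authors", "")),
        extras=extras,
    )


def _schema_to_raw(schema: ArraySchema) -> dict:
    raw: dict[str, Any] = {
        "name": schema.name,
        "shape": ["*" if e is None else int(e) for e in schema.shape],
    }
    if schema.special_type:
        raw["special_type"] = schema.special_type
    if schema.column_labels:
        raw["column_labels"] = list(schema.column_labels)
    return raw


def serialize_model_description(desc: ModelDescription) -> str:
    """Render a description back to YAML; ``parse ∘ serialize`` is the
    identity on parsed descriptors."""
    raw: dict[str, Any] = {
        "name": desc.name,
        "version": desc.version,
        "doc": desc.doc,
        "tags": list(desc.tags),
        "framework_kind": desc.framework_kind,
        "inputs": [_schema_to_raw(s) for s in desc.inputs],
        "targets": _schema_to_raw(desc.targets),
        "dataloader": {
            "fasta": desc.dataloader.fasta,
            "intervals": desc.dataloader.intervals,
            "sequence_length": desc.dataloader.sequence_length,
        },
        "artifacts": dict(desc.artifacts),
        "test": {
            "example_inputs": dict(desc.test.example_inputs),
            "expected_output": desc.test.expected_output,
            "tolerance": desc.test.tolerance,
        },
        "license": desc.license,
        "authors": desc.authors,
    }
    raw.update(desc.extras)
    return yaml.safe_dump(raw, sort_keys=False)


def validate_batch_against_schema(schema: ArraySchema, batch: np.ndarray) -> list[str]:
    """Return violation messages ([] means the batch conforms).

    Checks the trailing shape against the schema's non-wildcard extents
    and, for DNASeq schemas, the one-hot contract: binary entries with
    length-4 row sums of 0 or 1.
    """
    batch = np.asarray(batch)
    violations: list[str] = []
    want = schema.shape[1:]
    got = batch.shape[1:]
    if len(got) != len(want):
        violations.append(
            f"rank mismatch: schema expects {len(want)} trailing dims, batch has {len(got)}"
        )
        return violations
    for dim, (w, g) in enumerate(zip(want, got), start=1):
        if w != g:
            violations.append(f"dimension {dim}: expected extent {w}, got {g}")
    if schema.special_type == "DNASeq" and not violations:
        if not np.isin(batch, (0.0, 1.0)).all():
            bad = batch[~np.isin(batch, (0.0, 1.0))].flat[0]
            violations.append(f"DNASeq batch contains non-binary entry {bad!r}")
        else:
            sums = batch.sum(axis=-1)
            if not np.isin(sums, (0.0, 1.0)).all():
                violations.append(
                    "DNASeq rows must sum to 0 (N) or 1 (one-hot base)"
                )
    return violations


def resolve_artifacts(desc: ModelDescription, model_dir: str | os.PathLike) -> dict[str, str]:
    """Resolve artifact and test file roles to absolute paths, checking
    existence. Test files appear under ``test.example_inputs.<key>`` and
    ``test.expected_output``."""
    model_dir = Path(model_dir)
    if not model_dir.is_dir():
        raise FileNotFoundError(f"model directory not found: {model_dir}")
    resolved: dict[str, str] = {}

    def _resolve(role: str, rel: str) -> None:
        p = (model_dir / rel).resolve()
        if not p.exists():
            raise FileNotFoundError(f"artifact {role!r} not found at {model_dir / rel}")
        resolved[role] = str(p)

    for role, rel in desc.artifacts.items():
        _resolve(role, rel)
    for key, rel in desc.test.example_inputs.items():
        _resolve(f"test.example_inputs.{key}", rel)
    if desc.test.expected_output is not None:
        _resolve("test.expected_output", desc.test.expected_output)
    return resolved
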