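"""Local directory-tree model repository.

A registry is any directory whose subdirectories contain ``model.yaml``
descriptors; a model's name is its path relative to the registry root
(e.g. ``pwm/toy_pwm``). The test harness re-runs each model's
data-loader on its bundled example inputs and compares predictions to
the stored expected output, emulating a nightly reproducibility test.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import models as _m
from .dataloading import interval_batches, one_hot_encode, read_bed
from .model_spec import (
    ModelDescription,
    parse_model_description,
    resolve_artifacts,
    validate_batch_against_schema,
)

logger = logging.getLogger(__name__)

DESCRIPTOR_FILENAME = "model.yaml"


@dataclass
class RegistryEntry:
    name: str
    description: ModelDescription
    model_dir: str


@dataclass
class TestReport:
    model_name: str
    status: str  # PASS | FAIL | ERROR
    tolerance: float
    max_abs_deviation: float | None = None
    message: str = ""


class Model:
    """A loaded model: descriptor plus the executable core, presenting
    the uniform predict contract."""

    def __init__(self, description: ModelDescription, core: _m.BuiltinModel):
        self.description = description
        self.core = core

    @property
    def name(self) -> str:
        return self.description.name

    @property
    def input_length(self) -> int:
        dl = self.description.dataloader
        if dl.sequence_length is not None:
            return dl.sequence_length
        shape = self.description.inputs[0].shape
        if len(shape) >= 2 and shape[1] is not None:
            return shape[1]
        raise ValueError(f"model {self.name}: input sequence length unknown")

    @property
    def output_labels(self) -> list[str]:
        t = self.description.targets
        if t.column_labels:
            return list(t.column_labels)
        return [f"out{i}" for i in range(t.shape[-1] or 1)]

    def predict_on_batch(self, batch: np.ndarray) -> np.ndarray:
        violations = validate_batch_against_schema(self.description.inputs[0], batch)
        if violations:
            raise ValueError(
                f"batch violates input schema of {self.name}: " + "; ".join(violations)
            )
        return _m.predict_on_batch(self.core, batch)

    def predict_on_sequences(self, seqs: list[str]) -> np.ndarray:
        batch = np.stack([one_hot_encode(s) for s in seqs])
        return self.predict_on_batch(batch)


def index_models(
    root: str | os.PathLike,
    name_filter: str | None = None,
    tag_filter: str | None = None,
    framework_filter: str | None = None,
) -> list[RegistryEntry]:
    """Find every model under ``root``; filters are conjunctive and the
    result is sorted lexicographically by name. Unparseable descriptors
    are skipped with a warning rather than aborting the listing."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"registry root not found: {root}")
    entries: list[RegistryEntry] = []
    for yml in sorted(root.rglob(DESCRIPTOR_FILENAME)):
        name = yml.parent.relative_to(root).as_posix()
        try:
            desc = parse_model_description(yml.read_text())
        except Exception as exc:
            logger.warning("skipping %s: %s", yml, exc)
            continue
        if name_filter and name_filter not in name:
            continue
        if tag_filter and tag_filter not in desc.tags:
            continue
        if framework_filter and desc.framework_kind != framework_filter:
            continue
        entries.append(RegistryEntry(name=name, description=desc, model_dir=str(yml.parent)))
    entries.sort(key=lambda e: e.name)
    return entries


def get_entry(root: str | os.PathLike, name: str) -> RegistryEntry:
    yml = Path(root) / name / DESCRIPTOR_FILENAME
    if not yml.is_file():
        available = [e.name for e in index_models(root)]
        raise FileNotFoundError(
            f"model {name!r} not found under {root}; available: {available}"
        )
    return RegistryEntry(
        name=name,
        description=parse_model_description(yml.read_text()),
        model_dir=str(yml.parent),
    )


def _read_vector(path: str) -> np.ndarray:
    return _m.read_matrix_tsv(path).ravel()


def _build_core(desc: ModelDescription, artifacts: dict[str, str]) -> _m.BuiltinModel:
    kind = desc.framework_kind
    if kind == "pwm":
        probs = _m.read_matrix_tsv(artifacts["weights"])
        return _m.PWMModel(probs=probs)
    if kind == "linear":
        weights = _read_vector(artifacts["weights"])
        bias = float(_read_vector(artifacts["bias"])[0]) if "bias" in artifacts else 0.0
        return _m.LinearModel(weights=weights, bias=bias, link="identity")
    if kind == "mlp":
        # artifact roles layer1.weight / layer1.bias ... in depth order;
        # hidden layers relu, final layer sigmoid by convention
        ids = sorted(
            {int(r.split(".")[0][5:]) for r in artifacts if r.startswith("layer")}
        )
        layers = []
        for i, lid in enumerate(ids):
            W = _m.read_matrix_tsv(artifacts[f"layer{lid}.weight"])
            b = _read_vector(artifacts[f"layer{lid}.bias"])
            nl = "sigmoid" if i == len(ids) - 1 else "relu"
            layers.append(_m.Layer(W, b, nl))
        return _m.LayeredModel(layers)
    raise ValueError(f"unknown framework kind {kind!r}")


def load_model(entry: RegistryEntry) -> tuple[Model, "DataloaderConfig"]:
    """Materialise an entry into an executable :class:`Model` plus its
    data-loader configuration."""
    artifacts = resolve_artifacts(entry.description, entry.model_dir)
    core = _build_core(entry.description, artifacts)
    return Model(entry.description, core), entry.description.dataloader


def test_model(entry: RegistryEntry, batch_size: int = 64) -> TestReport:
    """Run the model on its bundled example inputs and compare to the
    stored expected output (max absolute deviation vs tolerance). Never
    raises: failures come back as FAIL, exceptions as ERROR."""
    tol = entry.description.test.tolerance
    try:
        model, dl = load_model(entry)
        artifacts = resolve_artifacts(entry.description, entry.model_dir)
        fasta = artifacts["test.example_inputs.fasta"]
        bed = artifacts["test.example_inputs.intervals"]
        expected = _m.read_matrix_tsv(artifacts["test.expected_output"])
        intervals = read_bed(bed)
        preds = [
            model.predict_on_batch(b.array)
            for b in interval_batches(fasta, intervals, model.input_length, batch_size)
        ]
        got = np.vstack(preds)
        if got.shape != expected.shape:
            return TestReport(
                entry.name, "FAIL", tol,
                message=f"shape mismatch: predicted {got.shape}, expected {expected.shape}",
            )
        dev = float(np.max(np.abs(got - expected)))
        status = "PASS" if dev <= tol else "FAIL"
        return TestReport(entry.name, status, tol, max_abs_deviation=dev)
    except Exception as exc:
        return TestReport(entry.name, "ERROR", tol, message=f"{type(exc).__name__}: {exc}")


from .model_spec import DataloaderConfig  # noqa: E402  (re-export for signatures)
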