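"""Deterministic synthetic data and toy models.

Everything the rest of the package consumes — genomes, bound/unbound
motif datasets, SNV call sets, component score tables for ensembles,
and a ready-made registry tree of toy models — is generated here from
an explicit seed, so the full pipeline is exercisable with no external
downloads.

Randomness comes from numpy's ``default_rng`` (PCG64), seeded per
operation as ``default_rng([seed, stream])`` with a fixed stream id per
generator, so outputs are byte-identical across runs and platforms and
the individual generators are statistically independent.

The synthetic datasets emulate, at desk scale, the study conditions the
package is exercised under: bound regions carry one sampled motif
instance per window (instances vary, so classification is
non-degenerate); ensemble features are standard normal with labels
drawn from a logistic model; variants are uniform SNVs whose REF always
matches the genome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Faidx

from .dataloading import (
    BASES,
    GenomicInterval,
    fetch_sequence,
    one_hot_encode,
    read_bed,
    write_bed,
)
from .models import PWMModel, write_matrix_tsv
from .model_spec import (
    ArraySchema,
    DataloaderConfig,
    ModelDescription,
    TestConfig,
    serialize_model_description,
)

# fixed per-operation RNG stream ids
_STREAM_GENOME = 1
_STREAM_MOTIF = 2
_STREAM_IMPLANT = 3
_STREAM_VCF = 4
_STREAM_ENSEMBLE = 5
_STREAM_MODELS = 6
_STREAM_ONEHOT = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


@dataclass
class EnsembleConfig:
    """Generative model for the composite-scoring dataset: features are
    i.i.d. standard normal, labels Bernoulli(sigmoid(X·weights + bias));
    per-component cells are masked unscored at ``missing_rates``."""

    weights: tuple[float, ...] = (1.5, -1.0, 0.5, 0.0)
    bias: float = 0.0
    missing_rates: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    n: int = 5000
    conservation_weight: float = 0.0


@dataclass
class FixtureConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    gc: float = 0.5
    motif: PWMModel | None = None  # defaults to a strong 8-mer
    n_pos: int = 200
    n_neg: int = 200
    window_len: int = 100
    n_variants: int = 50
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        for name, length in self.chrom_lengths.items():
            if length < self.window_len:
                raise ValueError(f"chromosome {name} shorter than window_len")
        for r in self.ensemble.missing_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing rates must be in [0, 1]")
        if self.motif is None:
            self.motif = make_strong_motif(self.seed)


def make_strong_motif(seed: int = 0, length: int = 8, max_prob: float = 0.97) -> PWMModel:
    """A near-consensus PWM: one dominant base per position at
    probability ``max_prob``, the rest sharing the remainder."""
    rng = _rng(seed, _STREAM_MOTIF)
    consensus = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), (1.0 - max_prob) / 3.0)
    probs[np.arange(length), consensus] = max_prob
    return PWMModel(probs=probs)


def uniform_motif(length: int = 8) -> PWMModel:
    """Null control: every base equally likely at every position, so
    log-odds against a uniform background are identically zero."""
    return PWMModel(probs=np.full((length, 4), 0.25))


# ---------------------------------------------------------------------------
# genome


def _base_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A C G T


def _write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    fai = Path(str(path) + ".fai")
    if fai.exists():
        fai.unlink()
    Faidx(str(path)).close()


def _read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def make_genome(cfg: FixtureConfig, out_path: str | os.PathLike) -> str:
    """Write an i.i.d. random genome (P(G)=P(C)=gc/2) plus its .fai."""
    rng = _rng(cfg.seed, _STREAM_GENOME)
    p = _base_probs(cfg.gc)
    seqs = {}
    for name, length in cfg.chrom_lengths.items():
        if length < 1:
            raise ValueError(f"zero-length chromosome {name!r}")
        idx = rng.choice(4, size=length, p=p)
        seqs[name] = "".join(BASES[i] for i in idx)
    _write_fasta(seqs, out_path)
    return str(out_path)


# ---------------------------------------------------------------------------
# motif-implant benchmark dataset


def sample_motif_instance(motif: PWMModel, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=row) for row in motif.probs]
    return "".join(BASES[i] for i in idx)


def implant_motif_dataset(
    cfg: FixtureConfig,
    genome_path: str | os.PathLike,
    bed_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> tuple[str, str]:
    """Carve disjoint windows out of the genome, implant one sampled
    motif instance (uniform-random offset) into each positive window,
    rewrite the genome in place, and emit BED + binary labels TSV."""
    rng = _rng(cfg.seed, _STREAM_IMPLANT)
    motif = cfg.motif
    W = cfg.window_len
    n_total = cfg.n_pos + cfg.n_neg
    seqs = _read_fasta(genome_path)
    slots: list[tuple[str, int]] = []
    for name, seq in seqs.items():
        slots.extend((name, s) for s in range(0, len(seq) - W + 1, W))
    if len(slots) < n_total:
        raise ValueError(
            f"genome provides {len(slots)} disjoint windows, need {n_total}"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    labels = np.zeros(n_total, dtype=int)
    labels[:cfg.n_pos] = 1
    rng.shuffle(labels)
    m = motif.motif_len
    intervals: list[GenomicInterval] = []
    mutable = {k: list(v) for k, v in seqs.items()}
    for i, slot_idx in enumerate(chosen):
        chrom, start = slots[slot_idx]
        if labels[i] == 1:
            offset = int(rng.integers(0, W - m + 1))
            instance = sample_motif_instance(motif, rng)
            mutable[chrom][start + offset:start + offset + m] = list(instance)
        intervals.append(GenomicInterval(chrom, start, start + W, "+", f"w{i:04d}"))
    _write_fasta({k: "".join(v) for k, v in mutable.items()}, genome_path)
    idx_sorted = sorted(range(n_total), key=lambda i: (intervals[i].chrom, intervals[i].start))
    write_bed([intervals[i] for i in idx_sorted], bed_path)
    with open(labels_path, "w") as fh:
        fh.write("name\tlabel\n")
        for i in idx_sorted:
            fh.write(f"{intervals[i].name}\t{labels[i]}\n")
    return str(bed_path), str(labels_path)


def make_labeled_onehot_dataset(
    motif: PWMModel,
    n_pos: int,
    n_neg: int,
    window_len: int,
    gc: float = 0.5,
    seed: int = 0,
    offset_jitter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory analogue of the implant dataset: one-hot windows with a
    motif instance implanted in the positives. Returns (X (n, L, 4), y)
    in shuffled order.

    By default the implant offset is uniform over the window; with
    ``offset_jitter`` the motif sits within +/- jitter positions of the
    window center, a positionally constrained variant that dense
    (non-convolutional) nets can learn."""
    rng = _rng(seed, _STREAM_ONEHOT)
    p = _base_probs(gc)
    n = n_pos + n_neg
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    m = motif.motif_len
    center = (window_len - m) // 2
    X = np.zeros((n, window_len, 4))
    for i in range(n):
        idx = rng.choice(4, size=window_len, p=p)
        if y[i] == 1:
            if offset_jitter is None:
                offset = int(rng.integers(0, window_len - m + 1))
            else:
                offset = center + int(rng.integers(-offset_jitter, offset_jitter + 1))
            inst = [rng.choice(4, p=row) for row in motif.probs]
            idx[offset:offset + m] = inst
        X[i, np.arange(window_len), idx] = 1.0
    return X, y


def perturb_motif(motif: PWMModel, n_positions: int, seed: int = 0) -> PWMModel:
    """A related motif: rotate the base probabilities at ``n_positions``
    randomly chosen motif positions. Used to define a transfer-learning
    task pair (same motif family, locally altered preference)."""
    rng = np.random.default_rng(seed)
    probs = motif.probs.copy()
    pos = rng.choice(len(probs), size=n_positions, replace=False)
    for p in pos:
        probs[p] = np.roll(probs[p], 1)
    return PWMModel(probs=probs)


def transfer_learning_benchmark(
    n_seeds: int = 5,
    base_seed: int = 0,
    window_len: int = 50,
    hidden: int = 32,
    pretrain_n: int = 1500,
    pretrain_epochs: int = 800,
    task_b_n: int = 250,
    scratch_epochs: int = 15,
    lr: float = 1.0,
) -> tuple[list[float], list[float]]:
    """Toy two-task transfer experiment.

    Per seed: pretrain a dense net on classifying windows containing
    motif A (center +/- 2 implants); define a related task B whose motif
    differs at one position; then compare, on held-out task-B data,
    (a) a logistic head fitted on the pretrained net's penultimate
    activations of n=2*task_b_n labeled task-B windows against (b) an
    identically shaped net trained from random initialization on the
    same labeled set under a small epoch budget. Returns the per-seed
    held-out auROC lists (transfer, scratch).
    """
    from .ensemble import auroc
    from .models import (
        fit_head_on_activations,
        layer_activations,
        predict_on_batch,
        train_layered_model,
    )

    transfer_scores: list[float] = []
    scratch_scores: list[float] = []
    for s in range(n_seeds):
        seed = base_seed + s
        motif_a = make_strong_motif(seed + 100)
        motif_b = perturb_motif(motif_a, 1, seed + 200)
        Xa, ya = make_labeled_onehot_dataset(
            motif_a, pretrain_n, pretrain_n, window_len, seed=seed * 10 + 1,
            offset_jitter=2,
        )
        pretrained = train_layered_model(
            Xa, ya, hidden_sizes=(hidden,), lr=lr, epochs=pretrain_epochs, seed=seed
        )
        Xb, yb = make_labeled_onehot_dataset(
            motif_b, task_b_n, task_b_n, window_len, seed=seed * 10 + 3,
            offset_jitter=2,
        )
        Xbt, ybt = make_labeled_onehot_dataset(
            motif_b, 500, 500, window_len, seed=seed * 10 + 4, offset_jitter=2
        )
        head = fit_head_on_activations(layer_activations(pretrained, 1, Xb), yb)
        transfer_scores.append(
            auroc(head.predict(layer_activations(pretrained, 1, Xbt)), ybt)
        )
        scratch = train_layered_model(
            Xb, yb, hidden_sizes=(hidden,), lr=lr, epochs=scratch_epochs, seed=seed + 1
        )
        scratch_scores.append(auroc(predict_on_batch(scratch, Xbt).ravel(), ybt))
    return transfer_scores, scratch_scores


# ---------------------------------------------------------------------------
# variants


def make_snv_vcf(
    cfg: FixtureConfig,
    genome_path: str | os.PathLike,
    out_path: str | os.PathLike,
    bed: str | os.PathLike | None = None,
    frac_outside: float = 0.0,
) -> str:
    """Write a sorted VCF v4.2 of random SNVs whose REF matches the
    genome. With ``bed``, positions are drawn inside the regions except
    for a ``frac_outside`` fraction forced outside them (for exercising
    anchored-mode unscored accounting)."""
    rng = _rng(cfg.seed, _STREAM_VCF)
    seqs = _read_fasta(genome_path)
    chroms = list(seqs)
    regions = read_bed(bed) if bed is not None else None

    def in_regions(chrom: str, pos0: int) -> bool:
        return any(
            r.chrom == chrom and r.start <= pos0 < r.end for r in regions
        )

    n = cfg.n_variants
    n_outside = int(round(n * frac_outside)) if regions is not None else 0
    n_inside = n - n_outside
    picked: set[tuple[str, int]] = set()
    variants: list[tuple[str, int, str, str]] = []

    def draw(pos_filter) -> None:
        for _ in range(200000):
            if regions is not None and pos_filter == "inside":
                r = regions[int(rng.integers(0, len(regions)))]
                chrom = r.chrom
                pos0 = int(rng.integers(r.start, r.end))
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                pos0 = int(rng.integers(0, len(seqs[chrom])))
                if pos_filter == "outside" and in_regions(chrom, pos0):
                    continue
            ref = seqs[chrom][pos0]
            if ref not in "ACGT" or (chrom, pos0) in picked:
                continue
            alts = [b for b in BASES if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            picked.add((chrom, pos0))
            variants.append((chrom, pos0 + 1, ref, alt))
            return
        raise RuntimeError("could not place variant; genome too constrained")

    for _ in range(n_inside):
        draw("inside" if regions is not None else "any")
    for _ in range(n_outside):
        draw("outside")
    variants.sort(key=lambda t: (t[0], t[1]))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in seqs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, (chrom, pos, ref, alt) in enumerate(variants, start=1):
            fh.write(f"{chrom}\t{pos}\tsnv{i:04d}\t{ref}\t{alt}\t.\t.\t.\n")
    return str(out_path)


# ---------------------------------------------------------------------------
# ensemble dataset


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_ensemble_arrays(
    cfg: FixtureConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X, missing_mask, conservation, labels) for the
    composite-model experiments."""
    ens = cfg.ensemble
    rng = _rng(cfg.seed, _STREAM_ENSEMBLE)
    K = len(ens.weights)
    X = rng.standard_normal((ens.n, K))
    conservation = rng.standard_normal(ens.n)
    logits = X @ np.asarray(ens.weights) + ens.conservation_weight * conservation + ens.bias
    labels = (rng.random(ens.n) < _sigmoid(logits)).astype(int)
    mask = np.zeros((ens.n, K), dtype=bool)
    for j, rate in enumerate(ens.missing_rates[:K]):
        if rate > 0:
            mask[:, j] = rng.random(ens.n) < rate
    return X, mask, conservation, labels


def make_ensemble_dataset(cfg: FixtureConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the ensemble arrays as per-component score tables plus
    conservation and label TSVs, keyed by synthetic variant identity."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, mask, conservation, labels = make_ensemble_arrays(cfg)
    n, K = X.shape
    keys = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n + 1),
        "ref": "A",
        "alt": "C",
    })
    paths: dict[str, str] = {}
    for j in range(K):
        df = keys.copy()
        df["score"] = np.where(mask[:, j], np.nan, X[:, j])
        df["scored"] = (~mask[:, j]).astype(int)
        p = outdir / f"component{j + 1}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"component{j + 1}"] = str(p)
    dfc = keys.copy()
    dfc["value"] = conservation
    dfc.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    paths["conservation"] = str(outdir / "conservation.tsv")
    dfl = keys.copy()
    dfl["label"] = labels
    dfl.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    paths["labels"] = str(outdir / "labels.tsv")
    return paths


# ---------------------------------------------------------------------------
# toy model registry tree


def _example_inputs(model_dir: Path, cfg: FixtureConfig, rng: np.random.Generator,
                    n_intervals: int = 8) -> tuple[Path, Path]:
    ex = model_dir / "example"
    ex.mkdir(parents=True, exist_ok=True)
    length = max(cfg.window_len * (n_intervals + 2), 1000)
    p = _base_probs(cfg.gc)
    idx = rng.choice(4, size=length, p=p)
    _write_fasta({"chr1": "".join(BASES[i] for i in idx)}, ex / "genome.fa")
    intervals = [
        GenomicInterval("chr1", i * cfg.window_len, (i + 1) * cfg.window_len, "+", f"ex{i}")
        for i in range(n_intervals)
    ]
    write_bed(intervals, ex / "intervals.bed")
    return ex / "genome.fa", ex / "intervals.bed"


def _base_description(name: str, kind: str, cfg: FixtureConfig,
                      artifacts: dict[str, str], tags: list[str]) -> ModelDescription:
    W = cfg.window_len
    return ModelDescription(
        name=name,
        framework_kind=kind,
        version="1",
        doc=f"toy {kind} fixture model",
        tags=tags,
        inputs=[ArraySchema("seq", (None, W, 4), special_type="DNASeq")],
        targets=ArraySchema("score", (None, 1), column_labels=["score"]),
        dataloader=DataloaderConfig(
            fasta="example/genome.fa",
            intervals="example/intervals.bed",
            sequence_length=W,
        ),
        artifacts=artifacts,
        test=TestConfig(
            example_inputs={
                "fasta": "example/genome.fa",
                "intervals": "example/intervals.bed",
            },
            expected_output="example/expected.tsv",
            tolerance=1e-5,
        ),
        license="MIT",
        authors="fixture generator",
    )


def make_toy_model_dirs(root: str | os.PathLike, cfg: FixtureConfig,
                        overwrite: bool = False) -> list[str]:
    """Build a registry tree with one model per framework kind (pwm,
    linear, mlp), each with example inputs and an expected output
    computed at generation time, so the test harness passes on every
    model out of the box."""
    from .registry import get_entry, load_model
    from .dataloading import interval_batches

    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} exists and is not empty (pass overwrite=True)")
    rng = _rng(cfg.seed, _STREAM_MODELS)
    W = cfg.window_len
    specs: list[tuple[str, str, dict[str, np.ndarray], dict[str, str], list[str]]] = []

    # pwm model
    specs.append((
        "pwm/toy_pwm", "pwm",
        {"weights": cfg.motif.probs},
        {"weights": "pwm.tsv"},
        ["binding", "motif"],
    ))
    # linear model on flattened one-hot
    lin_w = rng.normal(0.0, 0.1, size=(4 * W, 1))
    specs.append((
        "linear/toy_linear", "linear",
        {"weights": lin_w, "bias": np.array([[0.05]])},
        {"weights": "weights.tsv", "bias": "bias.tsv"},
        ["toy"],
    ))
    # mlp 4W -> 8 -> 1
    w1 = rng.normal(0.0, np.sqrt(2.0 / (4 * W)), size=(4 * W, 8))
    b1 = rng.normal(0.0, 0.01, size=(1, 8))
    w2 = rng.normal(0.0, 0.5, size=(8, 1))
    b2 = np.array([[0.0]])
    specs.append((
        "mlp/toy_mlp", "mlp",
        {"layer1.weight": w1, "layer1.bias": b1, "layer2.weight": w2, "layer2.bias": b2},
        {
            "layer1.weight": "layer1_weight.tsv", "layer1.bias": "layer1_bias.tsv",
            "layer2.weight": "layer2_weight.tsv", "layer2.bias": "layer2_bias.tsv",
        },
        ["toy", "activations"],
    ))

    names: list[str] = []
    for name, kind, matrices, artifact_paths, tags in specs:
        model_dir = root / name
        model_dir.mkdir(parents=True, exist_ok=True)
        for role, rel in artifact_paths.items():
            header = list(BASES) if kind == "pwm" else None
            write_matrix_tsv(matrices[role], model_dir / rel, header=header)
        _example_inputs(model_dir, cfg, rng)
        desc = _base_description(name, kind, cfg, artifact_paths, tags)
        (model_dir / "model.yaml").write_text(serialize_model_description(desc))
        # placeholder so the loader's artifact check passes before the
        # real expected output is computed below
        write_matrix_tsv(np.zeros((1, 1)), model_dir / "example" / "expected.tsv")
        # compute the expected output with the freshly written model
        entry = get_entry(root, name)
        model, _ = load_model(entry)
        ivs = read_bed(model_dir / "example" / "intervals.bed")
        preds = np.vstack([
            model.predict_on_batch(b.array)
            for b in interval_batches(model_dir / "example" / "genome.fa", ivs, W, 64)
        ])
        write_matrix_tsv(preds, model_dir / "example" / "expected.tsv", header=["score"])
        names.append(name)
    return names
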