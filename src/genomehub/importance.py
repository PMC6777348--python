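"""In-silico-mutagenesis feature importance: mutation maps.

A mutation map holds the effect score of every possible single-
nucleotide substitution across an interval — a 4 x L matrix (rows
A,C,G,T) in which the entry for the reference base at each position is
a structural zero. Summarising columns by the largest absolute effect
gives a per-position importance track.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .dataloading import BASES, GenomicInterval, fetch_sequence, open_fasta
from .variant_effects import effect_scores


@dataclass
class MutationMap:
    interval: GenomicInterval
    ref_seq: str
    effects: np.ndarray  # (4, L), rows A,C,G,T
    model_name: str
    output_label: str
    scoring_name: str
    n_positions: list[int] = field(default_factory=list)  # columns where ref is N

    def __post_init__(self) -> None:
        L = len(self.ref_seq)
        if self.effects.shape != (4, L):
            raise ValueError(f"effects must be (4, {L})")


def mutation_map(
    model,
    fasta,
    iv: GenomicInterval,
    scoring: str = "DIFF",
    output_label: str | None = None,
    batch_size: int = 128,
) -> MutationMap:
    """Score all 3L single-base substitutions of ``iv`` against a model.

    The interval is midpoint-resized to the model's input length when
    needed. Reference-base cells are exactly 0 by construction; columns
    whose reference base is N are all-zero and flagged in
    ``n_positions``. Evaluation is batched (results are independent of
    ``batch_size``).
    """
    fa = open_fasta(fasta)
    L = model.input_length
    if len(iv) != L:
        iv = iv.resized(L)
    ref_seq = fetch_sequence(fa, GenomicInterval(iv.chrom, iv.start, iv.end, "+"))
    labels = model.output_labels
    if output_label is None:
        output_label = labels[0]
    t = labels.index(output_label)

    p_ref = float(model.predict_on_sequences([ref_seq])[0, t])

    cells: list[tuple[int, int]] = []  # (base_row, position)
    alt_seqs: list[str] = []
    n_positions: list[int] = []
    for i, ref_base in enumerate(ref_seq):
        if ref_base == "N":
            n_positions.append(i)
            continue
        for b, base in enumerate(BASES):
            if base == ref_base:
                continue
            cells.append((b, i))
            alt_seqs.append(ref_seq[:i] + base + ref_seq[i + 1:])

    effects = np.zeros((4, L), dtype=np.float64)
    for start in range(0, len(alt_seqs), batch_size):
        chunk = alt_seqs[start:start + batch_size]
        preds = model.predict_on_sequences(chunk)[:, t]
        for (b, i), p_alt in zip(cells[start:start + batch_size], preds):
            effects[b, i] = effect_scores(p_ref, float(p_alt), (scoring,))[scoring]

    return MutationMap(
        interval=iv,
        ref_seq=ref_seq,
        effects=effects,
        model_name=model.name,
        output_label=output_label,
        scoring_name=scoring,
        n_positions=n_positions,
    )


def ism_position_importance(mm: MutationMap) -> np.ndarray:
    """Per-position importance: max over bases of |effect|."""
    return np.abs(mm.effects).max(axis=0)


def write_mutation_map_tsv(mm: MutationMap, path: str | os.PathLike) -> None:
    """Emit the map as TSV: position (0-based genomic), ref base, and
    one effect column per substituted base."""
    with open(path, "w") as fh:
        fh.write("position\tref\t" + "\t".join(BASES) + "\n")
        for i in range(len(mm.ref_seq)):
            vals = "\t".join(f"{mm.effects[b, i]:.6g}" for b in range(4))
            fh.write(f"{mm.interval.start + i}\t{mm.ref_seq[i]}\t{vals}\n")
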