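"""Variant effect prediction by in silico mutagenesis.

The core contrast: predict on the genomic window carrying the reference
allele and on the identical window carrying the alternative allele, and
score the difference. Two window-selection modes mirror the two model
families in the field — ``centered`` for models valid anywhere in the
genome (the window is centered on the variant) and ``anchored`` for
models valid only on predefined regions (e.g. exon-boundary windows),
where a variant is scored once per overlapping region and left unscored
when no region overlaps it.

Scores are written back into an annotated copy of the input VCF, one
INFO key per (model, output, scoring function).
"""

from __future__ import annotations

import gzip
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np

from .dataloading import GenomicInterval, fetch_sequence, open_fasta

logger = logging.getLogger(__name__)

SCORING_FUNCTIONS = ("DIFF", "LOGIT")
CLIP_EPS = 1e-7


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class EffectScoreRecord:
    variant: Variant
    model_name: str
    output_label: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    scored: bool = True
    region: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.scored and self.scores:
            raise ValueError("unscored records must carry no scores")


class RefMismatchError(ValueError):
    def __init__(self, variant: Variant, observed: str):
        self.variant = variant
        self.observed = observed
        super().__init__(
            f"variant {variant.id} at {variant.chrom}:{variant.pos}: "
            f"expected REF {variant.ref!r} but genome has {observed!r}"
        )


# ---------------------------------------------------------------------------
# VCF ingestion


def _open_text(path: str | os.PathLike):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_vcf_snvs(path: str | os.PathLike) -> tuple[list[Variant], int]:
    """Read single-nucleotide variants from a (possibly bgzipped) VCF.

    Multiallelic records are expanded to one variant per ALT allele;
    non-SNV alleles are counted in ``skipped_count`` and logged.
    """
    import pysam

    variants: list[Variant] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: malformed VCF header: {exc}") from exc
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
                    variants.append(
                        Variant(rec.chrom, rec.pos, ref, alt, rec.id or ".")
                    )
                else:
                    skipped += 1
                    logger.info(
                        "skipping non-SNV allele %s>%s at %s:%d",
                        ref, alt, rec.chrom, rec.pos,
                    )
    except Exception as exc:
        raise ValueError(f"{path}: malformed record near body line {lineno + 1}: {exc}") from exc
    finally:
        vcf.close()
    return variants, skipped


# ---------------------------------------------------------------------------
# window selection and allele injection


def center_on_variant(v: Variant, L: int) -> GenomicInterval:
    """Window of length L with the variant at 0-based offset L//2;
    negative starts are allowed (the fetch pads with N)."""
    if L < 1:
        raise ValueError("window length must be >= 1")
    start = (v.pos - 1) - L // 2
    return GenomicInterval(v.chrom, start, start + L, "+")


def match_anchored_regions(
    regions: list[GenomicInterval], variants: list[Variant]
) -> tuple[list[tuple[Variant, GenomicInterval]], list[Variant]]:
    """Pair each variant with every region containing it (chrom equal
    and pos-1 in [start, end)); variants with no match come back in the
    unscored list."""
    pairs: list[tuple[Variant, GenomicInterval]] = []
    unscored: list[Variant] = []
    for v in variants:
        hits = [
            r for r in regions
            if r.chrom == v.chrom and r.start <= (v.pos - 1) < r.end
        ]
        if hits:
            pairs.extend((v, r) for r in hits)
        else:
            unscored.append(v)
    return pairs, unscored


def inject_allele(seq: str, iv: GenomicInterval, v: Variant) -> tuple[str, str]:
    """Return (ref_seq, alt_seq) for the window; the genome base at the
    variant offset must equal v.ref, else :class:`RefMismatchError`."""
    if iv.strand != "+":
        raise ValueError("allele injection requires a '+' strand window")
    offset = (v.pos - 1) - iv.start
    if not 0 <= offset < len(seq):
        raise ValueError(f"variant position {v.pos} outside window {iv}")
    observed = seq[offset]
    if observed != v.ref:
        raise RefMismatchError(v, observed)
    alt_seq = seq[:offset] + v.alt + seq[offset + 1:]
    return seq, alt_seq


# ---------------------------------------------------------------------------
# scoring


def effect_scores(p_ref: float, p_alt: float, scorings) -> dict[str, float]:
    """Apply the named scoring functions to a (ref, alt) prediction pair.

    DIFF is the raw contrast p_alt - p_ref; LOGIT contrasts on the
    log-odds scale with predictions clipped to [eps, 1-eps], suited to
    probability outputs.
    """
    out: dict[str, float] = {}
    for s in scorings:
        if s == "DIFF":
            out[s] = float(p_alt - p_ref)
        elif s == "LOGIT":
            a = min(max(p_alt, CLIP_EPS), 1.0 - CLIP_EPS)
            r = min(max(p_ref, CLIP_EPS), 1.0 - CLIP_EPS)
            out[s] = float(np.log(a / (1.0 - a)) - np.log(r / (1.0 - r)))
        else:
            raise ValueError(f"unknown scoring {s!r}; known: {SCORING_FUNCTIONS}")
    return out


def score_variants(
    model,
    fasta,
    variants: list[Variant],
    mode: str = "centered",
    regions: list[GenomicInterval] | None = None,
    scorings=("DIFF",),
) -> list[EffectScoreRecord]:
    """Score SNVs against a loaded model.

    ``centered`` mode extracts a window of the model's input length
    centered on each variant; ``anchored`` mode scores each variant once
    per overlapping region (regions are midpoint-resized to the model's
    input length when they differ). REF-mismatching and unmatched
    variants are returned with ``scored=False`` rather than aborting.
    """
    if mode not in ("centered", "anchored"):
        raise ValueError("mode must be 'centered' or 'anchored'")
    if mode == "anchored" and regions is None:
        raise ValueError("anchored mode requires regions")
    fa = open_fasta(fasta)
    L = model.input_length
    labels = model.output_labels

    tasks: list[tuple[Variant, GenomicInterval | None]] = []
    if mode == "centered":
        tasks = [(v, center_on_variant(v, L)) for v in variants]
        unmatched: list[Variant] = []
    else:
        pairs, unmatched = match_anchored_regions(regions, variants)
        for v, region in pairs:
            iv = region.resized(L) if len(region) != L else region
            tasks.append((v, iv))

    records: list[EffectScoreRecord] = []
    seqs: list[str] = []
    pending: list[tuple[Variant, GenomicInterval]] = []
    for v, iv in tasks:
        if not (iv.start <= (v.pos - 1) < iv.end):
            logger.warning("variant %s no longer inside resized window %s", v, iv)
            records.append(
                EffectScoreRecord(v, model.name, scored=False)
            )
            continue
        seq = fetch_sequence(fa, GenomicInterval(iv.chrom, iv.start, iv.end, "+"))
        try:
            ref_seq, alt_seq = inject_allele(seq, iv, v)
        except RefMismatchError as exc:
            logger.warning("%s; variant left unscored", exc)
            records.append(EffectScoreRecord(v, model.name, scored=False))
            continue
        seqs.extend([ref_seq, alt_seq])
        pending.append((v, iv))

    if seqs:
        preds = model.predict_on_sequences(seqs)  # (2*m, T)
        for i, (v, iv) in enumerate(pending):
            p_ref, p_alt = preds[2 * i], preds[2 * i + 1]
            for t, label in enumerate(labels):
                records.append(
                    EffectScoreRecord(
                        v, model.name, label,
                        scores=effect_scores(float(p_ref[t]), float(p_alt[t]), scorings),
                        scored=True,
                        region=iv,
                    )
                )
    for v in unmatched if mode == "anchored" else []:
        records.append(EffectScoreRecord(v, model.name, scored=False))
    return records


# ---------------------------------------------------------------------------
# annotated VCF output


def _sanitize(token: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", token)


def info_key(model_name: str, output_label: str, scoring: str) -> str:
    return f"KV_{_sanitize(model_name)}_{_sanitize(output_label)}_{_sanitize(scoring)}"


def write_annotated_vcf(
    in_path: str | os.PathLike,
    records: list[EffectScoreRecord],
    out_path: str | os.PathLike,
) -> None:
    """Write an annotated copy of ``in_path``: same records in the same
    order, with one INFO key per (model, output, scoring) declared in the
    header (Number=A, Type=Float, values %.6g). Variants the records
    leave unscored carry '.' for each key; multi-region duplicates are
    collapsed to the score of largest magnitude (sign kept). Every other
    field is passed through byte-identically.
    """
    # aggregate: key -> variant key -> best-|.| score
    values: dict[str, dict[tuple, float]] = {}
    keys_order: list[str] = []
    known_variants: set[tuple] = set()
    for rec in records:
        known_variants.add(rec.variant.key)
        if not rec.scored:
            continue
        for scoring, val in rec.scores.items():
            k = info_key(rec.model_name, rec.output_label or "out0", scoring)
            if k not in values:
                values[k] = {}
                keys_order.append(k)
            cur = values[k].get(rec.variant.key)
            if cur is None or abs(val) > abs(cur):
                values[k][rec.variant.key] = val
    if not keys_order:
        raise ValueError("no scored records to annotate with")

    def annotate_line(line: str) -> str:
        fields = line.rstrip("\n").split("\t")
        chrom, pos, ref, alts = fields[0], int(fields[1]), fields[3].upper(), fields[4]
        alt_list = alts.split(",")
        all_keys = {(chrom, pos, ref, a.upper()) for a in alt_list}
        if not (all_keys & known_variants) and not all(
            len(ref) == 1 and len(a) == 1 for a in alt_list
        ):
            pass  # non-SNV record: keys simply resolve to '.'
        entries = []
        for k in keys_order:
            per_alt = []
            for a in alt_list:
                v = values[k].get((chrom, pos, ref, a.upper()))
                per_alt.append("." if v is None else f"{v:.6g}")
            entries.append(f"{k}={','.join(per_alt)}")
        info = fields[7] if len(fields) > 7 else "."
        new_info = ";".join(entries) if info in (".", "") else info + ";" + ";".join(entries)
        fields[7] = new_info
        return "\t".join(fields) + "\n"

    n_body = 0
    with _open_text(in_path) as src, open(out_path, "w") as dst:
        for line in src:
            if line.startswith("##"):
                dst.write(line)
            elif line.startswith("#CHROM"):
                for k in keys_order:
                    dst.write(
                        f'##INFO=<ID={k},Number=A,Type=Float,'
                        f'Description="Variant effect score {k}">\n'
                    )
                dst.write(line)
            elif line.strip():
                dst.write(annotate_line(line))
                n_body += 1

    # conservation check: every record's variant must come from the input
    file_variants, _ = read_vcf_snvs(out_path)
    file_keys = {v.key for v in file_variants}
    missing = known_variants - file_keys
    if missing:
        raise ValueError(
            f"records reference variants absent from {in_path}: {sorted(missing)[:3]}"
        )
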