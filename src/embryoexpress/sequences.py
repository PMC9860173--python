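"""Synthetic sequence libraries: random oligo pools and PCR-mutagenesis variants.

Two library designs are emulated:

* **random-sequence libraries** — pools of fixed-length random DNA (~180 bp in
  the original design) optionally carrying a known transcription-factor motif,
  by default placed at the centre of each sequence;
* **error-prone-PCR mutant libraries** — variants of a reference enhancer in
  which every base substitutes independently with a small per-base probability
  (~0.5 %/base, matching the 1–5 substitutions observed on 290–484 bp
  enhancers). Indels are not simulated.

Every generated record carries ground-truth metadata (motif offset, mutation
list) so downstream analyses can be validated exactly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InvalidDesignError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise InputError(f"empty {what}")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise InputError(f"{what} contains non-ACGT letters: {sorted(bad)}")
    return seq


@dataclass
class SequenceSet:
    """A named collection of DNA sequences with per-record ground truth.

    ``metadata[record_id]`` holds, when present, the embedded motif string and
    its 0-based offset within the record.
    """

    records: list[tuple[str, str]]
    metadata: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("sequence ids must be unique")
        for rid, seq in self.records:
            _check_dna(seq, f"sequence {rid!r}")
            meta = self.metadata.get(rid)
            if meta and meta.get("motif") is not None:
                motif, off = meta["motif"], meta["offset"]
                if seq[off:off + len(motif)] != motif:
                    raise InputError(
                        f"declared motif not found at offset {off} in {rid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> dict[str, int]:
        return {rid: len(seq) for rid, seq in self.records}

    def to_fasta(self, path: str | Path) -> Path:
        """Write records as FASTA, wrapped at 60 columns."""
        path = Path(path)
        with open(path, "w") as fh:
            for rid, seq in self.records:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        return path

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq).upper())
                   for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise InputError(f"no FASTA records in {path}")
        return cls(records=records)


@dataclass
class VariantRecord:
    """One mutant line: the full variant sequence plus its substitution list.

    ``mutations`` is a list of ``(position, ref_base, alt_base)`` with 0-based
    positions in strictly increasing order.
    """

    line_id: str
    sequence: str
    mutations: list[tuple[int, str, str]]

    def validate_against(self, reference: str) -> None:
        if apply_mutations(reference, self.mutations) != self.sequence:
            raise InputError(
                f"mutations of {self.line_id!r} do not reproduce its sequence")


@dataclass
class LibrarySummary:
    """Aggregate mutation statistics over a variant library."""

    n_lines: int
    total_mutations: int
    mean_mutations_per_line: float
    histogram: dict[int, int]


def apply_mutations(reference: str,
                    mutations: list[tuple[int, str, str]]) -> str:
    """Apply substitution mutations to a reference sequence."""
    seq = list(reference)
    last = -1
    for pos, ref, alt in mutations:
        if pos <= last:
            raise InputError("mutation positions must be strictly increasing")
        last = pos
        if seq[pos] != ref:
            raise InputError(
                f"ref base mismatch at {pos}: expected {seq[pos]}, got {ref}")
        if alt == ref:
            raise InputError(f"alt equals ref at position {pos}")
        seq[pos] = alt
    return "".join(seq)


def generate_random_sequences(n: int,
                              length: int,
                              embedded_motif: str | None = None,
                              offset_policy: str | int = "center",
                              seed: int = 0,
                              name_prefix: str = "rand") -> SequenceSet:
    """Generate ``n`` unique random DNA sequences of exact ``length``.

    Parameters
    ----------
    embedded_motif
        Optional motif to plant verbatim in every sequence.
    offset_policy
        ``"center"`` places the motif at ``(length - m) // 2``; an integer
        fixes the offset; ``"uniform"`` draws an offset uniformly per record.
    seed
        Seeds a private generator; identical arguments give identical output.

    Uniqueness is enforced by rejection-resampling on collision.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if length < 1:
        raise InputError("length must be >= 1")
    motif = None
    if embedded_motif is not None:
        motif = _check_dna(embedded_motif, "motif")
        if len(motif) > length:
            raise InvalidDesignError(
                f"motif ({len(motif)} bp) longer than sequence ({length} bp)")

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    metadata: dict[str, dict] = {}
    seen: set[str] = set()
    attempts = 0
    max_attempts = 1000 * n + 1000
    while len(records) < n:
        attempts += 1
        if attempts > max_attempts:
            raise InvalidDesignError(
                "could not generate enough unique sequences; "
                "design space too small")
        seq = "".join(rng.choice(list(ALPHABET), size=length))
        offset = None
        if motif is not None:
            if offset_policy == "center":
                offset = (length - len(motif)) // 2
            elif offset_policy == "uniform":
                offset = int(rng.integers(0, length - len(motif) + 1))
            elif isinstance(offset_policy, int):
                offset = offset_policy
                if not 0 <= offset <= length - len(motif):
                    raise InvalidDesignError(
                        f"fixed offset {offset} leaves motif outside sequence")
            else:
                raise InputError(f"unknown offset policy: {offset_policy!r}")
            seq = seq[:offset] + motif + seq[offset + len(motif):]
        if seq in seen:
            continue
        seen.add(seq)
        rid = f"{name_prefix}_{len(records) + 1:03d}"
        records.append((rid, seq))
        metadata[rid] = {"motif": motif, "offset": offset, "seed": seed}
    return SequenceSet(records=records, metadata=metadata, seed=seed)


def simulate_mutant_library(reference: str,
                            per_base_rate: float,
                            n_lines: int,
                            seed: int = 0,
                            name_prefix: str = "line") -> list[VariantRecord]:
    """Simulate an error-prone-PCR variant library.

    Each position of ``reference`` mutates independently with probability
    ``per_base_rate``; a mutated base substitutes to one of the three other
    bases uniformly. The per-line mutation count is therefore
    Binomial(len(reference), rate).
    """
    reference = _check_dna(reference, "reference")
    if not 0.0 <= per_base_rate <= 1.0:
        raise InputError("per_base_rate must be within [0, 1]")
    if n_lines < 1:
        raise InputError("n_lines must be >= 1")

    rng = np.random.default_rng(seed)
    L = len(reference)
    ref_idx = np.fromiter((_BASE_INDEX[b] for b in reference), dtype=np.int64,
                          count=L)
    variants: list[VariantRecord] = []
    for i in range(n_lines):
        hits = np.nonzero(rng.random(L) < per_base_rate)[0]
        # draw among the 3 non-reference bases: offset 1..3 around ref index
        shifts = rng.integers(1, 4, size=hits.size)
        alt_idx = (ref_idx[hits] + shifts) % 4
        muts = [(int(p), reference[p], ALPHABET[a])
                for p, a in zip(hits, alt_idx)]
        seq = apply_mutations(reference, muts)
        variants.append(
            VariantRecord(line_id=f"{name_prefix}_{i + 1:04d}",
                          sequence=seq, mutations=muts))
    return variants


def summarize_library(variants: list[VariantRecord]) -> LibrarySummary:
    """Summarise mutation counts across a variant library.

    The mean is reported as total mutations / number of lines, the same
    arithmetic used to summarise curated enhancer mutant collections
    (e.g. 505 substitutions over 91 lines -> 5.5 mutations/line).
    """
    if not variants:
        raise InputError("variant list is empty")
    counts = [len(v.mutations) for v in variants]
    total = int(sum(counts))
    hist = dict(sorted(Counter(counts).items()))
    return LibrarySummary(
        n_lines=len(variants),
        total_mutations=total,
        mean_mutations_per_line=total / len(variants),
        histogram=hist,
    )


def library_to_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    """Sidecar metadata table: line_id, n_mutations, ';'-joined positions."""
    return pd.DataFrame({
        "line_id": [v.line_id for v in variants],
        "n_mutations": [len(v.mutations) for v in variants],
        "positions": [";".join(str(p) for p, _, _ in v.mutations)
                      for v in variants],
    })


def write_library(variants: list[VariantRecord], outdir: str | Path) -> dict:
    """Write a variant library as FASTA + CSV + JSON metadata; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sset = SequenceSet(records=[(v.line_id, v.sequence) for v in variants])
    fasta = sset.to_fasta(outdir / "library.fa")
    csv = outdir / "library.csv"
    library_to_frame(variants).to_csv(csv, index=False)
    summary = summarize_library(variants)
    js = outdir / "library.json"
    with open(js, "w") as fh:
        json.dump({
            "n_lines": summary.n_lines,
            "total_mutations": summary.total_mutations,
            "mean_mutations_per_line": summary.mean_mutations_per_line,
            "histogram": {str(k): v for k, v in summary.histogram.items()},
            "lines": [{
                "line_id": v.line_id,
                "mutations": [list(m) for m in v.mutations],
            } for v in variants],
        }, fh, indent=1)
    return {"fasta": fasta, "csv": csv, "json": js}
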