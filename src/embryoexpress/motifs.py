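"""PWM information content and motif scanning with exact p-values.

A motif is a position weight matrix (PWM): per-position nucleotide
probabilities ``p[i, n]`` over a background ``b[n]``. Its information content
is the Kullback-Leibler divergence from background,

    I_motif = sum_i sum_n p[i, n] * log2(p[i, n] / b[n])   [bits],

and ``2**(-I_motif)`` approximates the per-position probability of a chance
motif hit in background DNA; the cumulative distribution of these expected
frequencies over a motif collection summarises how "findable" the motifs are
in random sequence.

Scanning scores every window of length L with the log2-odds score
``sum_i log2(p[i, w_i] / b[w_i])`` on both strands and converts scores to
p-values exactly, by dynamic programming over the discretized per-column
score distributions under the background model (the classic FIMO-style
construction, re-implemented so no external binary is needed). Windows are
scored in the same integer-score space used by the DP table, so the p-value
lookup is exact at the chosen granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .sequences import ALPHABET, SequenceSet

_COMPLEMENT = np.array([3, 2, 1, 0])
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Column-stochastic motif model with background frequencies."""

    name: str
    probs: np.ndarray                # (L, 4), columns A C G T
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise InputError("probs must have shape (L, 4)")
        if np.any(self.probs <= 0):
            raise InputError("all probabilities must be > 0 "
                             "(use a pseudocount)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("each PWM column must sum to 1")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise InputError("background must be 4 positive frequencies")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise InputError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds score matrix."""
        return np.log2(self.probs / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name + "_rc",
                   probs=self.probs[::-1, :][:, _COMPLEMENT],
                   background=self.background[_COMPLEMENT],
                   pseudocount=self.pseudocount)


def load_pwm(matrix,
             pseudocount: float = 0.01,
             background=None,
             name: str = "motif",
             kind: str = "auto") -> PWM:
    """Build a PWM from a count or probability matrix.

    ``matrix`` is (L, 4) or (4, L) with columns/rows ordered A, C, G, T.
    Counts get an additive per-cell ``pseudocount`` before normalization;
    probability input with a nonzero pseudocount is treated the same way.
    ``kind`` is "counts", "probabilities" or "auto" (probabilities iff every
    position already sums to ~1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or 4 not in m.shape:
        raise InputError("matrix must be (L, 4) or (4, L)")
    if m.shape[1] != 4:
        m = m.T
    if np.any(m < 0):
        raise InputError("matrix entries must be non-negative")
    if kind == "auto":
        kind = ("probabilities"
                if np.allclose(m.sum(axis=1), 1.0, atol=1e-6) else "counts")
    if kind not in ("counts", "probabilities"):
        raise InputError(f"unknown matrix kind {kind!r}")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    m = m + pseudocount
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        raise InputError("zero-sum column with zero pseudocount")
    probs = m / sums[:, None]
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background,
                                                                 dtype=float)
    return PWM(name=name, probs=probs, background=bg,
               pseudocount=pseudocount)


def information_content(pwm: PWM) -> float:
    """Kullback-Leibler information content of the PWM, in bits."""
    return float(np.sum(pwm.probs * np.log2(pwm.probs
                                            / pwm.background[None, :])))


def expected_hit_frequency(pwm: PWM) -> float:
    """2**(-I_motif): approximate per-position chance-hit probability."""
    return float(2.0 ** (-information_content(pwm)))


def ic_ecdf(pwms: list[PWM]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of expected hit frequencies over a motif collection.

    Returns (sorted expected frequencies, cumulative fractions k/N).
    """
    if not pwms:
        raise InputError("need at least one PWM")
    freqs = np.sort([expected_hit_frequency(p) for p in pwms])
    return freqs, np.arange(1, len(freqs) + 1) / len(freqs)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the log-odds score at fixed granularity.

    ``int_scores[i, n]`` are the per-column scores discretized to a common
    integer grid; ``survival[k]`` is the background probability of an integer
    score >= k. Windows scored with ``int_scores`` get exact p-values.
    """

    scale: float
    offset: float                    # real score at integer 0
    int_scores: np.ndarray           # (L, 4) ints
    survival: np.ndarray

    def pvalue_int(self, k) -> np.ndarray:
        k = np.clip(np.asarray(k, dtype=int), 0, len(self.survival) - 1)
        return self.survival[k]

    def pvalue(self, score) -> np.ndarray:
        """p-value for a real-valued log-odds score."""
        k = np.rint((np.asarray(score, dtype=float) - self.offset)
                    * self.scale).astype(int)
        return self.pvalue_int(np.clip(k, 0, None))

    def score_threshold(self, p: float) -> int:
        """Smallest integer score whose p-value is <= p."""
        idx = np.searchsorted(-self.survival, -p, side="left")
        return int(idx)


def score_pvalue_table(pwm: PWM, granularity: int = 1000) -> ScoreDistribution:
    """Exact score -> p-value map by per-position convolution.

    Per-column log-odds scores are shifted to be non-negative and discretized
    so the full attainable range spans ``granularity`` integer bins; the
    distribution of the integer total under the background is built by
    convolving the four-outcome column distributions position by position.
    """
    if granularity < 100:
        raise InputError("granularity must be >= 100 bins")
    s = pwm.log_odds()
    col_min = s.min(axis=1)
    col_max = s.max(axis=1)
    total_range = float((col_max - col_min).sum())
    scale = (granularity - 1) / total_range if total_range > 0 else 1.0
    ints = np.rint((s - col_min[:, None]) * scale).astype(int)

    kmax = int(ints.max(axis=1).sum())
    pmf = np.zeros(kmax + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(len(pwm)):
        new = np.zeros(top + int(ints[i].max()) + 1)
        for n in range(4):
            new[ints[i, n]:ints[i, n] + top + 1] += (
                pwm.background[n] * pmf[:top + 1])
        top = len(new) - 1
        pmf = np.zeros(kmax + 1)
        pmf[:top + 1] = new
    survival = pmf[::-1].cumsum()[::-1]
    return ScoreDistribution(scale=scale, offset=float(col_min.sum()),
                             int_scores=ints, survival=survival)


@dataclass
class MotifHit:
    """A scored motif occurrence on a sequence (forward-strand coordinates)."""

    seq_id: str
    start: int                       # 0-based, half-open
    end: int
    strand: str                      # + or -
    score: float                     # log2-odds bits
    p: float
    motif: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        out[arr == ord(b)] = i
    return out


def _scan_one_orientation(codes: np.ndarray, pwm: PWM,
                          dist: ScoreDistribution
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer and real scores plus validity for every window start."""
    L = len(pwm)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        empty = np.zeros(0)
        return empty, empty, np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    safe = np.where(win >= 0, win, 0)
    pos = np.arange(L)
    k = dist.int_scores[pos[None, :], safe].sum(axis=1)
    s = pwm.log_odds()[pos[None, :], safe].sum(axis=1)
    return k, s, valid


def scan_sequences(seqs: SequenceSet,
                   pwm: PWM,
                   p_threshold: float = 0.001,
                   strands: str = "both",
                   granularity: int = 1000) -> list[MotifHit]:
    """Scan a sequence set for motif hits with p <= ``p_threshold``.

    Both strands are scanned by default; hit coordinates are always reported
    on the forward strand as 0-based half-open intervals. Windows containing
    ambiguity letters are skipped. Sequences shorter than the motif yield no
    hits.
    """
    if strands not in ("both", "+", "-"):
        raise InputError("strands must be 'both', '+' or '-'")
    if not 0.0 < p_threshold <= 1.0:
        raise InputError("p_threshold must lie in (0, 1]")
    L = len(pwm)
    dist = score_pvalue_table(pwm, granularity)
    orientations: list[tuple[str, PWM, ScoreDistribution]] = []
    if strands in ("both", "+"):
        orientations.append(("+", pwm, dist))
    if strands in ("both", "-"):
        rc = pwm.reverse_complement()
        orientations.append(("-", rc, score_pvalue_table(rc, granularity)))

    hits: list[MotifHit] = []
    for seq_id, seq in seqs.records:
        codes = _encode(seq)
        for strand, opwm, odist in orientations:
            k, s, valid = _scan_one_orientation(codes, opwm, odist)
            if valid.size == 0:
                continue
            p = np.ones_like(s)
            p[valid] = odist.pvalue_int(k[valid])
            sel = valid & (p <= p_threshold)
            for j in np.nonzero(sel)[0]:
                hits.append(MotifHit(seq_id=seq_id, start=int(j),
                                     end=int(j) + L, strand=strand,
                                     score=float(s[j]), p=float(p[j]),
                                     motif=pwm.name))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


@dataclass
class HitStats:
    """Library-level hit statistics for one or more motifs."""

    per_sequence: pd.DataFrame       # rows sequences, columns motifs: counts
    per_bp: pd.DataFrame             # counts / sequence length
    set_averages: dict[str, float]   # motif-set -> mean per-sequence hits
    top_hits: list[MotifHit]         # top-fraction best-scoring hits


def hit_statistics(hits: list[MotifHit],
                   seqs: SequenceSet,
                   motif_sets: dict[str, list[str]] | None = None,
                   top_fraction: float = 0.30) -> HitStats:
    """Per-sequence counts, per-bp densities, set averages and a top-score
    filter.

    ``motif_sets`` maps set names (e.g. "early", "late") to member motif
    names; the set average is the mean over member motifs of the mean hit
    count per sequence. The top filter keeps, per motif across all
    sequences, the ceil(top_fraction * n) highest-scoring hits.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise InputError("top_fraction must lie in (0, 1]")
    lengths = seqs.lengths()
    motif_names = sorted({h.motif for h in hits})
    counts = pd.DataFrame(0, index=list(lengths), columns=motif_names,
                          dtype=int)
    for h in hits:
        if h.seq_id not in lengths:
            raise InputError(f"hit references unknown sequence {h.seq_id!r}")
        counts.loc[h.seq_id, h.motif] += 1
    lens = pd.Series(lengths)
    per_bp = counts.div(lens, axis=0)
    set_averages: dict[str, float] = {}
    for set_name, members in (motif_sets or {}).items():
        present = [m for m in members if m in counts.columns]
        if not present:
            set_averages[set_name] = 0.0
            continue
        set_averages[set_name] = float(
            np.mean([counts[m].mean() for m in present]))
    top: list[MotifHit] = []
    by_motif: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif, []).append(h)
    for motif, mh in by_motif.items():
        keep = int(np.ceil(top_fraction * len(mh)))
        top.extend(sorted(mh, key=lambda h: -h.score)[:keep])
    top.sort(key=lambda h: (h.motif, -h.score))
    return HitStats(per_sequence=counts, per_bp=per_bp,
                    set_averages=set_averages, top_hits=top)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "seq_id": h.seq_id, "start": h.start, "end": h.end,
        "strand": h.strand, "score": h.score, "p": h.p, "motif": h.motif,
    } for h in hits], columns=["seq_id", "start", "end", "strand",
                               "score", "p", "motif"])


def hits_to_tsv(hits: list[MotifHit], path: str | Path) -> Path:
    path = Path(path)
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
    return path


def hits_to_bed(hits: list[MotifHit], path: str | Path) -> Path:
    """BED6: seq, start, end, motif, scaled score, strand."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif}\t"
                     f"{min(int(round(h.score * 100)), 1000)}\t{h.strand}\n")
    return path


# ---------------------------------------------------------------------------
# PWM file formats: MEME minimal and plain 4-column count TSV


def read_meme(path: str | Path,
              pseudocount: float = 1e-4) -> list[PWM]:
    """Read PWMs from a MEME minimal-format file."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        probs = np.array([[m.pwm[b][i] for b in "ACGT"]
                          for i in range(m.length)], dtype=float)
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        # a small additive pseudocount keeps zero cells admissible while
        # perturbing stored probabilities by < 4e-4
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        out.append(PWM(name=m.name, probs=probs, background=bg / bg.sum(),
                       pseudocount=pseudocount))
    if not out:
        raise InputError(f"no motifs found in {path}")
    return out


def write_meme(pwms: list[PWM], path: str | Path) -> Path:
    """Write PWMs in MEME minimal format."""
    path = Path(path)
    bg = pwms[0].background if pwms else UNIFORM_BG
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            # large nsites: Bio.motifs round-trips probabilities through
            # integer counts, so nsites sets the quantization step
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} "
                     f"nsites= 1000000 E= 0\n")
            for row in p.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
    return path


def read_counts_tsv(path: str | Path,
                    pseudocount: float = 0.01,
                    background=None,
                    name: str | None = None) -> PWM:
    """Read a plain 4-column (A C G T) count matrix, one row per position."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] != 4:
        # maybe a header row of letters
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        if df.shape[1] != 4:
            raise InputError(f"{path}: expected 4 whitespace-separated "
                             "columns (A C G T)")
    return load_pwm(df.to_numpy(dtype=float), pseudocount=pseudocount,
                    background=background,
                    name=name or Path(path).stem, kind="counts")
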