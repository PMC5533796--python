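"""PWM scanning with exact log-odds score p-values (FIMO-style).

Scores are log2 odds of the motif model vs an i.i.d. background. The
exact null distribution of the score is computed by position-wise dynamic
programming over scores discretized to a fixed bin width (default 1e-3
bits), giving the tail probability P(score >= s) for any threshold.
Scanning reports every window, on either strand, whose exact p-value
passes the cutoff (default 1e-4); overlapping hits are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import PeakSet

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreDistribution",
    "read_meme",
    "write_meme",
    "read_fasta",
    "score_pvalue_table",
    "scan_sequences",
    "count_hits_per_region",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} with a background model."""

    name: str
    matrix: np.ndarray                  # L x 4 probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("matrix must be L x 4 with L >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each matrix row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.pseudocount == 0 and np.any((self.matrix > 0) & (self.background == 0)):
            raise ValueError(
                "zero background probability with nonzero matrix entry and "
                "zero pseudocount"
            )

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds after pseudocount regularization."""
        m = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        bg = np.where(self.background > 0, self.background, np.nan)
        return np.log2(m / bg)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=f"{self.name}_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[_COMPLEMENT].copy()
            if not np.allclose(self.background, self.background[_COMPLEMENT])
            else self.background.copy(),
            pseudocount=self.pseudocount,
        )


@dataclass
class MotifHit:
    sequence: str
    offset: int      # 0-based start on the forward strand
    strand: str      # + or -
    score: float     # log2 odds (bits)
    p_value: float


# ---------------------------------------------------------------------------
# MEME minimal format and FASTA I/O
# ---------------------------------------------------------------------------

def read_meme(path: str | Path) -> list[PWM]:
    """Parse motifs from MEME minimal format (letter-probability matrices)."""
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    name: str | None = None
    rows: list[list[float]] = []
    expecting_bg = False
    in_matrix = False

    def flush() -> None:
        nonlocal name, rows, in_matrix
        if name is not None and rows:
            motifs.append(PWM(name=name, matrix=np.array(rows), background=background.copy()))
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expecting_bg:
                toks = line.split()
                freqs = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)}
                background = np.array([freqs.get(b, 0.25) for b in ALPHABET])
                expecting_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expecting_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                toks = line.split()
                if len(toks) == 4:
                    rows.append([float(t) for t in toks])
                else:
                    in_matrix = False
    flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found (MEME minimal format expected)")
    return motifs


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Exact score distribution
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Exact tail distribution of discretized PWM log-odds scores.

    Integer scores are ``round(log_odds / precision)``; the probability
    mass function over total integer scores is built by convolving the
    per-position base distributions under the background model, and the
    tail P(score >= s) by a reverse cumulative sum.
    """

    def __init__(self, pwm: PWM, precision: float = 1e-3) -> None:
        if precision <= 0:
            raise ValueError("precision must be > 0")
        self.pwm = pwm
        self.precision = precision
        lo = pwm.log_odds()
        self.int_scores = np.rint(lo / precision).astype(np.int64)  # L x 4
        min_total = int(self.int_scores.min(axis=1).sum())
        max_total = int(self.int_scores.max(axis=1).sum())
        span = max_total - min_total + 1
        pmf = np.zeros(span)
        offset = 0  # current pmf index 0 corresponds to min partial score
        pmf[0] = 1.0
        cur_min = 0
        cur_max = 0
        for l in range(pwm.length):
            s = self.int_scores[l]
            new_min = cur_min + int(s.min())
            new_max = cur_max + int(s.max())
            new = np.zeros(new_max - new_min + 1)
            width = cur_max - cur_min + 1
            for b in range(4):
                shift = int(s[b]) + cur_min - new_min  # position of old min in new array
                new[shift:shift + width] += pmf[:width] * pwm.background[b]
            pmf, cur_min, cur_max = new, new_min, new_max
        self.min_score = cur_min
        self.pmf = pmf
        # tail[i] = P(score >= min_score + i)
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, score_bits: float) -> float:
        """Exact P(score >= s) for a score in bits."""
        idx = int(np.rint(score_bits / self.precision)) - self.min_score
        if idx <= 0:
            return 1.0
        if idx >= self.tail.size:
            return float(self.tail[-1]) if self.tail.size else 1.0
        return float(min(self.tail[idx], 1.0))

    def score_threshold(self, p_cutoff: float) -> int:
        """Smallest integer score whose tail probability is <= p_cutoff."""
        passing = np.flatnonzero(self.tail <= p_cutoff)
        if passing.size == 0:
            return self.min_score + self.tail.size  # unreachable threshold
        return self.min_score + int(passing[0])

    def as_table(self) -> pd.DataFrame:
        scores = (np.arange(self.tail.size) + self.min_score) * self.precision
        return pd.DataFrame({"score": scores, "tail_p": self.tail})


def score_pvalue_table(pwm: PWM, precision: float = 1e-3) -> ScoreDistribution:
    """Exact score -> tail-probability mapping for a PWM (see
    :class:`ScoreDistribution`)."""
    return ScoreDistribution(pwm, precision)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores and validity (no N) for each offset."""
    L = int_scores.shape[0]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for l in range(L):
        window_codes = codes[l:l + n_win]
        valid &= window_codes >= 0
        total += int_scores[l][safe[l:l + n_win]]
    return total, valid


def scan_sequences(
    seqs: Mapping[str, str],
    pwm: PWM,
    p_cutoff: float = 1e-4,
    both_strands: bool = True,
    precision: float = 1e-3,
) -> list[MotifHit]:
    """Scan sequences for PWM matches with exact p <= ``p_cutoff``.

    Windows containing any non-ACGT character are skipped. Reverse-strand
    scores use the reverse-complement matrix; a minus-strand hit's offset
    is the forward-strand start of the covered window.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    dist = ScoreDistribution(pwm, precision)
    threshold = dist.score_threshold(p_cutoff)
    strands: list[tuple[str, np.ndarray]] = [("+", dist.int_scores)]
    if both_strands:
        # reverse-complement integer scores from the same discretization so
        # +/- scores share one exact distribution
        strands.append(("-", dist.int_scores[::-1, ::-1].copy()))

    hits: list[MotifHit] = []
    for name in seqs:
        codes = _encode(seqs[name])
        for strand, int_scores in strands:
            total, valid = _window_scores(codes, int_scores)
            for off in np.flatnonzero(valid & (total >= threshold)):
                s = int(total[off])
                hits.append(
                    MotifHit(
                        sequence=name, offset=int(off), strand=strand,
                        score=s * precision,
                        p_value=dist.pvalue(s * precision),
                    )
                )
    hits.sort(key=lambda h: (h.sequence, h.offset, h.strand))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sequence": h.sequence, "offset": h.offset, "strand": h.strand,
             "score": h.score, "p_value": h.p_value}
            for h in hits
        ],
        columns=["sequence", "offset", "strand", "score", "p_value"],
    )


def count_hits_per_region(
    hits: Sequence[MotifHit], peaks: PeakSet
) -> pd.Series:
    """Per-peak motif occurrence counts, zero-filled over all peaks.

    Hit ``sequence`` identifiers must name peaks (peak ``name`` field);
    a hit referencing an unknown peak is an error.
    """
    names = []
    for i, iv in enumerate(peaks):
        names.append(iv.name if iv.name is not None else f"{peaks.label}_{i}")
    if len(set(names)) != len(names):
        raise ValueError("peak names must be unique to count hits per region")
    counts = pd.Series(0, index=pd.Index(names, name="peak"), dtype=int)
    for h in hits:
        if h.sequence not in counts.index:
            raise ValueError(f"hit references unknown peak {h.sequence!r}")
        counts[h.sequence] += 1
    return counts
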