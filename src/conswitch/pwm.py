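"""Position weight matrices and log-odds scanning.

A PWM is stored as a 4 x L count matrix (rows A, C, G, T).  Scoring uses
the log2-odds of the pseudocount-regularized position probabilities
against a background nucleotide distribution:

    log_odds[b, j] = log2( (counts[b, j] + pseudocount * bg[b])
                           / (colsum[j] + pseudocount) / bg[b] )

Hit counting applies a log2-odds cutoff, falling back to the maximal
attainable score of the matrix when that maximum is below the cutoff, so
weak matrices can still match at (and only at) their consensus.  Both
strands are scanned at every offset and overlapping hits are counted
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(BASES)}
# anything not ACGT (N etc.) maps to code 4, which scores -inf
_LUT = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_CUTOFF = 10.0


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (A=0 C=1 G=2 T=3, other=4)."""
    return _LUT[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWMModel:
    """Position count matrix with background model and scoring rule."""

    motif_id: str
    counts: np.ndarray  # (4, L), rows A C G T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix (finite everywhere by construction)."""
        bg = self.background[:, None]
        colsum = self.counts.sum(axis=0, keepdims=True)
        probs = (self.counts + self.pseudocount * bg) / (colsum + self.pseudocount)
        return np.log2(probs / bg)

    @property
    def max_score(self) -> float:
        """Best attainable log2-odds score (consensus score)."""
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def effective_cutoff(self, cutoff: float = DEFAULT_CUTOFF) -> float:
        return min(cutoff, self.max_score)


def _strand_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of one strand; -inf across non-ACGT."""
    L = log_odds.shape[1]
    n = codes.size
    if n < L:
        return np.empty(0)
    # row 4 catches ambiguous bases
    lom = np.vstack([log_odds, np.full((1, L), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lom[windows, np.arange(L)].sum(axis=1)


def scan_scores(sequence: str, pwm: PWMModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset scores on the forward and reverse strand.

    The reverse-strand score at offset i refers to the reverse complement
    of sequence[i:i+L], i.e. both arrays are indexed in forward coordinates.
    """
    codes = encode(sequence)
    fwd = _strand_scores(codes, pwm.log_odds)
    # scoring the reverse complement of each window == scoring the full
    # reverse complement and flipping the offset axis
    rc = encode(reverse_complement(sequence))
    rev = _strand_scores(rc, pwm.log_odds)[::-1]
    return fwd, rev


def count_hits(sequence: str, pwm: PWMModel,
               cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of motif hits (both strands, overlaps allowed).

    A hit is any offset whose log2-odds score reaches
    min(cutoff, max attainable score). Sequences shorter than the motif
    have zero hits.
    """
    if len(sequence) < pwm.length:
        return 0
    eff = pwm.effective_cutoff(cutoff)
    fwd, rev = scan_scores(sequence, pwm)
    # tolerance absorbs float summation order differences at the consensus
    return int((fwd >= eff - 1e-9).sum() + (rev >= eff - 1e-9).sum())


def count_hits_many(sequences: list[str], pwm: PWMModel,
                    cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    return np.array([count_hits(s, pwm, cutoff) for s in sequences],
                    dtype=int)
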