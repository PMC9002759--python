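"""Position matrices over the 14 AW-box slots and the derived consensus.

From an alignment of bound 14-mers this module builds the position frequency
matrix (raw counts), the position probability matrix (optionally
pseudocounted) and the position weight matrix (log2 odds against a background
base composition).  Because the training set is small, zero counts are a
signal in their own right: a base never observed at a variable slot among
motifs that bound the transcription factor is reported as *forbidden* there,
and the most frequent base at a slot is its *bias* base.

The IUPAC consensus is derived from the probability matrix under two
documented thresholds: a slot whose top base reaches ``collapse_threshold``
is written as that single base; otherwise the slot is written as the minimal
degeneracy code covering every base with probability >= ``include_threshold``.
With the default thresholds (0.2 / 0.6) the shipped bound set yields
CHTCGWKWAYWYCG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern import FIXED_SLOTS, MOTIF_LENGTH, N_SLOTS, iupac_code, matches_canonical

__all__ = [
    "BASES", "DEFAULT_INCLUDE_THRESHOLD", "DEFAULT_COLLAPSE_THRESHOLD",
    "DEFAULT_PSEUDOCOUNT", "PositionFrequencyMatrix", "PositionProbabilityMatrix",
    "PositionWeightMatrix", "ForbiddenReport", "build_pfm", "build_ppm",
    "build_pwm", "forbidden_and_bias", "iupac_consensus", "score_sequence",
    "to_meme_minimal", "text_logo",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_INCLUDE_THRESHOLD = 0.2
DEFAULT_COLLAPSE_THRESHOLD = 0.6


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    counts: np.ndarray  # (14, 4) nonnegative ints, slots x ACGT
    n_sequences: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (MOTIF_LENGTH, 4):
            raise ValueError(f"PFM must be {MOTIF_LENGTH}x4, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("PFM counts must be nonnegative")
        if not (counts.sum(axis=1) == self.n_sequences).all():
            raise ValueError("every PFM slot must sum to n_sequences")


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    probs: np.ndarray  # (14, 4)
    pseudocount: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (MOTIF_LENGTH, 4):
            raise ValueError(f"PPM must be {MOTIF_LENGTH}x4, got {probs.shape}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PPM slot must sum to 1")


@dataclass(frozen=True)
class PositionWeightMatrix:
    weights: np.ndarray  # (14, 4) log2 odds; -inf marks unobserved bases
    background: np.ndarray  # (4,) frequencies summing to 1

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "background", background)
        if weights.shape != (MOTIF_LENGTH, 4):
            raise ValueError(f"PWM must be {MOTIF_LENGTH}x4, got {weights.shape}")
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")


@dataclass(frozen=True)
class ForbiddenReport:
    """Per variable slot (N1..N9): unobserved bases and the most frequent base.

    ``forbidden`` maps the N index (1..9) to the set of bases with zero count;
    ``bias`` maps it to the set of most-frequent bases (a set so that ties are
    never broken arbitrarily) and ``bias_probability`` to their frequency.
    """

    forbidden: dict[int, frozenset[str]]
    bias: dict[int, frozenset[str]]
    bias_probability: dict[int, float]

    def allowed(self, n_index: int) -> frozenset[str]:
        return frozenset(BASES) - self.forbidden[n_index]


def build_pfm(seqs) -> PositionFrequencyMatrix:
    """Exact per-slot base counts over canonical 14-mers."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("cannot build a PFM from an empty sequence set")
    counts = np.zeros((MOTIF_LENGTH, 4), dtype=int)
    for s in seqs:
        if len(s) != MOTIF_LENGTH:
            raise ValueError(f"{s!r}: PFM sequences must be {MOTIF_LENGTH}-mers")
        if not matches_canonical(s):
            raise ValueError(f"{s!r} violates the canonical AW-box pattern")
        for slot, base in enumerate(s):
            counts[slot, _BASE_INDEX[base]] += 1
    return PositionFrequencyMatrix(counts, len(seqs))


def build_ppm(pfm: PositionFrequencyMatrix,
              pseudocount: float = 0.0) -> PositionProbabilityMatrix:
    """Per-slot probabilities: (count + a) / (n + 4a) with pseudocount a >= 0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pfm.n_sequences == 0:
        raise ValueError("cannot normalise a PFM with n_sequences == 0")
    probs = (pfm.counts + pseudocount) / (pfm.n_sequences + 4 * pseudocount)
    return PositionProbabilityMatrix(probs, pseudocount)


def build_pwm(ppm: PositionProbabilityMatrix,
              background=(0.25, 0.25, 0.25, 0.25)) -> PositionWeightMatrix:
    """log2(prob / background) per cell; zero probabilities map to -inf."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must have 4 frequencies")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    if (bg <= 0).any():
        raise ValueError("background frequencies must all be > 0")
    with np.errstate(divide="ignore"):
        weights = np.log2(ppm.probs / bg)
    return PositionWeightMatrix(weights, bg)


def forbidden_and_bias(pfm: PositionFrequencyMatrix) -> ForbiddenReport:
    """Zero-count (forbidden) bases and modal (bias) bases per N slot."""
    if pfm.n_sequences < 1:
        raise ValueError("forbidden-base detection needs at least one sequence")
    forbidden, bias, bias_p = {}, {}, {}
    for k, slot in enumerate(N_SLOTS, start=1):
        row = pfm.counts[slot]
        forbidden[k] = frozenset(b for b in BASES if row[_BASE_INDEX[b]] == 0)
        top = row.max()
        bias[k] = frozenset(b for b in BASES if row[_BASE_INDEX[b]] == top)
        bias_p[k] = top / pfm.n_sequences
    return ForbiddenReport(forbidden, bias, bias_p)


def iupac_consensus(ppm: PositionProbabilityMatrix,
                    mode: str = "bias-collapse",
                    include_threshold: float = DEFAULT_INCLUDE_THRESHOLD,
                    collapse_threshold: float = DEFAULT_COLLAPSE_THRESHOLD) -> str:
    """14-letter IUPAC consensus derived from the probability matrix.

    Fixed slots always emit their conserved base.  Each N slot emits the
    minimal IUPAC code over bases with probability >= include_threshold,
    except that in "bias-collapse" mode a slot whose top base reaches
    collapse_threshold emits that base alone.
    """
    if mode not in ("bias-collapse", "inclusion"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    if not 0 < include_threshold < 1 or not 0 < collapse_threshold < 1:
        raise ValueError("consensus thresholds must lie in (0, 1)")
    letters = []
    for slot in range(MOTIF_LENGTH):
        if slot in FIXED_SLOTS:
            letters.append(FIXED_SLOTS[slot])
            continue
        row = ppm.probs[slot]
        if mode == "bias-collapse" and row.max() >= collapse_threshold:
            letters.append(BASES[int(row.argmax())])
            continue
        included = {b for b in BASES if row[_BASE_INDEX[b]] >= include_threshold}
        if not included:  # degenerate thresholds: fall back to covering everything seen
            included = {b for b in BASES if row[_BASE_INDEX[b]] > 0}
        letters.append(iupac_code(included))
    return "".join(letters)


def score_sequence(pwm: PositionWeightMatrix, seq: str) -> float:
    """Sum of per-slot log-odds weights (bits) for a 14-mer."""
    if len(seq) != MOTIF_LENGTH:
        raise ValueError(f"score_sequence needs a {MOTIF_LENGTH}-mer")
    try:
        return float(sum(pwm.weights[i, _BASE_INDEX[b]] for i, b in enumerate(seq)))
    except KeyError as exc:
        raise ValueError(f"invalid base in {seq!r}") from exc


def to_meme_minimal(ppm: PositionProbabilityMatrix, name: str = "AW-box",
                    background=(0.25, 0.25, 0.25, 0.25),
                    n_sequences: int | None = None) -> str:
    """MEME minimal motif format rendering of the probability matrix."""
    bg = np.asarray(background, dtype=float)
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)), "",
        f"MOTIF {name}",
        "letter-probability matrix: alength= 4 w= {w} nsites= {n} E= 0".format(
            w=MOTIF_LENGTH, n=n_sequences if n_sequences is not None else 20),
    ]
    for row in ppm.probs:
        lines.append(" " + " ".join(f"{p:.6f}" for p in row))
    return "\n".join(lines) + "\n"


def text_logo(ppm: PositionProbabilityMatrix, width: int = 10) -> str:
    """Plain-text logo: per slot, bases stacked by descending probability."""
    lines = ["pos  stack (base:prob, descending)"]
    for slot in range(MOTIF_LENGTH):
        row = ppm.probs[slot]
        order = np.argsort(-row)
        stack = "  ".join(f"{BASES[i]}:{row[i]:.2f}" for i in order if row[i] > 0)
        bar = "#" * int(round(width * row.max()))
        lines.append(f"{slot + 1:>3}  {stack:<40} {bar}")
    return "\n".join(lines)
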