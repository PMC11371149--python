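"""N-terminal motif detection and per-position conservation barcodes.

Helper-clade NLRs of the NRC type carry a MADA-like alpha1-helix sequence at
the very N terminus, whereas their genetically linked sensors instead retain a
degenerate "MAHAAVVSLxQKLxx" pattern.  Detection here uses a position-specific
scoring model (log-odds over the 20 amino acids) scanned ungapped within an
N-terminal window, which is all an anchored, indel-free motif needs; a loader
for standard profile-HMM text files (match-state emissions only) lets an
externally built HMM stand behind the same interface.

Conservation barcodes are entropy-based: per alignment column the score is
1 - H/log(20) with gaps excluded from the residue distribution (gap fraction
reported separately), reindexed to the ungapped positions of a reference
sequence.  This is a declared proxy for tree-aware evolutionary-rate scoring;
the interface leaves room for a rate-based backend.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import AMINO_ACIDS, SequenceSet

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Degenerate N-terminal consensus of NRC0-linked sensor NLRs (x = any residue).
MAHA_PATTERN = "MAHAAVVSLxQKLxx"

DEFAULT_WINDOW = 30


@dataclass
class MotifProfile:
    """Position-specific scoring model for an N-terminal motif.

    ``matrix`` is (L, 20) log2-odds against ``background``; ``threshold`` is
    the pass score (bits) or None when uncalibrated; ``window`` bounds the
    1-based start position for an "N-terminal" call.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray
    threshold: float | None = None
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("profile matrix must be (L, 20)")
        if self.matrix.shape[0] < 1:
            raise ValueError("profile must have >= 1 column")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    def score_at(self, seq: str, start: int) -> float:
        """Ungapped score of the placement beginning at 1-based ``start``."""
        total = 0.0
        for k in range(len(self)):
            aa = seq[start - 1 + k]
            idx = _AA_INDEX.get(aa)
            if idx is not None:  # X / unknown scores 0 (= background odds)
                total += self.matrix[k, idx]
        return total


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based; 0 when no placement was possible
    score: float
    passed: bool
    reason: str = ""


def build_profile(
    seed_alignment: SequenceSet | Mapping[str, str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    name: str = "motif",
    window: int = DEFAULT_WINDOW,
) -> MotifProfile:
    """Log-odds PSSM from a seed alignment of the motif region.

    Column score for residue a: log2(((count_a + pc*bg_a) / (n + pc)) / bg_a)
    where n counts non-gap residues in the column.  A single-sequence seed
    under a large pseudocount therefore tends to the background (all scores
    -> 0).  Gap and X characters contribute nothing to the counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    seqs = dict(seed_alignment.items()) if hasattr(seed_alignment, "items") else dict(seed_alignment)
    if not seqs:
        raise ValueError("empty seed alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("seed alignment sequences must have equal length")
    L = lengths.pop()
    bg = (
        np.full(20, 1 / 20)
        if background is None
        else np.asarray(background, dtype=float)
    )
    bg = bg / bg.sum()
    counts = np.zeros((L, 20))
    for seq in seqs.values():
        for k, aa in enumerate(seq.upper()):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[k, idx] += 1
    n = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * bg) / (n + pseudocount)
    matrix = np.log2(freqs / bg)
    return MotifProfile(
        name=name, matrix=matrix, background=bg, window=window
    )


def calibrate_threshold(
    profile: MotifProfile,
    sequences: Mapping[str, str],
    rng: np.random.Generator,
    n_shuffles: int = 1000,
    fpr: float = 0.01,
) -> float:
    """Score threshold at a target false-positive rate on shuffled sequences.

    Composition-matched null: residues of each (randomly chosen) input
    sequence are permuted and the shuffle is scanned like a real sequence;
    the threshold is the (1-fpr) quantile of the null best-scores.
    """
    pool = [s for s in sequences.values() if len(s) >= len(profile)]
    if not pool:
        raise ValueError("no sequence long enough to calibrate on")
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        seq = pool[rng.integers(len(pool))]
        shuffled = "".join(rng.permutation(list(seq)))
        scores[i] = _best_placement(shuffled, profile)[1]
    return float(np.quantile(scores, 1.0 - fpr))


def _best_placement(seq: str, profile: MotifProfile) -> tuple[int, float]:
    L = len(profile)
    last_start = min(profile.window, len(seq) - L + 1)
    best = (0, -np.inf)
    for start in range(1, last_start + 1):
        s = profile.score_at(seq, start)
        if s > best[1]:
            best = (start, s)
    return best


def scan_n_terminus(
    seq: str,
    profile: MotifProfile,
    sequence_id: str = "seq",
    window: int | None = None,
) -> MotifHit:
    """Best ungapped N-terminal placement of the profile; pass iff score >= threshold.

    Placements start within the first ``window`` positions (1-based).  A
    sequence shorter than the profile fails with reason "too_short"; one
    shorter than window+L-1 is scanned over the placements available.
    """
    if window is not None:
        profile = MotifProfile(
            profile.name, profile.matrix, profile.background,
            profile.threshold, window,
        )
    if len(seq) < len(profile):
        return MotifHit(sequence_id, 0, -np.inf, False, reason="too_short")
    start, score = _best_placement(seq, profile)
    passed = profile.threshold is not None and score >= profile.threshold
    reason = "" if profile.threshold is not None else "no_threshold"
    return MotifHit(sequence_id, start, score, passed, reason=reason)


def scan_set(
    seqs: SequenceSet | Mapping[str, str], profile: MotifProfile
) -> pd.DataFrame:
    """Scan every sequence; one row per sequence with start/score/pass."""
    items = seqs.items() if hasattr(seqs, "items") else seqs
    rows = []
    for sid, seq in sorted(items):
        hit = scan_n_terminus(seq, profile, sequence_id=sid)
        rows.append(
            {"sequence_id": sid, "start": hit.start,
             "score": round(hit.score, 4), "passed": hit.passed,
             "reason": hit.reason}
        )
    return pd.DataFrame(
        rows, columns=["sequence_id", "start", "score", "passed", "reason"]
    )


def mahalike_presence(
    seq: str, pattern: str = MAHA_PATTERN, window: int = DEFAULT_WINDOW
) -> tuple[bool, str | None]:
    """Exact degenerate-pattern match anchored in the N-terminal window.

    ``x`` in the pattern matches any residue.  Returns (found, matched
    substring).  For soft scoring build a profile from example sequences
    instead; this is the hard call used for presence/absence tables.
    """
    regex = re.compile("".join("." if c == "x" else re.escape(c) for c in pattern))
    m = regex.search(seq, 0, window - 1 + len(pattern))
    if m and m.start() < window:
        return True, m.group(0)
    return False, None


@dataclass
class ConservationBarcode:
    """Per-reference-position conservation with variable-region calls.

    ``scores[i]`` is the conservation of reference position i+1 (1 =
    invariant column, 0 = maximally diverse); ``gap_fraction`` the fraction
    of gapped rows in the underlying alignment column.
    """

    reference_id: str
    scores: np.ndarray
    gap_fraction: np.ndarray
    alignment_columns: np.ndarray  # 0-based alignment column per ref position

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.scores) + 1),
                "conservation": self.scores,
                "gap_fraction": self.gap_fraction,
                "alignment_column": self.alignment_columns + 1,
            }
        )


def conservation_barcode(
    alignment: SequenceSet | Mapping[str, str], reference_id: str
) -> ConservationBarcode:
    """Entropy-based conservation mapped onto a reference sequence.

    Per column: score = 1 - H/log(20) over the residue distribution (gaps and
    X excluded; the gap fraction is reported alongside).  Columns where the
    reference holds a gap are skipped, so the barcode length equals the
    reference's ungapped length.
    """
    seqs = dict(alignment.items()) if hasattr(alignment, "items") else dict(alignment)
    if reference_id not in seqs:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = seqs[reference_id]
    n_rows = len(seqs)
    scores: list[float] = []
    gap_frac: list[float] = []
    columns: list[int] = []
    log20 = np.log(20.0)
    for col, ref_aa in enumerate(ref):
        if ref_aa in "-.":
            continue
        counts = np.zeros(20)
        gaps = 0
        for seq in seqs.values():
            aa = seq[col]
            idx = _AA_INDEX.get(aa)
            if idx is None:
                gaps += aa in "-."
                continue
            counts[idx] += 1
        total = counts.sum()
        if total == 0:
            score = 0.0
        else:
            p = counts[counts > 0] / total
            entropy = float(-(p * np.log(p)).sum())
            score = 1.0 - entropy / log20
        scores.append(score)
        gap_frac.append(gaps / n_rows)
        columns.append(col)
    return ConservationBarcode(
        reference_id=reference_id,
        scores=np.array(scores),
        gap_fraction=np.array(gap_frac),
        alignment_columns=np.array(columns, dtype=int),
    )


def call_variable_regions(
    barcode: ConservationBarcode | np.ndarray,
    smoothing_window: int = 10,
    quantile: float = 0.2,
    min_len: int = 5,
) -> list[tuple[int, int]]:
    """Maximal low-conservation runs in reference coordinates.

    The barcode is smoothed by a centered sliding mean; positions whose
    smoothed score falls strictly below the requested quantile of the
    smoothed scores form candidate runs; runs of length >= min_len are
    reported as 1-based inclusive intervals.  A flat barcode yields no
    regions (nothing is strictly below its own quantile).
    """
    scores = barcode.scores if isinstance(barcode, ConservationBarcode) else np.asarray(barcode, float)
    if len(scores) == 0:
        return []
    smoothed = (
        pd.Series(scores)
        .rolling(smoothing_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    cutoff = float(np.quantile(smoothed, quantile))
    below = smoothed < cutoff
    regions: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= min_len:
                regions.append((start + 1, i))
            start = None
    if start is not None and len(below) - start >= min_len:
        regions.append((start + 1, len(below)))
    return regions


def load_hmm_profile(
    path, threshold: float | None = None, window: int = DEFAULT_WINDOW
) -> MotifProfile:
    """Load a profile HMM (HMMER3 text format) as a match-state PSSM.

    Only match-state emissions are used: an anchored, ungapped N-terminal
    motif has no need for insert/delete transitions, so the HMM collapses to
    per-column log-odds against its own background composition.
    """
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        hmm = fh.read()
    alpha = hmm.alphabet.symbols[: hmm.alphabet.K]
    probs = np.asarray(hmm.match_emissions, dtype=float)[1:]  # row 0 = begin
    bg = np.asarray(pyhmmer.plan7.Background(hmm.alphabet).residue_frequencies, dtype=float)
    order = [alpha.index(aa) for aa in AMINO_ACIDS]
    probs = probs[:, order]
    bg = bg[order]
    bg = bg / bg.sum()
    matrix = np.log2(np.clip(probs, 1e-9, None) / bg)
    name = hmm.name or "hmm"
    if isinstance(name, bytes):
        name = name.decode()
    return MotifProfile(
        name=name,
        matrix=matrix,
        background=bg,
        threshold=threshold,
        window=window,
    )
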