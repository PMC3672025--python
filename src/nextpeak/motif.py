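"""PSSM motif scanning with exact p-values by score-distribution convolution.

Segment scores are sums of per-column log-odds scores (against an equal-base
background), kept on an integer lattice.  The null distribution of the score
of a random segment — bases i.i.d. uniform over {A, C, G, T} — is computed
exactly by convolving the L per-column score distributions (Staden's method),
and a site's p-value is the upper-tail mass at its score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "PSSM",
    "ScoreDistribution",
    "MotifSite",
    "score_segment",
    "score_distribution",
    "score_pvalue",
    "scan_sequence",
    "read_jaspar_pfm",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: default integer-lattice scale for log-odds scores (score = round(100*log2 odds))
SCORE_SCALE = 100


@dataclass(frozen=True)
class PSSM:
    """Position-specific score matrix: 4 rows (A, C, G, T) x L columns.

    Scores are integers on a fixed lattice; `from_counts` builds them as
    round(scale * log2(((count + 0.25) / (colsum + 1)) / 0.25)).
    """

    scores: np.ndarray  # (4, L) integer
    name: str = "pssm"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[0] != 4 or scores.shape[1] < 1:
            raise ValueError("PSSM scores must be a 4 x L matrix with L >= 1")
        if not np.all(np.isfinite(scores)):
            raise ValueError("PSSM scores must be finite")
        object.__setattr__(self, "scores", scores.astype(np.int64))

    @property
    def length(self) -> int:
        return int(self.scores.shape[1])

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        scale: int = SCORE_SCALE,
        name: str = "pssm",
    ) -> "PSSM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("count matrix must be 4 x L (rows A, C, G, T)")
        colsum = counts.sum(axis=0)
        probs = (counts + pseudocount) / (colsum + 4.0 * pseudocount)
        scores = np.rint(scale * np.log2(probs / 0.25)).astype(np.int64)
        return cls(scores=scores, name=name)

    def reverse_complement(self) -> "PSSM":
        """Matrix for scoring the reverse strand: complement the base rows
        (A<->T, C<->G) and reverse the column order."""
        return PSSM(scores=self.scores[::-1, ::-1].copy(), name=f"{self.name}(rc)")


def read_jaspar_pfm(path, name: str | None = None, scale: int = SCORE_SCALE) -> PSSM:
    """Read a JASPAR-style position frequency matrix from text.

    Accepts the 4-row raw layout or the bracketed JASPAR format
    (``A [ 1 2 3 ]``); a ``>`` header line supplies the name.
    """
    rows: list[list[float]] = []
    header = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:].strip() or None
            continue
        line = line.replace("[", " ").replace("]", " ")
        fields = line.split()
        if fields and fields[0].upper() in _BASE_INDEX and not _is_number(fields[0]):
            fields = fields[1:]
        rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise ValueError(f"expected 4 matrix rows in {path}, found {len(rows)}")
    counts = np.array(rows)
    return PSSM.from_counts(counts, scale=scale, name=name or header or Path(path).stem)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def score_segment(pssm: PSSM, segment: str) -> int:
    """Score of one DNA segment: the sum of the matched column scores."""
    if len(segment) != pssm.length:
        raise ValueError(
            f"segment length {len(segment)} != matrix length {pssm.length}"
        )
    try:
        idx = [_BASE_INDEX[b] for b in segment.upper()]
    except KeyError as exc:
        raise ValueError(f"segment contains a non-ACGT base: {exc}") from exc
    return int(sum(pssm.scores[i, c] for c, i in enumerate(idx)))


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact lattice distribution of segment scores under the equal-base null."""

    step: float
    min_score: int  # lattice units
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))

    def support(self) -> np.ndarray:
        """Attainable lattice scores (in lattice units)."""
        return self.min_score + np.arange(self.probs.size)

    def tail_probabilities(self) -> np.ndarray:
        """P(S >= s) for each lattice point s of the support."""
        return np.cumsum(self.probs[::-1])[::-1]


def score_distribution(
    pssm: PSSM, lattice_step: float = 1.0, max_rounding_error: float | None = None
) -> ScoreDistribution:
    """Exact null score distribution by iterated per-column convolution.

    Each column contributes a uniform-1/4 distribution over its four (lattice
    rounded) scores; the L column distributions are convolved.  Integer
    matrices with ``lattice_step = 1`` incur no rounding at all.
    """
    if lattice_step <= 0:
        raise ValueError("lattice_step must be > 0")
    lat = np.rint(pssm.scores / lattice_step).astype(np.int64)
    err = float(np.abs(pssm.scores - lat * lattice_step).max(axis=0).sum())
    if max_rounding_error is not None and err > max_rounding_error:
        warnings.warn(
            f"lattice step {lattice_step} too coarse: worst-case rounding error "
            f"{err:.3g} exceeds {max_rounding_error:.3g}",
            RuntimeWarning,
        )
    lo = int(lat.min(axis=0).sum())
    hi = int(lat.max(axis=0).sum())
    probs = np.zeros(hi - lo + 1)
    # running distribution over offsets relative to the running minimum
    cur = np.array([1.0])
    cur_min = 0
    for c in range(pssm.length):
        col = lat[:, c]
        cmin = int(col.min())
        width = int(col.max()) - cmin
        nxt = np.zeros(cur.size + width)
        for s in col:
            nxt[s - cmin : s - cmin + cur.size] += 0.25 * cur
        cur = nxt
        cur_min += cmin
    probs[cur_min - lo : cur_min - lo + cur.size] = cur
    return ScoreDistribution(step=float(lattice_step), min_score=lo, probs=probs)


def score_pvalue(dist: ScoreDistribution, score: float) -> float:
    """Exact p-value: probability of observing ``score`` or higher under the
    equal-base null.  Monotone non-increasing in the score."""
    k = int(np.ceil(score / dist.step - 1e-9))
    if k <= dist.min_score:
        return 1.0
    idx = k - dist.min_score
    if idx >= dist.probs.size:
        return 0.0
    return float(min(1.0, dist.probs[idx:].sum()))


class MotifSite(NamedTuple):
    """One motif hit: center coordinate (1-based), strand, lattice score,
    exact p-value."""

    pos: int
    strand: str
    score: int
    pvalue: float


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.size, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def _window_scores(scores: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every length-L window; invalid windows (non-ACGT) flagged."""
    L = scores.shape[1]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(idx >= 0, idx, 0)
    for c in range(L):
        sl = slice(c, c + n)
        total += scores[safe[sl], c]
        valid &= idx[sl] >= 0
    return total, valid


def scan_sequence(
    pssm: PSSM,
    sequence: str,
    pvalue_cutoff: float = 5e-6,
    dist: ScoreDistribution | None = None,
    offset: int = 0,
) -> list[MotifSite]:
    """Scan both strands of a sequence for motif sites with p <= cutoff.

    The reverse strand is scanned with the reverse-complemented matrix (its
    null score distribution is identical, so one distribution serves both).
    A site's coordinate is the center of the matched window, 1-based:
    window_start + L//2 (+ ``offset`` for subsequences).  Overlapping hits are
    all reported.
    """
    L = pssm.length
    if len(sequence) < L:
        return []
    if dist is None:
        dist = score_distribution(pssm, lattice_step=1.0)
    tails = dist.tail_probabilities()
    passing = np.nonzero(tails <= pvalue_cutoff)[0]
    if passing.size == 0:
        return []
    threshold = int(dist.support()[passing[0]])

    idx = _encode(sequence)
    sites: list[MotifSite] = []
    for strand, matrix in (("+", pssm.scores), ("-", pssm.reverse_complement().scores)):
        total, valid = _window_scores(matrix, idx)
        hits = np.nonzero(valid & (total >= threshold))[0]
        for h in hits:
            s = int(total[h])
            sites.append(
                MotifSite(
                    pos=offset + int(h) + 1 + L // 2,
                    strand=strand,
                    score=s,
                    pvalue=score_pvalue(dist, s),
                )
            )
    sites.sort(key=lambda site: (site.pos, site.strand))
    return sites
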