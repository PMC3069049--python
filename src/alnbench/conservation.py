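"""Residue similarity, the mean-distance (MD) objective-function family,
and position-specific profiles.

The column conservation measure is ``similarity = 1 - MD`` where MD is the
mean, over all unordered pairs of alignment rows at a column, of a
normalised substitution distance

    d(a, b) = 1 - S(a, b) / sqrt(S(a, a) * S(b, b)),   clipped to [0, 1],

with BLOSUM62 as the default score matrix. A gap is treated as maximally
distant: every pair involving a gap (including gap-gap) contributes
distance 1. With the pair denominator fixed at C(n, 2) this makes the
alignment-level normalised score (``normd``) provably bounded by the value
an alignment of identical sequences would attain.

``normd`` divides the column-score sum by the mean ungapped sequence
length — the score an alignment of identical, ungapped sequences of those
lengths would reach — so identical sequences score exactly 1.0 and padding
with near-empty columns strictly lowers the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .align_io import ALPHABET, GAP, Alignment

_IDX = {ch: i for i, ch in enumerate(ALPHABET)}
N_SYM = len(ALPHABET)  # 20 amino acids + X

DEFAULT_GAP_DISTANCE = 1.0


class SubstitutionModel:
    """A symmetric log-odds score matrix plus its normalised distance.

    ``scores`` is a (21, 21) integer-valued array over the alphabet
    ``ACDEFGHIKLMNPQRSTVWYX``; ``distance`` is the derived d(a, b) above.
    Loadable from any NCBI-format matrix file; BLOSUM62 is the default.
    """

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (N_SYM, N_SYM):
            raise ValueError(f"expected {(N_SYM, N_SYM)} matrix, got {scores.shape}")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.name = name
        self.scores = scores
        diag = np.diag(scores)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(np.outer(diag, diag))
            d = 1.0 - scores / denom
        # Self-distance is 0 by definition; pairs whose self-scores are not
        # both positive (only X in BLOSUM62) fall back to maximal distance.
        bad = (diag[:, None] <= 0) | (diag[None, :] <= 0)
        d = np.where(bad, 1.0, d)
        np.fill_diagonal(d, 0.0)
        self.distance = np.clip(d, 0.0, 1.0)

    @classmethod
    def from_name(cls, name: str = "BLOSUM62") -> "SubstitutionModel":
        mat = substitution_matrices.load(name)
        return cls._from_biopython(mat, name)

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionModel":
        """Load an NCBI-format substitution matrix file."""
        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        return cls._from_biopython(mat, str(path))

    @classmethod
    def _from_biopython(cls, mat, name: str) -> "SubstitutionModel":
        scores = np.zeros((N_SYM, N_SYM))
        alpha = mat.alphabet
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                aa = a if a in alpha else "X"
                bb = b if b in alpha else "X"
                scores[i, j] = mat[aa, bb]
        return cls(scores, name)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_IDX[a], _IDX[b]])

    def d(self, a: str, b: str) -> float:
        return float(self.distance[_IDX[a], _IDX[b]])


_default_model: SubstitutionModel | None = None


def default_model() -> SubstitutionModel:
    global _default_model
    if _default_model is None:
        _default_model = SubstitutionModel.from_name("BLOSUM62")
    return _default_model


# ---------------------------------------------------------------------------
# Column similarity and norMD
# ---------------------------------------------------------------------------

def column_similarity(
    residues,
    model: SubstitutionModel | None = None,
    gap_distance: float = DEFAULT_GAP_DISTANCE,
) -> float:
    """1 - MD for one alignment column (a sequence of residues/gaps).

    Requires at least two contributors; returns NaN otherwise. The result
    is permutation-invariant and bounded in [0, 1].
    """
    model = model or default_model()
    col = list(residues)
    n = len(col)
    if n < 2:
        return math.nan
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = col[i], col[j]
            if a == GAP or b == GAP:
                total += gap_distance
            else:
                total += model.d(a, b)
            npairs += 1
    return 1.0 - total / npairs


def _column_similarities(
    aln: Alignment,
    model: SubstitutionModel,
    gap_distance: float = DEFAULT_GAP_DISTANCE,
) -> np.ndarray:
    """Vectorised per-column 1 - MD; singleton alignments score 1 at
    residue columns and 0 at gap columns (a sequence trivially agrees
    with itself)."""
    rows = np.array([[_IDX.get(ch, -1) if ch != GAP else -1 for ch in s]
                     for s in aln.seqs], dtype=np.int64)
    n, m = rows.shape
    if n == 1:
        return (rows[0] >= 0).astype(float)
    sims = np.empty(m)
    dist = model.distance
    npairs = n * (n - 1) / 2
    for c in range(m):
        col = rows[:, c]
        res = col[col >= 0]
        k = len(res)
        # pairs involving >=1 gap all contribute gap_distance
        gap_pairs = npairs - k * (k - 1) / 2
        total = gap_pairs * gap_distance
        if k >= 2:
            sub = dist[np.ix_(res, res)]
            total += sub[np.triu_indices(k, 1)].sum()
        sims[c] = 1.0 - total / npairs
    return sims


def window_score(
    aln: Alignment,
    window: int = 5,
    model: SubstitutionModel | None = None,
    gap_distance: float = DEFAULT_GAP_DISTANCE,
) -> np.ndarray:
    """Sliding-window mean of column similarity, truncated at the ends.

    ``window`` must be odd; ``window=1`` returns the raw per-column vector.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    model = model or default_model()
    raw = _column_similarities(aln, model, gap_distance)
    if window == 1:
        return raw
    half = window // 2
    m = len(raw)
    out = np.empty(m)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    for c in range(m):
        lo = max(0, c - half)
        hi = min(m, c + half + 1)
        out[c] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def normd(
    aln: Alignment,
    model: SubstitutionModel | None = None,
    gap_distance: float = DEFAULT_GAP_DISTANCE,
) -> float:
    """Size-normalised mean-distance objective function of an alignment.

    Column scores (1 - MD) are summed over the full alignment length and
    divided by the maximum attainable sum given the unaligned sequence
    lengths — the mean ungapped length, which is what an alignment of
    identical copies would score.
    """
    if aln.n_seqs < 2:
        raise ValueError("normd requires at least 2 sequences")
    model = model or default_model()
    sims = _column_similarities(aln, model, gap_distance)
    mean_len = float(np.mean([aln.ungapped_length(i) for i in aln.ids]))
    if mean_len == 0:
        raise ValueError("alignment contains no residues")
    return float(np.clip(sims, 0.0, None).sum() / mean_len)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Profile:
    """A Gribskov average-score profile.

    ``weights`` has one row per column: the sequence-weighted mean of the
    substitution-matrix rows of the residues observed there (a gap
    contributes nothing). ``occupancy`` is the weighted non-gap fraction.
    """

    weights: np.ndarray  # (length, 21)
    occupancy: np.ndarray  # (length,)
    background: np.ndarray | None = None  # expected weight vector of a
    # random residue; subtracted before profile-profile comparison so the
    # large component common to all score-matrix rows does not inflate
    # the similarity of unrelated profiles

    def __post_init__(self):
        if self.weights.ndim != 2 or self.weights.shape[1] != N_SYM:
            raise ValueError("profile weights must be (length, 21)")
        if len(self.occupancy) != len(self.weights):
            raise ValueError("occupancy length mismatch")

    def centered(self) -> np.ndarray:
        if self.background is None:
            return self.weights
        return self.weights - self.background

    @property
    def length(self) -> int:
        return len(self.weights)


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalised to
    mean 1. Gapped cells collect no weight."""
    n, m = aln.n_seqs, aln.n_cols
    w = np.zeros(n)
    for c in range(m):
        col = [s[c] for s in aln.seqs]
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch != GAP:
                w[i] += 1.0 / (r * counts[ch])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def build_profile(
    aln: Alignment,
    seq_weights: np.ndarray | None = None,
    model: SubstitutionModel | None = None,
) -> Profile:
    """Build a weighted average-score profile from a (sub-)alignment."""
    if aln.n_seqs < 1 or aln.n_cols < 1:
        raise ValueError("cannot build a profile from an empty alignment")
    model = model or default_model()
    if seq_weights is None:
        seq_weights = henikoff_weights(aln)
    seq_weights = np.asarray(seq_weights, dtype=float)
    if len(seq_weights) != aln.n_seqs:
        raise ValueError("one weight per sequence required")
    total_w = seq_weights.sum()
    weights = np.zeros((aln.n_cols, N_SYM))
    occ = np.zeros(aln.n_cols)
    for c in range(aln.n_cols):
        wsum = 0.0
        vec = np.zeros(N_SYM)
        for s, wt in zip(aln.seqs, seq_weights):
            ch = s[c]
            if ch == GAP:
                continue
            vec += wt * model.scores[_IDX[ch]]
            wsum += wt
        if wsum > 0:
            weights[c] = vec / wsum
            occ[c] = wsum / total_w
    return Profile(
        weights=weights, occupancy=occ,
        background=model.scores[:20].mean(axis=0),
    )


def score_segment(profile: Profile, segment: str) -> float:
    """Length-normalised profile score of a gapped segment.

    The segment must span exactly the profile's columns; a gap scores 0.
    """
    if len(segment) != profile.length:
        raise ValueError(
            f"segment length {len(segment)} != profile length {profile.length}"
        )
    total = 0.0
    for c, ch in enumerate(segment):
        if ch != GAP:
            total += profile.weights[c, _IDX[ch]]
    return total / profile.length


def profile_profile_similarity(
    p1: Profile, p2: Profile, min_overlap: int = 3
) -> tuple[float, int]:
    """Best ungapped sliding-offset similarity of two profiles.

    Each offset is scored as the mean cosine similarity of the overlapping
    background-centered column weight vectors (in [-1, 1] per pair;
    unrelated profiles score near 0, identical ones 1). Returns
    ``(best_score, best_offset)`` where offset k aligns column 0 of ``p2``
    with column k of ``p1`` (k may be negative). Ties prefer the smallest
    |offset|.
    """
    if p1.length == 0 or p2.length == 0:
        raise ValueError("empty profile")
    min_overlap = min(min_overlap, p1.length, p2.length)

    w1, w2 = p1.centered(), p2.centered()
    n1 = np.linalg.norm(w1, axis=1)
    n2 = np.linalg.norm(w2, axis=1)
    best: tuple[float, int] | None = None
    for k in range(-(p2.length - min_overlap), p1.length - min_overlap + 1):
        lo1, hi1 = max(0, k), min(p1.length, k + p2.length)
        lo2, hi2 = lo1 - k, hi1 - k
        dots = np.einsum("ij,ij->i", w1[lo1:hi1], w2[lo2:hi2])
        denom = n1[lo1:hi1] * n2[lo2:hi2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, dots / denom, 0.0)
        score = float(np.mean(cos))
        if (
            best is None
            or score > best[0] + 1e-12
            or (abs(score - best[0]) <= 1e-12 and abs(k) < abs(best[1]))
        ):
            best = (score, k)
    assert best is not None
    return best
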