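"""Block-aware evaluation of test alignments against an annotated
reference.

For each reference block *b* with *n_b* member sequences and *m_b*
columns, column *i* scores C_bi = 1 when all member residues of that
reference column co-occur in a single test-alignment column, else 0.

* BCS (block column score) = mean C_bi over the block's columns; each
  block tops out at 1 regardless of how many sequences carry it.
* CS (column score) = sum_b n_b * BCS_b / sum_b n_b — the per-block means
  weighted by the number of sequences in the block. Regions outside
  blocks never contribute.
* The combined score takes, per block, the maximum BCS over several
  programs' alignments and averages those maxima unweighted — the score
  a single alignment assembling every program's best-aligned blocks
  would reach.

Correctness is judged on block members only: residues of non-member
sequences sharing a test column are ignored, and a member gapped at the
reference column contributes nothing to the column's correctness set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align_io import GAP, Alignment, BlockAnnotation
from .blocks import BlockAttributes


class SequenceMismatchError(ValueError):
    """Reference and test alignments disagree on sequence content."""


def _residue_column_maps(aln: Alignment) -> dict[str, list[int]]:
    """Per sequence, the alignment column of each residue (by residue index)."""
    maps: dict[str, list[int]] = {}
    for sid, s in zip(aln.ids, aln.seqs):
        maps[sid] = [c for c, ch in enumerate(s) if ch != GAP]
    return maps


def check_same_content(ref: Alignment, test: Alignment) -> None:
    """Test alignment must contain exactly the reference sequences, with
    identical residues up to gapping."""
    if set(ref.ids) != set(test.ids):
        missing = sorted(set(ref.ids) ^ set(test.ids))
        raise SequenceMismatchError(f"sequence id sets differ: {missing}")
    for sid in ref.ids:
        if ref.ungapped(sid) != test.ungapped(sid):
            raise SequenceMismatchError(
                f"sequence '{sid}' differs between reference and test"
            )


@dataclass(frozen=True)
class ScoreReport:
    """CS of one test alignment plus its per-block BCS values."""

    program_label: str
    cs: float
    per_block: dict[str, float]  # block_id -> BCS
    block_sizes: dict[str, int]  # block_id -> n_b

    def mean_bcs(self) -> float:
        return float(np.mean(list(self.per_block.values())))


@dataclass(frozen=True)
class CombinedReport:
    per_block_max: dict[str, tuple[float, str]]  # block_id -> (bcs, program)
    mean_combined: float


class BlockScorer:
    """Scores one or more test alignments against a fixed annotated
    reference; the reference residue->column maps are built once."""

    def __init__(self, ref: Alignment, blocks: list[BlockAnnotation]):
        if not blocks:
            raise ValueError("at least one block required")
        for b in blocks:
            b.validate(ref)
        self.ref = ref
        self.blocks = blocks
        self._ref_maps = _residue_column_maps(ref)

    def column_correct(
        self, block: BlockAnnotation, ref_col: int, test: Alignment,
        _test_maps: dict[str, list[int]] | None = None,
    ) -> int:
        """1 iff all member residues of the reference column land in one
        test column."""
        if not block.start <= ref_col < block.stop:
            raise ValueError(f"column {ref_col} outside block '{block.block_id}'")
        test_maps = _test_maps if _test_maps is not None else _residue_column_maps(test)
        test_cols = set()
        for sid in block.members:
            row = self.ref.row(sid)
            if row[ref_col] == GAP:
                continue
            ridx = sum(1 for ch in row[: ref_col] if ch != GAP)
            test_cols.add(test_maps[sid][ridx])
        if not test_cols:
            return 1  # no member residue present: vacuously correct
        return 1 if len(test_cols) == 1 else 0

    def block_column_score(
        self, block: BlockAnnotation, test: Alignment,
        _test_maps: dict[str, list[int]] | None = None,
    ) -> float:
        if _test_maps is None:
            check_same_content(self.ref, test)
            _test_maps = _residue_column_maps(test)
        vals = [
            self.column_correct(block, c, test, _test_maps=_test_maps)
            for c in range(block.start, block.stop)
        ]
        return float(np.mean(vals))

    def score(self, test: Alignment, program_label: str = "test") -> ScoreReport:
        """CS and per-block BCS of one test alignment."""
        check_same_content(self.ref, test)
        test_maps = _residue_column_maps(test)
        per_block: dict[str, float] = {}
        sizes: dict[str, int] = {}
        for b in self.blocks:
            per_block[b.block_id] = self.block_column_score(
                b, test, _test_maps=test_maps
            )
            sizes[b.block_id] = len(b.members)
        total_w = sum(sizes.values())
        cs = sum(sizes[bid] * bcs for bid, bcs in per_block.items()) / total_w
        return ScoreReport(
            program_label=program_label, cs=cs, per_block=per_block,
            block_sizes=sizes,
        )


def column_score(
    ref: Alignment, blocks: list[BlockAnnotation], test: Alignment
) -> float:
    """Convenience wrapper: the n_b-weighted CS of one test alignment."""
    return BlockScorer(ref, blocks).score(test).cs


def combine(reports: list[ScoreReport]) -> CombinedReport:
    """Per-block maximum BCS over programs, averaged unweighted.

    Ties go to the lexicographically first program label. All reports
    must cover the same block set.
    """
    if not reports:
        raise ValueError("no reports to combine")
    block_ids = set(reports[0].per_block)
    for r in reports[1:]:
        if set(r.per_block) != block_ids:
            raise ValueError(
                f"inconsistent block sets between '{reports[0].program_label}' "
                f"and '{r.program_label}'"
            )
    by_label = sorted(reports, key=lambda r: r.program_label)
    per_block_max: dict[str, tuple[float, str]] = {}
    for bid in sorted(block_ids):
        best_val, best_prog = -1.0, ""
        for r in by_label:  # ties keep the lexicographically first label
            if r.per_block[bid] > best_val:
                best_val, best_prog = r.per_block[bid], r.program_label
        per_block_max[bid] = (best_val, best_prog)
    mean_combined = float(np.mean([v for v, _ in per_block_max.values()]))
    return CombinedReport(per_block_max=per_block_max, mean_combined=mean_combined)


def correlate(x, y) -> float:
    """Pearson product-moment correlation with pairwise deletion of
    missing values; NaN when undefined (zero variance or < 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


_ATTR_NAMES = ("similarity", "length", "frequency", "disorder_frac")


def binned_means(
    scores: dict[str, float],
    attrs: dict[str, BlockAttributes],
    axes: tuple[str, str],
    edges: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean block score in each attribute-bin rectangle.

    Returns ``(means, counts)`` with shape (len(edges[0])-1,
    len(edges[1])-1); empty cells hold NaN. Values equal to the last edge
    fall in the last bin; blocks outside the edge range are dropped.
    """
    for ax in axes:
        if ax not in _ATTR_NAMES:
            raise ValueError(f"unknown attribute '{ax}'; choose from {_ATTR_NAMES}")
    e0 = np.asarray(edges[0], dtype=float)
    e1 = np.asarray(edges[1], dtype=float)
    for e in (e0, e1):
        if len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
    shape = (len(e0) - 1, len(e1) - 1)
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)

    def locate(v: float, e: np.ndarray) -> int | None:
        if v < e[0] or v > e[-1]:
            return None
        if v == e[-1]:
            return len(e) - 2
        return int(np.searchsorted(e, v, side="right")) - 1

    for bid, score in scores.items():
        a = attrs[bid]
        i = locate(getattr(a, axes[0]), e0)
        j = locate(getattr(a, axes[1]), e1)
        if i is None or j is None:
            continue
        sums[i, j] += score
        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts
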