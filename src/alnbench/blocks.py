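"""Subfamily partitioning, conserved-block detection, cross-subfamily
block merging, and block/global attribute computation.

A block is a reference-alignment region of at least ``min_cols`` columns
whose sliding-window conservation (window length 5 by default) stays above
a threshold (0.2 by default), computed on the sub-alignment of one
subfamily. Blocks found independently in several subfamilies are merged
when their column intervals overlap and their profiles agree, which lets
merged blocks span any subset of the sequences — including rare blocks
present in only a small fraction of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align_io import GAP, Alignment, BlockAnnotation, DisorderAnnotation
from .conservation import (
    Profile,
    SubstitutionModel,
    build_profile,
    default_model,
    column_similarity,
    normd,
    profile_profile_similarity,
    window_score,
)

DEFAULT_WINDOW = 5
DEFAULT_THRESHOLD = 0.2
DEFAULT_MIN_COLS = 3
DEFAULT_MERGE_THRESHOLD = 0.5

# Elbow rule for cutting the UPGMA dendrogram: split at the largest
# ratio between consecutive merge heights, smoothed by EPS; no split if
# the best ratio is below MIN_RATIO (one homogeneous family).
_ELBOW_EPS = 0.05
_ELBOW_MIN_RATIO = 2.0


@dataclass(frozen=True)
class Subfamily:
    """A cell of the sequence partition used to scope block finding and
    discrepancy detection."""

    id: str
    member_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class BlockAttributes:
    similarity: float  # mean 1-MD over block columns, members only
    length: float  # mean residues per member inside the interval
    frequency: float  # members / total sequences
    disorder_frac: float  # member residues inside disordered intervals


@dataclass(frozen=True)
class GlobalAttributes:
    n_seqs: int
    mean_len: float
    normd: float
    block_coverage: float  # fraction of non-gap cells inside blocks


# ---------------------------------------------------------------------------
# Subfamily partitioning
# ---------------------------------------------------------------------------

def percent_identity(a: str, b: str) -> float:
    """Identity over columns where both rows have residues (0 if none)."""
    both = matches = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


def partition_subfamilies(aln: Alignment) -> list[Subfamily]:
    """Deterministic partition into more-related subfamilies.

    UPGMA (average linkage) on pairwise percent-identity distances, cut at
    the largest relative gap between consecutive merge heights. If no gap
    ratio reaches the elbow threshold the family is kept whole. Identical
    sequences always land in one subfamily; singletons are permitted.
    """
    n = aln.n_seqs
    if n == 1:
        return [Subfamily("S1", aln.ids)]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - percent_identity(aln.seqs[i], aln.seqs[j])
            dmat[i, j] = dmat[j, i] = d
    z = linkage(squareform(dmat, checks=False), method="average")
    heights = z[:, 2]
    labels = None
    if len(heights) >= 2:
        hs = np.sort(heights)
        ratios = (hs[1:] + _ELBOW_EPS) / (hs[:-1] + _ELBOW_EPS)
        k = int(np.argmax(ratios))
        if ratios[k] >= _ELBOW_MIN_RATIO:
            cut = (hs[k] + hs[k + 1]) / 2.0
            labels = fcluster(z, t=cut, criterion="distance")
    if labels is None:
        labels = np.ones(n, dtype=int)
    # stable subfamily order: by first appearance in the alignment
    order: dict[int, list[str]] = {}
    for sid, lab in zip(aln.ids, labels):
        order.setdefault(int(lab), []).append(sid)
    subs = sorted(order.values(), key=lambda ids: aln.ids.index(ids[0]))
    return [Subfamily(f"S{i + 1}", tuple(ids)) for i, ids in enumerate(subs)]


# ---------------------------------------------------------------------------
# Block finding and merging
# ---------------------------------------------------------------------------

def find_subfamily_blocks(
    aln: Alignment,
    subfam: Subfamily,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_cols: int = DEFAULT_MIN_COLS,
    model: SubstitutionModel | None = None,
) -> list[BlockAnnotation]:
    """Maximal runs of >= min_cols columns whose windowed conservation on
    the subfamily sub-alignment exceeds ``threshold``.

    Run edges are trimmed back to columns whose *raw* similarity also
    exceeds the threshold: the sliding window otherwise bleeds
    conservation into flanking unconserved columns, padding short
    conserved runs up to block length and shifting block boundaries into
    linkers. Members are the subfamily sequences with at least one
    residue in the run; all-gap members are excluded.
    """
    if not subfam.member_ids:
        raise ValueError("empty subfamily")
    model = model or default_model()
    sub = aln.take_rows(subfam.member_ids)
    ws = window_score(sub, window=window, model=model)
    raw = window_score(sub, window=1, model=model)
    above = ws > threshold
    blocks: list[BlockAnnotation] = []
    c = 0
    k = 0
    m = len(above)
    while c < m:
        if above[c]:
            start = c
            while c < m and above[c]:
                c += 1
            end = c
            while start < end and raw[start] <= threshold:
                start += 1
            while end > start and raw[end - 1] <= threshold:
                end -= 1
            if end - start >= min_cols:
                members = frozenset(
                    sid
                    for sid in subfam.member_ids
                    if any(ch != GAP for ch in aln.row(sid)[start:end])
                )
                if members:
                    k += 1
                    blocks.append(
                        BlockAnnotation(
                            block_id=f"{subfam.id}_b{k}",
                            start=start,
                            stop=end,
                            members=members,
                        )
                    )
        else:
            c += 1
    return blocks


def _block_profile(
    aln: Alignment, block: BlockAnnotation, model: SubstitutionModel
) -> Profile:
    sub = aln.take_rows(sorted(block.members)).take_cols(block.start, block.stop)
    return build_profile(sub, model=model)


def merge_blocks(
    aln: Alignment,
    blocks_by_subfamily: dict[str, list[BlockAnnotation]],
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_cols: int = DEFAULT_MIN_COLS,
    model: SubstitutionModel | None = None,
) -> list[BlockAnnotation]:
    """Merge blocks shared between subfamilies.

    Blocks from different subfamilies whose column intervals overlap on
    the shared reference axis AND whose profile-profile similarity exceeds
    ``merge_threshold`` are unioned: members are merged and the interval
    is the intersection of the source intervals, extended outward while
    the windowed conservation of the merged membership stays above the
    block threshold. Blocks that merge into something shorter than
    ``min_cols`` are passed through unchanged instead.
    """
    model = model or default_model()
    flat: list[tuple[str, BlockAnnotation]] = [
        (sf, b) for sf, bs in blocks_by_subfamily.items() for b in bs
    ]
    nb = len(flat)
    profiles = [_block_profile(aln, b, model) for _, b in flat]
    parent = list(range(nb))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(nb):
        for j in range(i + 1, nb):
            sfi, bi = flat[i]
            sfj, bj = flat[j]
            if sfi == sfj:
                continue
            if bi.start >= bj.stop or bj.start >= bi.stop:
                continue  # no column overlap
            score, _ = profile_profile_similarity(profiles[i], profiles[j])
            if score > merge_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(nb):
        groups.setdefault(find(i), []).append(i)

    out: list[BlockAnnotation] = []
    for idxs in groups.values():
        if len(idxs) == 1:
            out.append(flat[idxs[0]][1])
            continue
        sources = [flat[i][1] for i in idxs]
        members = frozenset().union(*(b.members for b in sources))
        start = max(b.start for b in sources)
        stop = min(b.stop for b in sources)
        merged = _extend_interval(
            aln, members, start, stop, window, threshold, model
        )
        if merged is None or merged[1] - merged[0] < min_cols:
            out.extend(sources)
            continue
        bid = "+".join(sorted(b.block_id for b in sources))
        out.append(
            BlockAnnotation(
                block_id=bid, start=merged[0], stop=merged[1], members=members
            )
        )
    out.sort(key=lambda b: (b.start, b.block_id))
    return out


def _extend_interval(
    aln: Alignment,
    members: frozenset[str],
    start: int,
    stop: int,
    window: int,
    threshold: float,
    model: SubstitutionModel,
) -> tuple[int, int] | None:
    if stop <= start:
        return None
    sub = aln.take_rows(sorted(members))
    ws = window_score(sub, window=window, model=model)
    raw = window_score(sub, window=1, model=model)
    while start > 0 and ws[start - 1] > threshold:
        start -= 1
    while stop < aln.n_cols and ws[stop] > threshold:
        stop += 1
    while start < stop and raw[start] <= threshold:
        start += 1
    while stop > start and raw[stop - 1] <= threshold:
        stop -= 1
    if stop <= start:
        return None
    return start, stop


def find_blocks(
    aln: Alignment,
    subfamilies: list[Subfamily] | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_cols: int = DEFAULT_MIN_COLS,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    model: SubstitutionModel | None = None,
) -> list[BlockAnnotation]:
    """End-to-end block identification: partition into subfamilies, find
    per-subfamily blocks, merge shared blocks across subfamilies."""
    model = model or default_model()
    if subfamilies is None:
        subfamilies = partition_subfamilies(aln)
    per_sf = {
        sf.id: find_subfamily_blocks(
            aln, sf, window=window, threshold=threshold,
            min_cols=min_cols, model=model,
        )
        for sf in subfamilies
    }
    return merge_blocks(
        aln, per_sf, merge_threshold=merge_threshold, window=window,
        threshold=threshold, min_cols=min_cols, model=model,
    )


# ---------------------------------------------------------------------------
# Attributes
# ---------------------------------------------------------------------------

def block_attributes(
    block: BlockAnnotation,
    aln: Alignment,
    disorder: DisorderAnnotation | None = None,
    model: SubstitutionModel | None = None,
) -> BlockAttributes:
    """The four per-block attributes: similarity (1 - MD over members),
    mean member length, frequency, and disordered-residue fraction."""
    model = model or default_model()
    block.validate(aln)
    members = sorted(block.members)
    rows = [aln.row(sid)[block.start : block.stop] for sid in members]
    if len(members) >= 2:
        sims = [
            column_similarity([r[c] for r in rows], model=model)
            for c in range(block.n_cols)
        ]
        similarity = float(np.mean(sims))
    else:
        similarity = 1.0  # a single segment trivially agrees with itself
    res_counts = [sum(1 for ch in r if ch != GAP) for r in rows]
    length = float(np.mean(res_counts))
    frequency = len(members) / aln.n_seqs
    dis_res = 0
    tot_res = 0
    if disorder is not None:
        for sid in members:
            row = aln.row(sid)
            ungapped_before = sum(
                1 for ch in row[: block.start] if ch != GAP
            )
            k = ungapped_before
            for c in range(block.start, block.stop):
                if row[c] != GAP:
                    tot_res += 1
                    if disorder.is_disordered(sid, k):
                        dis_res += 1
                    k += 1
    else:
        tot_res = sum(res_counts)
    disorder_frac = dis_res / tot_res if tot_res else 0.0
    return BlockAttributes(
        similarity=similarity,
        length=length,
        frequency=frequency,
        disorder_frac=disorder_frac,
    )


def global_attributes(
    aln: Alignment,
    blocks: list[BlockAnnotation],
    model: SubstitutionModel | None = None,
) -> GlobalAttributes:
    """The four alignment-level attributes: sequence count, mean ungapped
    length, normd, and the fraction of residues covered by blocks (each
    cell counted once even under overlapping blocks)."""
    model = model or default_model()
    lengths = [aln.ungapped_length(i) for i in aln.ids]
    total_cells = sum(lengths)
    covered: set[tuple[str, int]] = set()
    for b in blocks:
        for sid in b.members:
            row = aln.row(sid)
            for c in range(b.start, b.stop):
                if row[c] != GAP:
                    covered.add((sid, c))
    coverage = len(covered) / total_cells if total_cells else 0.0
    nd = normd(aln, model=model) if aln.n_seqs >= 2 else float("nan")
    return GlobalAttributes(
        n_seqs=aln.n_seqs,
        mean_len=float(np.mean(lengths)),
        normd=nd,
        block_coverage=coverage,
    )
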