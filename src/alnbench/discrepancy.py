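"""Rule-based detection of fragmentary or mispredicted sequences in a
reference alignment.

Four empirical rules are applied per subfamily:

1. **terminal_error** — a sequence whose N- or C-terminal residue column
   falls outside the open window (Q1 - 10, Q3 + 10) of the subfamily's
   terminal-position distribution (badly predicted start/stop sites).
2. **outlier_segment** — a sequence scoring anomalously low against the
   weighted profile of a conserved core block (badly predicted exons);
   the flagged interval is extended to the nearest flanking core blocks
   in which the sequence scores normally, or to the sequence terminus.
3. **inserted_segment** — a run of >= 9 intervening columns occupied by a
   single sequence between two fully occupied columns i, j with
   j - i >= 10 (a retained intron).
4. **deleted_segment** — a run of >= 9 intervening columns in which a
   single sequence is gapped while all others have residues, between two
   fully occupied columns with j - i >= 10 (a missing exon).

Sequences flagged by the terminal rule are treated as fragments and
excluded from the occupancy counts of rules 3-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align_io import GAP, Alignment, BlockAnnotation
from .blocks import (
    DEFAULT_MIN_COLS,
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW,
    Subfamily,
    find_subfamily_blocks,
    partition_subfamilies,
)
from .conservation import (
    SubstitutionModel,
    build_profile,
    default_model,
    henikoff_weights,
    score_segment,
)

logger = logging.getLogger(__name__)

KINDS = ("outlier_segment", "terminal_error", "inserted_segment", "deleted_segment")

TERMINAL_MARGIN = 10  # columns beyond the quartiles still considered normal
MIN_INTERVENING_SPAN = 10  # the rule text's j - i >= 10
MIN_SUBFAMILY = 4  # quartile-based rules need at least this many members
DEFAULT_FENCE = 1.5  # Tukey fence multiplier on the IQR
DEFAULT_SCORE_FLOOR = 0.5  # flag only below this fraction of the median score


@dataclass(frozen=True)
class Discrepancy:
    seq_id: str
    kind: str
    start: int  # 0-based half-open columns
    stop: int
    terminal_side: str | None = None  # 'N' or 'C', terminal_error only
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown discrepancy kind '{self.kind}'")
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        if (self.kind == "terminal_error") != (self.terminal_side is not None):
            raise ValueError("terminal_side set iff kind is terminal_error")


@dataclass
class ReliabilityReport:
    """Per-sequence discrepancy flags plus the derived reliable set."""

    ids: tuple[str, ...]
    discrepancies: list[Discrepancy] = field(default_factory=list)

    @property
    def flagged_ids(self) -> set[str]:
        return {d.seq_id for d in self.discrepancies}

    @property
    def reliable_ids(self) -> list[str]:
        bad = self.flagged_ids
        return [i for i in self.ids if i not in bad]

    def for_sequence(self, seq_id: str) -> list[Discrepancy]:
        return [d for d in self.discrepancies if d.seq_id == seq_id]


# ---------------------------------------------------------------------------
# Rule 1: badly predicted start/stop sites
# ---------------------------------------------------------------------------

def detect_terminal_errors(
    aln: Alignment,
    subfam: Subfamily,
    margin: int = TERMINAL_MARGIN,
) -> list[Discrepancy]:
    """Flag members whose terminal residue column lies outside the open
    window (Q1 - margin, Q3 + margin) of the subfamily terminal positions.

    Quartiles use linear interpolation. A terminal exactly at a window
    edge is flagged (the window is open). Subfamilies with fewer than 4
    members yield no flags (a warning is logged).
    """
    if len(subfam) < MIN_SUBFAMILY:
        logger.warning(
            "subfamily %s has %d members (<%d); terminal rule skipped",
            subfam.id, len(subfam), MIN_SUBFAMILY,
        )
        return []
    out: list[Discrepancy] = []
    for side in ("N", "C"):
        if side == "N":
            terms = {s: aln.first_residue_column(s) for s in subfam.member_ids}
        else:
            terms = {s: aln.last_residue_column(s) for s in subfam.member_ids}
        vals = np.array([t for t in terms.values() if t is not None], dtype=float)
        if len(vals) < MIN_SUBFAMILY:
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        for sid, t in terms.items():
            if t is None:
                continue
            if t <= q1 - margin or t >= q3 + margin:
                out.append(
                    Discrepancy(
                        seq_id=sid,
                        kind="terminal_error",
                        start=t,
                        stop=t + 1,
                        terminal_side=side,
                        detail=(
                            f"{side}-terminal column {t + 1} outside "
                            f"({q1 - margin + 1:g}, {q3 + margin + 1:g})"
                        ),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Rule 2: badly predicted exons (outlier segments)
# ---------------------------------------------------------------------------

def core_blocks_of(
    aln: Alignment,
    subfam: Subfamily,
    blocks: list[BlockAnnotation] | None = None,
    model: SubstitutionModel | None = None,
    **block_kwargs,
) -> list[BlockAnnotation]:
    """Subfamily blocks present in a strict majority of subfamily members."""
    if blocks is None:
        blocks = find_subfamily_blocks(aln, subfam, model=model, **block_kwargs)
    majority = len(subfam) / 2.0
    return [b for b in blocks if len(b.members & set(subfam.member_ids)) > majority]


def detect_outlier_segments(
    aln: Alignment,
    subfam: Subfamily,
    core_blocks: list[BlockAnnotation],
    model: SubstitutionModel | None = None,
    fence: float = DEFAULT_FENCE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[Discrepancy]:
    """Flag members scoring anomalously low against a core block's profile.

    Per core block, every subfamily member's segment is scored against the
    weighted profile built from the *other* block members (leave-one-out:
    with position-based weights an anomalous segment otherwise receives a
    large weight and drags the profile toward itself, masking the very
    outlier being sought). The outlier threshold is the Tukey fence
    Q1 - fence*(Q3 - Q1); in addition the score must fall below
    ``score_floor`` times the median member score, which keeps
    small-sample quartile noise from flagging healthy sequences. Flagged
    intervals are extended to the nearest flanking core blocks where the
    sequence scores above threshold, or to the sequence terminus.
    """
    if len(subfam) < MIN_SUBFAMILY or not core_blocks:
        return []
    model = model or default_model()
    cores = sorted(core_blocks, key=lambda b: b.start)
    member_ids = list(subfam.member_ids)
    # score matrix: rows = members, cols = core blocks
    scores = np.zeros((len(member_ids), len(cores)))
    thresholds = np.zeros(len(cores))
    for j, blk in enumerate(cores):
        block_rows = sorted(blk.members & set(member_ids)) or sorted(blk.members)
        profiles: dict[str | None, object] = {}

        def loo_profile(exclude: str | None):
            if exclude not in profiles:
                rows = [r for r in block_rows if r != exclude] or block_rows
                sub = aln.take_rows(rows).take_cols(blk.start, blk.stop)
                profiles[exclude] = build_profile(
                    sub, seq_weights=henikoff_weights(sub), model=model
                )
            return profiles[exclude]

        for i, sid in enumerate(member_ids):
            seg = aln.row(sid)[blk.start : blk.stop]
            prof = loo_profile(sid if sid in block_rows else None)
            scores[i, j] = score_segment(prof, seg)
        q1, q3 = np.percentile(scores[:, j], [25, 75])
        med = np.median(scores[:, j])
        thresholds[j] = min(q1 - fence * (q3 - q1), score_floor * med)
    out: list[Discrepancy] = []
    per_seq: dict[str, list[tuple[int, int, str]]] = {}
    for i, sid in enumerate(member_ids):
        for j, blk in enumerate(cores):
            if scores[i, j] >= thresholds[j]:
                continue
            # extend outward to the nearest well-scoring core blocks
            left = None
            for jj in range(j - 1, -1, -1):
                if scores[i, jj] >= thresholds[jj]:
                    left = cores[jj]
                    break
            right = None
            for jj in range(j + 1, len(cores)):
                if scores[i, jj] >= thresholds[jj]:
                    right = cores[jj]
                    break
            first = aln.first_residue_column(sid)
            last = aln.last_residue_column(sid)
            if first is None:
                continue
            start = left.stop if left is not None else first
            stop = right.start if right is not None else last + 1
            start = min(start, blk.start)
            stop = max(stop, blk.stop)
            per_seq.setdefault(sid, []).append(
                (start, stop, blk.block_id)
            )
    for sid, ivs in per_seq.items():
        for a, b, detail in _merge_flag_intervals(ivs):
            out.append(
                Discrepancy(
                    seq_id=sid,
                    kind="outlier_segment",
                    start=a,
                    stop=b,
                    detail=f"low profile score in core block(s) {detail}",
                )
            )
    return out


def _merge_flag_intervals(
    ivs: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, list[str]]] = []
    for a, b, tag in sorted(ivs):
        if merged and a <= merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], b), prev[2] + [tag])
        else:
            merged.append((a, b, [tag]))
    return [(a, b, ",".join(tags)) for a, b, tags in merged]


# ---------------------------------------------------------------------------
# Rules 3-4: inserted introns / missing exons
# ---------------------------------------------------------------------------

def _occupancy_runs(
    aln: Alignment, members: list[str]
) -> tuple[np.ndarray, list[int]]:
    """Per-column residue counts over ``members`` and the fully occupied
    column indices."""
    n = len(members)
    rows = [aln.row(sid) for sid in members]
    occ = np.array(
        [sum(1 for r in rows if r[c] != GAP) for c in range(aln.n_cols)]
    )
    full = [c for c in range(aln.n_cols) if occ[c] == n]
    return occ, full


def detect_inserted_segments(
    aln: Alignment,
    subfam: Subfamily,
    excluded: set[str] | None = None,
    min_span: int = MIN_INTERVENING_SPAN,
) -> list[Discrepancy]:
    """A single sequence's residues spanning >= min_span - 1 intervening
    columns between two fully occupied columns i, j (occupancy exactly 1
    at every strictly intervening column, j - i >= min_span)."""
    excluded = excluded or set()
    members = [s for s in subfam.member_ids if s not in excluded]
    if len(members) < 2:
        return []
    rows = {sid: aln.row(sid) for sid in members}
    occ, full = _occupancy_runs(aln, members)
    out: list[Discrepancy] = []
    for i, j in zip(full, full[1:]):
        if j - i < min_span:
            continue
        between = range(i + 1, j)
        if not all(occ[k] == 1 for k in between):
            continue
        owners = set()
        for k in between:
            owners.update(sid for sid in members if rows[sid][k] != GAP)
        if len(owners) != 1:
            continue
        sid = owners.pop()
        out.append(
            Discrepancy(
                seq_id=sid,
                kind="inserted_segment",
                start=i + 1,
                stop=j,
                detail=f"single-sequence run of {j - i - 1} columns",
            )
        )
    return out


def detect_deleted_segments(
    aln: Alignment,
    subfam: Subfamily,
    excluded: set[str] | None = None,
    min_span: int = MIN_INTERVENING_SPAN,
) -> list[Discrepancy]:
    """A single sequence gapped across >= min_span - 1 intervening columns
    while every other member has residues there (occupancy N - 1 at every
    strictly intervening column, full boundary columns, j - i >= min_span)."""
    excluded = excluded or set()
    members = [s for s in subfam.member_ids if s not in excluded]
    n = len(members)
    if n < 2:
        return []
    rows = {sid: aln.row(sid) for sid in members}
    occ, full = _occupancy_runs(aln, members)
    out: list[Discrepancy] = []
    for i, j in zip(full, full[1:]):
        if j - i < min_span:
            continue
        between = range(i + 1, j)
        if not all(occ[k] == n - 1 for k in between):
            continue
        absent = None
        ok = True
        for k in between:
            missing = [sid for sid in members if rows[sid][k] == GAP]
            if len(missing) != 1:
                ok = False
                break
            if absent is None:
                absent = missing[0]
            elif absent != missing[0]:
                ok = False
                break
        if not ok or absent is None:
            continue
        out.append(
            Discrepancy(
                seq_id=absent,
                kind="deleted_segment",
                start=i + 1,
                stop=j,
                detail=f"all-gap run of {j - i - 1} columns",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def scan(
    aln: Alignment,
    subfamilies: list[Subfamily] | None = None,
    core_blocks: dict[str, list[BlockAnnotation]] | None = None,
    model: SubstitutionModel | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_cols: int = DEFAULT_MIN_COLS,
    fence: float = DEFAULT_FENCE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> ReliabilityReport:
    """Apply all four rules in order terminal -> outlier -> inserted ->
    deleted, per subfamily, with terminal-flagged sequences excluded from
    the occupancy counts of rules 3-4.

    An outlier flag whose interval overlaps a terminal/inserted/deleted
    flag on the same sequence is dropped (the more specific rule wins),
    so a single planted error yields a single flag.
    """
    model = model or default_model()
    if subfamilies is None:
        subfamilies = partition_subfamilies(aln)
    report = ReliabilityReport(ids=aln.ids)
    for sf in subfamilies:
        terminal = detect_terminal_errors(aln, sf)
        excluded = {d.seq_id for d in terminal}
        if core_blocks is not None:
            cores = core_blocks.get(sf.id, [])
        else:
            cores = core_blocks_of(
                aln, sf, model=model,
                window=window, threshold=threshold, min_cols=min_cols,
            )
        outliers = detect_outlier_segments(
            aln, sf, cores, model=model, fence=fence, score_floor=score_floor
        )
        inserted = detect_inserted_segments(aln, sf, excluded=excluded)
        deleted = detect_deleted_segments(aln, sf, excluded=excluded)
        specific = terminal + inserted + deleted
        kept_outliers = []
        for d in outliers:
            clash = any(
                o.seq_id == d.seq_id and d.start < o.stop + 1 and o.start < d.stop + 1
                for o in specific
            )
            if not clash:
                kept_outliers.append(d)
        report.discrepancies.extend(terminal + kept_outliers + inserted + deleted)
    report.discrepancies.sort(key=lambda d: (d.seq_id, d.start, d.kind))
    return report


def filter_reliable(
    aln: Alignment,
    report: ReliabilityReport,
    blocks: list[BlockAnnotation] | None = None,
) -> tuple[Alignment, list[BlockAnnotation] | None]:
    """Sub-alignment of the reliable sequences with all-gap columns
    removed; block annotations are re-projected onto the new column axis.

    Raises if no sequence survives.
    """
    keep = report.reliable_ids
    if not keep:
        raise ValueError("no reliable sequences remain")
    sub = aln.take_rows(keep)
    sub, kept_cols = sub.drop_allgap_columns()
    if blocks is None:
        return sub, None
    old_to_new = {c: i for i, c in enumerate(kept_cols)}
    new_blocks: list[BlockAnnotation] = []
    for b in blocks:
        cols = [old_to_new[c] for c in range(b.start, b.stop) if c in old_to_new]
        members = frozenset(
            sid for sid in b.members
            if sid in set(keep)
            and any(
                sub.row(sid)[c] != GAP for c in cols
            )
        )
        if not cols or not members:
            continue
        new_blocks.append(
            BlockAnnotation(
                block_id=b.block_id,
                start=min(cols),
                stop=max(cols) + 1,
                members=members,
            )
        )
    return sub, new_blocks
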