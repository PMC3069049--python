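"""Synthetic protein families with planted ground truth.

The generator emulates the structure of curated reference alignments:
sequences fall into subfamilies, conserved blocks of a chosen similarity
are shared by arbitrary subsets of subfamilies (giving a wide block
frequency spectrum including rare blocks), blocks may be marked natively
disordered (low-complexity, with an explicit annotation), and linkers
between blocks are drawn independently per sequence so they are
unalignable by construction. Planted discrepancies reproduce the four
error shapes the detection rules target, and ``corrupt_alignment``
produces test alignments with an analytically known column score.

Mutations are per-site substitutions only — indels live in linkers and
planted discrepancies — so every planted coordinate is exact. All
randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align_io import (
    AA20,
    GAP,
    Alignment,
    BlockAnnotation,
    DisorderAnnotation,
)
from .blocks import Subfamily
from .conservation import SubstitutionModel, column_similarity, default_model
from .discrepancy import Discrepancy

DISORDER_ALPHABET = "AEGKPQST"  # low-complexity residue pool
SIMILARITY_TOL = 0.1  # accepted deviation of realized from target similarity
MAX_CALIBRATION_ATTEMPTS = 100


@dataclass(frozen=True)
class BlockSpec:
    """One planted block: its length in columns, the subfamilies carrying
    it, the target mean column similarity, and a disorder flag."""

    length: int
    subfamilies: tuple[int, ...]
    similarity: float = 0.9
    disordered: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("block length must be positive")
        if not 0 < self.similarity <= 1:
            raise ValueError("target similarity must be in (0, 1]")
        if not self.subfamilies:
            raise ValueError("a block needs at least one subfamily")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family; the seed is mandatory."""

    subfamily_sizes: tuple[int, ...]
    blocks: tuple[BlockSpec, ...]
    seed: int
    linker_length: int = 15
    linker_jitter: int = 3
    divergence_ratio: float = 3.0  # subfamily consensus rate / member rate
    plants: tuple[tuple[str, int, int], ...] = ()  # (kind, subfamily, magnitude)

    def __post_init__(self):
        if not self.subfamily_sizes or any(s <= 0 for s in self.subfamily_sizes):
            raise ValueError("subfamily sizes must be positive")
        if self.linker_length < 0 or self.linker_jitter < 0:
            raise ValueError("linker parameters must be non-negative")
        for b in self.blocks:
            if any(not 0 <= s < len(self.subfamily_sizes) for s in b.subfamilies):
                raise ValueError("block references unknown subfamily")


@dataclass
class SyntheticTruth:
    """A generated family plus everything planted in it."""

    alignment: Alignment
    blocks: list[BlockAnnotation]
    subfamilies: list[Subfamily]
    discrepancies: list[Discrepancy]
    disorder: DisorderAnnotation


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

_replacement_cache: dict[int, np.ndarray] = {}


def _replacement_table(model: SubstitutionModel) -> np.ndarray:
    """P(b | a) over the 20 amino acids, proportional to exp(S(a,b)/2)
    with self-replacement excluded."""
    key = id(model)
    if key not in _replacement_cache:
        s = model.scores[:20, :20]
        p = np.exp(s / 2.0)
        np.fill_diagonal(p, 0.0)
        _replacement_cache[key] = p / p.sum(axis=1, keepdims=True)
    return _replacement_cache[key]


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    model: SubstitutionModel | None = None,
    alphabet: str | None = None,
) -> str:
    """Per-site substitution at probability ``rate``.

    Replacements are drawn from a BLOSUM-conditioned distribution given
    the current residue, or uniformly from ``alphabet`` (minus the
    current residue) when one is given (used for low-complexity
    disordered segments).
    """
    model = model or default_model()
    table = _replacement_table(model)
    idx = {ch: i for i, ch in enumerate(AA20)}
    out = []
    for ch in seq:
        if ch not in idx or rng.random() >= rate:
            out.append(ch)
            continue
        if alphabet is not None:
            choices = [c for c in alphabet if c != ch] or [ch]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(AA20[rng.choice(20, p=table[idx[ch]])])
    return "".join(out)


def _realize_block(
    spec: BlockSpec,
    members_by_subfam: list[list[int]],
    rate: float,
    ratio: float,
    rng: np.random.Generator,
    model: SubstitutionModel,
) -> dict[int, str]:
    """Draw member segments for one block at a given member mutation rate."""
    alphabet = DISORDER_ALPHABET if spec.disordered else None
    pool = alphabet or AA20
    ancestral = "".join(pool[i] for i in rng.integers(len(pool), size=spec.length))
    between = min(0.95, ratio * rate)
    segments: dict[int, str] = {}
    for sf in spec.subfamilies:
        consensus = mutate_sequence(ancestral, between, rng, model, alphabet)
        for row in members_by_subfam[sf]:
            segments[row] = mutate_sequence(consensus, rate, rng, model, alphabet)
    return segments


def _realized_similarity(
    segments: dict[int, str], model: SubstitutionModel
) -> float:
    rows = list(segments.values())
    if len(rows) < 2:
        return 1.0
    length = len(rows[0])
    sims = [
        column_similarity([r[c] for r in rows], model=model)
        for c in range(length)
    ]
    return float(np.mean(sims))


def _calibrate_block(
    spec: BlockSpec,
    members_by_subfam: list[list[int]],
    ratio: float,
    seed_path: tuple[int, ...],
    model: SubstitutionModel,
) -> dict[int, str]:
    """Bisect the member mutation rate until the realized block similarity
    is within the tolerance of the target; error if 100 attempts fail."""
    lo, hi = 0.0, 0.95
    rate = min(0.95, max(0.0, 1.0 - spec.similarity))
    for attempt in range(MAX_CALIBRATION_ATTEMPTS):
        rng = np.random.default_rng(seed_path + (attempt,))
        segments = _realize_block(spec, members_by_subfam, rate, ratio, rng, model)
        realized = _realized_similarity(segments, model)
        if abs(realized - spec.similarity) <= SIMILARITY_TOL:
            return segments
        if realized > spec.similarity:
            lo = rate
        else:
            hi = rate
        rate = (lo + hi) / 2.0
    raise ValueError(
        f"could not reach similarity {spec.similarity} for block of length "
        f"{spec.length} after {MAX_CALIBRATION_ATTEMPTS} attempts"
    )


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def generate(spec: FamilySpec, model: SubstitutionModel | None = None) -> SyntheticTruth:
    """Build a family: alternating per-sequence linkers and planted blocks,
    deterministic given the spec's seed."""
    model = model or default_model()
    n_seqs = sum(spec.subfamily_sizes)
    ids = []
    members_by_subfam: list[list[int]] = []
    row = 0
    for si, size in enumerate(spec.subfamily_sizes):
        rows = []
        for k in range(size):
            ids.append(f"sf{si + 1}_s{k + 1}")
            rows.append(row)
            row += 1
        members_by_subfam.append(rows)
    subfamilies = [
        Subfamily(f"S{si + 1}", tuple(ids[r] for r in rows))
        for si, rows in enumerate(members_by_subfam)
    ]

    rng = np.random.default_rng((spec.seed, 0))
    pieces: list[list[str]] = [[] for _ in range(n_seqs)]
    col = 0
    truth_blocks: list[BlockAnnotation] = []
    disorder: dict[str, list[tuple[int, int]]] = {}
    res_count = [0] * n_seqs  # ungapped residues emitted so far

    def add_linker():
        nonlocal col
        if spec.linker_length == 0:
            return
        lo = max(0, spec.linker_length - spec.linker_jitter)
        hi = spec.linker_length + spec.linker_jitter
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_seqs)]
        width = max(lengths)
        for r in range(n_seqs):
            link = "".join(AA20[i] for i in rng.integers(20, size=lengths[r]))
            pieces[r].append(link + GAP * (width - lengths[r]))
            res_count[r] += lengths[r]
        col += width

    for bi, bspec in enumerate(spec.blocks):
        add_linker()
        segments = _calibrate_block(
            bspec, members_by_subfam, spec.divergence_ratio,
            (spec.seed, 1, bi), model,
        )
        member_ids = []
        for r in range(n_seqs):
            if r in segments:
                pieces[r].append(segments[r])
                member_ids.append(ids[r])
                if bspec.disordered:
                    disorder.setdefault(ids[r], []).append(
                        (res_count[r], res_count[r] + bspec.length)
                    )
                res_count[r] += bspec.length
            else:
                pieces[r].append(GAP * bspec.length)
        truth_blocks.append(
            BlockAnnotation(
                block_id=f"B{bi + 1}",
                start=col,
                stop=col + bspec.length,
                members=frozenset(member_ids),
            )
        )
        col += bspec.length
    add_linker()

    aln = Alignment(tuple(ids), tuple("".join(p) for p in pieces))
    truth = SyntheticTruth(
        alignment=aln,
        blocks=truth_blocks,
        subfamilies=subfamilies,
        discrepancies=[],
        disorder=DisorderAnnotation(disorder),
    )
    for i, (kind, subfam, magnitude) in enumerate(spec.plants):
        truth = plant_discrepancy(
            truth, kind, magnitude, seed=int(np.random.default_rng(
                (spec.seed, 2, i)).integers(2**31)), subfamily=subfam,
        )
    return truth


# ---------------------------------------------------------------------------
# Planting discrepancies
# ---------------------------------------------------------------------------

def _universal_blocks(truth: SyntheticTruth, min_len: int) -> list[BlockAnnotation]:
    all_ids = set(truth.alignment.ids)
    dis_ids = set(truth.disorder.intervals)
    out = []
    for b in truth.blocks:
        if b.members != all_ids or b.n_cols < min_len:
            continue
        # skip disordered blocks: keeps disorder bookkeeping exact
        if any(
            truth.disorder.is_disordered(
                sid, truth.alignment.column_to_ungapped(sid, b.start)
            )
            for sid in (dis_ids & b.members)
        ):
            continue
        out.append(b)
    return out


def _shift_disorder(
    disorder: DisorderAnnotation, seq_id: str, at_residue: int, delta: int
) -> DisorderAnnotation:
    ivs = dict(disorder.intervals)
    if seq_id in ivs:
        ivs[seq_id] = [
            (a + delta, b + delta) if a >= at_residue else (a, b)
            for a, b in ivs[seq_id]
        ]
    return DisorderAnnotation(ivs)


def _insert_columns(
    aln: Alignment, at: int, width: int, filler: dict[str, str]
) -> Alignment:
    """Insert ``width`` columns at position ``at``; ``filler`` maps ids to
    the residues they carry there (everyone else gets gaps)."""
    seqs = []
    for sid, s in zip(aln.ids, aln.seqs):
        ins = filler.get(sid, GAP * width)
        seqs.append(s[:at] + ins + s[at:])
    return Alignment(aln.ids, tuple(seqs))


def _shift_blocks(
    blocks: list[BlockAnnotation], at: int, delta: int,
    split_host: str | None = None,
) -> list[BlockAnnotation]:
    out = []
    for b in blocks:
        if b.start >= at:
            out.append(replace(b, start=b.start + delta, stop=b.stop + delta))
        elif b.stop <= at:
            out.append(b)
        elif b.block_id == split_host:
            out.append(replace(b, block_id=b.block_id + "a", stop=at))
            out.append(
                replace(
                    b, block_id=b.block_id + "b",
                    start=at + delta, stop=b.stop + delta,
                )
            )
        else:
            out.append(replace(b, stop=b.stop + delta))
    return out


def plant_discrepancy(
    truth: SyntheticTruth,
    kind: str,
    magnitude: int,
    seed: int,
    subfamily: int = 0,
    target_id: str | None = None,
    block_id: str | None = None,
) -> SyntheticTruth:
    """Plant one discrepancy of the given kind and magnitude in one
    sequence of the given subfamily; returns an updated truth.

    Magnitudes are in columns (insertion/deletion length, terminal
    offset) or ignored for ``outlier_segment`` (the whole host block is
    shuffled). Sub-threshold magnitudes are allowed so specificity can be
    probed.
    """
    rng = np.random.default_rng(seed)
    aln = truth.alignment
    members = truth.subfamilies[subfamily].member_ids
    target = target_id or members[int(rng.integers(len(members)))]

    def pick_host(min_len: int) -> BlockAnnotation:
        cands = _universal_blocks(truth, min_len)
        if block_id is not None:
            cands = [b for b in cands if b.block_id == block_id]
        if not cands:
            raise ValueError(
                f"no universal block of >= {min_len} columns to host '{kind}'"
            )
        return cands[int(rng.integers(len(cands)))]

    if kind == "inserted_segment":
        host = pick_host(4)
        split = (host.start + host.stop) // 2
        insert = "".join(AA20[i] for i in rng.integers(20, size=magnitude))
        new_aln = _insert_columns(aln, split, magnitude, {target: insert})
        r0 = aln.column_to_ungapped(target, split)
        new_blocks = _shift_blocks(
            truth.blocks, split, magnitude, split_host=host.block_id
        )
        disc = Discrepancy(
            seq_id=target, kind=kind, start=split, stop=split + magnitude,
            detail=f"planted insertion of {magnitude} columns",
        )
        new_dis = _shift_disorder(truth.disorder, target, r0, magnitude)
        discs = [
            replace(d, start=d.start + magnitude, stop=d.stop + magnitude)
            if d.start >= split else d
            for d in truth.discrepancies
        ]
        return SyntheticTruth(
            new_aln, new_blocks, truth.subfamilies, discs + [disc], new_dis
        )

    if kind == "deleted_segment":
        host = pick_host(magnitude + 2)
        del_start = host.start + (host.n_cols - magnitude) // 2
        del_start = max(host.start + 1, min(del_start, host.stop - magnitude - 1))
        r0 = aln.column_to_ungapped(target, del_start)
        row = list(aln.row(target))
        for c in range(del_start, del_start + magnitude):
            row[c] = GAP
        seqs = tuple(
            "".join(row) if sid == target else s
            for sid, s in zip(aln.ids, aln.seqs)
        )
        disc = Discrepancy(
            seq_id=target, kind=kind, start=del_start,
            stop=del_start + magnitude,
            detail=f"planted deletion of {magnitude} columns",
        )
        new_dis = _shift_disorder(truth.disorder, target, r0, -magnitude)
        return SyntheticTruth(
            Alignment(aln.ids, seqs), truth.blocks, truth.subfamilies,
            truth.discrepancies + [disc], new_dis,
        )

    if kind == "terminal_error":
        ext = "".join(AA20[i] for i in rng.integers(20, size=magnitude))
        new_aln = _insert_columns(aln, 0, magnitude, {target: ext})
        new_blocks = _shift_blocks(truth.blocks, 0, magnitude)
        disc = Discrepancy(
            seq_id=target, kind=kind, start=0, stop=magnitude,
            terminal_side="N",
            detail=f"planted N-terminal extension of {magnitude} columns",
        )
        new_dis = _shift_disorder(truth.disorder, target, 0, magnitude)
        discs = [
            replace(d, start=d.start + magnitude, stop=d.stop + magnitude)
            for d in truth.discrepancies
        ]
        return SyntheticTruth(
            new_aln, new_blocks, truth.subfamilies, discs + [disc], new_dis
        )

    if kind == "outlier_segment":
        host = pick_host(max(4, magnitude))
        row = list(aln.row(target))
        seg = [row[c] for c in range(host.start, host.stop)]
        for _ in range(20):
            perm = rng.permutation(len(seg))
            shuffled = [seg[i] for i in perm]
            if shuffled != seg:
                break
        for c, ch in zip(range(host.start, host.stop), shuffled):
            row[c] = ch
        seqs = tuple(
            "".join(row) if sid == target else s
            for sid, s in zip(aln.ids, aln.seqs)
        )
        disc = Discrepancy(
            seq_id=target, kind=kind, start=host.start, stop=host.stop,
            detail=f"planted shuffled segment in {host.block_id}",
        )
        return SyntheticTruth(
            Alignment(aln.ids, seqs), truth.blocks, truth.subfamilies,
            truth.discrepancies + [disc], truth.disorder,
        )

    raise ValueError(f"unknown discrepancy kind '{kind}'")


# ---------------------------------------------------------------------------
# Controlled corruption of test alignments
# ---------------------------------------------------------------------------

def corrupt_alignment(
    reference: Alignment,
    blocks: list[BlockAnnotation],
    fraction: float,
    seed: int,
) -> tuple[Alignment, float]:
    """Displace one member residue in a fraction of block columns.

    Per block, ``round(fraction * m_b)`` columns are chosen and in each
    one randomly chosen member residue is moved into a fresh gap column,
    breaking that column's co-occurrence while leaving every other column
    intact. Returns the corrupted test alignment and the analytic
    expected column score 1 - sum_b n_b k_b / m_b / sum_b n_b. Sequence
    content is preserved up to gapping.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = {sid: list(s) for sid, s in zip(reference.ids, reference.seqs)}
    used: set[int] = set()
    corruptions: list[tuple[int, str]] = []  # (column, seq_id)
    total_w = 0
    lost = 0.0
    for b in blocks:
        n_b = len(b.members)
        m_b = b.n_cols
        total_w += n_b
        k_b = int(np.floor(fraction * m_b + 0.5))
        if k_b == 0:
            continue
        eligible = []
        for c in range(b.start, b.stop):
            if c in used:
                continue
            holders = [sid for sid in b.members if reference.row(sid)[c] != GAP]
            if len(holders) >= 2:
                eligible.append((c, holders))
        if len(eligible) < k_b:
            raise ValueError(
                f"block '{b.block_id}': only {len(eligible)} corruptible "
                f"columns for {k_b} requested"
            )
        picks = rng.choice(len(eligible), size=k_b, replace=False)
        for p in sorted(int(x) for x in picks):
            c, holders = eligible[p]
            used.add(c)
            corruptions.append((c, holders[int(rng.integers(len(holders)))]))
        lost += n_b * k_b / m_b
    expected_cs = 1.0 - lost / total_w if total_w else 1.0

    # apply right-to-left so earlier columns keep their indices
    for c, sid in sorted(corruptions, reverse=True):
        res = rows[sid][c]
        for other in rows:
            rows[other].insert(c + 1, res if other == sid else GAP)
        rows[sid][c] = GAP
    test = Alignment(
        reference.ids, tuple("".join(rows[sid]) for sid in reference.ids)
    )
    return test, expected_cs
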