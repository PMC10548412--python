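"""N-way collinear segment detection from complete-profile alignment anchors.

An alignment block containing every clade species is a "multiple alignment
anchor".  Anchors are ranked along each species chromosome by interval
start, and collinear segments are maximal runs of anchors (in reference
order) whose ranks move strictly monotonically — one fixed direction per
species — with per-step rank gaps bounded by ``max_rank_gap``.  A retained
run must contain at least ``q_min`` anchors and pass a closed-form
randomness bound: under independent uniform rank placement each of the
q-1 consecutive steps lands within the gap bound with chance at most
g/(M_s-1) (M_s = anchors on that species chromosome) and matches the
chain's orientation with chance 1/2 once the direction is set, so the
product over non-reference species and steps must fall below ``p_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentBlock, GenomicInterval

__all__ = [
    "AnchorMarker",
    "CollinearSegment",
    "build_anchor_table",
    "detect_collinear",
    "segment_span",
]


@dataclass(frozen=True)
class AnchorMarker:
    """A complete-profile alignment block reduced to per-species markers."""

    anchor_id: str
    intervals: dict[str, GenomicInterval]  # species -> oriented interval
    strands: dict[str, str]
    ranks: dict[str, int]  # species -> ordinal among anchors on its chromosome
    ref_rank: int


@dataclass
class CollinearSegment:
    segment_id: str
    anchors: list[AnchorMarker]
    orientations: dict[str, str]  # per-species rank direction, '+' or '-'

    @property
    def q_obs(self) -> int:
        return len(self.anchors)


def build_anchor_table(
    blocks: list[AlignmentBlock], clade: list[str]
) -> list[AnchorMarker]:
    """Anchors = blocks with all clade species, ranked per species chromosome.

    Blocks sharing an identical reference interval (tandem duplicates of a
    marker) are collapsed to the first; ids are deterministic, assigned in
    reference order.
    """
    ref_sp = None
    complete = []
    seen_ref: set[tuple[str, int, int]] = set()
    for b in blocks:
        if not b.is_complete(clade):
            continue
        iv = b.ref_interval
        key = (iv.chrom, iv.start, iv.end)
        if key in seen_ref:
            continue
        seen_ref.add(key)
        complete.append(b)
        ref_sp = b.ref_species
    if not complete:
        return []
    complete.sort(key=lambda b: (b.ref_interval.chrom, b.ref_interval.start))

    # per-species-chromosome ordinal ranks by interval start
    per_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for idx, b in enumerate(complete):
        for sp in clade:
            iv = b.rows[sp].interval
            per_chrom.setdefault((sp, iv.chrom), []).append((iv.start, idx))
    ranks: list[dict[str, int]] = [dict() for _ in complete]
    for (sp, _chrom), items in per_chrom.items():
        items.sort()
        for rank, (_start, idx) in enumerate(items):
            ranks[idx][sp] = rank

    anchors = []
    for idx, b in enumerate(complete):
        anchors.append(
            AnchorMarker(
                anchor_id=f"anchor_{idx:06d}",
                intervals={sp: b.rows[sp].interval for sp in clade},
                strands={sp: b.rows[sp].strand for sp in clade},
                ranks=ranks[idx],
                ref_rank=idx,
            )
        )
    return anchors


def _step_ok(
    a: AnchorMarker, b: AnchorMarker, species: list[str], max_rank_gap: int
) -> dict[str, int] | None:
    """Per-species rank step a->b if valid: same chromosome, constant
    relative strand (an inverted block cannot chain with its uninverted
    neighbours), and 1 <= |rank gap| <= G."""
    deltas: dict[str, int] = {}
    for sp in species:
        if a.intervals[sp].chrom != b.intervals[sp].chrom:
            return None
        if a.strands[sp] != b.strands[sp]:
            return None
        d = b.ranks[sp] - a.ranks[sp]
        if d == 0 or abs(d) > max_rank_gap:
            return None
        deltas[sp] = d
    return deltas


def _random_run_probability(
    segment_anchors: list[AnchorMarker],
    species: list[str],
    ref_species_rank_counts: dict[tuple[str, str], int],
    max_rank_gap: int,
) -> float:
    """Upper bound on the chance of the observed run under random ranks."""
    q = len(segment_anchors)
    if q < 2:
        return 1.0
    p = 1.0
    for sp in species:
        chrom = segment_anchors[0].intervals[sp].chrom
        m = ref_species_rank_counts.get((sp, chrom), q)
        step = min(1.0, max_rank_gap / max(m - 1, 1))
        # each of the q-1 steps must land within the gap bound; after the
        # first step the direction is fixed, so a random step also matches
        # the chain's orientation with probability 1/2
        p *= step ** (q - 1) * 0.5 ** (q - 2)
    return p


def detect_collinear(
    anchors: list[AnchorMarker],
    q_min: int = 3,
    max_rank_gap: int = 25,
    p_cut: float = 0.01,
    ref_species: str | None = None,
) -> list[CollinearSegment]:
    """Chain anchors into maximal order/orientation-consistent segments.

    Anchors are scanned in reference order (per reference chromosome).  A
    run extends across a step iff every species' rank gap is within
    ``max_rank_gap`` and its sign matches the run's per-species direction
    (set by the run's first step).  Runs shorter than ``q_min`` or failing
    the randomness bound are dropped; each anchor belongs to at most one
    segment, resolved longest-run-first with ties to the leftmost
    reference start.
    """
    if not anchors:
        return []
    species = sorted(anchors[0].ranks)
    if ref_species is None:
        # reference = the species whose rank order matches ref_rank
        ref_species = species[0]
        for sp in species:
            if all(
                a.ranks.get(sp) is not None for a in anchors
            ):
                order = sorted(anchors, key=lambda a: a.ref_rank)
                if all(
                    x.ranks[sp] <= y.ranks[sp]
                    or x.intervals[sp].chrom != y.intervals[sp].chrom
                    for x, y in zip(order, order[1:])
                ):
                    ref_species = sp
                    break
    non_ref = [sp for sp in species if sp != ref_species]

    rank_counts: dict[tuple[str, str], int] = {}
    for a in anchors:
        for sp in species:
            key = (sp, a.intervals[sp].chrom)
            rank_counts[key] = rank_counts.get(key, 0) + 1

    ordered = sorted(
        anchors, key=lambda a: (a.intervals[ref_species].chrom, a.ref_rank)
    )

    # maximal runs: split at invalid steps and at direction changes
    runs: list[list[AnchorMarker]] = []
    cur = [ordered[0]]
    cur_dirs: dict[str, int] | None = None
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.intervals[ref_species].chrom != nxt.intervals[ref_species].chrom:
            runs.append(cur)
            cur, cur_dirs = [nxt], None
            continue
        deltas = _step_ok(prev, nxt, species, max_rank_gap)
        if deltas is None:
            runs.append(cur)
            cur, cur_dirs = [nxt], None
            continue
        dirs = {sp: (1 if d > 0 else -1) for sp, d in deltas.items()}
        if cur_dirs is not None and dirs != cur_dirs:
            runs.append(cur)
            cur, cur_dirs = [prev, nxt], dirs
            continue
        cur.append(nxt)
        cur_dirs = dirs
    runs.append(cur)

    candidates = [r for r in runs if len(r) >= q_min]
    candidates = [
        r
        for r in candidates
        if _random_run_probability(r, non_ref, rank_counts, max_rank_gap) < p_cut
    ]
    # longest first, ties by leftmost reference start; each anchor used once
    candidates.sort(
        key=lambda r: (-len(r), r[0].intervals[ref_species].chrom,
                       r[0].intervals[ref_species].start)
    )
    used: set[str] = set()
    segments: list[CollinearSegment] = []
    for run in candidates:
        run = [a for a in run if a.anchor_id not in used]
        if len(run) < q_min:
            continue
        used.update(a.anchor_id for a in run)
        dirs: dict[str, str] = {}
        for sp in species:
            d = run[1].ranks[sp] - run[0].ranks[sp] if len(run) > 1 else 1
            dirs[sp] = "+" if d > 0 else "-"
        segments.append(
            CollinearSegment(segment_id="", anchors=run, orientations=dirs)
        )
    segments.sort(
        key=lambda s: (
            s.anchors[0].intervals[ref_species].chrom,
            s.anchors[0].intervals[ref_species].start,
        )
    )
    for i, seg in enumerate(segments):
        seg.segment_id = f"segment_{i:05d}"
    return segments


def segment_span(segment: CollinearSegment, species: str) -> GenomicInterval:
    """Smallest interval covering every member anchor in ``species``."""
    if species not in segment.anchors[0].intervals:
        raise KeyError(f"species {species!r} not in segment")
    ivs = [a.intervals[species] for a in segment.anchors]
    chrom = ivs[0].chrom
    return GenomicInterval(chrom, min(v.start for v in ivs), max(v.end for v in ivs))
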