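"""Projection of TE insertion breakpoints into genomes lacking the TE.

For each polymorphic TE the upstream and downstream flanking sequences
(default +/- 500 bp) and their concatenation are taken from a carrier
genome and located in a non-carrier genome.  A breakpoint is called only
when all three queries place uniquely, upstream and downstream land on the
same chromosome in order, and the signed gap/overlap between them is
within the tolerance (default +/- 50 bp).

Real data flows in as PAF alignments produced by an external aligner; for
synthetic genomes an exact-substring mapper is built in so the test suite
needs no aligner.
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import Config
from .io_formats import PafRecord, TEInsertion

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"
INCONSISTENT = "inconsistent"

QUERY_UP = "up"
QUERY_DOWN = "down"
QUERY_CONCAT = "concat"


@dataclass
class BreakpointCall:
    te_id: str
    target_strain: str
    status: str  # unique | ambiguous | unmapped | inconsistent
    position: int | None = None  # junction point, 0-based, when unique
    gap_bp: int | None = None  # gap > 0 / overlap < 0 between flanks

    def __post_init__(self) -> None:
        if self.status == UNIQUE and self.position is None:
            raise ValueError("unique call requires a position")
        if self.status != UNIQUE:
            self.position = None


@dataclass
class FlankSet:
    upstream: str
    downstream: str
    truncated: bool = False

    @property
    def concatenated(self) -> str:
        return self.upstream + self.downstream


def extract_flanks(
    te: TEInsertion, carrier_strain: str, genome: str, flank_bp: int = 500
) -> FlankSet:
    """Extract the upstream/downstream flanks of a TE from a carrier genome.

    upstream = [start - flank_bp, start), downstream = [end, end + flank_bp).
    Flanks running off a contig end are truncated and flagged.
    """
    if carrier_strain not in te.interval:
        raise KeyError(f"{te.te_id} has no recorded interval in strain {carrier_strain}")
    iv = te.interval[carrier_strain]
    up_start = max(0, iv.start - flank_bp)
    down_end = min(len(genome), iv.end + flank_bp)
    truncated = up_start > iv.start - flank_bp or down_end < iv.end + flank_bp
    return FlankSet(genome[up_start : iv.start], genome[iv.end : down_end], truncated)


# ---------------------------------------------------------------------------
# Built-in exact mapper for synthetic genomes
# ---------------------------------------------------------------------------

def find_occurrences(query: str, target: str, max_hits: int = 3) -> list[int]:
    """Start positions of exact occurrences of ``query`` in ``target``.

    Stops after ``max_hits`` hits — callers only need to distinguish
    0 / 1 / many.
    """
    hits: list[int] = []
    pos = target.find(query)
    while pos != -1 and len(hits) < max_hits:
        hits.append(pos)
        pos = target.find(query, pos + 1)
    return hits


def map_flanks_exact(
    flanks: FlankSet, target: str, target_name: str = "chr"
) -> dict[str, list[PafRecord]]:
    """Map the three flank queries by exact substring search.

    Emits PAF-like records (mapq 60, full query coverage) so the same
    :func:`call_breakpoint` logic serves synthetic and aligner-produced
    input.
    """
    grouped: dict[str, list[PafRecord]] = {}
    for qname, seq in (
        (QUERY_UP, flanks.upstream),
        (QUERY_DOWN, flanks.downstream),
        (QUERY_CONCAT, flanks.concatenated),
    ):
        records = []
        if seq:
            for pos in find_occurrences(seq, target):
                records.append(
                    PafRecord(
                        query=qname,
                        query_len=len(seq),
                        query_start=0,
                        query_end=len(seq),
                        strand="+",
                        target=target_name,
                        target_len=len(target),
                        target_start=pos,
                        target_end=pos + len(seq),
                        n_match=len(seq),
                        block_len=len(seq),
                        mapq=60,
                    )
                )
        grouped[qname] = records
    return grouped


# ---------------------------------------------------------------------------
# Breakpoint calling
# ---------------------------------------------------------------------------

def _accepted(records: list[PafRecord], min_mapq: int, min_coverage: float) -> list[PafRecord]:
    return [
        r
        for r in records
        if r.primary and r.mapq >= min_mapq and r.query_coverage >= min_coverage
    ]


def call_breakpoint(
    alignments: dict[str, list[PafRecord]],
    te_id: str,
    target_strain: str,
    config: Config | None = None,
) -> BreakpointCall:
    """Classify a flank-alignment triple into a breakpoint call.

    status=unique requires exactly one accepted placement for each of the
    up/down/concat queries, up and down on the same chromosome and in
    order, and |gap| <= tolerance.  The junction position is the midpoint
    of the gap/overlap interval, rounded toward the upstream side.
    """
    cfg = config or Config()
    accepted = {
        q: _accepted(alignments.get(q, []), cfg.min_mapq, cfg.min_flank_coverage)
        for q in (QUERY_UP, QUERY_DOWN, QUERY_CONCAT)
    }
    if any(len(v) == 0 for v in accepted.values()):
        return BreakpointCall(te_id, target_strain, UNMAPPED)
    if any(len(v) > 1 for v in accepted.values()):
        return BreakpointCall(te_id, target_strain, AMBIGUOUS)
    up, down = accepted[QUERY_UP][0], accepted[QUERY_DOWN][0]
    if up.target != down.target:
        return BreakpointCall(te_id, target_strain, INCONSISTENT)
    if down.target_start < up.target_start:
        return BreakpointCall(te_id, target_strain, INCONSISTENT)
    gap = down.target_start - up.target_end
    if abs(gap) > cfg.breakpoint_tolerance_bp:
        return BreakpointCall(te_id, target_strain, INCONSISTENT, gap_bp=gap)
    position = up.target_end + (gap // 2)
    return BreakpointCall(te_id, target_strain, UNIQUE, position=position, gap_bp=gap)


def project_breakpoints(
    tes: list[TEInsertion],
    genomes: dict[str, str],
    config: Config | None = None,
    chrom: str = "chr",
) -> list[BreakpointCall]:
    """Project every polymorphic TE into each of its non-carrier strains.

    Uses the built-in exact mapper on the supplied genome sequences; one
    carrier (the first) donates the flanks.
    """
    cfg = config or Config()
    calls: list[BreakpointCall] = []
    for te in tes:
        if not te.is_polymorphic:
            continue
        carrier = te.carriers[0]
        flanks = extract_flanks(te, carrier, genomes[carrier], cfg.flank_bp)
        for strain in te.non_carriers:
            grouped = map_flanks_exact(flanks, genomes[strain], chrom)
            calls.append(call_breakpoint(grouped, te.te_id, strain, cfg))
    return calls
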