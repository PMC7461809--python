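"""Run-off-sequencing inference: doublet calling, geometry, consensus.

Breaks introduced by a restriction/nicking enzyme terminate Taq extension
on the broken template strand; the non-templated adenine appended to the
terminated product superimposes an A peak on the call at the last
templated base, producing the diagnostic G/A, C/A or T/A doublet (or a
single extra-high A when the templated call is itself A).  This module
detects those signatures against an uncut control, maps them back to
linkage coordinates, aggregates per-site cleavage offsets into an Nt/Nb
geometry, and compiles position-weight-matrix consensus sequences around
the breaks.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from .core import InputError, ModifiedDuplex, RecognitionSite, iupac_code
from .digestion import CutEvent
from .simulate import RunoffTrace

logger = logging.getLogger(__name__)

__all__ = [
    "BreakCall",
    "CutGeometry",
    "PWM",
    "call_breaks",
    "events_to_calls",
    "infer_cut_geometry",
    "build_pwm",
    "information_content",
    "iupac_consensus",
]

_CHANNELS = "ACGT"


@dataclass(frozen=True)
class BreakCall:
    """One inferred strand break.

    ``inferred_linkage`` is the top-coordinate linkage of the break on
    ``template_strand``; ``evidence`` is the subset of {doublet, high_A,
    dropoff} rules that fired; ``secondary_fraction`` is the ratio of the
    secondary (A) peak to the primary peak at the doublet position.
    """

    template_strand: str
    inferred_linkage: int
    evidence: frozenset[str]
    secondary_fraction: float = 0.0
    read_pos: int | None = None


@dataclass
class CutGeometry:
    """Aggregated Nt/Nb cleavage geometry inferred from break calls."""

    enzyme_hint: str
    top_offset_mode: int | None
    bottom_offset_mode: int | None
    overhang: int | None
    offset_dispersion: tuple[int, int]
    top_offsets: Counter
    bottom_offsets: Counter
    n_unassigned: int
    undetermined: bool


@dataclass
class PWM:
    """Per-column base frequencies of aligned break windows.

    ``cut_column`` is the index of the cleaved linkage within the window:
    the cut falls between window columns ``cut_column - 1`` and
    ``cut_column``.
    """

    columns: list[dict[str, float]]
    n_sites: int
    cut_column: int


# --------------------------------------------------------------------------
# break calling


def _total(heights) -> float:
    return sum(heights)


def call_breaks(
    trace: RunoffTrace,
    control: RunoffTrace,
    theta_doublet: float = 0.25,
    theta_highA: float = 1.4,
    theta_dropoff: float = 0.3,
    dropoff_window: int = 5,
) -> list[BreakCall]:
    """Detect strand breaks in a partial-digest trace against its control.

    A call is emitted where (a) the A channel is secondary with height at
    least ``theta_doublet`` times the primary peak (doublet rule), or
    (b) the templated call is A and its height is at least ``theta_highA``
    times the control A height (high-A rule).  A sharp signal drop of at
    least ``theta_dropoff`` (mean over ``dropoff_window`` positions)
    corroborates either rule; on its own it still localizes a break but is
    emitted as low-confidence (evidence = {dropoff} only).

    Raises InputError when trace and control do not cover the same
    template columns.
    """
    if trace.columns != control.columns or trace.direction != control.direction:
        raise InputError("trace and control cover different template columns")
    recs, ctl = trace.records, control.records
    n = len(recs)

    def dropoff_at(i: int) -> bool:
        lo, hi = i - dropoff_window, i + dropoff_window
        if lo < 0 or hi >= n:
            return False
        up = sum(_total(recs[j].heights) for j in range(lo, i)) / dropoff_window
        down = sum(_total(recs[j].heights) for j in range(i + 1, hi + 1)) / dropoff_window
        return up > 0 and (up - down) / up >= theta_dropoff

    def linkage_at(i: int) -> int:
        c = recs[i].template_col
        return c if trace.direction == 1 else c - 1

    calls: list[BreakCall] = []
    called_positions: set[int] = set()
    for i, (r, c) in enumerate(zip(recs, ctl)):
        heights = dict(zip(_CHANNELS, r.heights))
        primary = max(heights, key=heights.get)
        evidence: set[str] = set()
        secondary = 0.0
        if primary != "A" and heights[primary] > 0:
            ctl_hA = dict(zip(_CHANNELS, c.heights))["A"]
            ratio = heights["A"] / heights[primary]
            if ratio >= theta_doublet and heights["A"] > 2.0 * ctl_hA:
                evidence.add("doublet")
                secondary = ratio
        if primary == "A":
            ctl_hA = dict(zip(_CHANNELS, c.heights))["A"]
            if ctl_hA > 0 and heights["A"] >= theta_highA * ctl_hA:
                evidence.add("high_A")
                secondary = heights["A"] / ctl_hA
        if evidence:
            if dropoff_at(i):
                evidence.add("dropoff")
            calls.append(
                BreakCall(
                    trace.template_strand,
                    linkage_at(i),
                    frozenset(evidence),
                    secondary,
                    read_pos=i,
                )
            )
            called_positions.add(i)

    # drop-off-only candidates, away from already-called positions
    cand = [
        i
        for i in range(n)
        if dropoff_at(i) and not any(abs(i - j) <= dropoff_window for j in called_positions)
    ]
    for group in _group_consecutive(cand):
        best = max(
            group,
            key=lambda i: _total(recs[i].heights)
            - _total(recs[min(i + 1, n - 1)].heights),
        )
        calls.append(
            BreakCall(
                trace.template_strand,
                linkage_at(best),
                frozenset({"dropoff"}),
                0.0,
                read_pos=best,
            )
        )
    calls.sort(key=lambda b: b.read_pos if b.read_pos is not None else -1)
    return calls


def _group_consecutive(idxs: list[int]) -> list[list[int]]:
    groups: list[list[int]] = []
    for i in sorted(idxs):
        if groups and i == groups[-1][-1] + 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def events_to_calls(
    events, strands: str = "both"
) -> list[BreakCall]:
    """Turn known digestion events into break calls (oracle plumbing).

    ``strands="both"`` emits one call per severed strand of a ds cut;
    ``"guide"`` emits only the guiding-strand call, appropriate for
    blunt pattern-directed cuts whose two strand windows would otherwise
    align at mirrored cut indices.
    """
    calls = []
    for ev in events:
        pairs = []
        if ev.kind in ("ds_cut", "nick_top") and ev.top_cut_linkage is not None:
            pairs.append(("top", ev.top_cut_linkage))
        if ev.kind in ("ds_cut", "nick_bottom") and ev.bottom_cut_linkage is not None:
            pairs.append(("bottom", ev.bottom_cut_linkage))
        if strands == "guide" and ev.kind == "ds_cut":
            pairs = [p for p in pairs if p[0] == ev.guide_strand]
        for strand, lnk in pairs:
            calls.append(BreakCall(strand, lnk, frozenset({"doublet"})))
    return calls


# --------------------------------------------------------------------------
# geometry inference


def _frame_offset(site: RecognitionSite, motif_len: int, guide: str, linkage: int,
                  length: int, circular: bool) -> int:
    """Offset (nt 3' of the motif end) of a break in the frame guided by
    ``guide``; negative offsets are upstream of the motif in that frame."""
    s = site.start
    e = s + motif_len - 1
    off = (linkage - e) if guide == "top" else ((s - 1) - linkage)
    if circular:
        off %= length
        if off > length // 2:
            off -= length
    return off


def infer_cut_geometry(
    calls: list[BreakCall],
    sites: list[RecognitionSite],
    motif_len: int = 4,
    max_distance: int = 30,
    duplex_length: int | None = None,
    circular: bool = False,
    enzyme_hint: str = "",
    dispersion_limit: int = 5,
) -> CutGeometry:
    """Aggregate break calls into an Nt/Nb cleavage geometry.

    Each call is assigned to the nearest recognition site within
    ``max_distance`` nt, in the frame (motif-strand reading direction)
    that gives the smallest non-negative offset; a call whose cleaved
    strand is the frame's motif strand contributes a guiding-strand (t)
    observation, otherwise an opposite-strand (b) observation.  Calls
    upstream of every frame keep their (negative) offset rather than
    being reassigned, preserving hemi-site directionality.  Offsets
    count nucleotides 3' of the last motif base, REBASE-style, so a cut
    at linkage ``end + 7`` is N7.

    The geometry is undetermined when no call can be assigned or when
    the per-strand offset dispersion exceeds ``dispersion_limit``.
    """
    if not calls:
        raise InputError("no break calls supplied")
    L = duplex_length or 0
    t_obs: Counter = Counter()
    b_obs: Counter = Counter()
    unassigned = 0
    for call in calls:
        best: tuple[int, int, str] | None = None  # (|off|, off, role)
        for site in sites:
            for guide in ("top", "bottom"):
                off = _frame_offset(site, motif_len, guide, call.inferred_linkage,
                                    L, circular)
                if abs(off) > max_distance:
                    continue
                role = "t" if call.template_strand == guide else "b"
                key = (0 if off >= 0 else 1, abs(off))
                if best is None or key < (0 if best[1] >= 0 else 1, abs(best[1])):
                    best = (key[1], off, role)
        if best is None:
            unassigned += 1
            continue
        (t_obs if best[2] == "t" else b_obs)[best[1]] += 1
    if unassigned:
        logger.info("%d break calls not within %d nt of any site", unassigned, max_distance)

    def mode(counter: Counter) -> int | None:
        if not counter:
            return None
        top_count = max(counter.values())
        return min(off for off, cnt in counter.items() if cnt == top_count)

    t_mode, b_mode = mode(t_obs), mode(b_obs)
    overhang = t_mode - b_mode if t_mode is not None and b_mode is not None else None
    dispersion = (len(t_obs), len(b_obs))
    undetermined = (
        (not t_obs and not b_obs)
        or max(dispersion) > dispersion_limit
    )
    return CutGeometry(
        enzyme_hint=enzyme_hint,
        top_offset_mode=t_mode,
        bottom_offset_mode=b_mode,
        overhang=overhang,
        offset_dispersion=dispersion,
        top_offsets=t_obs,
        bottom_offsets=b_obs,
        n_unassigned=unassigned,
        undetermined=undetermined,
    )


# --------------------------------------------------------------------------
# consensus


def _window_bases(d: ModifiedDuplex, strand: str, linkage: int, left: int, right: int) -> str | None:
    """``left + right`` bases around a break, read 5'->3' on the cleaved
    strand (cut after position ``left - 1``).  None if out of bounds on a
    linear molecule."""
    L = d.length
    if strand == "top":
        cols = range(linkage - left + 1, linkage + right + 1)
    else:
        cols = range(linkage + left, linkage - right, -1)
    out = []
    for c in cols:
        if not d.is_circular and not 0 <= c < L:
            return None
        out.append(d.strand_base(strand, c % L))
    return "".join(out)


def build_pwm(
    d: ModifiedDuplex, calls: list[BreakCall], left: int = 3, right: int = 3
) -> PWM:
    """Stack break windows into a position-frequency matrix.

    Windows of ``left + right`` bases around each break linkage are read
    on the cleaved strand 5'->3' and tallied per column; ``cut_column``
    equals ``left``.  Out-of-bounds windows on linear molecules are
    skipped (logged).
    """
    width = left + right
    counts = [Counter() for _ in range(width)]
    n = 0
    for call in calls:
        win = _window_bases(d, call.template_strand, call.inferred_linkage, left, right)
        if win is None:
            logger.info("window at linkage %d out of bounds; skipped", call.inferred_linkage)
            continue
        for k, base in enumerate(win):
            counts[k][base] += 1
        n += 1
    if n == 0:
        raise InputError("no in-bounds break windows to stack")
    columns = [
        {b: counts[k].get(b, 0) / n for b in "ACGT"} for k in range(width)
    ]
    return PWM(columns=columns, n_sites=n, cut_column=left)


def information_content(pwm: PWM) -> list[float]:
    """Per-column information content in bits (base-2, no small-sample
    correction): ``2 + sum(f log2 f)``."""
    out = []
    for col in pwm.columns:
        h = -sum(f * math.log2(f) for f in col.values() if f > 0)
        out.append(2.0 - h)
    return out


def iupac_consensus(pwm: PWM, include_threshold: float = 0.25) -> str:
    """IUPAC consensus with a cut mark.

    Per column, the degeneracy code covering all bases at frequency
    >= ``include_threshold``; a column where no base reaches the threshold
    renders as N (warning logged).  The cut mark is inserted at
    ``pwm.cut_column``.
    """
    if not 0 < include_threshold <= 1:
        raise InputError("include_threshold must be in (0, 1]")
    symbols = []
    for k, col in enumerate(pwm.columns):
        bases = {b for b, f in col.items() if f >= include_threshold}
        if not bases:
            logger.warning("column %d: no base reaches threshold; rendered N", k)
            symbols.append("N")
        else:
            symbols.append(iupac_code(bases))
    symbols.insert(pwm.cut_column, "↓")
    return "".join(symbols)
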