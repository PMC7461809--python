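"""Modification-licensed digestion: site scanning, licensing, cutting.

The engine draws per-molecule cleavage events for an enzyme/condition pair.
Licensing follows the behavior established for the GpsAAC/GpsTTC family:

* In a *specific* cofactor mode (e.g. EcoWI + Mg2+, Ksp11411I + Ni2+) only
  PT-marked sites fire.  A mark on a strand licenses a double-strand cut on
  the side of the site given by the enzyme's hemi-site directionality
  (EcoWI cleaves downstream of the marked strand's motif, Ksp11411I
  upstream of the GpsT dinucleotide); fully modified sites license both
  orientations and one is sampled per event.
* In the *relaxed* mode (Mn2+ star activity) every motif or pattern match
  fires regardless of marks.
* ``partial`` behaves like specific at the relaxed (reduced) probability;
  ``nick_only`` restricts events to single-strand breaks; ``inactive``
  yields nothing.

Cleavage geometry is REBASE-style: for a cut oriented along strand X's
reading direction the X-strand break sits t nt 3' of the motif end and the
opposite-strand break b nt, with t - b the 3'-overhang length.  Wobbled
enzymes sample (t, b) uniformly from their ranges, rejecting t < b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    ConfigurationError,
    EnzymeSpec,
    ModifiedDuplex,
    PtdrError,
    RecognitionSite,
    find_motif_sites,
    find_pattern_matches,
    site_mark_linkages,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Conditions",
    "CutEvent",
    "Fragment",
    "scan_sites",
    "license_site",
    "digest",
    "fragments",
    "exo1_filter",
]


@dataclass
class Conditions:
    """Reaction conditions for a digestion run.

    ``p_ds_given_cleave`` defaults to 0.75, reproducing the ~3:1 ratio of
    double-strand cuts to nicks observed at high enzyme concentration.
    ``p_cleave_specific``/``p_cleave_relaxed`` are per-site, per-molecule
    firing probabilities for licensed and star events respectively.
    """

    cofactor: str = "Mg"
    enzyme_level: str = "high"
    p_ds_given_cleave: float = 0.75
    p_cleave_specific: float = 0.9
    p_cleave_relaxed: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_ds_given_cleave", "p_cleave_specific", "p_cleave_relaxed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CutEvent:
    """A strand break: a double-strand cut or a nick at one linkage.

    ``guide_strand`` records which strand's reading direction oriented the
    event (the strand whose motif/pattern points 3' toward the cut).
    """

    site_ref: RecognitionSite | None
    kind: str  # ds_cut | nick_top | nick_bottom
    top_cut_linkage: int | None = None
    bottom_cut_linkage: int | None = None
    guide_strand: str = "top"

    def __post_init__(self) -> None:
        if self.kind == "ds_cut":
            if self.top_cut_linkage is None or self.bottom_cut_linkage is None:
                raise PtdrError("ds_cut requires both cut linkages")
        elif self.kind == "nick_top":
            if self.top_cut_linkage is None or self.bottom_cut_linkage is not None:
                raise PtdrError("nick_top requires exactly the top linkage")
        elif self.kind == "nick_bottom":
            if self.bottom_cut_linkage is None or self.top_cut_linkage is not None:
                raise PtdrError("nick_bottom requires exactly the bottom linkage")
        else:
            raise PtdrError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Fragment:
    """A digestion product: per-strand (start, end) column intervals.

    Intervals are inclusive top-coordinate column ranges; on circular
    parents an interval may wrap (start > end).  ``nicks`` carries the
    unsevered single-strand breaks of an otherwise intact molecule.
    """

    top_piece: tuple[int, int] | None
    bottom_piece: tuple[int, int] | None
    length: int
    single_stranded: bool = False
    nicks: tuple[CutEvent, ...] = field(default=())


def _other(strand: str) -> str:
    return "bottom" if strand == "top" else "top"


# --------------------------------------------------------------------------


def scan_sites(d: ModifiedDuplex, spec: EnzymeSpec) -> list[RecognitionSite]:
    """All recognition-motif occurrences on both strands, IUPAC-aware.

    Circular molecules include wrap-around occurrences.  Deterministic
    order: start column, then top strand before bottom.
    """
    if not spec.recognition:
        return []
    return find_motif_sites(d, spec.recognition, spec.pt_linkage_offset)


def _effective_marks(site: RecognitionSite, d: ModifiedDuplex, spec: EnzymeSpec) -> dict[str, bool]:
    """Which strands of the site carry a countable PT mark (Rp-filtered)."""
    positions = site_mark_linkages(
        site, d.length, spec.pt_linkage_offset, len(spec.recognition)
    )
    by_pos = {(m.strand, m.linkage): m for m in d.pt_marks}
    out = {}
    for strand in ("top", "bottom"):
        mark = by_pos.get((strand, positions[strand]))
        out[strand] = bool(mark) and (not spec.rp_only or mark.stereo == "Rp")
    return out


def _licensed_orientations(marks: dict[str, bool], spec: EnzymeSpec) -> set[str]:
    """Cut orientations (guiding strand) enabled by the site's marks."""
    if spec.requires_full and not (marks["top"] and marks["bottom"]):
        return set()
    orients: set[str] = set()
    for strand, present in marks.items():
        if not present:
            continue
        if spec.hemi_side == "downstream":
            orients.add(strand)
        elif spec.hemi_side == "upstream":
            orients.add(_other(strand))
        else:
            orients.update(("top", "bottom"))
    return orients


def license_site(
    site: RecognitionSite,
    d: ModifiedDuplex,
    spec: EnzymeSpec,
    cond: Conditions,
    n_licensed: int = 1,
) -> tuple[float, float]:
    """Cleavage probabilities (p_top, p_bottom) for the two cut orientations.

    ``p_top`` is the probability of an event oriented along the top strand's
    reading direction (cut to the right of the motif columns), ``p_bottom``
    along the bottom strand's (cut to the left).  ``n_licensed`` is the
    number of licensed sites on the molecule; with
    ``spec.two_site_factor > 1`` a second licensed site boosts the
    probability (capped at 1), reproducing two-site activation.
    """
    mode = spec.cofactor_mode(cond.cofactor)
    if mode == "inactive":
        return (0.0, 0.0)
    if mode == "relaxed":
        p = cond.p_cleave_relaxed
        return (p, p)
    # specific / partial / nick_only licensing
    p_base = cond.p_cleave_specific if mode in ("specific", "nick_only") else cond.p_cleave_relaxed
    if n_licensed >= 2 and spec.two_site_factor > 1.0:
        p_base = min(1.0, p_base * spec.two_site_factor)
    marks = _effective_marks(site, d, spec)
    orients = _licensed_orientations(marks, spec)
    return (
        p_base if "top" in orients else 0.0,
        p_base if "bottom" in orients else 0.0,
    )


def _sample_offsets(spec: EnzymeSpec, rng: np.random.Generator) -> tuple[int, int]:
    t0, t1 = spec.top_offset_range
    b0, b1 = spec.bottom_offset_range
    for _ in range(100):
        t = int(rng.integers(t0, t1 + 1))
        b = int(rng.integers(b0, b1 + 1))
        if t >= b:
            return t, b
    raise PtdrError(f"{spec.name}: could not sample offsets with t >= b")


def _oriented_linkages(
    site: RecognitionSite, motif_len: int, orient: str, t: int, b: int, d: ModifiedDuplex
) -> tuple[int, int] | None:
    """(top_linkage, bottom_linkage) of a cut guided by ``orient``.

    Returns None when a fixed-offset cut would fall off a linear molecule.
    """
    L = d.length
    s = site.start
    e = s + motif_len - 1
    if orient == "top":
        top_lnk, bot_lnk = e + t, e + b
    else:
        bot_lnk, top_lnk = s - 1 - t, s - 1 - b
    if d.is_circular:
        return top_lnk % L, bot_lnk % L
    if 0 <= min(top_lnk, bot_lnk) and max(top_lnk, bot_lnk) < L - 1:
        return top_lnk, bot_lnk
    logger.debug("cut of site at %d falls off linear duplex %s", s, d.id)
    return None


def _pt_site_events(
    d: ModifiedDuplex,
    spec: EnzymeSpec,
    cond: Conditions,
    n_molecules: int,
    rng: np.random.Generator,
    sites: Sequence[RecognitionSite],
) -> list[list[CutEvent]]:
    mode = spec.cofactor_mode(cond.cofactor)
    motif_len = len(spec.recognition)
    # count licensed sites once (for the two-site boost), then per-site probs
    licensed = [
        bool(sum(license_site(s, d, spec, cond, n_licensed=1))) for s in sites
    ]
    n_lic = sum(licensed)
    probs = [license_site(s, d, spec, cond, n_licensed=n_lic) for s in sites]
    ensemble: list[list[CutEvent]] = []
    for _ in range(n_molecules):
        events: list[CutEvent] = []
        for site, (p_top, p_bottom) in zip(sites, probs):
            enabled = [o for o, p in (("top", p_top), ("bottom", p_bottom)) if p > 0]
            if not enabled:
                continue
            p_fire = max(p_top, p_bottom)
            if rng.random() >= p_fire:
                continue
            orient = enabled[int(rng.integers(len(enabled)))]
            t, b = _sample_offsets(spec, rng)
            linkages = _oriented_linkages(site, motif_len, orient, t, b, d)
            if linkages is None:
                continue
            top_lnk, bot_lnk = linkages
            if mode != "nick_only" and rng.random() < cond.p_ds_given_cleave:
                events.append(
                    CutEvent(site, "ds_cut", top_lnk, bot_lnk, guide_strand=orient)
                )
            else:
                nick_strand = ("top", "bottom")[int(rng.integers(2))]
                if nick_strand == "top":
                    events.append(CutEvent(site, "nick_top", top_lnk, None, orient))
                else:
                    events.append(CutEvent(site, "nick_bottom", None, bot_lnk, orient))
        ensemble.append(events)
    return ensemble


def _pattern_events(
    d: ModifiedDuplex,
    spec: EnzymeSpec,
    cond: Conditions,
    n_molecules: int,
    rng: np.random.Generator,
) -> list[list[CutEvent]]:
    mode = spec.cofactor_mode(cond.cofactor)
    if mode == "inactive":
        return [[] for _ in range(n_molecules)]
    # base-modification-window enzymes star out at high enzyme level
    if spec.license_mode == "basemod_window" and mode == "specific" and cond.enzyme_level == "high":
        mode = "relaxed"
    if spec.license_mode == "pattern_only" or mode == "relaxed":
        pattern = spec.pattern
        p_fire = cond.p_cleave_relaxed
        licensed_only = False
    else:
        pattern = spec.preferred_pattern or spec.pattern
        p_fire = cond.p_cleave_specific if mode in ("specific", "nick_only") else cond.p_cleave_relaxed
        licensed_only = spec.license_mode == "basemod_window"
    matches = find_pattern_matches(d, pattern)
    if licensed_only:
        mark_cols = [bm.column for bm in d.base_marks]
        L = d.length

        def near(col: int) -> bool:
            for mc in mark_cols:
                dist = abs(col - mc)
                if d.is_circular:
                    dist = min(dist, L - dist)
                if dist <= spec.window:
                    return True
            return False

        matches = [m for m in matches if near(m[2])]
    nicks_only = mode == "nick_only" or spec.license_mode == "pattern_only"
    ensemble: list[list[CutEvent]] = []
    for _ in range(n_molecules):
        events: list[CutEvent] = []
        for strand, _start, cut_lnk in matches:
            if rng.random() >= p_fire:
                continue
            if nicks_only or rng.random() >= cond.p_ds_given_cleave:
                if strand == "top":
                    events.append(CutEvent(None, "nick_top", cut_lnk, None, strand))
                else:
                    events.append(CutEvent(None, "nick_bottom", None, cut_lnk, strand))
            else:
                # blunt double-strand break at the pattern cut linkage
                events.append(CutEvent(None, "ds_cut", cut_lnk, cut_lnk, strand))
        ensemble.append(events)
    return ensemble


def digest(
    d: ModifiedDuplex,
    spec: EnzymeSpec,
    cond: Conditions,
    n_molecules: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[list[CutEvent]]:
    """Digest an ensemble of identical molecules; one event list per molecule.

    Each recognition site (or pattern match) fires independently per
    molecule according to :func:`license_site`; a firing event is a
    double-strand cut with probability ``cond.p_ds_given_cleave``, else a
    nick.  "Complete digestion" means one sampling round per molecule at
    the stated probabilities — no kinetics are modeled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec.cofactor_mode(cond.cofactor)  # raise early on unknown cofactor
    if spec.license_mode == "pt_site":
        sites = scan_sites(d, spec)
        return _pt_site_events(d, spec, cond, n_molecules, rng, sites)
    return _pattern_events(d, spec, cond, n_molecules, rng)


# --------------------------------------------------------------------------
# fragmentation


def _pieces(length: int, cuts: list[int], circular: bool) -> list[tuple[int, int]]:
    """Split one strand of columns 0..L-1 at the given linkages.

    Returns inclusive (start, end) intervals; for circular molecules with k
    cuts there are k intervals (possibly wrapping), for linear k+1.
    """
    cuts = sorted(set(cuts))
    if circular:
        if not cuts:
            return []
        out = []
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            out.append(((c + 1) % length, nxt % length))
        return out
    bounds = [-1] + cuts + [length - 1]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


def _piece_len(piece: tuple[int, int], length: int, circular: bool) -> int:
    s, e = piece
    if circular and e < s:
        return length - s + e + 1
    return e - s + 1


def fragments(d: ModifiedDuplex, events: Sequence[CutEvent]) -> list[Fragment]:
    """Digestion products of one molecule from its cut events.

    Double-strand cuts sever the molecule; k cuts give k fragments on a
    circle and k+1 on a line.  Per-strand piece lengths are conserved
    (sum to L on each strand).  A molecule with only nicks is reported
    intact, nicks annotated; an uncut circle yields no fragments.
    """
    ds = [ev for ev in events if ev.kind == "ds_cut"]
    nicks = tuple(ev for ev in events if ev.kind != "ds_cut")
    L = d.length
    circular = d.is_circular
    if not ds:
        if circular:
            return []
        return [Fragment((0, L - 1), (0, L - 1), L, nicks=nicks)]
    ds_unique = sorted(
        {(ev.top_cut_linkage, ev.bottom_cut_linkage) for ev in ds}
    )
    top_pieces = _pieces(L, [t for t, _ in ds_unique], circular)
    bottom_pieces = _pieces(L, [b for _, b in ds_unique], circular)
    if circular:
        # align piece lists so that fragment i starts just after cut i on
        # both strands (cuts sorted identically by construction for
        # orientation-consistent staggered ends)
        bottom_pieces = _align_circular(top_pieces, bottom_pieces, L)
    out = []
    for tp, bp in zip(top_pieces, bottom_pieces):
        lt = _piece_len(tp, L, circular)
        lb = _piece_len(bp, L, circular)
        out.append(Fragment(tp, bp, max(lt, lb), nicks=nicks))
    return out


def _align_circular(
    top_pieces: list[tuple[int, int]], bottom_pieces: list[tuple[int, int]], L: int
) -> list[tuple[int, int]]:
    """Rotate the bottom piece list to pair each top piece with the bottom
    piece whose start is nearest (staggered ends are a few nt apart)."""
    if len(bottom_pieces) <= 1:
        return bottom_pieces
    t0 = top_pieces[0][0]

    def circ_dist(a: int, b: int) -> int:
        dd = abs(a - b)
        return min(dd, L - dd)

    k = min(range(len(bottom_pieces)), key=lambda i: circ_dist(bottom_pieces[i][0], t0))
    return bottom_pieces[k:] + bottom_pieces[:k]


def exo1_filter(frags: Sequence[Fragment]) -> list[Fragment]:
    """Exonuclease I treatment: remove single-stranded fragments.

    Double-stranded fragments, including those with short 3' overhangs,
    survive unchanged.
    """
    return [f for f in frags if not f.single_stranded]
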