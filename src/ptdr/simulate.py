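"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the wet-lab substrates of a PT-restriction study:

* dnd+ plasmids whose GAAC/GTTC sites are partially phosphorothioated
  (default penetrance 0.20, the level reached by overexpressed dnd
  clusters; marks Rp on plasmids, racemic on synthetic oligos),
* the 60-mer oligoduplex panels with one or two sites in defined
  hemi/full modification states,
* partial-digest dideoxy run-off traces with the Taq extra-A doublet at
  broken template positions,
* gene-neighborhood tables with a configurable PTDR-dnd co-occurrence
  rate for the proximity screen.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    BaseMark,
    GenerationError,
    ModifiedDuplex,
    PTMark,
    find_motif_sites,
    site_mark_linkages,
)
from .digestion import CutEvent

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "TraceRecord",
    "RunoffTrace",
    "NeighborhoodTable",
    "DND_LABELS",
    "make_random_plasmid",
    "random_sequence_duplex",
    "apply_dnd_marks",
    "make_oligoduplex_panel",
    "simulate_runoff_trace",
    "make_neighborhood_tables",
]

SITE_MOTIF = "GAAC"  # scanning motif; GTTC occurrences are bottom-strand sites
DND_LABELS = ("dndB", "dndC", "dndD", "dndE", "dndF", "dndG", "dndH")
GENE_LABELS = DND_LABELS + ("ptdr", "transposase", "other")


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic-data generators.

    penetrance
        Probability that a duplex site carries any PT mark.  Default 0.20:
        overexpressed dnd clusters modify about 20% of potential PT sites.
    hemi_fraction
        Probability a marked site is hemi- rather than fully modified
        (site selection for full/hemi modification is not understood;
        0.5 is an uninformative split).
    rp_fraction
        Probability a mark is the Rp diastereomer.  1.0 for enzymatically
        modified plasmids; synthetic phosphoramidite oligos are racemic
        (use 0.5).
    cut_fraction
        Fraction of template molecules broken in a partial-digest run-off
        trace.
    noise_sd
        Relative (multiplicative) peak-height noise.
    """

    seed: int | np.random.SeedSequence = 0
    penetrance: float = 0.20
    hemi_fraction: float = 0.5
    rp_fraction: float = 1.0
    cut_fraction: float = 0.5
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("penetrance", "hemi_fraction", "rp_fraction", "cut_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")


# --------------------------------------------------------------------------
# plasmid generation

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _site_starts(seq: str, circular: bool) -> set[int]:
    import re

    text = seq + (seq if circular else "")
    L = len(seq)
    starts = set()
    for pat in ("GAAC", "GTTC"):
        for m in re.finditer(f"(?=({pat}))", text):
            if m.start() < L and (circular or m.start() + 4 <= L):
                starts.add(m.start() % L)
    return starts


def make_random_plasmid(
    length: int,
    n_sites: int,
    topology: str = "linear",
    seed: int | np.random.Generator = 0,
    max_tries: int = 40,
) -> ModifiedDuplex:
    """Random duplex with exactly ``n_sites`` GAAC/GTTC occurrences, unmarked.

    Sites are planted at least 10 bp apart (and, on linear molecules, at
    least 10 nt from either end so fixed-offset cleavage products stay on
    the molecule); the remaining sequence is scrubbed of accidental
    occurrences.  Reproducible under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length < 50:
        raise GenerationError(f"length {length} < 50")
    if n_sites * 10 >= length:
        raise GenerationError(f"cannot place {n_sites} sites >=10 bp apart in {length} nt")
    circular = topology == "circular"

    spacing = length // n_sites if n_sites else length
    planted: list[int] = []
    if n_sites:
        lo_margin = 0 if circular else 10
        for i in range(n_sites):
            lo = i * spacing + (lo_margin if i == 0 else 0)
            hi = (i + 1) * spacing - 10  # keep >=10 bp to the next block start
            if not circular:
                hi = min(hi, length - 14)  # site + end margin
            if hi < lo:
                raise GenerationError("site placement infeasible at this density")
            planted.append(int(rng.integers(lo, hi + 1)))

    seq = _random_seq(rng, length)
    protected = np.zeros(length, dtype=bool)
    for s in planted:
        motif = "GAAC" if rng.random() < 0.5 else "GTTC"
        for k, ch in enumerate(motif):
            seq[(s + k) % length] = ch
            protected[(s + k) % length] = True

    planted_set = set(planted)
    for _ in range(max_tries):
        extra = _site_starts("".join(seq), circular) - planted_set
        missing = planted_set - _site_starts("".join(seq), circular)
        if missing:  # a scrub mutated into a planted site footprint (shouldn't happen)
            raise GenerationError("planted site destroyed during scrubbing")
        if not extra:
            d = ModifiedDuplex(
                id=f"plasmid_L{length}_n{n_sites}", top_seq="".join(seq), topology=topology
            )
            found = _site_starts(d.top_seq, circular)
            if len(found) != n_sites:
                break
            return d
        for q in extra:
            cols = [(q + k) % length for k in range(4)]
            free = [c for c in cols if not protected[c]]
            if not free:
                raise GenerationError("accidental site fully inside planted footprint")
            c = free[int(rng.integers(len(free)))]
            choices = [b for b in "ACGT" if b != seq[c]]
            seq[c] = choices[int(rng.integers(3))]
    raise GenerationError("could not scrub accidental GAAC/GTTC occurrences")


def random_sequence_duplex(
    length: int,
    topology: str = "linear",
    seed: int | np.random.Generator = 0,
    dup_id: str | None = None,
) -> ModifiedDuplex:
    """Plain uniform-random duplex (no site-count constraint)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ModifiedDuplex(
        id=dup_id or f"random_L{length}",
        top_seq="".join(_random_seq(rng, length)),
        topology=topology,
    )


# --------------------------------------------------------------------------
# dnd marking


def apply_dnd_marks(d: ModifiedDuplex, p: SimParams) -> ModifiedDuplex:
    """Phosphorothioate the duplex's GAAC/GTTC sites per the dnd model.

    Each site is independently marked with probability ``p.penetrance``;
    a marked site is fully modified (GpsA and GpsT linkages on both
    strands) with probability ``1 - p.hemi_fraction``, else one strand is
    chosen uniformly.  Each mark is Rp with probability ``p.rp_fraction``.
    Marks are placed only at the GpsA/GpsT linkages of scanned sites.
    """
    rng = np.random.default_rng(p.seed)
    sites = find_motif_sites(d, SITE_MOTIF)
    out = d.copy()
    for site in sites:
        if rng.random() >= p.penetrance:
            continue
        positions = site_mark_linkages(site, d.length)
        if rng.random() < p.hemi_fraction:
            strands = [("top", "bottom")[int(rng.integers(2))]]
        else:
            strands = ["top", "bottom"]
        for strand in strands:
            stereo = "Rp" if rng.random() < p.rp_fraction else "Sp"
            out.pt_marks.add(PTMark(strand, positions[strand], stereo))
    return out


# --------------------------------------------------------------------------
# oligoduplex panel

_OLIGO_LEN = 60
_SINGLE_SITE_START = 26
_TWO_SITE_STARTS = (15, 35)  # two GTTC motif starts, 20 bp apart


def _mark_site(
    d: ModifiedDuplex, start: int, state: str, rng: np.random.Generator, rp_fraction: float
) -> None:
    """Add PT marks for one GTTC-on-top site: U (none), HT (GpsTTC strand),
    HB (GpsAAC strand) or F (both)."""
    strands = {"U": [], "HT": ["top"], "HB": ["bottom"], "F": ["top", "bottom"]}[state]
    for strand in strands:
        linkage = start if strand == "top" else start + 2
        stereo = "Rp" if rng.random() < rp_fraction else "Sp"
        d.pt_marks.add(PTMark(strand, linkage, stereo))


def _clean_background(rng: np.random.Generator, starts: Iterable[int]) -> list[str]:
    for _ in range(200):
        seq = list(_random_seq(rng, _OLIGO_LEN))
        for s in starts:
            seq[s : s + 4] = "GTTC"
        if _site_starts("".join(seq), circular=False) == set(starts):
            return seq
    raise GenerationError("could not build a clean oligo background")


def make_oligoduplex_panel(seed: int = 1, rp_fraction: float = 0.5) -> list[ModifiedDuplex]:
    """The synthetic 60-mer oligoduplex panel.

    Returns 13 duplexes: four single-site members (fully modified
    GpsTTC/GpsAAC, unmodified GTTC/GAAC, and the two hemi forms) followed
    by nine two-site members covering every {unmodified, hemi, full}
    combination of two sites whose GTTC motif starts are 20 bp apart
    (0-4 PT marks total).  Sites are identically positioned across panel
    members; backbones are seeded random sequence free of accidental
    sites.  Marks are racemic by default, as synthetic PT oligos contain
    both Rp and Sp diastereomers.  The 5'-FAM label of the bench assay is
    metadata only and carries no signal model.
    """
    rng = np.random.default_rng(seed)
    single_bg = _clean_background(rng, [_SINGLE_SITE_START])
    double_bg = _clean_background(rng, _TWO_SITE_STARTS)
    panel: list[ModifiedDuplex] = []
    for state, label in (("F", "full"), ("U", "unmod"), ("HT", "hemi_gpsT"), ("HB", "hemi_gpsA")):
        d = ModifiedDuplex(id=f"oligo1_{label}", top_seq="".join(single_bg))
        _mark_site(d, _SINGLE_SITE_START, state, rng, rp_fraction)
        panel.append(d)
    for s1 in ("U", "HT", "F"):
        for s2 in ("U", "HT", "F"):
            d = ModifiedDuplex(id=f"oligo2_{s1}_{s2}", top_seq="".join(double_bg))
            _mark_site(d, _TWO_SITE_STARTS[0], s1, rng, rp_fraction)
            _mark_site(d, _TWO_SITE_STARTS[1], s2, rng, rp_fraction)
            panel.append(d)
    return panel


# --------------------------------------------------------------------------
# run-off trace simulation


@dataclass(frozen=True)
class TraceRecord:
    read_pos: int
    template_col: int
    called_base: str
    heights: tuple[float, float, float, float]  # hA, hC, hG, hT


@dataclass
class RunoffTrace:
    """Simulated dideoxy run-off trace of one template strand.

    ``records[i].template_col == primer_start + direction * i``; the call
    is the channel with maximal height (the complement of the template
    base away from break doublets).
    """

    read_id: str
    template_strand: str
    primer_start: int
    direction: int
    records: list[TraceRecord] = field(default_factory=list)

    @property
    def columns(self) -> list[int]:
        return [r.template_col for r in self.records]


_CHANNELS = "ACGT"


def _break_linkages_on_strand(breaks: Iterable[CutEvent], strand: str) -> list[int]:
    out = []
    for ev in breaks:
        lnk = ev.top_cut_linkage if strand == "top" else ev.bottom_cut_linkage
        if lnk is None:
            logger.info("break %s not on sequenced strand %s; ignored", ev.kind, strand)
            continue
        out.append(lnk)
    return sorted(set(out))


def simulate_runoff_trace(
    d: ModifiedDuplex,
    breaks: Iterable[CutEvent],
    primer_start: int,
    template_strand: str = "top",
    p: SimParams | None = None,
    direction: int = 1,
    read_length: int | None = None,
    read_id: str = "trace",
) -> RunoffTrace:
    """Simulate a run-off trace over a partially broken template population.

    A fraction ``p.cut_fraction`` of template molecules is broken at each
    break linkage (applied sequentially in read order).  Taq adds a
    non-templated A to the terminated product, which co-migrates with the
    last templated base: at that read position the templated channel keeps
    the full surviving signal and the A channel gains ``f * cut_fraction``
    (the G/A, C/A or T/A doublet; a templated A shows as a single
    extra-high A peak).  All positions past a break are scaled by
    ``1 - cut_fraction``.  Relative Gaussian noise ``p.noise_sd`` is
    applied per channel.

    Breaks not on the sequenced strand are ignored (logged).  The
    doublet-position convention (direction +1: doublet at the column equal
    to the break linkage; -1: at linkage + 1) is shared with the caller in
    :mod:`ptdr.mapping`.
    """
    p = p or SimParams()
    rng = np.random.default_rng(p.seed)
    L = d.length
    if direction not in (1, -1):
        raise GenerationError("direction must be +1 or -1")
    linkages = _break_linkages_on_strand(breaks, template_strand)

    # map each break to the read position of its doublet (last templated base)
    def doublet_col(lnk: int) -> int:
        return lnk if direction == 1 else (lnk + 1) % L

    if read_length is None:
        if d.is_circular:
            read_length = L
        else:
            read_length = (L - primer_start) if direction == 1 else primer_start + 1
    cols = [(primer_start + direction * i) % L for i in range(read_length)]
    dcol_to_breaks: dict[int, int] = {}
    for lnk in linkages:
        c = doublet_col(lnk)
        if c not in cols:
            raise GenerationError(
                f"break at linkage {lnk} not downstream of primer at {primer_start}"
            )
        dcol_to_breaks[c] = dcol_to_breaks.get(c, 0) + 1

    records: list[TraceRecord] = []
    f = 1.0
    for i, c in enumerate(cols):
        heights = dict.fromkeys(_CHANNELS, 0.0)
        template_base = d.strand_base(template_strand, c)
        called = template_base.translate(str.maketrans("ACGTN", "TGCAN"))
        if called == "N":
            called = "A"
        n_here = dcol_to_breaks.get(c, 0)
        if n_here:
            f_after = f * (1.0 - p.cut_fraction) ** n_here
            heights[called] += f  # all current molecules template this base
            heights["A"] += f - f_after  # co-migrating terminal +A products
            f = f_after
        else:
            heights[called] += f
        if p.noise_sd > 0:
            for ch in _CHANNELS:
                if heights[ch] > 0:
                    heights[ch] = max(0.0, heights[ch] * (1.0 + rng.normal(0.0, p.noise_sd)))
        hs = tuple(heights[ch] for ch in _CHANNELS)
        call = _CHANNELS[int(np.argmax(hs))]
        records.append(TraceRecord(i, c, call, hs))
    return RunoffTrace(read_id, template_strand, primer_start, direction, records)


# --------------------------------------------------------------------------
# gene neighborhoods


@dataclass
class NeighborhoodTable:
    """Ordered gene list of one genome for the co-occurrence screen."""

    genome_id: str
    genes: list[tuple[int, str, str]]  # (gene_index, label, strand)


def make_neighborhood_tables(
    n_genomes: int,
    cooccur_rate: float,
    genes_per_genome: int = 15,
    max_sep_distribution: Sequence[int] = (1, 2, 3),
    seed: int | np.random.Generator = 0,
    background_dnd_rate: float = 0.3,
) -> list[NeighborhoodTable]:
    """Synthetic gene neighborhoods with a controlled PTDR-dnd association.

    Each genome holds exactly one ``ptdr`` gene.  With probability
    ``cooccur_rate`` a dnd-labeled gene is planted at a separation drawn
    from ``max_sep_distribution`` (defaults strictly below the screen's
    flagging threshold of 4); otherwise any background dnd gene is placed
    at least 5 genes away, so it never flags.  Requires at least 11 genes
    per genome to guarantee a non-flagging placement exists.
    """
    if genes_per_genome < 11:
        raise GenerationError("genes_per_genome must be >= 11")
    if not 0.0 <= cooccur_rate <= 1.0:
        raise GenerationError("cooccur_rate outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = []
    n = genes_per_genome
    for g in range(n_genomes):
        labels = ["other"] * n
        ptdr_idx = int(rng.integers(n))
        labels[ptdr_idx] = "ptdr"
        if rng.random() < cooccur_rate:
            sep = int(max_sep_distribution[int(rng.integers(len(max_sep_distribution)))])
            options = [i for i in (ptdr_idx - sep, ptdr_idx + sep) if 0 <= i < n]
            idx = options[int(rng.integers(len(options)))]
            labels[idx] = DND_LABELS[int(rng.integers(len(DND_LABELS)))]
        elif rng.random() < background_dnd_rate:
            far = [i for i in range(n) if abs(i - ptdr_idx) >= 5]
            idx = far[int(rng.integers(len(far)))]
            labels[idx] = DND_LABELS[int(rng.integers(len(DND_LABELS)))]
        if rng.random() < 0.1:
            free = [i for i, lab in enumerate(labels) if lab == "other"]
            if free:
                labels[free[int(rng.integers(len(free)))]] = "transposase"
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
        tables.append(
            NeighborhoodTable(
                genome_id=f"genome_{g:05d}",
                genes=[(i, labels[i], strands[i]) for i in range(n)],
            )
        )
    return tables
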