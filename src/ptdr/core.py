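"""Domain model for phosphorothioate (PT)-dependent restriction analysis.

This module defines the shared coordinate conventions, the substrate and
enzyme data types, and the enzyme-specification registry used by the
digestion, trace-simulation and cut-site-inference stages.

Coordinate conventions
----------------------
All positions are 0-based *top-strand column* coordinates.

* A **column** ``c`` addresses the top-strand base ``top_seq[c]`` and the
  bottom-strand base paired with it (the complement).
* A **linkage** ``i`` addresses an internucleotide phosphate.  On the top
  strand, linkage ``i`` is the phosphate between columns ``i`` and ``i+1``.
  On the bottom strand, linkage ``i`` is the bottom-strand phosphate spanning
  the bases complementary to columns ``i`` and ``i+1``.  On a circular
  molecule of length ``L`` the linkage ``L-1`` wraps between columns ``L-1``
  and ``0``; on a linear molecule it does not exist.
* Recognition-site cleavage offsets use REBASE-style ``Nt/Nb`` notation:
  for a site whose motif reads left-to-right on the guiding strand and ends
  at column ``e``, the guiding-strand cut is at linkage ``e + t`` and the
  opposite-strand cut at ``e + b`` (mirrored for sites read on the bottom
  strand).  ``t - b > 0`` yields a 3' overhang of ``t - b`` nucleotides.

For a GAAC site read on the top strand at columns ``s..s+3``, the
PT-licensable GpsA linkage is ``(top, s)``; the complementary GTTC strand
carries its GpsT linkage at ``(bottom, s+2)``.  For a GAAC site read on the
bottom strand (the top strand shows GTTC at ``s..s+3``) the positions are
mirrored: GpsA at ``(bottom, s+2)`` and GpsT at ``(top, s)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PtdrError",
    "RegistryError",
    "GeometryError",
    "SubstrateError",
    "GenerationError",
    "ConfigurationError",
    "InputError",
    "PTMark",
    "BaseMark",
    "ModifiedDuplex",
    "RecognitionSite",
    "EnzymeSpec",
    "IUPAC_BASES",
    "iupac_code",
    "iupac_regex",
    "reverse_complement",
    "reverse_complement_duplex",
    "find_motif_sites",
    "find_pattern_matches",
    "site_mark_linkages",
    "load_enzyme_specs",
    "shipped_registry_path",
    "validate_substrate",
]


class PtdrError(Exception):
    """Base class for all package errors."""


class RegistryError(PtdrError):
    """Invalid enzyme registry content."""


class GeometryError(RegistryError):
    """Inconsistent cleavage-offset geometry in an enzyme record."""


class SubstrateError(PtdrError):
    """A substrate violates the duplex/mark invariants."""


class GenerationError(PtdrError):
    """A synthetic-data generator could not satisfy its contract."""


class ConfigurationError(PtdrError):
    """Invalid run conditions (e.g. unknown cofactor mode)."""


class InputError(PtdrError):
    """Invalid user-supplied analysis input."""


# --------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

IUPAC_BASES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODE_FOR = {frozenset(bases): code for code, bases in IUPAC_BASES.items()}

STRANDS = ("top", "bottom")
COFACTOR_KEYS = frozenset({"Mg", "Mn", "Ni", "Ca", "Co", "EDTA", "none"})
COFACTOR_MODES = frozenset({"specific", "relaxed", "nick_only", "partial", "inactive"})
LICENSE_MODES = frozenset({"pt_site", "basemod_window", "pattern_only"})
BASE_MODS = frozenset({"5mC", "5hmC", "g5hmC"})
STEREO = frozenset({"Rp", "Sp"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC degeneracy code covering exactly the given set of ACGT bases."""
    key = frozenset(bases)
    try:
        return _CODE_FOR[key]
    except KeyError:
        raise ValueError(f"not a base set: {sorted(key)!r}") from None


def iupac_regex(motif: str) -> str:
    """Regex character-class expansion of an IUPAC motif."""
    parts = []
    for ch in motif.upper():
        bases = IUPAC_BASES.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def _other(strand: str) -> str:
    return "bottom" if strand == "top" else "top"


# --------------------------------------------------------------------------
# substrate types


@dataclass(frozen=True, order=True)
class PTMark:
    """A phosphorothioate mark on one internucleotide linkage.

    ``linkage`` is a top-coordinate linkage index (see module docstring);
    ``stereo`` is the sulfur diastereomer, Rp being the physiological form.
    """

    strand: str
    linkage: int
    stereo: str = "Rp"


@dataclass(frozen=True, order=True)
class BaseMark:
    """A modified cytosine (5mC / 5hmC / g5hmC) at one column of one strand."""

    strand: str
    column: int
    mod: str = "5mC"


@dataclass
class ModifiedDuplex:
    """A double-stranded DNA molecule with backbone and base modifications.

    The top strand is stored 5'->3'; the bottom strand is implied by
    complementarity.  ``pt_marks`` and ``base_marks`` live in top-strand
    coordinates regardless of the strand they sit on.
    """

    id: str
    top_seq: str
    topology: str = "linear"
    pt_marks: set[PTMark] = field(default_factory=set)
    base_marks: set[BaseMark] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.top_seq = self.top_seq.upper()

    @property
    def length(self) -> int:
        return len(self.top_seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def top_base(self, column: int) -> str:
        return self.top_seq[column % self.length]

    def bottom_base(self, column: int) -> str:
        """Base on the bottom strand paired with ``column`` (a single letter)."""
        return self.top_base(column).translate(_COMPLEMENT)

    def strand_base(self, strand: str, column: int) -> str:
        return self.top_base(column) if strand == "top" else self.bottom_base(column)

    def copy(self, **changes) -> "ModifiedDuplex":
        base = replace(self, pt_marks=set(self.pt_marks), base_marks=set(self.base_marks))
        for key, value in changes.items():
            setattr(base, key, value)
        return base


@dataclass(frozen=True)
class RecognitionSite:
    """One occurrence of an enzyme's recognition motif on a duplex.

    ``start``/``end`` are top coordinates of the motif's first and last base
    *in top-strand reading order* (``end`` may wrap past the origin on a
    circular molecule, in which case it is stored modulo L).  For
    ``site_strand == "bottom"``, the motif read 5'->3' on the bottom strand
    runs from column ``end`` down to column ``start``.
    """

    duplex_id: str
    site_strand: str
    start: int
    end: int
    ga_linkage: tuple[str, int]


# --------------------------------------------------------------------------
# enzyme specification


@dataclass(frozen=True)
class EnzymeSpec:
    """Declarative model of one modification-dependent endonuclease.

    Parameters mirror how the enzymes are described in the restriction
    field: an IUPAC ``recognition`` motif, REBASE-style cleavage offset
    ranges ``top_offset_range``/``bottom_offset_range`` (nt 3' of the motif
    end, guiding strand and opposite strand respectively), hemi-site
    directionality, stereoselectivity, a two-site activity boost, and a
    cofactor -> activity-mode table.
    """

    name: str
    license_mode: str
    recognition: str = ""
    pt_linkage_offset: int = 0
    top_offset_range: tuple[int, int] = (0, 0)
    bottom_offset_range: tuple[int, int] = (0, 0)
    hemi_side: str = "both"
    requires_full: bool = False
    two_site_factor: float = 1.0
    rp_only: bool = False
    pattern: str = ""
    preferred_pattern: str = ""
    window: int = 20
    cofactors: Mapping[str, str] = field(default_factory=dict)

    @property
    def overhang_range(self) -> tuple[int, int]:
        t0, t1 = self.top_offset_range
        b0, b1 = self.bottom_offset_range
        return (t0 - b1, t1 - b0)

    def cofactor_mode(self, cofactor: str) -> str:
        if cofactor not in COFACTOR_KEYS:
            raise ConfigurationError(f"unknown cofactor {cofactor!r}")
        return self.cofactors.get(cofactor, "inactive")


def _as_range(value, name: str) -> tuple[int, int]:
    if isinstance(value, int):
        return (value, value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        lo, hi = int(value[0]), int(value[1])
        if lo > hi:
            raise RegistryError(f"{name}: range {value!r} has lo > hi")
        return (lo, hi)
    raise RegistryError(f"{name}: offset range must be an int or [lo, hi], got {value!r}")


def _validate_record(rec: dict) -> EnzymeSpec:
    name = rec.get("name")
    if not name:
        raise RegistryError("enzyme record without a name")
    mode = rec.get("license_mode")
    if mode not in LICENSE_MODES:
        raise RegistryError(f"{name}: unknown license_mode {mode!r}")
    cofactors = dict(rec.get("cofactors") or {})
    for key, cmode in cofactors.items():
        if key not in COFACTOR_KEYS:
            raise RegistryError(f"{name}: unknown cofactor key {key!r}")
        if cmode not in COFACTOR_MODES:
            raise RegistryError(f"{name}: unknown cofactor mode {cmode!r}")

    top = _as_range(rec.get("top_offset", (0, 0)), f"{name}.top_offset")
    bottom = _as_range(rec.get("bottom_offset", (0, 0)), f"{name}.bottom_offset")
    if mode == "pt_site":
        if not rec.get("recognition"):
            raise RegistryError(f"{name}: pt_site enzymes need a recognition motif")
        if top[0] < bottom[0] or top[1] < bottom[1]:
            raise GeometryError(
                f"{name}: top offsets {top} below bottom offsets {bottom} (t < b)"
            )
    if mode in ("basemod_window", "pattern_only") and "^" not in rec.get("pattern", ""):
        raise RegistryError(f"{name}: {mode} enzymes need a cleavage pattern with '^'")

    return EnzymeSpec(
        name=name,
        license_mode=mode,
        recognition=rec.get("recognition", "").upper(),
        pt_linkage_offset=int(rec.get("pt_linkage_offset", 0)),
        top_offset_range=top,
        bottom_offset_range=bottom,
        hemi_side=rec.get("hemi_side", "both"),
        requires_full=bool(rec.get("requires_full", False)),
        two_site_factor=float(rec.get("two_site_factor", 1.0)),
        rp_only=bool(rec.get("rp_only", False)),
        pattern=rec.get("pattern", "").upper(),
        preferred_pattern=rec.get("preferred_pattern", "").upper(),
        window=int(rec.get("window", 20)),
        cofactors=cofactors,
    )


def shipped_registry_path() -> Path:
    """Path to the packaged ``enzymes.yaml`` registry."""
    return Path(resources.files("ptdr").joinpath("data/enzymes.yaml"))  # type: ignore[arg-type]


def load_enzyme_specs(registry_path: str | Path | None = None) -> dict[str, EnzymeSpec]:
    """Load and validate an enzyme registry (YAML list of records).

    With no argument, loads the registry shipped with the package, which
    transcribes the characterized GpsAAC/GpsTTC-family endonucleases plus
    ScoMcrA and the SprMcrA-S nickase.
    """
    path = Path(registry_path) if registry_path is not None else shipped_registry_path()
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise RegistryError("registry must be a YAML list of enzyme records")
    registry: dict[str, EnzymeSpec] = {}
    for rec in records:
        spec = _validate_record(rec)
        if spec.name in registry:
            raise RegistryError(f"duplicate enzyme name {spec.name!r}")
        registry[spec.name] = spec
    return registry


# --------------------------------------------------------------------------
# substrate validation


def validate_substrate(d: ModifiedDuplex) -> ModifiedDuplex:
    """Check all ModifiedDuplex invariants; return the input unchanged if valid.

    Raises SubstrateError for an empty/invalid sequence, an out-of-bounds
    mark, duplicate (strand, linkage) PT marks, or a cytosine-modification
    mark on a non-C base.
    """
    L = d.length
    if L == 0:
        raise SubstrateError(f"{d.id}: empty sequence")
    if not re.fullmatch("[ACGTN]+", d.top_seq):
        raise SubstrateError(f"{d.id}: sequence has characters outside ACGTN")
    if d.topology not in ("linear", "circular"):
        raise SubstrateError(f"{d.id}: unknown topology {d.topology!r}")
    max_linkage = L if d.is_circular else L - 1
    seen: set[tuple[str, int]] = set()
    for mark in d.pt_marks:
        if mark.strand not in STRANDS:
            raise SubstrateError(f"{d.id}: bad strand {mark.strand!r}")
        if mark.stereo not in STEREO:
            raise SubstrateError(f"{d.id}: bad stereochemistry {mark.stereo!r}")
        if not 0 <= mark.linkage < max_linkage:
            raise SubstrateError(
                f"{d.id}: PT linkage {mark.linkage} out of bounds for "
                f"{d.topology} duplex of length {L}"
            )
        key = (mark.strand, mark.linkage)
        if key in seen:
            raise SubstrateError(f"{d.id}: duplicate PT mark at {key}")
        seen.add(key)
    for bm in d.base_marks:
        if bm.strand not in STRANDS:
            raise SubstrateError(f"{d.id}: bad strand {bm.strand!r}")
        if bm.mod not in BASE_MODS:
            raise SubstrateError(f"{d.id}: unknown base modification {bm.mod!r}")
        if not 0 <= bm.column < L:
            raise SubstrateError(f"{d.id}: base mark column {bm.column} out of bounds")
        if d.strand_base(bm.strand, bm.column) != "C":
            raise SubstrateError(
                f"{d.id}: {bm.mod} mark at ({bm.strand}, {bm.column}) is not on a C "
                f"(found {d.strand_base(bm.strand, bm.column)})"
            )
    return d


# --------------------------------------------------------------------------
# motif and pattern scanning


def _scan_one_strand(d: ModifiedDuplex, regex: str) -> list[int]:
    """Start columns of overlapping matches on the top-strand string.

    Circular molecules are scanned over a doubled string so matches may
    wrap the origin; starts are reported modulo L and deduplicated.
    """
    text = d.top_seq + (d.top_seq if d.is_circular else "")
    pat = re.compile(f"(?=({regex}))")
    L = d.length
    starts: set[int] = set()
    for m in pat.finditer(text):
        if m.start() < L:
            starts.add(m.start() % L)
    return sorted(starts)


def site_mark_linkages(site: RecognitionSite, length: int, pt_offset: int = 0,
                       motif_len: int = 4) -> dict[str, int]:
    """Top-coordinate PT linkage positions of a GAAC/GTTC-style duplex site.

    Returns ``{"top": i, "bottom": j}`` where the top entry is the phosphate
    on the top strand between motif bases ``pt_offset`` and ``pt_offset+1``
    (as read on whichever strand spells the recognition motif leftward in
    top coordinates) and the bottom entry is its complementary-strand
    counterpart.  For GAAC/GTTC with ``pt_offset = 0`` these are the GpsA
    and GpsT linkages.
    """
    s = site.start
    e_un = s + motif_len - 1
    return {
        "top": (s + pt_offset) % length,
        "bottom": (e_un - pt_offset - 1) % length,
    }


def find_motif_sites(d: ModifiedDuplex, motif: str, pt_offset: int = 0) -> list[RecognitionSite]:
    """All occurrences of an IUPAC motif on both strands of a duplex.

    A bottom-strand site is an occurrence of the motif's reverse complement
    on the top-strand string.  Sites are ordered by start column, top strand
    before bottom.  Palindromic motifs are reported once per location per
    strand orientation that matches.
    """
    L = d.length
    m = len(motif)
    sites: list[RecognitionSite] = []
    rc = reverse_complement(motif)
    for strand, mot in (("top", motif), ("bottom", rc)):
        for s in _scan_one_strand(d, iupac_regex(mot)):
            e_un = s + m - 1
            if not d.is_circular and e_un >= L:
                continue
            if strand == "top":
                ga = ("top", (s + pt_offset) % L)
            else:
                ga = ("bottom", (e_un - pt_offset - 1) % L)
            sites.append(
                RecognitionSite(
                    duplex_id=d.id,
                    site_strand=strand,
                    start=s,
                    end=e_un % L,
                    ga_linkage=ga,
                )
            )
    if motif == rc:
        # palindromic motif: top and bottom scans see the same occurrences;
        # keep the top-strand report only
        sites = [s for s in sites if s.site_strand == "top"]
    sites.sort(key=lambda s: (s.start, s.site_strand != "top"))
    return sites


def find_pattern_matches(d: ModifiedDuplex, pattern: str) -> list[tuple[str, int, int]]:
    """Occurrences of a cleavage pattern (IUPAC with a ``^`` cut mark).

    Returns ``(strand, start_column, cut_linkage)`` tuples for matches on
    both strands; ``cut_linkage`` is the top-coordinate linkage of the cut
    on the *match* strand.  The start column is the leftmost top coordinate
    of the matched window regardless of strand.
    """
    if "^" not in pattern:
        raise ValueError(f"pattern {pattern!r} lacks a '^' cut mark")
    cut = pattern.index("^")
    core = pattern.replace("^", "")
    m = len(core)
    L = d.length
    out: list[tuple[str, int, int]] = []
    for s in _scan_one_strand(d, iupac_regex(core)):
        e_un = s + m - 1
        if not d.is_circular and e_un >= L:
            continue
        out.append(("top", s, (s + cut - 1) % L))
    rc = reverse_complement(core)
    rc_scan = rc != core or True  # bottom scan always needed for cut position
    if rc_scan:
        for s in _scan_one_strand(d, iupac_regex(rc)):
            e_un = s + m - 1
            if not d.is_circular and e_un >= L:
                continue
            # pattern index k sits at top column e_un - k; cut between
            # indices cut-1 and cut -> linkage spanning columns
            # (e_un - cut, e_un - cut + 1)
            out.append(("bottom", s, (e_un - cut) % L))
    out.sort(key=lambda t: (t[1], t[0] != "top"))
    return out


# --------------------------------------------------------------------------
# coordinate transforms (used by property tests and mark plumbing)


def reverse_complement_duplex(d: ModifiedDuplex) -> ModifiedDuplex:
    """The same physical molecule written with the strands swapped.

    Columns map as ``c -> L-1-c``; a linkage spanning columns ``(i, i+1)``
    maps to the linkage spanning ``(L-2-i, L-1-i)`` (modulo L when
    circular), and every mark switches strand.
    """
    L = d.length
    wrap = L if d.is_circular else None

    def map_linkage(i: int) -> int:
        j = L - 2 - i
        return j % wrap if wrap else j

    pt = {
        PTMark(_other(m.strand), map_linkage(m.linkage), m.stereo) for m in d.pt_marks
    }
    bm = {
        BaseMark(_other(b.strand), L - 1 - b.column, b.mod) for b in d.base_marks
    }
    return ModifiedDuplex(
        id=d.id + "_rc",
        top_seq=reverse_complement(d.top_seq),
        topology=d.topology,
        pt_marks=pt,
        base_marks=bm,
    )
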