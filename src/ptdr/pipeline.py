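"""End-to-end drivers chaining the simulation and inference stages.

These functions reproduce the characterization experiments in silico:
simulate a modified substrate, digest it, sequence the products by
run-off traces, call the breaks and infer the cleavage geometry or
consensus.  They are the entry points used by the acceptance checks and
the CLI; each is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .assay import EnsembleSummary, ensemble_summary
from .core import BaseMark, EnzymeSpec, ModifiedDuplex, find_pattern_matches, load_enzyme_specs
from .digestion import Conditions, CutEvent, digest, scan_sites
from .mapping import (
    BreakCall,
    CutGeometry,
    build_pwm,
    call_breaks,
    events_to_calls,
    infer_cut_geometry,
    iupac_consensus,
)
from .simulate import (
    SimParams,
    apply_dnd_marks,
    make_neighborhood_tables,
    make_random_plasmid,
    random_sequence_duplex,
    simulate_runoff_trace,
)
from .neighborhood import CooccurrenceEstimate, cooccurrence_fraction, proximity_scan

__all__ = [
    "geometry_roundtrip",
    "pattern_consensus",
    "scomcra_consensus",
    "penetrance_recovery",
    "ds_ss_ratio_ensemble",
    "neighborhood_recovery",
]


def _streams(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent per-stage seed sequences spawned from one root seed."""
    return np.random.SeedSequence(seed).spawn(n)


def _unique_events(ensemble) -> list[CutEvent]:
    seen = set()
    out = []
    for events in ensemble:
        for ev in events:
            key = (ev.kind, ev.top_cut_linkage, ev.bottom_cut_linkage)
            if key not in seen:
                seen.add(key)
                out.append(ev)
    return out


def geometry_roundtrip(
    enzyme: str | EnzymeSpec,
    cofactor: str,
    seed: int = 1,
    length: int = 300,
    n_molecules: int = 40,
    cut_fraction: float = 0.5,
    noise_sd: float = 0.02,
) -> CutGeometry:
    """Full simulate -> digest -> trace -> call -> infer round trip.

    Generates a linear duplex with one fully Rp-modified site, digests it
    to completion (firing probability 1, all double-strand cuts),
    sequences both strands as partial-digest run-off traces and infers
    the Nt/Nb geometry from the called breaks.
    """
    spec = enzyme if isinstance(enzyme, EnzymeSpec) else load_enzyme_specs()[enzyme]
    s_gen, s_mark, s_dig, s_trace, s_ctl = _streams(seed, 5)
    d = make_random_plasmid(length, 1, "linear", np.random.default_rng(s_gen))
    d = apply_dnd_marks(
        d, SimParams(seed=s_mark, penetrance=1.0, hemi_fraction=0.0, rp_fraction=1.0)
    )
    cond = Conditions(cofactor=cofactor, p_cleave_specific=1.0, p_ds_given_cleave=1.0)
    ensemble = digest(d, spec, cond, n_molecules=n_molecules, seed=np.random.default_rng(s_dig))
    breaks = _unique_events(ensemble)
    trace_params = SimParams(seed=s_trace, cut_fraction=cut_fraction, noise_sd=noise_sd)
    control_params = SimParams(seed=s_ctl, cut_fraction=cut_fraction, noise_sd=noise_sd)
    calls: list[BreakCall] = []
    for strand, primer, direction in (("top", 0, 1), ("bottom", d.length - 1, -1)):
        trace = simulate_runoff_trace(d, breaks, primer, strand, trace_params, direction)
        control = simulate_runoff_trace(d, [], primer, strand, control_params, direction)
        calls.extend(call_breaks(trace, control))
    sites = scan_sites(d, spec)
    return infer_cut_geometry(
        calls, sites, motif_len=len(spec.recognition), duplex_length=d.length,
        enzyme_hint=spec.name,
    )


def pattern_consensus(
    enzyme: str | EnzymeSpec = "SprMcrA-S",
    cofactor: str = "Mn",
    seed: int = 1,
    length: int = 10_000,
    left: int = 2,
    right: int = 2,
    include_threshold: float = 0.25,
) -> tuple[str, int]:
    """Consensus of pattern-directed nicks on random DNA.

    Digests a random duplex, maps every nick back to its window on the
    nicked strand and compiles the IUPAC consensus; returns it with the
    number of stacked sites.
    """
    spec = enzyme if isinstance(enzyme, EnzymeSpec) else load_enzyme_specs()[enzyme]
    s_gen, s_dig = _streams(seed, 2)
    d = random_sequence_duplex(length, "linear", np.random.default_rng(s_gen))
    cond = Conditions(cofactor=cofactor, p_cleave_relaxed=1.0)
    ensemble = digest(d, spec, cond, n_molecules=1, seed=np.random.default_rng(s_dig))
    calls = events_to_calls(_unique_events(ensemble), strands="guide")
    pwm = build_pwm(d, calls, left=left, right=right)
    return iupac_consensus(pwm, include_threshold), pwm.n_sites


def scomcra_consensus(
    seed: int = 1,
    length: int = 10_000,
    relaxed: bool = False,
    max_marks: int = 60,
) -> tuple[str, int]:
    """ScoMcrA cleavage consensus on a methylated random substrate.

    In specific mode the substrate's cytosines near preferred-pattern
    matches are 5mC-marked (mimicking Dcm-adjacent licensing) and the
    enzyme is run at low level in Mn2+; in relaxed mode (high enzyme
    level) all relaxed-pattern matches fire.
    """
    registry = load_enzyme_specs()
    spec = registry["ScoMcrA"]
    s_gen, s_dig = _streams(seed, 2)
    d = random_sequence_duplex(length, "linear", np.random.default_rng(s_gen))
    if not relaxed:
        # mark the internal C of preferred-pattern matches (column start+1
        # on the match strand is a C for ACNGT on either strand)
        for strand, start, _cut in find_pattern_matches(d, spec.preferred_pattern)[:max_marks]:
            col = start + 1 if strand == "top" else start + 3
            if d.strand_base(strand, col) == "C":
                d.base_marks.add(BaseMark(strand, col, "5mC"))
    cond = Conditions(
        cofactor="Mn",
        enzyme_level="high" if relaxed else "low",
        p_cleave_specific=1.0,
        p_cleave_relaxed=1.0,
        p_ds_given_cleave=1.0,
    )
    ensemble = digest(d, spec, cond, n_molecules=1, seed=np.random.default_rng(s_dig))
    calls = events_to_calls(_unique_events(ensemble), strands="guide")
    pwm = build_pwm(d, calls, left=3, right=2)
    return iupac_consensus(pwm), pwm.n_sites


def penetrance_recovery(
    seed: int = 7,
    n_sites: int = 10_000,
    penetrance: float | None = None,
) -> EnsembleSummary:
    """Recover the dnd marking penetrance by complete EcoWI digestion.

    Builds a circular plasmid with ``n_sites`` GAAC/GTTC sites, marks it
    at the (default 20%) penetrance with Rp stereochemistry, digests to
    completion in Mg2+ and reports the fraction of sites with at least
    one break.
    """
    spec = load_enzyme_specs()["EcoWI"]
    length = max(16 * n_sites, 200)
    s_gen, s_mark, s_dig = _streams(seed, 3)
    d = make_random_plasmid(length, n_sites, "circular", np.random.default_rng(s_gen))
    params = SimParams(seed=s_mark, rp_fraction=1.0)
    if penetrance is not None:
        params.penetrance = penetrance
    d = apply_dnd_marks(d, params)
    cond = Conditions(cofactor="Mg", p_cleave_specific=1.0)
    ensemble = digest(d, spec, cond, n_molecules=1, seed=np.random.default_rng(s_dig))
    return ensemble_summary(ensemble, n_sites)


def ds_ss_ratio_ensemble(
    seed: int = 5,
    n_sites: int = 20,
    n_molecules: int = 10_000,
) -> EnsembleSummary:
    """ds:ss break ratio of a high-enzyme EcoWI ensemble.

    Fully modified circular plasmid, default event-type probability
    (ds cut with p = 0.75, reproducing the ~3:1 ratio observed at high
    enzyme concentration).
    """
    spec = load_enzyme_specs()["EcoWI"]
    s_gen, s_mark, s_dig = _streams(seed, 3)
    d = make_random_plasmid(max(30 * n_sites, 200), n_sites, "circular", np.random.default_rng(s_gen))
    d = apply_dnd_marks(
        d, SimParams(seed=s_mark, penetrance=1.0, hemi_fraction=0.0, rp_fraction=1.0)
    )
    cond = Conditions(cofactor="Mg", enzyme_level="high")
    ensemble = digest(d, spec, cond, n_molecules=n_molecules, seed=np.random.default_rng(s_dig))
    return ensemble_summary(ensemble, n_sites)


def neighborhood_recovery(
    seed: int = 11,
    n_genomes: int = 5_000,
    cooccur_rate: float = 0.036,
    max_sep: int = 4,
) -> CooccurrenceEstimate:
    """Inject a PTDR-dnd co-occurrence rate and recover it by the screen."""
    (s_gen,) = _streams(seed, 1)
    tables = make_neighborhood_tables(n_genomes, cooccur_rate, seed=np.random.default_rng(s_gen))
    results = [proximity_scan(t, max_sep=max_sep) for t in tables]
    return cooccurrence_fraction(results)
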