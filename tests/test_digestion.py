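"""Site scanning, licensing rules, cutting geometry, fragmentation."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptdr.core import ConfigurationError, PTMark, find_pattern_matches
from ptdr.digestion import (
    Conditions,
    CutEvent,
    Fragment,
    digest,
    exo1_filter,
    fragments,
    license_site,
    scan_sites,
)
from ptdr.simulate import SimParams, apply_dnd_marks, make_random_plasmid, random_sequence_duplex

from .conftest import brute_force_site_starts, make_duplex


def fully_marked(length=300, n_sites=1, topology="linear", seed=1, stereo_rp=True):
    d = make_random_plasmid(length, n_sites, topology, seed)
    return apply_dnd_marks(
        d,
        SimParams(seed=seed, penetrance=1.0, hemi_fraction=0.0,
                  rp_fraction=1.0 if stereo_rp else 0.0),
    )


COMPLETE = dict(p_cleave_specific=1.0, p_ds_given_cleave=1.0)


# --------------------------------------------------------------------------
# scanning


def test_scan_finds_sites_on_both_strands(registry):
    spec = registry["EcoWI"]
    d = make_duplex("TTTTGAACTTTTTTTTGTTCTTTT")
    sites = scan_sites(d, spec)
    assert [(s.site_strand, s.start) for s in sites] == [("top", 4), ("bottom", 16)]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), circular=st.booleans())
def test_scan_matches_brute_force_oracle(registry, seed, circular):
    d = random_sequence_duplex(400, "circular" if circular else "linear", seed)
    found = {(s.site_strand, s.start) for s in scan_sites(d, registry["EcoWI"])}
    assert found == brute_force_site_starts(d.top_seq, circular)


def test_scan_order_is_deterministic(registry):
    d = random_sequence_duplex(10_000, "linear", 42)
    sites = scan_sites(d, registry["EcoWI"])
    assert sites == sorted(sites, key=lambda s: (s.start, s.site_strand != "top"))


# --------------------------------------------------------------------------
# licensing


def test_unmarked_site_not_licensed_in_specific_mode(registry):
    d = make_random_plasmid(300, 1, "linear", 1)
    (site,) = scan_sites(d, registry["EcoWI"])
    assert license_site(site, d, registry["EcoWI"], Conditions(cofactor="Mg")) == (0.0, 0.0)


def test_fully_marked_site_licensed_both_orientations(registry):
    d = fully_marked()
    (site,) = scan_sites(d, registry["EcoWI"])
    p = license_site(site, d, registry["EcoWI"], Conditions(cofactor="Mg"))
    assert p[0] > 0 and p[1] > 0


def test_hemi_site_directionality_ecowi_vs_ksp(registry):
    """EcoWI cleaves downstream of the marked strand, Ksp11411I upstream."""
    d = make_random_plasmid(300, 1, "linear", 1)
    (site,) = scan_sites(d, registry["EcoWI"])
    # mark only the top strand (GpsA of a top GAAC / GpsT of a top GTTC)
    d.pt_marks.add(PTMark("top", site.start if site.site_strand == "top" else site.start, "Rp"))
    p_eco = license_site(site, d, registry["EcoWI"], Conditions(cofactor="Mg"))
    p_ksp = license_site(site, d, registry["Ksp11411I"], Conditions(cofactor="Ni"))
    assert p_eco[0] > 0 and p_eco[1] == 0
    assert p_ksp[0] == 0 and p_ksp[1] > 0


def test_bsp305i_requires_full_modification(registry):
    d = make_random_plasmid(300, 1, "linear", 1)
    (site,) = scan_sites(d, registry["Bsp305I"])
    d.pt_marks.add(PTMark("top", site.ga_linkage[1] if site.ga_linkage[0] == "top" else site.start, "Rp"))
    assert license_site(site, d, registry["Bsp305I"], Conditions(cofactor="Mg")) == (0.0, 0.0)
    full = fully_marked()
    (fsite,) = scan_sites(full, registry["Bsp305I"])
    p = license_site(fsite, full, registry["Bsp305I"], Conditions(cofactor="Mg"))
    assert p[0] > 0 and p[1] > 0


def test_sp_marks_do_not_license_rp_only_enzymes(registry):
    d = fully_marked(stereo_rp=False)
    (site,) = scan_sites(d, registry["EcoWI"])
    assert license_site(site, d, registry["EcoWI"], Conditions(cofactor="Mg")) == (0.0, 0.0)


def test_relaxed_mode_fires_regardless_of_marks(registry):
    d = make_random_plasmid(300, 1, "linear", 1)
    (site,) = scan_sites(d, registry["EcoWI"])
    cond = Conditions(cofactor="Mn", p_cleave_relaxed=0.4)
    assert license_site(site, d, registry["EcoWI"], cond) == (0.4, 0.4)


def test_two_site_boost_caps_at_one(registry):
    d = fully_marked(length=600, n_sites=2, seed=3)
    site = scan_sites(d, registry["EcoWI"])[0]
    cond = Conditions(cofactor="Mg", p_cleave_specific=0.5)
    single = license_site(site, d, registry["EcoWI"], cond, n_licensed=1)
    boosted = license_site(site, d, registry["EcoWI"], cond, n_licensed=2)
    assert single == (0.5, 0.5)
    assert boosted == (1.0, 1.0)  # 0.5 * factor 3, capped


def test_unknown_cofactor_raises(registry):
    d = fully_marked()
    (site,) = scan_sites(d, registry["EcoWI"])
    with pytest.raises(ConfigurationError):
        license_site(site, d, registry["EcoWI"], Conditions(cofactor="Fe"))


# --------------------------------------------------------------------------
# digestion


def test_complete_digestion_cuts_every_molecule_at_fixed_offsets(registry):
    d = fully_marked()
    spec = registry["EcoWI"]
    (site,) = scan_sites(d, spec)
    s, e = site.start, site.start + 3
    ensemble = digest(d, spec, Conditions(cofactor="Mg", **COMPLETE), 50, seed=2)
    expected = {(e + 7, e + 6), (s - 7, s - 8)}  # the two cut orientations
    for events in ensemble:
        assert len(events) == 1
        (ev,) = events
        assert ev.kind == "ds_cut"
        assert (ev.top_cut_linkage, ev.bottom_cut_linkage) in expected
        assert ev.top_cut_linkage - ev.bottom_cut_linkage == 1  # 1-nt 3' overhang


def test_unmodified_substrate_stays_intact(registry):
    d = make_random_plasmid(300, 1, "linear", 1)
    ensemble = digest(d, registry["EcoWI"], Conditions(cofactor="Mg", **COMPLETE), 100, seed=2)
    assert all(not events for events in ensemble)


def test_protection_invariant_large_ensemble(registry):
    """Specific-mode pt_site enzymes never cut unmarked DNA (1e4 molecules)."""
    d = make_random_plasmid(2000, 8, "circular", seed=17)
    for seed in (0, 1, 99):
        ensemble = digest(d, registry["EcoWI"], Conditions(cofactor="Mg"), 10_000, seed=seed)
        assert sum(len(ev) for ev in ensemble) == 0


def test_geometry_invariant_overhang_equals_t_minus_b(registry):
    for name in ("EcoWI", "Ksp11411I"):
        spec = registry[name]
        cof = "Mg" if name == "EcoWI" else "Ni"
        d = fully_marked(length=2000, n_sites=6, topology="circular", seed=4)
        ensemble = digest(d, spec, Conditions(cofactor=cof, **COMPLETE), 20, seed=5)
        for events in ensemble:
            for ev in events:
                assert abs(ev.top_cut_linkage - ev.bottom_cut_linkage) % d.length in (1, d.length - 1)


def test_racemic_marks_give_partial_cleavage(registry):
    """rp_fraction 0.5 on both strands: per-site firing sits between zero
    and the fully-Rp rate (partially cleaved oligos)."""
    spec = registry["EcoWI"]
    n = 2000
    fired = 0
    d = make_random_plasmid(300, 1, "linear", 1)
    marked = apply_dnd_marks(
        d, SimParams(seed=11, penetrance=1.0, hemi_fraction=0.0, rp_fraction=0.5)
    )
    ensemble = digest(marked, spec, Conditions(cofactor="Mg", **COMPLETE), n, seed=6)
    fired = sum(bool(ev) for ev in ensemble)
    (site,) = scan_sites(marked, spec)
    stereo = {m.strand: m.stereo for m in marked.pt_marks}
    if "Rp" in stereo.values():
        assert 0 < fired == n  # at least one Rp strand licenses every molecule
    else:
        assert fired == 0


def test_sprmcras_nicks_match_pattern_scan(registry):
    spec = registry["SprMcrA-S"]
    d = random_sequence_duplex(3000, "linear", 21)
    cond = Conditions(cofactor="Mn", p_cleave_relaxed=1.0)
    (events,) = digest(d, spec, cond, 1, seed=7)
    assert events and all(ev.kind in ("nick_top", "nick_bottom") for ev in events)
    got = {
        (ev.guide_strand, ev.top_cut_linkage if ev.kind == "nick_top" else ev.bottom_cut_linkage)
        for ev in events
    }
    expected = {(strand, lnk) for strand, _s, lnk in find_pattern_matches(d, "SS^RT")}
    assert got == expected


def test_scomcra_specific_cuts_only_near_base_marks(registry):
    from ptdr.core import BaseMark

    spec = registry["ScoMcrA"]
    d = random_sequence_duplex(5000, "linear", 22)
    matches = find_pattern_matches(d, spec.preferred_pattern)
    assert len(matches) > 4
    strand, start, cut = matches[len(matches) // 2]
    col = start + 1 if strand == "top" else start + 3
    d.base_marks.add(BaseMark(strand, col, "5mC"))
    cond = Conditions(cofactor="Mn", enzyme_level="low",
                      p_cleave_specific=1.0, p_ds_given_cleave=1.0)
    (events,) = digest(d, spec, cond, 1, seed=8)
    assert events
    for ev in events:
        lnk = ev.top_cut_linkage if ev.top_cut_linkage is not None else ev.bottom_cut_linkage
        assert abs(lnk - col) <= spec.window


# --------------------------------------------------------------------------
# fragments


def brute_force_linear_pieces(length, cuts):
    bounds = [-1] + sorted(set(cuts)) + [length - 1]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


@pytest.mark.parametrize("n_cuts", [1, 2, 3])
def test_linear_fragmentation_matches_interval_oracle(n_cuts):
    d = make_duplex("ACGT" * 50)
    rng = np.random.default_rng(n_cuts)
    cuts = sorted(rng.choice(np.arange(20, 180), size=n_cuts, replace=False))
    events = [CutEvent(None, "ds_cut", int(c), int(c) - 1) for c in cuts]
    frags = fragments(d, events)
    assert len(frags) == n_cuts + 1
    assert [f.top_piece for f in frags] == brute_force_linear_pieces(200, [int(c) for c in cuts])
    assert sum(f.top_piece[1] - f.top_piece[0] + 1 for f in frags) == 200
    assert sum(f.bottom_piece[1] - f.bottom_piece[0] + 1 for f in frags) == 200


def test_circular_fragment_count_and_conservation():
    d = make_duplex("ACGT" * 1250, "circular")  # L = 5000
    events = [
        CutEvent(None, "ds_cut", 1000, 999),
        CutEvent(None, "ds_cut", 3000, 2999),
    ]
    frags = fragments(d, events)
    assert len(frags) == 2
    total = sum(f.length for f in frags)
    assert total == 5000


def test_single_cut_linearizes_circle():
    d = make_duplex("ACGT" * 1250, "circular")
    frags = fragments(d, [CutEvent(None, "ds_cut", 100, 99)])
    assert len(frags) == 1 and frags[0].length == 5000


def test_nick_only_molecule_reported_intact():
    d = make_duplex("ACGT" * 25)
    nick = CutEvent(None, "nick_top", 40, None)
    frags = fragments(d, [nick])
    assert len(frags) == 1
    assert frags[0].top_piece == (0, 99) and frags[0].nicks == (nick,)
    assert fragments(make_duplex("ACGT" * 25, "circular"), [nick]) == []


def test_exo1_filter_removes_single_stranded_only():
    ds1 = Fragment((0, 30), (0, 29), 31)
    ss = Fragment((31, 40), None, 10, single_stranded=True)
    ds2 = Fragment((41, 99), (30, 99), 70)
    assert exo1_filter([ss, ds1, ds2]) == [ds1, ds2]
    assert exo1_filter([ds1, ds2]) == [ds1, ds2]
    assert exo1_filter([]) == []
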