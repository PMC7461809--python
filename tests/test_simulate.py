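"""Synthetic-data generators: plasmids, marks, oligo panel, traces, tables."""

import numpy as np
import pytest
from scipy import stats

from ptdr.core import GenerationError, find_motif_sites, site_mark_linkages, validate_substrate
from ptdr.digestion import CutEvent
from ptdr.simulate import (
    SimParams,
    apply_dnd_marks,
    make_neighborhood_tables,
    make_oligoduplex_panel,
    make_random_plasmid,
    simulate_runoff_trace,
)
from ptdr.neighborhood import proximity_scan

from .conftest import brute_force_site_starts


def binom_ci99(p, n):
    lo, hi = stats.binom.interval(0.99, n, p)
    return lo / n, hi / n


# --------------------------------------------------------------------------
# plasmid generation


@pytest.mark.parametrize(
    "length,n_sites,topology",
    [(300, 1, "linear"), (5000, 20, "circular"), (2000, 12, "linear")],
)
def test_plasmid_has_exactly_the_requested_sites(length, n_sites, topology):
    d = make_random_plasmid(length, n_sites, topology, seed=2)
    found = brute_force_site_starts(d.top_seq, d.is_circular)
    assert len(found) == n_sites
    starts = sorted(s for _, s in found)
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    if topology == "circular" and len(starts) > 1:
        gaps.append(length - starts[-1] + starts[0])
    assert all(g >= 10 for g in gaps)
    validate_substrate(d)


def test_plasmid_generation_is_deterministic():
    a = make_random_plasmid(1000, 5, "circular", seed=9)
    b = make_random_plasmid(1000, 5, "circular", seed=9)
    assert a.top_seq == b.top_seq


def test_infeasible_site_density_raises():
    with pytest.raises(GenerationError):
        make_random_plasmid(60, 10, "linear", seed=1)


# --------------------------------------------------------------------------
# dnd marking


def test_full_penetrance_marks_every_site_rp():
    d = make_random_plasmid(2000, 10, "circular", seed=3)
    m = apply_dnd_marks(d, SimParams(seed=0, penetrance=1.0, hemi_fraction=0.0, rp_fraction=1.0))
    assert len(m.pt_marks) == 20  # both strands of all 10 sites
    assert all(mk.stereo == "Rp" for mk in m.pt_marks)
    validate_substrate(m)


def test_zero_penetrance_leaves_no_marks():
    d = make_random_plasmid(2000, 10, "circular", seed=3)
    m = apply_dnd_marks(d, SimParams(seed=0, penetrance=0.0))
    assert not m.pt_marks


def test_marks_only_at_gps_linkages_of_scanned_sites():
    d = make_random_plasmid(3000, 15, "circular", seed=4)
    m = apply_dnd_marks(d, SimParams(seed=1, penetrance=0.8, hemi_fraction=0.5))
    allowed = set()
    for site in find_motif_sites(d, "GAAC"):
        pos = site_mark_linkages(site, d.length)
        allowed.update({("top", pos["top"]), ("bottom", pos["bottom"])})
    assert {(mk.strand, mk.linkage) for mk in m.pt_marks} <= allowed


def test_default_penetrance_recovered_over_many_sites():
    """~20% of potential PT sites modified by the overexpressed dnd model."""
    d = make_random_plasmid(160_000, 10_000, "circular", seed=6)
    m = apply_dnd_marks(d, SimParams(seed=7))
    sites = find_motif_sites(d, "GAAC")
    marked_starts = set()
    by_pos = {(mk.strand, mk.linkage) for mk in m.pt_marks}
    for site in sites:
        pos = site_mark_linkages(site, d.length)
        if ("top", pos["top"]) in by_pos or ("bottom", pos["bottom"]) in by_pos:
            marked_starts.add(site.start)
    frac = len(marked_starts) / len(sites)
    lo, hi = binom_ci99(0.2, len(sites))
    assert lo <= frac <= hi


# --------------------------------------------------------------------------
# oligoduplex panel


def test_oligo_panel_composition():
    panel = make_oligoduplex_panel(seed=1)
    assert all(d.length == 60 for d in panel)
    singles = [d for d in panel if d.id.startswith("oligo1")]
    doubles = [d for d in panel if d.id.startswith("oligo2")]
    assert len(singles) == 4 and len(doubles) == 9
    # single-site states: full, unmodified, and the two hemi forms
    assert sorted(len(d.pt_marks) for d in singles) == [0, 1, 1, 2]
    # two-site members cover 0-4 marks
    assert sorted(len(d.pt_marks) for d in doubles) == [0, 1, 1, 2, 2, 2, 3, 3, 4]
    for d in panel:
        validate_substrate(d)


def test_two_site_oligos_have_gttc_starts_20_bp_apart():
    panel = make_oligoduplex_panel(seed=1)
    for d in panel:
        if not d.id.startswith("oligo2"):
            continue
        starts = sorted(
            s.start for s in find_motif_sites(d, "GAAC") if s.site_strand == "bottom"
        )
        assert len(starts) == 2
        assert starts[1] - starts[0] == 20


def test_oligo_sites_identically_positioned_across_members():
    panel = make_oligoduplex_panel(seed=1)
    keyed = {}
    for d in panel:
        kind = d.id.split("_")[0]
        starts = tuple(sorted(s.start for s in find_motif_sites(d, "GAAC")))
        keyed.setdefault(kind, set()).add(starts)
    assert all(len(v) == 1 for v in keyed.values())


# --------------------------------------------------------------------------
# run-off traces


def _nick_top(linkage):
    return CutEvent(None, "nick_top", linkage, None)


def test_break_free_trace_matches_control_profile():
    d = make_random_plasmid(120, 1, "linear", seed=5)
    p0 = SimParams(seed=1, noise_sd=0.0)
    trace = simulate_runoff_trace(d, [], 0, "top", p0)
    for r in trace.records:
        assert sum(r.heights) == pytest.approx(1.0)
        assert r.called_base == d.bottom_base(r.template_col)


def test_single_break_closed_form_signal():
    """cut_fraction 0.5, no noise: secondary A peak of 0.5 at the doublet
    position, all heights halved thereafter."""
    d = make_random_plasmid(120, 1, "linear", seed=5)
    lnk = 60
    # ensure a non-A doublet call for the pure-doublet case
    while d.bottom_base(lnk) == "A":
        lnk += 1
    p = SimParams(seed=1, cut_fraction=0.5, noise_sd=0.0)
    trace = simulate_runoff_trace(d, [_nick_top(lnk)], 0, "top", p)
    by_col = {r.template_col: r for r in trace.records}
    doublet = by_col[lnk]
    heights = dict(zip("ACGT", doublet.heights))
    assert heights[d.bottom_base(lnk)] == pytest.approx(1.0)
    assert heights["A"] == pytest.approx(0.5)
    after = by_col[lnk + 1]
    assert sum(after.heights) == pytest.approx(0.5)
    before = by_col[lnk - 1]
    assert sum(before.heights) == pytest.approx(1.0)


def test_templated_a_break_gives_single_elevated_peak():
    """A/A doublet: A height 1.5x the control at cut_fraction 0.5."""
    d = make_random_plasmid(200, 1, "linear", seed=8)
    lnk = next(
        c for c in range(80, 150) if d.bottom_base(c) == "A"
    )
    p = SimParams(seed=1, cut_fraction=0.5, noise_sd=0.0)
    trace = simulate_runoff_trace(d, [_nick_top(lnk)], 0, "top", p)
    control = simulate_runoff_trace(d, [], 0, "top", p)
    h = dict(zip("ACGT", trace.records[lnk].heights))["A"]
    h0 = dict(zip("ACGT", control.records[lnk].heights))["A"]
    assert h / h0 == pytest.approx(1.5)


def test_signal_conservation_away_from_doublets():
    """Channel heights sum to the surviving template fraction at every
    non-doublet position (the doublet position carries the extra
    co-migrating +A product on top of the templated signal)."""
    d = make_random_plasmid(150, 1, "linear", seed=5)
    p = SimParams(seed=1, cut_fraction=0.3, noise_sd=0.0)
    lnk = 70
    trace = simulate_runoff_trace(d, [_nick_top(lnk)], 0, "top", p)
    for r in trace.records:
        expected = 1.0 if r.template_col <= lnk else 0.7
        if r.template_col == lnk:
            assert sum(r.heights) == pytest.approx(1.3)
        else:
            assert sum(r.heights) == pytest.approx(expected)


def test_bottom_strand_trace_reads_complement():
    d = make_random_plasmid(100, 1, "linear", seed=5)
    p = SimParams(seed=1, noise_sd=0.0)
    trace = simulate_runoff_trace(d, [], d.length - 1, "bottom", p, direction=-1)
    for r in trace.records:
        assert r.called_base == d.top_base(r.template_col)


def test_break_off_sequenced_strand_is_ignored():
    d = make_random_plasmid(100, 1, "linear", seed=5)
    p = SimParams(seed=1, noise_sd=0.0)
    bottom_nick = CutEvent(None, "nick_bottom", None, 50)
    trace = simulate_runoff_trace(d, [bottom_nick], 0, "top", p)
    control = simulate_runoff_trace(d, [], 0, "top", p)
    assert [r.heights for r in trace.records] == [r.heights for r in control.records]


# --------------------------------------------------------------------------
# neighborhood tables


def test_cooccur_rate_extremes_flag_none_or_all():
    none = make_neighborhood_tables(50, 0.0, seed=1, background_dnd_rate=0.5)
    assert sum(proximity_scan(t).flagged for t in none) == 0
    full = make_neighborhood_tables(50, 1.0, seed=1)
    assert sum(proximity_scan(t).flagged for t in full) == 50


def test_injected_cooccurrence_rate_recovered():
    tables = make_neighborhood_tables(4000, 0.25, seed=3)
    frac = sum(proximity_scan(t).flagged for t in tables) / len(tables)
    lo, hi = binom_ci99(0.25, 4000)
    assert lo <= frac <= hi


def test_too_few_genes_rejected():
    with pytest.raises(GenerationError):
        make_neighborhood_tables(5, 0.5, genes_per_genome=10, seed=1)


def test_tables_are_deterministic_under_seed():
    a = make_neighborhood_tables(20, 0.3, seed=4)
    b = make_neighborhood_tables(20, 0.3, seed=4)
    assert [t.genes for t in a] == [t.genes for t in b]
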