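# Registry of characterized phosphorothioate- and base-modification-dependent
# endonucleases.  Offsets are REBASE-style Nt/Nb counts of nucleotides 3' of
# the recognition motif end (guiding strand / opposite strand); single ints
# are fixed offsets, [lo, hi] pairs are uniformly wobbled ranges.
# Cofactor modes: specific (modification-licensed cleavage), relaxed (star
# activity at motif/pattern matches regardless of marks), partial (licensed
# but reduced probability), nick_only (licensed single-strand breaks),
# inactive.

- name: EcoWI
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: 7
  bottom_offset: 6
  hemi_side: downstream      # cleaves downstream of the GpsT-modified strand
  rp_only: true
  two_site_factor: 3.0
  cofactors:
    Mg: specific
    Mn: relaxed
    Ni: partial              # specificity in Ni2+ not fully established
    Ca: partial              # specificity in Ca2+ not fully established
    Co: inactive
    EDTA: inactive

- name: Ksp11411I
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: 5
  bottom_offset: 4
  hemi_side: upstream        # cleaves upstream of the GpsT dinucleotide
  rp_only: true
  two_site_factor: 1.0
  cofactors:
    Ni: specific
    Mn: relaxed
    Co: partial
    Mg: inactive
    EDTA: inactive

- name: Bsp305I
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: 6
  bottom_offset: [4, 5]      # wobbled bottom cut; possibly exonuclease nibbling
  hemi_side: both
  requires_full: true        # hemi-modified oligos are poor substrates
  rp_only: true
  two_site_factor: 1.0
  cofactors:
    Mg: specific
    Mn: relaxed
    Ni: partial
    Ca: partial
    EDTA: inactive

- name: Mae9806I
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: [8, 10]
  bottom_offset: [8, 9]
  hemi_side: both
  rp_only: true
  two_site_factor: 1.0
  cofactors:
    Mn: specific
    EDTA: inactive

- name: Sau43800I
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: [8, 9]
  bottom_offset: [7, 8]
  hemi_side: both
  rp_only: true
  two_site_factor: 1.0
  cofactors:
    Mn: specific
    EDTA: inactive

- name: SprMcrA
  license_mode: pt_site
  recognition: GAAC
  pt_linkage_offset: 0
  top_offset: [11, 13]
  bottom_offset: [10, 12]
  hemi_side: both
  rp_only: true
  two_site_factor: 1.0
  cofactors:
    Mn: specific
    Co: partial
    Mg: inactive
    EDTA: inactive

- name: SprMcrA-S
  license_mode: pattern_only   # SBD-truncated: PT-independent nickase
  pattern: SS^RT
  cofactors:
    Mn: nick_only
    Co: partial
    Mg: inactive
    EDTA: inactive

- name: ScoMcrA
  license_mode: basemod_window
  pattern: RYN^RY              # relaxed cleavage preference
  preferred_pattern: ACN^GT    # preferred target next to modified cytosines
  window: 20
  cofactors:
    Mn: specific
    Ni: nick_only
    Co: partial
    Mg: inactive
    EDTA: inactive
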