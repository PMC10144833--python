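# Default feature-block configuration: 52 named blocks, 1610 dimensions.
# Groups: general (11), physicochemical (24), domain_motif (11), structural (6).
# Blocks of kind 'external' are predictor-derived (signal peptide, transmembrane,
# glycosylation, disorder, secondary structure, ...) and are never recomputed
# internally; supply them via the external-feature ingestion path.
blocks:
- name: sequence_length
  group: general
  length: 1
  kind: length
- name: mass
  group: general
  length: 1
  kind: mass
- name: aac
  group: general
  length: 20
  kind: aac
- name: dpc
  group: general
  length: 400
  kind: dpc
- name: moreau_broto
  group: general
  length: 90
  kind: autocorrelation
  params:
    scales: &id001
    - hydrophobicity
    - polarity
    - polarizability
    maxlag: 30
    variant: moreau_broto_normalized
- name: moran
  group: general
  length: 90
  kind: autocorrelation
  params:
    scales: *id001
    maxlag: 30
    variant: moran
- name: geary
  group: general
  length: 90
  kind: autocorrelation
  params:
    scales: *id001
    maxlag: 30
    variant: geary
- name: qso
  group: general
  length: 160
  kind: qso
  params:
    maxlag: 60
    weight: 0.1
    matrices:
    - sw_like
    - grantham
- name: paac
  group: general
  length: 150
  kind: paac
  params:
    lam: 130
    weight: 0.05
- name: apaac
  group: general
  length: 80
  kind: apaac
  params:
    lam: 30
    weight: 0.05
- name: total_aa_property
  group: general
  length: 3
  kind: total_aa_property
  params:
    scales:
    - hydrophobicity
    - charge
    - polarity
- name: profile_hydrophobicity
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: hydrophobicity
- name: profile_vdw_volume
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: vdw_volume
- name: profile_polarity
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: polarity
- name: profile_polarizability
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: polarizability
- name: profile_charge
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: charge
- name: profile_solvent_accessibility
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: solvent_accessibility
- name: profile_surface_tension
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: surface_tension
- name: profile_molecular_weight
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: molecular_weight
- name: profile_water_solubility
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: water_solubility
- name: profile_hbond_donors
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: hbond_donors
- name: profile_hbond_acceptors
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: hbond_acceptors
- name: profile_clogp
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: clogp
- name: profile_flexibility
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: flexibility
- name: profile_ppi_hotspot_bogan
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: ppi_hotspot_bogan
- name: profile_ppi_propensity_ma
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: ppi_propensity_ma
- name: profile_dna_interface_schneider
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: dna_interface_schneider
- name: profile_dna_interface_ahmad
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: dna_interface_ahmad
- name: profile_rna_interface_kim
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: rna_interface_kim
- name: profile_rna_interface_ellis
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: rna_interface_ellis
- name: profile_rna_interface_phipps
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: rna_interface_phipps
- name: profile_ligand_binding_khazanov
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: ligand_binding_khazanov
- name: profile_ligand_valid_binding_khazanov
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: ligand_valid_binding_khazanov
- name: profile_ligand_polar_imai
  group: physicochemical
  length: 21
  kind: property_profile
  params:
    scale: ligand_polar_imai
- name: isoelectric_point
  group: physicochemical
  length: 1
  kind: isoelectric_point
- name: twin_arginine_signal_peptide
  group: domain_motif
  length: 1
  kind: external
- name: transmembrane_domains
  group: domain_motif
  length: 1
  kind: external
- name: signal_peptide
  group: domain_motif
  length: 1
  kind: external
- name: n_glycosylation_sites
  group: domain_motif
  length: 1
  kind: external
- name: glycosylation_presence
  group: domain_motif
  length: 1
  kind: external
- name: phosphorylation_sites
  group: domain_motif
  length: 1
  kind: external
- name: cleavage_site
  group: domain_motif
  length: 3
  kind: external
- name: subcellular_location
  group: domain_motif
  length: 3
  kind: external
- name: coil_content
  group: domain_motif
  length: 1
  kind: external
- name: n_motif_sites
  group: domain_motif
  length: 1
  kind: external
- name: transmembrane_helices
  group: domain_motif
  length: 1
  kind: external
- name: secondary_structure
  group: structural
  length: 21
  kind: external
- name: unfoldability
  group: structural
  length: 1
  kind: external
- name: fldbin_charge
  group: structural
  length: 1
  kind: external
- name: n_disordered_regions
  group: structural
  length: 1
  kind: external
- name: longest_disordered_region
  group: structural
  length: 1
  kind: external
- name: n_disordered_residues
  group: structural
  length: 1
  kind: external
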