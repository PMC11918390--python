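# Default model configuration: single duodenal enterocyte iron-absorption model.
#
# Kinetic constants follow the published rate-law tables for DMT1 transport and
# endocytosis, ferritin iron sequestration, FPN export and its plasma-iron
# (hepcidin) regulation, IRPs regulation of ferritin expression, and the three
# auxiliary mass-action routes.  Compartment sizes, initial concentrations and a
# handful of constants whose printed units are not self-consistent were fixed by
# requiring the model to reproduce the published steady-state table at clamped
# luminal iron (12.5 nM / 0 M / 125 nM); those entries are marked "calibrated".

compartments:
  lumen:            {dimension: 3, size: "1.3e-11 L"}    # calibrated (block timing)
  cytoplasm:        {dimension: 3, size: "1.0e-12 L"}    # ~1 pL cell volume
  blood:            {dimension: 3, size: "5.9e-12 L"}    # calibrated (basal/high blood iron)
  apical_membrane:  {dimension: 2, size: "1.0e-9 cm^2"}  # ~100 um^2
  basal_membrane:   {dimension: 2, size: "1.0e-9 cm^2"}

# Initial intensive values (M for 3D species, mol/cm^2 for membrane species).
# Protein moiety totals (DMT1, FPN, IRPs) are conserved by the network, so the
# initial totals are structural parameters of the model.
initial:
  Fe_lumen:       "12.5 nM"
  LIP:            "0.12 uM"
  DFP:            "0.13 nM"
  core:           "0.368 uM"
  FT:             "2.38 nM"
  DMT1_active:    "3.12 pmol/cm^2"
  DMT1_cytoplasm: "1.88 nM"
  FPN_active:     "0.1 pmol/cm^2"
  FPN_inactive:   "0 M"
  IRPs_active:    "76.2 pM"
  IRPs_inactive:  "0 M"
  Fe_blood:       "5 nM"
  Fe_body:        "0 M"

reactions:
  dmt1_endocytosis_free:          # DMT1_active -> DMT1_cytoplasm, mass action
    k_cat: "29.4 1/s"
  dmt1_endocytosis_lip:           # DMT1_active -> DMT1_cytoplasm, Hill in LIP
    k_cat: "14.5 1/s"
    K_m: "2.805e-5 M"             # calibrated scale (printed mantissa 2.805)
    n: 1.03
  dmt1_fusion:                    # DMT1_cytoplasm -> DMT1_active
    k_cat: "50 1/s"
  dmt1_iron_transport:            # Fe_lumen -> LIP, HMM in Fe_lumen
    k_cat: "6844 1/s"
    K_m: "2.835e-2 M"             # calibrated scale (printed mantissa 2.835)
  oxidation:                      # 2 LIP -> DFP
    k_cat: "591 1/s"
    K_m: "0.35 mM"
    n: 1.3
    rO: 2
    H: 24
  reduction:                      # DFP -> 2 LIP
    k_deg: "0.2605 1/s"
  nucleation:                     # 2 DFP -> 4 core
    k_cat: "5e7 1/(M^2 s)"
    K_i: "0.4615 mM"
    n: 4
    rN: 50
    L: 0
  mineralization:                 # DFP -> 2 core
    k_cat: "0.101564 1/s"
    K_m: "5e-6 M"
    K_i: "4.6458 mM"
    n: 4
    m: 8
    capacity: 4300
  ft_core_release:                # core -> LIP
    k_deg: "5.46e-6 1/s"
  ft_degradation:                 # FT -> 0
    k_deg: "5.46e-6 1/s"
  fpn_inactivation:               # FPN_active -> FPN_inactive, Hill in Fe_blood
    k_cat: "1.44e-6 1/s"
    K_m: "122.1 nM"               # calibrated scale (printed mantissa 12.21)
    n: 2.72
  fpn_activation:                 # FPN_inactive -> FPN_active
    k_cat: "1.011e-7 1/s"         # calibrated (high-Fe FPN active/inactive split)
  fpn_iron_transport:             # LIP -> Fe_blood, HMM in LIP
    k_cat: "1.88 1/s"
    K_m: "2.31 uM"
  irps_inactivation:              # IRPs_active -> IRPs_inactive, bimolecular in LIP
    k_cat: "4 1/(M s)"
  irps_activation:                # IRPs_inactive -> IRPs_active
    k_cat: "4.63e-6 1/s"
  ft_expression:                  # 0 -> FT, repressed by active IRPs
    k_cat: "0.0768 pM/s"
    K_m: "14 pM"
    n: 1
  body_sequestration:             # Fe_blood -> Fe_body
    k_cat: "0.000329 1/s"
  basal_uptake:                   # Fe_blood -> LIP
    k_cat: "2.22e-16 1/s"
  paracellular:                   # Fe_lumen <-> Fe_blood
    k_for: "3.88e-22 1/s"
    k_rev: "3.17e-15 1/s"

protocols:
  steady_state:
    horizon: "5.5e6 s"
  block_assay:
    loading_dose: "2.5 uM"
    test_dose: "2.5 uM"
    readout_window: "1800 s"
    n_intervals: 300
    max_interval: "72 h"
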