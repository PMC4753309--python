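# Per-site defaults for the two Norris Geyser Basin acid-sulfate-chloride
# springs.  Rate constants, colonization rates, bulk O2, oxyanion:Fe ratios
# and hydrodynamic context are the field-study values; profile constraints
# (surface flux and Thiele modulus) are resolved into (k1, L_f) at load time
# given D_e.  Scalars a field scientist would tune live here, not in code.
osp:
  site_name: osp
  fe_k: 0.05             # day^-1
  fe_x0: 0.5             # umol cm^-2
  dna_r: 0.028           # day^-1
  dna_x0: 2.0            # ng cm^-2
  fe_detection_limit: 0.05   # umol cm^-2; below this a slide shows no visible Fe
  coloniz_rate_rod: 3.7e6    # cells cm^-2 day^-1 (Hydrogenobaculum-like rods)
  coloniz_rate_coccus: 9.2e5 # cells cm^-2 day^-1 (Metallosphaera-like cocci)
  o2_bulk: 55.0          # uM at the mat-water interface (2013 survey)
  o2_flux: 1.14e-4       # umol cm^-2 s^-1, surface flux the profile must honour
  thiele_modulus: 28.0   # dimensionless, ditto
  d_e: 4.5e-5            # cm^2 s^-1, effective O2 diffusivity at 70-75 C
  as_fe_ratio: 0.5
  p_fe_ratio: 0.01
  w_fe_ratio: 0.002
  extraction_volume_l: 0.05
  slide_area_cm2: 18.75
  channel_velocity_cm_s: 3.5   # midpoint of the observed 2-5 cm/s
  reynolds: 1.5e3
  community:
    rod_taxon: Hydrogenobaculum
    rod_start: 0.85
    rod_start_day: 4.0
    rod_decline_per_day: 0.01
    rod_floor: 0.01
    feox_taxon: Metallosphaera yellowstonensis
    feox_fraction: 0.15
    het_midpoint_day: 45.0
    het_steepness: 0.15
    heterotrophs:
      Geoarchaeota: 0.55
      Novel archaeal group 2: 0.30
      Other Sulfolobales: 0.07
      Thaumarchaeota: 0.05
      Novel archaeal group 3: 0.03
beowulf:
  site_name: beowulf
  fe_k: 0.047
  fe_x0: 0.3
  dna_r: 0.043
  dna_x0: 1.0
  fe_detection_limit: 0.05
  coloniz_rate_rod: 6.8e6
  coloniz_rate_coccus: 8.6e5
  o2_bulk: 44.0
  o2_flux: 1.64e-4       # 2011 survey value for this spring
  thiele_modulus: 60.0
  d_e: 4.5e-5
  as_fe_ratio: 0.67
  p_fe_ratio: 0.01
  w_fe_ratio: 0.002
  extraction_volume_l: 0.05
  slide_area_cm2: 18.75
  channel_velocity_cm_s: 25.0
  reynolds: 1.4e4
  community:
    rod_taxon: Hydrogenobaculum
    rod_start: 0.85
    rod_start_day: 4.0
    rod_decline_per_day: 0.01
    rod_floor: 0.01
    feox_taxon: Metallosphaera yellowstonensis
    feox_fraction: 0.15
    het_midpoint_day: 45.0
    het_steepness: 0.15
    heterotrophs:
      Novel archaeal group 2: 0.45
      Novel archaeal group 3: 0.30
      Other Sulfolobales: 0.10
      Geoarchaeota: 0.08
      Thaumarchaeota: 0.07
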