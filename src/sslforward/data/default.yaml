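# Default run configuration: survey medium, echosounder band plan,
# scattering-model parameter tables, uncertainty priors and the sampled
# community presets for the surface and deep scattering layers.

medium:
  sound_speed: 1500.0     # m/s
  density: 1026.0         # kg/m^3
  temperature: 283.15     # K, used for gas thermodynamics

bin_width_mm: 0.1         # length-class width for the forward model

bands:
  - {name: ES18, f_min: 18.0, f_max: 18.0, kind: CW, use_in_clustering: true}
  - {name: ES38, f_min: 38.0, f_max: 38.0, kind: CW, use_in_clustering: true}
  - {name: ES70, f_min: 47.0, f_max: 90.0, kind: FM, use_in_clustering: true}
  - {name: ES120, f_min: 95.0, f_max: 160.0, kind: FM, use_in_clustering: true}
  - {name: ES200, f_min: 180.0, f_max: 240.0, kind: FM, use_in_clustering: true}
  # limited range: kept in spectra, excluded from clustering features
  - {name: ES333, f_min: 280.0, f_max: 420.0, kind: FM, use_in_clustering: false}
exclusions:               # noise-spike interval removed from analysis
  - [240.0, 260.0]

# Fluid-like (DWBA) parameter groups: length-to-width ratio L/2a,
# orientation N(mean, SD) in degrees from horizontal, density contrast g,
# sound-speed contrast h.
fluid_like:
  euphausiids:            # euphausiids and decapod shrimp
    shape: bent_cylinder
    length_to_width_ratio: 5.0
    orientation_mean: 20.0
    orientation_sd: 20.0
    g: 1.016
    h: 1.019
  copepods:
    shape: prolate_spheroid
    length_to_width_ratio: 2.55
    orientation_mean: 90.0
    orientation_sd: 30.0
    g: 0.949
    h: 0.995
  fish_no_swimbladder:
    shape: bent_cylinder
    length_to_width_ratio: 4.0
    orientation_mean: 0.0
    orientation_sd: 30.0
    g: 1.01
    h: 1.025

elastic_shell:
  pteropods:
    reflection_coefficient: 0.5

# Gas-bearing groups: gas-inclusion length-to-width ratio L/2a, tissue
# viscosity (Pa s) and surface tension (N/m).
gas_bearing:
  crystallogobius_linearis: {length_to_width_ratio: 1.63, viscosity: 1.0, surface_tension: 200.0}
  carapus_acus: {length_to_width_ratio: 2.75, viscosity: 1.0, surface_tension: 200.0}
  other_fish: {length_to_width_ratio: 1.5, viscosity: 1.0, surface_tension: 200.0}
  siphonophore_pneumatophore: {length_to_width_ratio: 2.35, viscosity: 0.1, surface_tension: 15.0}

# Taxon label -> scattering model class and parameter group. Excluded taxa
# are carried through I/O but never modelled (low density, weak
# backscatter).
taxon_map:
  euphausiids: {model_class: fluid_like_cylinder, group: euphausiids}
  limacina: {model_class: elastic_shell, group: pteropods}
  copepods: {model_class: fluid_like_spheroid, group: copepods}
  crystallogobius_linearis: {model_class: gas_bearing, group: crystallogobius_linearis, length_kind: gas_inclusion}
  carapus_acus: {model_class: gas_bearing, group: carapus_acus, length_kind: gas_inclusion}
  swimbladdered_fish: {model_class: gas_bearing, group: other_fish, length_kind: gas_inclusion}
  fish_no_swimbladder: {model_class: fluid_like_cylinder, group: fish_no_swimbladder}
  siphonophore_pneumatophore: {model_class: gas_bearing, group: siphonophore_pneumatophore, length_kind: gas_inclusion}
  jellyfish: {model_class: excluded}
  swimming_crabs: {model_class: excluded}
  comb_jelly: {model_class: excluded}

# Re-run bladderless fish (Argentina sphyranea juveniles) as gas-bearing
# with the generic fish swimbladder parameters (their swimbladder
# development timing is uncertain).
fish_no_swimbladder_as_gas_bearing: false

# Uncertainty priors per parameter group. "length_to_radius_ratio" priors
# are on L/a (body length over mid-body radius).
priors:
  siphonophore_pneumatophore:
    length_to_width_ratio: {kind: normal, mu: 2.35, sd: 0.3}
    viscosity: {kind: lognormal, mu: -2.3, sd: 1.0}
    surface_tension: {kind: lognormal, mu: 2.7, sd: 1.0}
  swimbladdered_fish:
    length_to_width_ratio: {kind: normal, mu: 1.5, sd: 0.2}  # mean is species dependent
    viscosity: {kind: lognormal, mu: 0.0, sd: 1.0}
    surface_tension: {kind: lognormal, mu: 5.3, sd: 1.0}
  copepods:
    length_to_radius_ratio: {kind: normal, mu: 5.5, sd: 1.0}
    g: {kind: normal, mu: 0.96, sd: 0.0075}
    h: {kind: normal, mu: 0.99, sd: 0.0075}
  euphausiids:
    length_to_radius_ratio: {kind: normal, mu: 10.0, sd: 1.5}
    g: {kind: normal, mu: 1.016, sd: 0.0075}
    h: {kind: normal, mu: 1.019, sd: 0.0075}
  fish_no_swimbladder:
    length_to_radius_ratio: {kind: normal, mu: 8.0, sd: 1.5}
    g: {kind: normal, mu: 1.01, sd: 0.0075}
    h: {kind: normal, mu: 1.025, sd: 0.0075}
  pteropods:
    reflection_coefficient: {kind: lognormal, mu: -0.69, sd: 0.4}

# Sampled community presets per layer: mean length (SD) in mm and
# numerical density in ind/m^3 of the dominant scatterers. Swimbladdered
# fish densities in the deep layer are split across the sampled species
# composition (50% C. linearis, 20% C. acus, 30% other juveniles); their
# lengths are directly measured swimbladder lengths. The single surface
# swimbladdered fish is carried but not modelled.
layers:
  surface:
    depth_min_m: 10.0
    depth_max_m: 24.0
    noise_sd_db: 2.0
    taxa:
      - {taxon: euphausiids, mean_length_mm: 4.26, sd_length_mm: 2.22, density_ind_m3: 14.2}
      - {taxon: limacina, mean_length_mm: 0.75, sd_length_mm: 0.12, density_ind_m3: 5358.0}
      - {taxon: copepods, mean_length_mm: 1.28, sd_length_mm: 0.37, density_ind_m3: 1403.0}
      - {taxon: swimbladdered_fish, mean_length_mm: 1.53, sd_length_mm: 0.0, density_ind_m3: 0.0, excluded: true}
      - {taxon: siphonophore_pneumatophore, mean_length_mm: 0.27, sd_length_mm: 0.11, density_ind_m3: 8.32}
      - {taxon: jellyfish, mean_length_mm: 30.1, sd_length_mm: 10.0, density_ind_m3: 0.033}
  deep:
    depth_min_m: 70.0
    depth_max_m: 96.0
    noise_sd_db: 2.0
    taxa:
      - {taxon: euphausiids, mean_length_mm: 13.7, sd_length_mm: 9.15, density_ind_m3: 1.53}
      - {taxon: limacina, mean_length_mm: 0.71, sd_length_mm: 0.15, density_ind_m3: 126.0}
      - {taxon: copepods, mean_length_mm: 1.41, sd_length_mm: 0.52, density_ind_m3: 126.0}
      - {taxon: crystallogobius_linearis, mean_length_mm: 0.52, sd_length_mm: 0.15, density_ind_m3: 0.00325}
      - {taxon: carapus_acus, mean_length_mm: 0.52, sd_length_mm: 0.15, density_ind_m3: 0.0013}
      - {taxon: swimbladdered_fish, mean_length_mm: 0.52, sd_length_mm: 0.15, density_ind_m3: 0.00195}
      - {taxon: fish_no_swimbladder, mean_length_mm: 21.5, sd_length_mm: 3.89, density_ind_m3: 0.012}
      - {taxon: siphonophore_pneumatophore, mean_length_mm: 1.23, sd_length_mm: 0.31, density_ind_m3: 0.48}
      - {taxon: jellyfish, mean_length_mm: 24.47, sd_length_mm: 13.38, density_ind_m3: 0.006}
      - {taxon: swimming_crabs, mean_length_mm: 31.75, sd_length_mm: 3.54, density_ind_m3: 0.0015}
      - {taxon: comb_jelly, mean_length_mm: 13.6, sd_length_mm: 7.0, density_ind_m3: 0.0022}
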