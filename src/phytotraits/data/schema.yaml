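# Canonical trait-table schema: 10 identity/taxonomy columns + 53 trait
# variables (continuous / categorical / boolean / text), in file order.
# Values for categorical and boolean kinds are closed vocabularies; the
# missing token of the CSV dialect (default "#NA") maps to an explicit
# missing value for every kind.
identity:
  - {name: Taxa_Name, kind: text, required: true}
  - {name: Taxa_Code, kind: text, required: true}
  - name: Group
    kind: categorical
    required: true
    allowed_values: [chlorophytes, cyanobacteria, diatoms, chrysophytes,
                     xanthophytes, dinophytes, euglenophytes, cryptophytes,
                     haptophytes]
  - {name: Phylum, kind: text}
  - {name: Class, kind: text}
  - {name: Order, kind: text}
  - {name: Family, kind: text}
  - {name: Genus, kind: text}
  - {name: Species, kind: text}
  - {name: Infra_Species, kind: text}

traits:
  # --- life forms and geometric forms -------------------------------------
  - {name: Life_Form, kind: categorical, required: true,
     allowed_values: [cell, colony, filament]}
  - {name: Second_Life_Form, kind: categorical,
     allowed_values: [cell, colony, filament]}
  - &form_def
    name: Cell_Form
    kind: categorical
    allowed_values: [sphere, cylinder, rotational_ellipsoid,
                     flattened_ellipsoid, cymbelloid, staurastrum, ceratium,
                     oval_cylinder, double_cone, parallelepiped,
                     prism_on_parallelogram_base, prism_on_triangular_base,
                     cone_with_half_sphere, tetrahedron]
  - <<: *form_def
    name: Individual_Form
  # --- linear dimensions (um) ---------------------------------------------
  - {name: Min_Cell_Length, kind: continuous, units: um}
  - {name: Max_Cell_Length, kind: continuous, units: um}
  - {name: Min_Cell_Width, kind: continuous, units: um}
  - {name: Max_Cell_Width, kind: continuous, units: um}
  - {name: Min_Cell_Thickness, kind: continuous, units: um}
  - {name: Max_Cell_Thickness, kind: continuous, units: um}
  - {name: Min_Individual_Length, kind: continuous, units: um}
  - {name: Max_Individual_Length, kind: continuous, units: um}
  - {name: Cells_Per_Individual, kind: continuous, units: cells}
  # --- biovolume and carbon -----------------------------------------------
  - {name: Cell_Biovolume, kind: continuous, units: um3}
  - {name: Individual_Biovolume, kind: continuous, units: um3}
  - {name: Carbon_Content, kind: continuous, units: pg C}
  # --- size classes ---------------------------------------------------------
  - &sieburth_def
    name: Sieburth_Class_Min_Length
    kind: categorical
    allowed_values: [picophytoplankton, nanophytoplankton,
                     microphytoplankton, mesophytoplankton]
  - <<: *sieburth_def
    name: Sieburth_Class_Max_Length
  - {name: Ignatiades_Class, kind: categorical,
     allowed_values: [picoplankton, nanoplankton, microplankton,
                      macroplankton]}
  # --- binary traits (1-presence, 0-absence) -------------------------------
  - {name: Motility, kind: boolean}
  - {name: Flagellum, kind: boolean}
  - {name: Aerotope, kind: boolean}
  - {name: Contractile_Vacuole, kind: boolean}
  - {name: Mucilage, kind: boolean}
  - {name: Akinete, kind: boolean}
  - {name: Heterocyte, kind: boolean}
  - {name: Cyst, kind: boolean}
  - {name: Plast, kind: boolean}
  - {name: Sheath, kind: boolean}
  - {name: Tractus, kind: boolean}
  - {name: Siliceous_Skeleton, kind: boolean}
  - {name: Lorica, kind: boolean}
  - {name: External_Plate, kind: boolean}
  - {name: Scale, kind: boolean}
  - {name: Ornamentation, kind: boolean}
  - {name: Protuberance, kind: boolean}
  - {name: Chlorophyll_B, kind: boolean}
  - {name: Chlorophyll_C, kind: boolean}
  - {name: Xanthophyll, kind: boolean}
  - {name: Phycobilin, kind: boolean}
  - {name: Toxin, kind: boolean}
  # --- counts and protuberance detail --------------------------------------
  - {name: Flagella_Number, kind: continuous, units: count}
  - {name: Plastid_Number, kind: continuous, units: count}
  - {name: Protuberance_Type, kind: categorical,
     allowed_values: [granule, needle, bristle, spine, horn, wart, wing, None]}
  - {name: Protuberance_Size, kind: categorical,
     allowed_values: [small, large, None]}
  - {name: Protuberance_Number, kind: continuous, units: count}
  - {name: Toxin_Family, kind: categorical,
     allowed_values: [microcystin, anatoxin-a, anatoxin-a(S),
                      cylindrospermopsin, saxitoxin,
                      Beta-Methylamino-L-Alanin]}
  # --- ecology -------------------------------------------------------------
  - {name: Nutrition_Mode, kind: categorical,
     allowed_values: [autotroph, mixotroph, heterotroph]}
  - {name: Reproduction_Mode, kind: text}
  - {name: Water_Type, kind: categorical,
     allowed_values: [freshwater, marine, freshwater-marine]}
  - {name: Water_Trophy, kind: categorical,
     allowed_values: [oligotrophic, oligo-mesotrophic, mesotrophic,
                      meso-eutrophic, eutrophic, hypereutrophic]}
  - {name: Tolerance, kind: text}
  - {name: Reynolds_Group, kind: text}

# Alias map: header spellings seen in external deposits -> canonical names.
# Extend/replace via TraitSchema.from_yaml on a user file.
aliases:
  Taxa_name: Taxa_Name
  Taxon_Name: Taxa_Name
  Taxa_code: Taxa_Code
  Code: Taxa_Code
  Group_Name: Group
  Life_form: Life_Form
  Second_life_form: Second_Life_Form
  Cell_form: Cell_Form
  Individual_form: Individual_Form
  Chlorophyll_b: Chlorophyll_B
  Chlorophyll_c: Chlorophyll_C
  Infraspecies: Infra_Species
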