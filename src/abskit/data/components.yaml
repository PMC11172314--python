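# Phase-forming species of the fluorinated-IL ABS study.
# Molar masses (g/mol) from standard reference data (cation + anion sums for
# the ionic liquids); the study itself does not print them.
- name: "[C2C1Im][C4F9SO3]"
  molar_mass_g_mol: 410.26   # 1-ethyl-3-methylimidazolium (111.17) + perfluorobutanesulfonate (299.09)
  role: fluorinated_IL
- name: "[N1112(OH)][C4F9SO3]"
  molar_mass_g_mol: 403.26   # cholinium (104.17) + perfluorobutanesulfonate (299.09)
  role: fluorinated_IL
- name: "[C2C1Im][CF3SO3]"
  molar_mass_g_mol: 260.23   # 1-ethyl-3-methylimidazolium + triflate (149.07)
  role: fluoro_containing_IL
- name: "[C4C1Im][CF3SO3]"
  molar_mass_g_mol: 288.29   # 1-butyl-3-methylimidazolium (139.22) + triflate
  role: fluoro_containing_IL
- name: "[N1112(OH)][H2PO4]"
  molar_mass_g_mol: 201.16   # cholinium + dihydrogen phosphate (96.99)
  role: stabilizer
- name: "K3PO4"
  molar_mass_g_mol: 212.27
  role: inorganic_salt
- name: "glucose"
  molar_mass_g_mol: 180.16
  role: carbohydrate
- name: "sucrose"
  molar_mass_g_mol: 342.30
  role: carbohydrate
- name: "water"
  molar_mass_g_mol: 18.015
  role: water
- name: "lysozyme"
  molar_mass_g_mol: 14300.0
  role: protein
- name: "BSA"
  molar_mass_g_mol: 66500.0
  role: protein
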