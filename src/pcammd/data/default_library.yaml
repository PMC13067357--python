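energies:
- 70.0
- 150.0
materials:
- name: air
  hu:
  - -1000.0
  - -1000.0
- name: water
  hu:
  - 0.0
  - 0.0
- name: lipid
  hu:
  - -119.5810070546676
  - -86.46041789830731
- name: collagen
  hu:
  - 257.36710221802593
  - 284.77800505115346
- name: iodine
  hu:
  - 518.2107465023319
  - 97.49271405380325
  reference_concentration: 20.0
- name: hydroxyapatite
  hu:
  - 583.848809266164
  - 403.8016958338127
  reference_concentration: 400.0
domains:
- label: air-soft-tissue
  vertices:
  - air
  - water
  - collagen
- label: fat-muscle
  vertices:
  - lipid
  - water
  - collagen
- label: bone-soft-tissue
  vertices:
  - water
  - collagen
  - hydroxyapatite
- label: iodine-near-air
  vertices:
  - water
  - air
  - iodine
- label: calcified-with-iodine
  vertices:
  - water
  - iodine
  - hydroxyapatite
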