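name: asymmetry_distortion
variables:
  asymmetry:
  - absent
  - present
  asymmetry_type:
  - none
  - missing
  - focal
  - developing
  distortion:
  - absent
  - present
  distortion_type:
  - none
  - primary
  - associated
output:
  name: R3
  labels:
  - label: very-low
    a: 0.0
    b: 0.0
    c: 25.0
  - label: low
    a: 0.0
    b: 25.0
    c: 50.0
  - label: medium
    a: 25.0
    b: 50.0
    c: 75.0
  - label: high
    a: 50.0
    b: 75.0
    c: 100.0
  - label: very-high
    a: 75.0
    b: 100.0
    c: 100.0
config:
  structure: Mamdani
  defuzz: centroid
  implication: MIN
  aggregation: MAX
resolution: 10001
rules:
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: absent
    distortion_type: none
  then: very-low
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: absent
    distortion_type: primary
  then: low
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: absent
    distortion_type: associated
  then: low
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: present
    distortion_type: none
  then: low
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: present
    distortion_type: primary
  then: low
- if:
    asymmetry: absent
    asymmetry_type: none
    distortion: present
    distortion_type: associated
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: absent
    distortion_type: none
  then: low
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: absent
    distortion_type: primary
  then: low
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: absent
    distortion_type: associated
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: present
    distortion_type: none
  then: low
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: present
    distortion_type: primary
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: missing
    distortion: present
    distortion_type: associated
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: absent
    distortion_type: none
  then: low
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: absent
    distortion_type: primary
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: absent
    distortion_type: associated
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: present
    distortion_type: none
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: present
    distortion_type: primary
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: focal
    distortion: present
    distortion_type: associated
  then: high
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: absent
    distortion_type: none
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: absent
    distortion_type: primary
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: absent
    distortion_type: associated
  then: high
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: present
    distortion_type: none
  then: medium
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: present
    distortion_type: primary
  then: high
- if:
    asymmetry: absent
    asymmetry_type: developing
    distortion: present
    distortion_type: associated
  then: high
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: absent
    distortion_type: none
  then: low
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: absent
    distortion_type: primary
  then: low
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: absent
    distortion_type: associated
  then: medium
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: present
    distortion_type: none
  then: low
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: present
    distortion_type: primary
  then: medium
- if:
    asymmetry: present
    asymmetry_type: none
    distortion: present
    distortion_type: associated
  then: medium
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: absent
    distortion_type: none
  then: low
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: absent
    distortion_type: primary
  then: medium
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: absent
    distortion_type: associated
  then: medium
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: present
    distortion_type: none
  then: medium
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: present
    distortion_type: primary
  then: medium
- if:
    asymmetry: present
    asymmetry_type: missing
    distortion: present
    distortion_type: associated
  then: high
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: absent
    distortion_type: none
  then: medium
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: absent
    distortion_type: primary
  then: medium
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: absent
    distortion_type: associated
  then: high
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: present
    distortion_type: none
  then: medium
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: present
    distortion_type: primary
  then: high
- if:
    asymmetry: present
    asymmetry_type: focal
    distortion: present
    distortion_type: associated
  then: high
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: absent
    distortion_type: none
  then: medium
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: absent
    distortion_type: primary
  then: high
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: absent
    distortion_type: associated
  then: high
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: present
    distortion_type: none
  then: high
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: present
    distortion_type: primary
  then: high
- if:
    asymmetry: present
    asymmetry_type: developing
    distortion: present
    distortion_type: associated
  then: very-high
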