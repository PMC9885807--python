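# Oxygen-glucose deprivation (OGD) exemplar term set.
# Phrase words may be separated by space, hyphen, en-/em-dash or slash in text;
# the abbreviation matches exact-case at word boundaries.
terms:
  - phrase: [oxygen, glucose, deprivation]
    variants:
      - [oxygen, and, glucose, deprivation]
      - [glucose, and, oxygen, deprivation]
      - [glucose, oxygen, deprivation]
      - [deprived, of, oxygen, and, glucose]
      - [deprived, of, glucose, and, oxygen]
      - [deprivation, of, oxygen, and, glucose]
      - [deprivation, of, glucose, and, oxygen]
      - [oxygen, glucose, deprived]
    abbrev: OGD
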