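# MISS 2 — the simplified study score sheet: three criteria, levels 0/1/2/4.
# Cumulative grading: 0 normal, 1-7 morbid (increase monitoring), >=8 euthanize.
name: MISS2
euthanasia_threshold: 8
criteria:
  - name: appearance
    levels:
      - {description: "Normal", points: 0}
      - {description: "Reduced grooming", points: 1}
      - {description: "Dull/rough coat", points: 2}
      - {description: "Absence of grooming, piloerection, hunched up", points: 4}
  - name: general_behavior
    levels:
      - {description: "Normal", points: 0}
      - {description: "Minor changes, less peer interaction", points: 1}
      - {description: "Little peer interaction, less mobile and alert, isolated", points: 2}
      - {description: "No peer interaction, vocalization, restless or still", points: 4}
  - name: provoked_behavior
    levels:
      - {description: "Normal", points: 0}
      - {description: "Subdued; responds to stimulation", points: 1}
      - {description: "Subdued even to stimulation", points: 2}
      - {description: "Unresponsive to gentle prodding", points: 4}
grading:
  - {label: normal, min: 0, max: 0}
  - {label: morbid, min: 1, max: 7}
  - {label: moribund, min: 8}
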