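# MISS 1 — the original score sheet. Four criteria (no weight criterion in the
# printed sheet). Its grading bands were never published separately; the shipped
# config reuses the MISS 3 bands, which its own sheet points to.
name: MISS1
euthanasia_threshold: 12
criteria:
  - name: appearance
    levels:
      - {description: "Normal (smooth coat, clear eyes/nose)", points: 0}
      - {description: "Hunched and/or fluffed", points: 1}
      - {description: "Ocular discharge, and/or edema", points: 3}
      - {description: "Blue mucus membranes/skin (cyanosis)", points: 12, flag: euthanize_immediate}
  - name: respiratory_rate
    levels:
      - {description: "Normal breathing", points: 0}
      - {description: "Increased breathing (double normal rate, rapid, shallow)", points: 6}
      - {description: "Abdominal breathing (gasping +/- open mouth breathing)", points: 12, flag: euthanize_immediate}
  - name: general_behavior
    levels:
      - {description: "Normal (based on baseline observations)", points: 0}
      - {description: "Decreased mobility", points: 2}
      - {description: "Ataxia, wobbly, weak", points: 6, flag: notify}
      - {description: "Inability to stand", points: 12, flag: euthanize_immediate}
  - name: provoked_behavior
    levels:
      - {description: "Normal (moves when cage is disturbed, runs from hand)", points: 0}
      - {description: "Subdued; responds to stimulation (moves away briskly)", points: 1}
      - {description: "Subdued even to stimulation (moves away slowly)", points: 3}
      - {description: "Unresponsive to gentle prodding", points: 6, flag: notify}
      - {description: "Does not right when placed gently on side within 5 seconds", points: 12, flag: euthanize_immediate}
grading:
  - {label: normal, min: 0, max: 5}
  - {label: morbid, min: 6, max: 11}
  - {label: moribund, min: 12}
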