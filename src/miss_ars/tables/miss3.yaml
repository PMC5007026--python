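# MISS 3 — the recommended score sheet. Five criteria with 6/12-point severe
# levels; "notify" levels demand immediate escalation regardless of total,
# "euthanize_immediate" levels (definitive criteria) mandate euthanasia because
# death is imminent. Weight-loss levels are selected from the percent loss from
# the pre-irradiation baseline (see scoring.weight_loss_level).
name: MISS3
euthanasia_threshold: 12
criteria:
  - name: appearance
    levels:
      - {description: "Normal (smooth coat, clear eyes/nose)", points: 0}
      - {description: "Hunched and/or fluffed", points: 1}
      - {description: "Ocular discharge and/or edema", points: 3}
      - {description: "Pale, white mucus membranes/skin", points: 6, flag: notify}
      - {description: "Blue mucus membranes/skin (cyanosis)", points: 12, flag: euthanize_immediate}
  - name: respiratory_rate
    levels:
      - {description: "Normal breathing", points: 0}
      - {description: "Increased breathing (double normal rate, rapid, shallow)", points: 6}
      - {description: "Abdominal breathing (+/- gasping or open mouth breathing)", points: 12, flag: euthanize_immediate}
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
      - {description: "Does not right when placed on side within 5 seconds", points: 12, flag: euthanize_immediate}
  - name: weight_loss
    levels:
      - {description: "< 20%", points: 0}
      - {description: "20-25%", points: 3}
      - {description: "26-30%", points: 6}
      - {description: "31-35%", points: 9}
      - {description: ">= 35%", points: 12, flag: euthanize_immediate}
grading:
  - {label: normal, min: 0, max: 5}
  - {label: morbid, min: 6, max: 11}
  - {label: moribund, min: 12}
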