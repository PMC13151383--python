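# EORTC QLQ-C30 version 3.0 item-to-scale mapping.
# Each of the 30 items belongs to exactly one of the 15 subscales.
# item_range is the score range of the response format: 3 for the
# four-point items (1..4), 6 for the seven-point global items (1..7).
scales:
  - code: Q1
    name: physical functioning
    category: functional
    items: [1, 2, 3, 4, 5]
    item_range: 3
  - code: Q2
    name: role functioning
    category: functional
    items: [6, 7]
    item_range: 3
  - code: Q3
    name: emotional functioning
    category: functional
    items: [21, 22, 23, 24]
    item_range: 3
  - code: Q4
    name: cognitive functioning
    category: functional
    items: [20, 25]
    item_range: 3
  - code: Q5
    name: social functioning
    category: functional
    items: [26, 27]
    item_range: 3
  - code: Q6
    name: fatigue
    category: symptom
    items: [10, 12, 18]
    item_range: 3
  - code: Q7
    name: nausea and vomiting
    category: symptom
    items: [14, 15]
    item_range: 3
  - code: Q8
    name: pain
    category: symptom
    items: [9, 19]
    item_range: 3
  - code: Q9
    name: dyspnea
    category: symptom
    items: [8]
    item_range: 3
  - code: Q10
    name: insomnia
    category: symptom
    items: [11]
    item_range: 3
  - code: Q11
    name: appetite loss
    category: symptom
    items: [13]
    item_range: 3
  - code: Q12
    name: constipation
    category: symptom
    items: [16]
    item_range: 3
  - code: Q13
    name: diarrhea
    category: symptom
    items: [17]
    item_range: 3
  - code: Q14
    name: financial difficulties
    category: symptom
    items: [28]
    item_range: 3
  - code: Q15
    name: global health status
    category: global
    items: [29, 30]
    item_range: 6
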