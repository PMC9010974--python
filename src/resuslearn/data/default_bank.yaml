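declared:
  n_questions: 21
  equipment_totals:
    totally_correct: 21
    partially_correct: 6
    incorrect: 13
questions:
- id: q01
  options:
  - id: q01_a
    correct: false
  - id: q01_b
    correct: false
  - id: q01_c
    correct: false
  - id: q01_d
    correct: true
  - id: q01_e
    correct: false
  - id: q01_f
    correct: false
- id: q02
  options:
  - id: q02_a
    correct: true
  - id: q02_b
    correct: false
  - id: q02_c
    correct: false
  - id: q02_d
    correct: false
  - id: q02_e
    correct: false
  - id: q02_f
    correct: false
- id: q03
  options:
  - id: q03_a
    correct: false
  - id: q03_b
    correct: false
  - id: q03_c
    correct: false
  - id: q03_d
    correct: true
  - id: q03_e
    correct: false
  - id: q03_f
    correct: false
- id: q04
  options:
  - id: q04_a
    correct: true
  - id: q04_b
    correct: false
  - id: q04_c
    correct: false
  - id: q04_d
    correct: false
  - id: q04_e
    correct: false
  - id: q04_f
    correct: false
- id: q05
  options:
  - id: q05_a
    correct: false
  - id: q05_b
    correct: false
  - id: q05_c
    correct: false
  - id: q05_d
    correct: true
  - id: q05_e
    correct: false
  - id: q05_f
    correct: false
- id: q06
  options:
  - id: q06_a
    correct: true
  - id: q06_b
    correct: false
  - id: q06_c
    correct: false
  - id: q06_d
    correct: false
  - id: q06_e
    correct: false
  - id: q06_f
    correct: false
- id: q07
  options:
  - id: q07_a
    correct: false
  - id: q07_b
    correct: false
  - id: q07_c
    correct: false
  - id: q07_d
    correct: true
  - id: q07_e
    correct: false
  - id: q07_f
    correct: false
- id: q08
  options:
  - id: q08_a
    correct: true
  - id: q08_b
    correct: false
  - id: q08_c
    correct: false
  - id: q08_d
    correct: false
  - id: q08_e
    correct: false
  - id: q08_f
    correct: false
- id: q09
  options:
  - id: q09_a
    correct: false
  - id: q09_b
    correct: false
  - id: q09_c
    correct: false
  - id: q09_d
    correct: true
  - id: q09_e
    correct: false
  - id: q09_f
    correct: false
- id: q10
  options:
  - id: q10_a
    correct: true
  - id: q10_b
    correct: false
  - id: q10_c
    correct: false
  - id: q10_d
    correct: false
  - id: q10_e
    correct: false
  - id: q10_f
    correct: false
- id: q11
  options:
  - id: q11_a
    correct: false
  - id: q11_b
    correct: false
  - id: q11_c
    correct: false
  - id: q11_d
    correct: true
  - id: q11_e
    correct: false
  - id: q11_f
    correct: false
- id: q12
  options:
  - id: q12_a
    correct: true
  - id: q12_b
    correct: false
  - id: q12_c
    correct: false
  - id: q12_d
    correct: false
  - id: q12_e
    correct: false
  - id: q12_f
    correct: false
- id: q13
  options:
  - id: q13_a
    correct: false
  - id: q13_b
    correct: false
  - id: q13_c
    correct: false
  - id: q13_d
    correct: true
  - id: q13_e
    correct: false
  - id: q13_f
    correct: false
- id: q14
  options:
  - id: q14_a
    correct: true
  - id: q14_b
    correct: false
  - id: q14_c
    correct: false
  - id: q14_d
    correct: false
  - id: q14_e
    correct: false
  - id: q14_f
    correct: false
- id: q15
  options:
  - id: q15_a
    correct: false
  - id: q15_b
    correct: false
  - id: q15_c
    correct: false
  - id: q15_d
    correct: true
  - id: q15_e
    correct: false
  - id: q15_f
    correct: false
- id: q16
  options:
  - id: q16_a
    correct: true
  - id: q16_b
    correct: false
  - id: q16_c
    correct: false
  - id: q16_d
    correct: false
  - id: q16_e
    correct: false
  - id: q16_f
    correct: false
- id: q17
  options:
  - id: q17_a
    correct: false
  - id: q17_b
    correct: false
  - id: q17_c
    correct: false
  - id: q17_d
    correct: true
  - id: q17_e
    correct: false
  - id: q17_f
    correct: false
- id: q18
  options:
  - id: q18_a
    correct: true
  - id: q18_b
    correct: false
  - id: q18_c
    correct: false
  - id: q18_d
    correct: false
  - id: q18_e
    correct: false
  - id: q18_f
    correct: false
- id: q19
  options:
  - id: q19_a
    correct: false
  - id: q19_b
    correct: false
  - id: q19_c
    correct: false
  - id: q19_d
    correct: true
  - id: q19_e
    correct: false
  - id: q19_f
    correct: false
- id: q20
  options:
  - id: q20_a
    correct: true
  - id: q20_b
    correct: false
  - id: q20_c
    correct: false
  - id: q20_d
    correct: false
  - id: q20_e
    correct: false
  - id: q20_f
    correct: false
- id: q21
  options:
  - id: q21_a
    correct: false
  - id: q21_b
    correct: false
  - id: q21_c
    correct: false
  - id: q21_d
    correct: true
  - id: q21_e
    correct: false
  - id: q21_f
    correct: false
equipment:
- id: e01
  label: radiant warmer
  category: totally_correct
- id: e02
  label: pre-warmed towels
  category: totally_correct
- id: e03
  label: polyethylene wrap
  category: totally_correct
- id: e04
  label: newborn hat
  category: totally_correct
- id: e05
  label: suction device
  category: totally_correct
- id: e06
  label: suction catheter
  category: totally_correct
- id: e07
  label: self-inflating bag
  category: totally_correct
- id: e08
  label: T-piece resuscitator
  category: totally_correct
- id: e09
  label: term face mask
  category: totally_correct
- id: e10
  label: preterm face mask
  category: totally_correct
- id: e11
  label: oropharyngeal airway
  category: totally_correct
- id: e12
  label: oxygen blender
  category: totally_correct
- id: e13
  label: pulse oximeter
  category: totally_correct
- id: e14
  label: ECG leads
  category: totally_correct
- id: e15
  label: stethoscope
  category: totally_correct
- id: e16
  label: laryngoscope with size-1 blade
  category: totally_correct
- id: e17
  label: ET tube with stylet
  category: totally_correct
- id: e18
  label: umbilical vein catheter kit
  category: totally_correct
- id: e19
  label: adrenaline
  category: totally_correct
- id: e20
  label: normal saline
  category: totally_correct
- id: e21
  label: timer clock
  category: totally_correct
- id: e22
  label: laryngeal mask airway
  category: partially_correct
- id: e23
  label: neonatal incubator check
  category: partially_correct
- id: e24
  label: E.R. bag
  category: partially_correct
- id: e25
  label: intensive care ventilator
  category: partially_correct
- id: e26
  label: nasal cannula
  category: partially_correct
- id: e27
  label: CPAP prongs
  category: partially_correct
- id: e28
  label: ultrasound machine
  category: incorrect
- id: e29
  label: ultrasound probe
  category: incorrect
- id: e30
  label: thin surfactant catheter
  category: incorrect
- id: e31
  label: adult face mask
  category: incorrect
- id: e32
  label: defibrillator
  category: incorrect
- id: e33
  label: adult laryngoscope blade
  category: incorrect
- id: e34
  label: chest drain kit
  category: incorrect
- id: e35
  label: infusion pump
  category: incorrect
- id: e36
  label: blood gas analyzer
  category: incorrect
- id: e37
  label: adult BP cuff
  category: incorrect
- id: e38
  label: glucometer
  category: incorrect
- id: e39
  label: phototherapy lamp
  category: incorrect
- id: e40
  label: transport ventilator
  category: incorrect
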