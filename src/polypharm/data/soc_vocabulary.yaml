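# Indication -> organ-system classification vocabulary.
#
# 27 categories: the 26 System Organ Classes (the top level of the MedDRA
# hierarchy, as used by the CTCAE) plus an added "Trauma-related pain"
# category covering nociceptive and neuropathic pain, which the standard
# classes do not represent well in a trauma population.
#
# `categories` is ordered: keyword ties (same matched length) resolve to the
# category listed first. Matching is case-insensitive substring with
# longest-keyword-wins. `overrides` maps an exact (case-folded) indication
# string to a category and always takes precedence over keywords.
#
# The keyword lexicon is a curated starting point, not a licensed MedDRA
# term list; users can supply their own file with the same schema.
categories:
  - name: Trauma-related pain
    keywords:
      - neuropathic pain
      - nociceptive pain
      - musculoskeletal pain
      - incisional pain
      - back pain
      - neck pain
      - shoulder pain
      - pain control
      - pain
      - analgesia
  - name: Infections and infestations
    keywords:
      - urinary tract infection
      - wound infection
      - respiratory infection
      - fungal infection
      - infection
      - pneumonia
      - sepsis
      - cellulitis
      - osteomyelitis
      - bacteremia
      - candidiasis
  - name: Gastrointestinal disorders
    keywords:
      - gastric ulcer
      - stress ulcer
      - peptic ulcer
      - ulcer
      - constipation
      - bowel regimen
      - bowel management
      - heartburn
      - gastroesophageal reflux
      - reflux
      - nausea
      - vomiting
      - gastritis
      - ileus
      - diarrhea
  - name: Vascular disorders
    keywords:
      - deep vein thrombosis
      - deep venous thrombosis
      - dvt
      - thromboembolism
      - thrombosis
      - pulmonary embolism
      - hypotension
      - hypertension
      - orthostatic
  - name: Psychiatric disorders
    keywords:
      - depression
      - anxiety
      - insomnia
      - agitation
      - sleep
      - delirium
  - name: Nervous system disorders
    keywords:
      - seizure
      - spasticity
      - muscle spasm
      - headache
      - dizziness
      - autonomic dysreflexia
  - name: Respiratory, thoracic and mediastinal disorders
    keywords:
      - respiratory secretions
      - respiratory failure
      - atelectasis
      - bronchospasm
      - asthma
      - dyspnea
      - ventilation
  - name: Renal and urinary disorders
    keywords:
      - neurogenic bladder
      - urinary retention
      - bladder spasm
      - bladder
      - renal failure
      - oliguria
  - name: Cardiac disorders
    keywords:
      - bradycardia
      - tachycardia
      - arrhythmia
      - heart failure
      - cardiac arrest
  - name: Blood and lymphatic system disorders
    keywords:
      - anemia
      - anaemia
      - thrombocytopenia
      - neutropenia
  - name: Metabolism and nutrition disorders
    keywords:
      - hyperglycemia
      - hypoglycemia
      - hypokalemia
      - hyponatremia
      - electrolyte
      - nutrition
      - dehydration
  - name: Musculoskeletal and connective tissue disorders
    keywords:
      - contracture
      - heterotopic ossification
      - myalgia
  - name: Skin and subcutaneous tissue disorders
    keywords:
      - pressure ulcer
      - pressure sore
      - decubitus
      - rash
      - pruritus
      - wound care
  - name: Surgical and medical procedures
    keywords:
      - surgery
      - surgical
      - anesthesia
      - anaesthesia
      - sedation for procedure
      - intubation
      - laminectomy
      - decompression
      - imaging procedure
      - procedure
  - name: General disorders and administration site conditions
    keywords:
      - fever
      - pyrexia
      - edema
      - malaise
      - fatigue
  - name: Immune system disorders
    keywords:
      - allergic reaction
      - allergy
      - anaphylaxis
  - name: Endocrine disorders
    keywords:
      - thyroid
      - adrenal insufficiency
  - name: Eye disorders
    keywords:
      - conjunctivitis
      - eye irritation
      - glaucoma
  - name: Ear and labyrinth disorders
    keywords:
      - vertigo
      - ear infection
      - tinnitus
  - name: Hepatobiliary disorders
    keywords:
      - hepatic
      - liver
      - cholecystitis
  - name: Investigations
    keywords:
      - laboratory test
      - diagnostic test
      - contrast
  - name: Neoplasms benign, malignant and unspecified
    keywords:
      - tumor
      - tumour
      - cancer
      - malignancy
  - name: Pregnancy, puerperium and perinatal conditions
    keywords:
      - pregnancy
  - name: Congenital, familial and genetic disorders
    keywords:
      - congenital
  - name: Injury, poisoning and procedural complications
    keywords:
      - overdose
      - poisoning
      - procedural complication
  - name: Reproductive system and breast disorders
    keywords:
      - menstrual
      - erectile
  - name: Social circumstances
    keywords:
      - social circumstance
overrides:
  dvt prophylaxis: Vascular disorders
  stress ulcer prophylaxis: Gastrointestinal disorders
  surgical prophylaxis: Infections and infestations
  perioperative antibiotic: Infections and infestations
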