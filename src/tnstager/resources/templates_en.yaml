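# English sentence templates for the synthetic report generator.  A second
# language is a drop-in replacement of this file plus the matching lexicon.
# Placeholders in {braces} are filled by the generator.

section_text:
  clinical_details:
    - "Known pulmonary malignancy, staging CT."
    - "Staging of suspected lung carcinoma."
    - "Follow-up of abnormal chest radiograph, question of malignancy."
  modality:
    - "Contrast-enhanced CT of the chest."
    - "CT thorax after intravenous contrast administration."
  body_part:
    - "Chest."
    - "Thorax."

tumor_words: [tumor, mass, carcinoma]
lobes: [upper, lower]

tumor_sized:
  - "There is a {size} {tumor_word} in the {side} {lobe} lobe{involvement}."
  - "A {tumor_word} measuring {size} is seen in the {side} {lobe} lobe{involvement}."
  - "The {side} {lobe} lobe contains a {tumor_word} of {size}{involvement}."
tumor_unsized:
  - "There is a {tumor_word} in the {side} {lobe} lobe{involvement}."
  - "An irregular {tumor_word} is seen in the {side} {lobe} lobe{involvement}."

involvement_phrases:
  visceral_pleura: [" with invasion of the visceral pleura"]
  main_bronchus: [" extending into the main bronchus"]
  chest_wall: [" with invasion of the chest wall", " invading the chest wall"]
  parietal_pericardium: [" with invasion of the parietal pericardium"]
  phrenic_nerve: [" with involvement of the phrenic nerve"]
  mediastinum: [" with invasion of the mediastinum", " invading the mediastinum"]
  diaphragm: [" with invasion of the diaphragm"]
  heart: [" with invasion of the heart"]
  great_vessels: [" encasing the aorta"]
  carina: [" extending to the carina"]
  trachea: [" with invasion of the trachea"]
  esophagus: [" with invasion of the esophagus"]
  vertebra: [" with invasion of the vertebral body"]
  recurrent_laryngeal_nerve: [" with involvement of the recurrent laryngeal nerve"]
  atelectasis: [" with accompanying atelectasis", " with atelectasis of the adjacent lobe"]
  obstructive_pneumonitis: [" with obstructive pneumonitis"]
  same_lobe_nodule: [" with a separate nodule in the same lobe"]
  other_lobe_nodule: [" with a separate nodule in a different ipsilateral lobe"]

# Three surface patterns for a pathological node: (1) compound adjective or
# lymphadenopathy, (2) enlarged size, (3) plain node plus a detached
# pathological modifier.
node_compound:
  - "There are pathological lymph nodes at {station}."
  - "Enlarged lymph nodes at {station}."
  - "There is lymphadenopathy at {station}."
  - "Pathologically enlarged lymph node at {station}."
node_sized:
  - "A lymph node at {station} measuring {nsize}."
  - "There is a {nsize} lymph node at {station}."
  - "At {station} a lymph node of {nsize} is seen."
node_modifier:
  - "The lymph nodes at {station} appear enlarged."
  - "The lymph node at {station} is pathological."
  - "There are enlarged nodes at {station}."

node_negated:
  - "No pathological lymph nodes."
  - "No enlarged lymph nodes."
  - "No lymphadenopathy."
  - "There is no lymphadenopathy."

node_uncertain:
  - "Possibly enlarged lymph node at {station}."
  - "Questionable lymphadenopathy at {station}."

distractors:
  - "No pleural effusion."
  - "No pericardial effusion."
  - "The upper abdomen is unremarkable."
  - "The airways are patent."

impression:
  - "Findings consistent with a {side}-sided pulmonary malignancy."
  - "Pulmonary malignancy in the {side} lung as described above."
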