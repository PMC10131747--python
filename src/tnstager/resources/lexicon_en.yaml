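# English reference lexicon for chest-CT TN staging.
#
# This is a synthetic reconstruction of a clinical concept lexicon: the term
# lists were written from the TNM-8 vocabulary and common English radiology
# phrasing, not harvested from any report corpus.  Swapping this file is the
# intended way to support another language or institution; the rule engine
# itself never changes.
#
# All patterns are Python regular expressions, matched case-insensitively and
# wrapped in word boundaries by the loader.

headings:
  "clinical (?:details|information|history|indication)": clinical_details
  "(?:description of (?:the )?)?(?:modality|technique|protocol)": modality
  "(?:report|findings|description)": report
  "body ?part": body_part
  "(?:impression|conclusion|opinion)": impression

# Tokens whose trailing period must not end a sentence.
abbreviations: [dr, prof, ca, approx, vs, eg, ie, fig, max, min, diam, resp]

tumor:
  - "tumou?r(?: mass)?"
  - "mass(?:es)? lesion"
  - "mass"
  - "carcinoma"
  - "neoplasm"
  - "malignancy"
  - "primary lesion"
  - "spiculated lesion"

# Compound surface forms carry the pathological attribute intrinsically
# (adjective folded into the mention).
lymph_node:
  - pattern: "pathological(?:ly)?(?: enlarged)? lymph ?nodes?"
    pathological: true
  - pattern: "enlarged(?: \\w+)? lymph ?nodes?"
    pathological: true
  - pattern: "nodal metastas[ei]s"
    pathological: true
  - pattern: "lymph ?nodes?"
  - pattern: "nodes?"

lymphadenopathy:
  - "lymph ?adenopathy"
  - "adenopathy"

# One entry per thoracic nodal station of the IASLC map (1 supraclavicular,
# 2-9 mediastinal incl. subcarinal 7, 10-14 hilar/intrapulmonary).  Numeric
# patterns capture an optional R/L suffix as the node side.
stations:
  1: ["(?:station|level)s? 1(?!\\d)(?P<side>[RL])?", "supraclavicular(?: region| fossa)?", "low cervical"]
  2: ["(?:station|level)s? 2(?!\\d)(?P<side>[RL])?", "upper paratracheal"]
  3: ["(?:station|level)s? 3(?!\\d)(?P<side>[AP])?", "pre-?vascular", "retrotracheal"]
  4: ["(?:station|level)s? 4(?!\\d)(?P<side>[RL])?", "lower paratracheal", "paratracheal"]
  5: ["(?:station|level)s? 5(?!\\d)", "subaortic", "aortopulmonary window"]
  6: ["(?:station|level)s? 6(?!\\d)", "para-?aortic"]
  7: ["(?:station|level)s? 7(?!\\d)", "subcarinal(?: region)?"]
  8: ["(?:station|level)s? 8(?!\\d)(?P<side>[RL])?", "para-?esophageal"]
  9: ["(?:station|level)s? 9(?!\\d)(?P<side>[RL])?", "pulmonary ligament"]
  10: ["(?:station|level)s? 10(?P<side>[RL])?", "hilar(?: region)?", "peribronchial"]
  11: ["(?:station|level)s? 11(?P<side>[RL])?", "interlobar"]
  12: ["(?:station|level)s? 12(?P<side>[RL])?", "lobar"]
  13: ["(?:station|level)s? 13(?P<side>[RL])?", "segmental"]
  14: ["(?:station|level)s? 14(?P<side>[RL])?", "subsegmental"]

laterality:
  left: ["left(?:-sided| sided)?"]
  right: ["right(?:-sided| sided)?"]
  ipsilateral: ["ipsilateral(?:ly)?"]
  contralateral: ["contralateral(?:ly)?"]
  bilateral: ["bilateral(?:ly)?", "both sides", "on either side"]

# Invaded structures; each carries the T level that invasion implies under
# TNM-8.  Patterns include the invasion verb so an incidental anatomic word
# ("mediastinal lymph node") is not read as tumor involvement.
structures:
  visceral_pleura:
    implies_t: T2
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the visceral pleura", "visceral pleural invasion"]
  main_bronchus:
    implies_t: T2
    patterns: ["(?:invasion of|invades|invading|extend(?:s|ing) into|involv(?:es|ing|ement of)) the main(?:stem)? bronchus", "main bronchus involvement"]
  chest_wall:
    implies_t: T3
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)|extend(?:s|ing) into) the chest wall", "chest wall invasion"]
  parietal_pericardium:
    implies_t: T3
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the (?:parietal )?pericardium", "pericardial invasion"]
  phrenic_nerve:
    implies_t: T3
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the phrenic nerve", "phrenic nerve involvement"]
  mediastinum:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|extend(?:s|ing) into|involv(?:es|ing|ement of)) the mediastinum", "mediastinal invasion"]
  diaphragm:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the diaphragm", "diaphragmatic invasion"]
  heart:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the heart", "cardiac invasion"]
  great_vessels:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|encas(?:es|ing)|involv(?:es|ing|ement of)) the (?:great vessels|aorta|superior vena cava|pulmonary artery)"]
  carina:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)|extend(?:s|ing) to) the carina", "carinal invasion"]
  trachea:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the trachea", "tracheal invasion"]
  esophagus:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the o?esophagus", "o?esophageal invasion"]
  vertebra:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) (?:a|the) vertebral bod(?:y|ies)", "vertebral invasion"]
  recurrent_laryngeal_nerve:
    implies_t: T4
    patterns: ["(?:invasion of|invades|invading|involv(?:es|ing|ement of)) the recurrent laryngeal nerve"]

# Presence findings: observations (not invasions) that imply a T level.
presence_findings:
  atelectasis:
    implies_t: T2
    patterns: ["atelectasis", "collapse of the (?:\\w+ )?(?:lung|lobe)"]
  obstructive_pneumonitis:
    implies_t: T2
    patterns: ["(?:post-?)?obstructive pneumonitis"]
  same_lobe_nodule:
    implies_t: T3
    patterns: ["(?:additional|separate|satellite) (?:tumou?r )?nodules? in the same lobe"]
  other_lobe_nodule:
    implies_t: T4
    patterns: ["(?:additional|separate) (?:tumou?r )?nodules? in (?:another|a different) ipsilateral lobe"]

pathological_terms:
  - "pathological(?:ly)?"
  - "enlarged"
  - "metastatic"
  - "malignant"

context_modifiers:
  - {category: negation, pattern: "no(?: evidence of| signs? of)?", direction: forward}
  - {category: negation, pattern: "without", direction: forward}
  - {category: negation, pattern: "absence of", direction: forward}
  - {category: negation, pattern: "free of", direction: forward}
  - {category: negation, pattern: "not (?:seen|identified|present|visuali[sz]ed)", direction: backward}
  - {category: negation, pattern: "(?:is|are) absent", direction: backward}
  - {category: negation, pattern: "ruled out", direction: backward}
  - {category: uncertainty, pattern: "suspicious for", direction: forward}
  - {category: uncertainty, pattern: "suspected", direction: forward}
  - {category: uncertainty, pattern: "possib(?:le|ly)", direction: forward}
  - {category: uncertainty, pattern: "probab(?:le|ly)", direction: forward}
  - {category: uncertainty, pattern: "may represent", direction: backward}
  - {category: uncertainty, pattern: "cannot be excluded", direction: backward}
  - {category: uncertainty, pattern: "equivocal", direction: bidirectional}
  - {category: uncertainty, pattern: "questionable", direction: forward}
  - {category: pathological, pattern: "pathological(?:ly)?", direction: bidirectional}
  - {category: pathological, pattern: "(?:appears? )?enlarged", direction: bidirectional}
  - {category: pathological, pattern: "metastatic", direction: bidirectional}
  - {category: pathological, pattern: "malignant", direction: forward}
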