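# TNM 8th-edition rule parameters for the TN staging engine.
#
# Size bands are left-open/right-closed in millimetres: a tumor of exactly
# 30 mm is T1c (T1 caps at <=3 cm), 30.1 mm is T2a.  The last band is
# open-ended (max_mm: null).

t_size_bands:
  - {label: T1a, max_mm: 10}
  - {label: T1b, max_mm: 20}
  - {label: T1c, max_mm: 30}
  - {label: T2a, max_mm: 40}
  - {label: T2b, max_mm: 50}
  - {label: T3, max_mm: 70}
  - {label: T4, max_mm: null}

# Radiological node-enlargement convention: short axis >= 10 mm.
node_short_axis_threshold_mm: 10.0

# Tumor size for T staging uses the largest measured dimension; the node
# short axis is the smallest.
tumor_axis: max
node_axis: min

# Hedged positive findings ("possibly enlarged node") are excluded from
# staging when false (conservative default).
uncertain_positive_counts: false

# ConText-style scope: a modifier reaches at most this many tokens in its
# direction, stopping early at a terminator token.
scope_window_tokens: 8
scope_terminators: [but, however, although, whereas]

# false -> a modifier links only to the nearest in-direction target;
# true  -> it links to every target in scope (ablation switch).
modifier_broadcast: false

# Sections whose findings are ignored during staging (e.g. clinical_details
# to drop referral text); empty by default.
excluded_sections: []

# IASLC station grouping used by the N rules.
station_groups:
  supraclavicular: [1]
  mediastinal: [2, 3, 4, 5, 6, 7, 8, 9]
  midline: [7]
  hilar_intrapulmonary: [10, 11, 12, 13, 14]
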