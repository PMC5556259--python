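{
  "description": "Machine-readable copy of the published study tables for the two real corpora (a French breast-cancer forum and four Facebook groups). Used as printed inputs for derived-number computations; the raw corpora themselves are not redistributable.",
  "corpora": {
    "forum": {
      "name": "cancerdusein.org",
      "n_users": 675,
      "n_threads": 1050,
      "n_messages": 16868,
      "validation": {"validated": 39, "invalidated": 14},
      "topic_document_counts": [978, 590, 1147, 860, 1315, 759, 810, 523, 877, 692, 675, 523, 1113, 692, 843, 1063, 1248, 540, 1198, 422]
    },
    "facebook": {
      "name": "Facebook groups",
      "n_users": 1394,
      "n_threads": 11013,
      "n_messages": 70092,
      "validation": {"validated": 36, "invalidated": 17},
      "topic_document_counts": [3294, 3925, 3785, 4065, 2804, 3715, 3014, 3084, 3645, 3505, 2804, 2734, 5047, 3014, 2804, 2734, 3575, 5607, 3432, 3505]
    }
  },
  "dimension_map": [
    {"questionnaire": "EORTC QLQ-C30", "scale": "Physical functioning", "items": "1-5", "forum_topics": ["Everyday life during cancer", "Treatment period"], "facebook_topics": ["Treatment period"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Role functioning", "items": "6, 7", "forum_topics": ["Everyday life during cancer"], "facebook_topics": []},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Emotional functioning", "items": "21-24", "forum_topics": ["Diagnosis", "Breast cancer as a daily battle", "Waiting for results of analysis, concerns", "Support from patient's family and friends"], "facebook_topics": ["Diagnosis", "Breast cancer as a daily battle", "Anxiety and fatigue", "Support from patient's family and friends"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Cognitive functioning", "items": "20, 25", "forum_topics": ["Search for medical information", "Media and forum information exchange"], "facebook_topics": []},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Social functioning", "items": "26, 27", "forum_topics": ["Support from patient's family and friends", "Work life during cancer and financial aspects"], "facebook_topics": ["Support from patient's family and friends", "Work life during cancer and financial aspects"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Fatigue", "items": "10, 12, 18", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Anxiety and fatigue", "Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Nausea and vomiting", "items": "14, 15", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Pain", "items": "9, 19", "forum_topics": ["Chemotherapy and its secondary effects", "Surgery"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Dyspnea", "items": "8", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Insomnia", "items": "11", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Appetite loss", "items": "13", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Constipation", "items": "16", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Diarrhea", "items": "17", "forum_topics": ["Chemotherapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Financial difficulties", "items": "28", "forum_topics": ["Work life during cancer and financial aspects"], "facebook_topics": ["Work life during cancer and financial aspects"]},
    {"questionnaire": "EORTC QLQ-C30", "scale": "Global health status and quality of life", "items": "29, 30", "forum_topics": [], "facebook_topics": []},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Body image", "items": "39-42", "forum_topics": ["Breast reconstruction", "Body care and body image during cancer, and sexuality", "Surgery"], "facebook_topics": ["Breast reconstruction", "Body care and body image during cancer"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Sexual functioning", "items": "44, 45", "forum_topics": ["Body care and body image during cancer, and sexuality"], "facebook_topics": ["Sexuality"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Sexual enjoyment", "items": "46", "forum_topics": ["Body care and body image during cancer, and sexuality"], "facebook_topics": ["Sexuality"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Future perspectives", "items": "43", "forum_topics": ["Healing"], "facebook_topics": ["Healing", "Relapse"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Systemic therapy side effects", "items": "31-34, 36-38", "forum_topics": ["Chemotherapy and its secondary effects", "Hormone therapy and its secondary effects"], "facebook_topics": ["Secondary effects of treatments", "Chemotherapy and its secondary effects"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Breast symptoms", "items": "50-53", "forum_topics": ["Breast reconstruction", "Radiotherapy and its secondary effects", "Surgery"], "facebook_topics": ["Breast reconstruction"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Arm symptoms", "items": "47-49", "forum_topics": ["Breast reconstruction", "Surgery"], "facebook_topics": ["Breast reconstruction"]},
    {"questionnaire": "EORTC QLQ-BR23", "scale": "Hair loss", "items": "35", "forum_topics": ["Hair loss"], "facebook_topics": ["Hair loss"]}
  ],
  "unrelated_topics": {
    "forum": ["Complementary and alternative medicine", "Mourning", "Family members with breast cancer"],
    "facebook": ["Family background and breast cancer", "Family members with breast cancer", "Healing of family member"]
  },
  "highlight_shares": {
    "complementary_and_alternative_medicine": {"count": 523, "total": 16868, "corpus": "forum"},
    "family_background_and_breast_cancer": {"count": 3014, "total": 70092, "corpus": "facebook"}
  }
}
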