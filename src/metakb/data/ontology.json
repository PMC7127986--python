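{
  "_note": "Synthetic cancer-slim subset of a disease is-a ontology, hand-built for offline use. Edges are child -> parent. The topnodes list is the designated high-level grouping slim.",
  "nodes": [
    {"id": "DOID:4", "label": "disease", "synonyms": []},
    {"id": "DOID:14566", "label": "disease of cellular proliferation", "synonyms": []},
    {"id": "DOID:162", "label": "cancer", "synonyms": ["advanced solid tumor", "solid tumor", "malignant neoplasm"]},
    {"id": "DOID:1612", "label": "breast cancer", "synonyms": ["neoplasm of breast", "breast neoplasm", "mammary cancer"]},
    {"id": "DOID:3459", "label": "breast carcinoma", "synonyms": []},
    {"id": "DOID:3007", "label": "breast ductal carcinoma", "synonyms": ["ductal carcinoma of the breast"]},
    {"id": "DOID:3008", "label": "invasive ductal carcinoma", "synonyms": ["breast invasive ductal carcinoma"]},
    {"id": "DOID:0050938", "label": "breast lobular carcinoma", "synonyms": ["lobular carcinoma of the breast"]},
    {"id": "DOID:0060080", "label": "Her2-receptor negative breast cancer", "synonyms": ["her2-receptor-negative breast cancer", "her2 negative breast cancer"]},
    {"id": "DOID:1324", "label": "lung cancer", "synonyms": ["neoplasm of lung", "lung neoplasm"]},
    {"id": "DOID:3908", "label": "non-small cell lung carcinoma", "synonyms": ["NSCLC", "non-small cell lung cancer"]},
    {"id": "DOID:3910", "label": "lung adenocarcinoma", "synonyms": ["adenocarcinoma of lung"]},
    {"id": "DOID:3907", "label": "lung squamous cell carcinoma", "synonyms": []},
    {"id": "DOID:2531", "label": "hematologic cancer", "synonyms": ["hematological cancer", "blood cancer"]},
    {"id": "DOID:1240", "label": "leukemia", "synonyms": []},
    {"id": "DOID:1040", "label": "chronic lymphocytic leukemia", "synonyms": ["CLL"]},
    {"id": "DOID:9952", "label": "acute lymphoblastic leukemia", "synonyms": ["ALL"]},
    {"id": "DOID:5672", "label": "large intestine cancer", "synonyms": []},
    {"id": "DOID:9256", "label": "colorectal cancer", "synonyms": ["CRC"]},
    {"id": "DOID:219", "label": "colon cancer", "synonyms": []},
    {"id": "DOID:1909", "label": "melanoma", "synonyms": []},
    {"id": "DOID:8923", "label": "skin melanoma", "synonyms": ["cutaneous melanoma"]},
    {"id": "DOID:2394", "label": "ovarian cancer", "synonyms": ["neoplasm of ovary"]},
    {"id": "DOID:11054", "label": "urinary bladder cancer", "synonyms": ["bladder cancer"]},
    {"id": "DOID:1319", "label": "brain cancer", "synonyms": []},
    {"id": "DOID:0060108", "label": "glioma", "synonyms": []},
    {"id": "DOID:184", "label": "bone cancer", "synonyms": []},
    {"id": "DOID:1115", "label": "sarcoma", "synonyms": []},
    {"id": "DOID:10763", "label": "hypertension", "synonyms": []}
  ],
  "edges": [
    ["DOID:14566", "DOID:4"],
    ["DOID:162", "DOID:14566"],
    ["DOID:1612", "DOID:162"],
    ["DOID:3459", "DOID:1612"],
    ["DOID:3007", "DOID:3459"],
    ["DOID:3008", "DOID:3007"],
    ["DOID:0050938", "DOID:3459"],
    ["DOID:0060080", "DOID:1612"],
    ["DOID:1324", "DOID:162"],
    ["DOID:3908", "DOID:1324"],
    ["DOID:3910", "DOID:3908"],
    ["DOID:3907", "DOID:3908"],
    ["DOID:2531", "DOID:162"],
    ["DOID:1240", "DOID:2531"],
    ["DOID:1040", "DOID:1240"],
    ["DOID:9952", "DOID:1240"],
    ["DOID:5672", "DOID:162"],
    ["DOID:9256", "DOID:5672"],
    ["DOID:219", "DOID:9256"],
    ["DOID:1909", "DOID:162"],
    ["DOID:8923", "DOID:1909"],
    ["DOID:2394", "DOID:162"],
    ["DOID:11054", "DOID:162"],
    ["DOID:1319", "DOID:162"],
    ["DOID:0060108", "DOID:1319"],
    ["DOID:184", "DOID:162"],
    ["DOID:1115", "DOID:162"],
    ["DOID:10763", "DOID:4"]
  ],
  "topnodes": [
    "DOID:1612",
    "DOID:1324",
    "DOID:2531",
    "DOID:5672",
    "DOID:1909",
    "DOID:2394",
    "DOID:11054"
  ]
}
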