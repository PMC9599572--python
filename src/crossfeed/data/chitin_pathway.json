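{
  "name": "chitin_nag_breakdown_v1",
  "description": "Eight-step chitin/NAG breakdown and assimilation pathway. Early steps bind and cleave the chitin polymer, mid steps convert oligomers to NAG and deacetylate amino sugars, late steps phosphorylate and deacetylate NAG for entry into glycolysis via fructose-6-phosphate.",
  "steps": [
    {
      "step_id": "chitin_binding",
      "stage": "early",
      "accepted_terms": [["KO", "K03933"]]
    },
    {
      "step_id": "chitinase_gh18",
      "stage": "early",
      "accepted_terms": [["GH", "GH18"], ["EC", "3.2.1.14"]]
    },
    {
      "step_id": "chitinase_gh19",
      "stage": "early",
      "accepted_terms": [["GH", "GH19"], ["KO", "K03791"]]
    },
    {
      "step_id": "hexosaminidase",
      "stage": "mid",
      "accepted_terms": [["GH", "GH20"], ["EC", "3.2.1.52"]]
    },
    {
      "step_id": "ce4_deacetylase",
      "stage": "mid",
      "accepted_terms": [["CE", "CE4"], ["EC", "3.5.1.104"]]
    },
    {
      "step_id": "nag_pts_import",
      "stage": "mid",
      "accepted_terms": [["EC", "2.7.1.193"]]
    },
    {
      "step_id": "nag6p_deacetylase",
      "stage": "late",
      "accepted_terms": [["EC", "3.5.1.25"]]
    },
    {
      "step_id": "glucosamine_kinase",
      "stage": "late",
      "accepted_terms": [["EC", "2.7.1.8"]]
    }
  ]
}
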