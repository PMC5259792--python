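{
  "comment": "Synthetic TM4 window snippets (positions 4.44-4.63, anchor W at 4.50) exemplifying the three proline-motif classes seen in serotonin receptors. These are constructed fixtures consistent with the published motif classes (lone P at 4.60 with Ala at 4.56; adjacent PP ending at 4.60; PxP ending at 4.61), not UniProt-derived sequences.",
  "windows": {
    "5HT6-like-P": {
      "sequence": "LAILVSWLFVISATLFPLLG",
      "anchor_index": 7,
      "anchor_bw": "4.50",
      "motif": "P",
      "expected_exposed": ["4.56"]
    },
    "5HT1B-like-PP": {
      "sequence": "LAILVSWLFVISATLPPLLG",
      "anchor_index": 7,
      "anchor_bw": "4.50",
      "motif": "PP",
      "expected_exposed": ["4.55", "4.56"]
    },
    "5HT2B-like-PxP": {
      "sequence": "LAILVSWLFVISATLPLPLG",
      "anchor_index": 7,
      "anchor_bw": "4.50",
      "motif": "PxP",
      "expected_exposed": ["4.55", "4.57"]
    }
  }
}
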