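{
  "_comment": [
    "Editable annotation of Hsp70 nucleotide-binding-domain (NBD) subdomains",
    "and reference helices, keyed to author residue numbering of human",
    "mortalin (HSPA9; modeled construct starts near residue 46). Published",
    "comparisons do not state exact lobe boundaries, so these spans are",
    "literature-conventional estimates transferred from the DnaK NBD fold;",
    "edit them to match your own assignment before quantitative use.",
    "Each entry: chain, list of inclusive residue ranges. 'atoms' optional",
    "(defaults to backbone N, CA, C, O)."
  ],
  "mortalin": {
    "nbd-lobe-IA": {"chain": "A", "ranges": [[46, 85], [162, 234]]},
    "nbd-lobe-IB": {"chain": "A", "ranges": [[86, 161]]},
    "nbd-lobe-IIA": {"chain": "A", "ranges": [[235, 274], [353, 429]]},
    "nbd-lobe-IIB": {"chain": "A", "ranges": [[275, 352]]},
    "iib-inward-helix": {"chain": "A", "ranges": [[290, 310]]},
    "sbd-beta": {"chain": "A", "ranges": [[440, 555]]},
    "sbd-alpha-lid": {"chain": "A", "ranges": [[556, 639]]}
  },
  "grpel1": {
    "stalk-B": {"chain": "B", "ranges": [[40, 138]]},
    "beta-wing-B": {"chain": "B", "ranges": [[160, 217]]}
  }
}
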