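{
  "_comment": "UvrD subdomain residue ranges derived from the closed-state crystal structure annotation (RecA-like motor domains 1A/2A with 1B/2B insertions). Override with your own JSON for other proteins.",
  "1A": [[1, 85], [216, 280]],
  "1B": [[86, 215]],
  "2A": [[281, 377], [551, 647]],
  "2B": [[378, 550]]
}
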