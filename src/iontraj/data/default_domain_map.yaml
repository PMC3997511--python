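# Default N/P/A/TM residue-range partition (author numbering).
# This is a documented repository default for a ~994-residue P-type ATPase;
# it is NOT claimed to reproduce any published partition exactly.
domains:
  N: [[360, 600]]
  P: [[330, 359], [601, 739]]
  A: [[1, 43], [124, 235]]
  TM: [[44, 123], [236, 329], [740, 994]]
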