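{
  "polarity": {
    "polar": ["S", "T", "N", "Q", "Y", "C", "D", "E", "K", "R", "H"],
    "nonpolar": ["G", "A", "V", "L", "I", "P", "F", "M", "W"]
  },
  "charge": {
    "positive": ["R", "K", "H"],
    "negative": ["D", "E"]
  },
  "aromatic": ["F", "W", "Y"],
  "codon_counts": {
    "L": 6, "R": 6, "S": 6,
    "A": 4, "G": 4, "P": 4, "T": 4, "V": 4,
    "I": 3,
    "C": 2, "D": 2, "E": 2, "F": 2, "H": 2, "K": 2, "N": 2, "Q": 2, "Y": 2,
    "M": 1, "W": 1
  },
  "volume_a3": {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1,
    "P": 112.7, "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0,
    "Q": 143.8, "H": 153.2, "M": 162.9, "I": 166.7, "L": 166.7,
    "K": 168.6, "R": 173.4, "F": 189.9, "Y": 193.6, "W": 227.8
  }
}
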