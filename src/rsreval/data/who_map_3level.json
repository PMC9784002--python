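{
 "High": {
  "High,High": "A",
  "High,Medium": "B",
  "High,Low": "B",
  "Medium,High": "E",
  "Medium,Medium": "F",
  "Medium,Low": "B",
  "Low,High": "E",
  "Low,Medium": "E",
  "Low,Low": "F"
 },
 "Medium": {
  "High,High": "C",
  "High,Medium": "D",
  "High,Low": "B",
  "Medium,High": "G",
  "Medium,Medium": "A",
  "Medium,Low": "B",
  "Low,High": "G",
  "Low,Medium": "E",
  "Low,Low": "F"
 },
 "Low": {
  "High,High": "C",
  "High,Medium": "D",
  "High,Low": "D",
  "Medium,High": "G",
  "Medium,Medium": "C",
  "Medium,Low": "D",
  "Low,High": "G",
  "Low,Medium": "G",
  "Low,Low": "H"
 }
}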